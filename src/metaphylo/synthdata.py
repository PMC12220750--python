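"""Synthetic metabarcoding communities with planted intraspecific structure.

The generator emulates the statistical shape of a denoised COI ESV table from
a regional stream-monitoring survey:

* several species whose amplicon sequences are far apart (>= 2x the OTU
  threshold by default), each carrying 1–5 haplotypes that differ by 1–3
  substitutions;
* haplotype occurrence structured by geographic region — each haplotype is,
  with probability ``structure_strength``, private to one region (spread
  round-robin across regions within a species so structured species span
  regions), otherwise shared by all regions;
* three field replicates per sample with overdispersed (negative binomial)
  read depths;
* rare spurious one-off variants with low read counts that the quality
  filters are expected to remove;
* sample coordinates scattered around well-separated region centroids inside
  a Rocky-Mountain-like bounding box (lon -118..-113, lat 49..52).

Randomness is split into two streams derived from the seed: a *structure*
stream (species sizes, occupancy, coordinates, depths) and a *sequence*
stream (nucleotide draws).  Two configs differing only in amplicon name and
length therefore share identical planted occupancy — the device used for
cross-amplicon consistency experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_io import EsvRecord, SampleInfo

__all__ = ["SynthConfig", "SynthTruth", "mutate_sequence", "generate_dataset"]

_BASES = np.array(list("ACGT"))
_BBOX = {"lon_min": -118.0, "lon_max": -113.0, "lat_min": 49.0, "lat_max": 52.0}


@dataclass
class SynthConfig:
    """Parameters of the planted community; defaults are the study conditions."""

    n_regions: int = 4
    samples_per_region: int = 10
    n_species: int = 15
    haplotypes_per_species: tuple[int, int] = (1, 5)
    amplicon: str = "F230R"
    amplicon_length: int = 229
    interspecies_min_subs: int = 14  # 2x the d=7 OTU threshold for 229 nt
    intraspecies_subs: tuple[int, int] = (1, 3)
    structure_strength: float = 1.0
    community_structure: float = 0.0
    haplotype_home: str = "spread"  # "spread": round-robin within species; "iid": independent
    detection_prob: float = 0.9
    mean_depth: float = 300.0
    depth_dispersion: float = 5.0
    noise_esv_rate: float = 0.5
    replicate_count: int = 3
    assigned_fraction: float = 1.0
    coord_sigma: float = 0.08
    year: int = 2021
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_regions, self.samples_per_region, self.n_species,
               self.replicate_count, self.amplicon_length) <= 0:
            raise ValueError("counts must be positive")
        for p in (self.structure_strength, self.community_structure,
                  self.detection_prob, self.assigned_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.haplotypes_per_species[0] < 1:
            raise ValueError("need at least one haplotype per species")
        if self.haplotype_home not in ("spread", "iid"):
            raise ValueError("haplotype_home must be 'spread' or 'iid'")
        if self.intraspecies_subs[0] < 1:
            raise ValueError("intraspecific substitutions must be >= 1")
        if self.interspecies_min_subs > self.amplicon_length:
            raise ValueError("interspecies divergence exceeds amplicon length")


@dataclass
class SynthTruth:
    """Planted structure: what a perfect analysis should recover."""

    species_haplotypes: dict[str, list[str]]  # species -> esv_ids
    haplotype_sequences: dict[str, str]  # esv_id -> sequence
    haplotype_regions: dict[str, list[str]]  # esv_id -> regions where it occurs
    region_samples: dict[str, list[str]]
    noise_esvs: list[str] = field(default_factory=list)

    @property
    def n_species(self) -> int:
        return len(self.species_haplotypes)

    def region_labels(self) -> dict[str, str]:
        return {s: r for r, samples in self.region_samples.items() for s in samples}


def mutate_sequence(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    """Return a sequence at Hamming distance exactly n_subs from ``seq``."""
    if n_subs > len(seq):
        raise ValueError(f"cannot place {n_subs} substitutions in length {len(seq)}")
    if n_subs == 0:
        return seq
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    out = list(seq)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alternatives[rng.integers(3)]
    return "".join(out)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _base_sequences(cfg: SynthConfig, rng: np.random.Generator) -> list[str]:
    """Species base sequences pairwise >= interspecies_min_subs apart."""
    bases: list[str] = []
    for _ in range(cfg.n_species):
        for _attempt in range(200):
            cand = _random_sequence(cfg.amplicon_length, rng)
            if all(_hamming(cand, b) >= cfg.interspecies_min_subs for b in bases):
                bases.append(cand)
                break
        else:
            raise ValueError(
                "could not place species base sequences at the requested divergence"
            )
    return bases


def generate_dataset(
    cfg: SynthConfig,
) -> tuple[list[EsvRecord], list[SampleInfo], SynthTruth]:
    """Generate an ESV table, sample metadata, and the planted ground truth.

    Deterministic given ``cfg.seed``.  Noise ESVs are single-substitution
    shadows of true haplotypes planted with Poisson(5) reads in one random
    sample replicate; they are guaranteed under the 100-read total filter.
    """
    struct_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    seq_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))

    regions = [f"region_{i}" for i in range(cfg.n_regions)]

    # --- samples: Gaussian scatter around centroids on a line through the bbox
    centroid_lons = np.linspace(
        _BBOX["lon_min"] + 0.5, _BBOX["lon_max"] - 0.5, cfg.n_regions
    )
    centroid_lats = np.linspace(
        _BBOX["lat_min"] + 0.5, _BBOX["lat_max"] - 0.5, cfg.n_regions
    )
    samples: list[SampleInfo] = []
    region_samples: dict[str, list[str]] = {r: [] for r in regions}
    for r_idx, region in enumerate(regions):
        for s_idx in range(cfg.samples_per_region):
            sid = f"S{r_idx:02d}_{s_idx:02d}"
            lat = float(np.clip(
                centroid_lats[r_idx] + struct_rng.normal(0, cfg.coord_sigma),
                _BBOX["lat_min"], _BBOX["lat_max"],
            ))
            lon = float(np.clip(
                centroid_lons[r_idx] + struct_rng.normal(0, cfg.coord_sigma),
                _BBOX["lon_min"], _BBOX["lon_max"],
            ))
            samples.append(SampleInfo(sid, lat, lon, cfg.year, wetland=False))
            region_samples[region].append(sid)

    # --- haplotypes and their region occupancy
    # Species-level occupancy: with probability community_structure a species
    # is restricted to a contiguous block of regions (at least 2, so it can
    # still qualify for intraspecific analysis); otherwise it spans them all.
    # Haplotype-level structure then acts within the species' region set.
    lo, hi = cfg.haplotypes_per_species
    hap_counts = struct_rng.integers(lo, hi + 1, size=cfg.n_species)
    restricted_width = max(2, cfg.n_regions // 2)
    species_regions: list[list[str]] = []
    hap_private = []  # per species: bool per haplotype
    hap_home = []  # per species: home region (within the species set) per haplotype
    for sp_idx in range(cfg.n_species):
        if struct_rng.random() < cfg.community_structure and restricted_width < cfg.n_regions:
            start = int(struct_rng.integers(cfg.n_regions))
            sp_regs = [regions[(start + i) % cfg.n_regions] for i in range(restricted_width)]
        else:
            sp_regs = list(regions)
        species_regions.append(sp_regs)
        private = struct_rng.random(hap_counts[sp_idx]) < cfg.structure_strength
        if cfg.haplotype_home == "spread":
            # round-robin from a random offset: a species' private haplotypes
            # cover its region set evenly (species-coherent structure)
            offset = int(struct_rng.integers(len(sp_regs)))
            homes = [sp_regs[(offset + h) % len(sp_regs)] for h in range(hap_counts[sp_idx])]
        else:
            # homes independent of species membership: haplotype-community
            # structure without any species-attributable component
            homes = [sp_regs[int(struct_rng.integers(len(sp_regs)))]
                     for _ in range(hap_counts[sp_idx])]
        hap_private.append(private)
        hap_home.append(homes)

    # occupancy: sample x haplotype detection draws (structure stream)
    detect = {}
    for sp_idx in range(cfg.n_species):
        for h_idx in range(hap_counts[sp_idx]):
            if hap_private[sp_idx][h_idx]:
                occ_regions = [hap_home[sp_idx][h_idx]]
            else:
                occ_regions = list(species_regions[sp_idx])
            occupied = []
            for region in occ_regions:
                for sid in region_samples[region]:
                    if struct_rng.random() < cfg.detection_prob:
                        occupied.append(sid)
            detect[(sp_idx, h_idx)] = (occ_regions, occupied)

    # depth draws (structure stream): negative binomial, mean mean_depth,
    # dispersion depth_dispersion => p = r / (r + mu)
    r = cfg.depth_dispersion
    p_nb = r / (r + cfg.mean_depth)

    counts_for: dict[tuple[int, int], dict[tuple[str, str], int]] = {}
    for key, (_regs, occupied) in detect.items():
        cell_counts: dict[tuple[str, str], int] = {}
        for sid in occupied:
            for rep in range(1, cfg.replicate_count + 1):
                reads = int(struct_rng.negative_binomial(r, p_nb))
                if reads > 0:
                    cell_counts[(sid, str(rep))] = reads
        counts_for[key] = cell_counts

    # assignment flags (structure stream)
    assigned_flags = {
        key: struct_rng.random() < cfg.assigned_fraction for key in detect
    }
    sbp_draws = {key: float(struct_rng.uniform(0.8, 1.0)) for key in detect}

    # noise plan (structure stream): Poisson-many shadows of random haplotypes
    n_true = int(hap_counts.sum())
    n_noise = int(struct_rng.poisson(cfg.noise_esv_rate * n_true))
    flat_keys = [(s, h) for s in range(cfg.n_species) for h in range(hap_counts[s])]
    noise_parents = [flat_keys[struct_rng.integers(len(flat_keys))] for _ in range(n_noise)]
    noise_cells = []
    for _ in range(n_noise):
        sid = samples[struct_rng.integers(len(samples))].sample_id
        rep = str(1 + struct_rng.integers(cfg.replicate_count))
        reads = int(min(99, 1 + struct_rng.poisson(5.0)))
        noise_cells.append(((sid, rep), reads))

    # --- sequences (sequence stream only)
    bases = _base_sequences(cfg, seq_rng)
    k_lo, k_hi = cfg.intraspecies_subs
    hap_seqs: dict[tuple[int, int], str] = {}
    for sp_idx in range(cfg.n_species):
        existing = {bases[sp_idx]}
        for h_idx in range(hap_counts[sp_idx]):
            if h_idx == 0:
                hap_seqs[(sp_idx, 0)] = bases[sp_idx]
                continue
            for _attempt in range(200):
                k = int(seq_rng.integers(k_lo, k_hi + 1))
                cand = mutate_sequence(bases[sp_idx], k, seq_rng)
                if cand not in existing:
                    existing.add(cand)
                    hap_seqs[(sp_idx, h_idx)] = cand
                    break
            else:
                raise ValueError("could not generate distinct haplotypes")

    # --- assemble records and truth
    records: list[EsvRecord] = []
    truth = SynthTruth(
        species_haplotypes={},
        haplotype_sequences={},
        haplotype_regions={},
        region_samples=region_samples,
    )
    used_seqs = set(hap_seqs.values())
    for sp_idx in range(cfg.n_species):
        species = f"species_{sp_idx:03d}"
        truth.species_haplotypes[species] = []
        for h_idx in range(hap_counts[sp_idx]):
            esv_id = f"ESV_{sp_idx:03d}_{h_idx}"
            key = (sp_idx, h_idx)
            assigned = assigned_flags[key]
            records.append(
                EsvRecord(
                    esv_id=esv_id,
                    amplicon=cfg.amplicon,
                    sequence=hap_seqs[key],
                    counts=counts_for[key],
                    species=species if assigned else None,
                    sbp=sbp_draws[key] if assigned else None,
                )
            )
            truth.species_haplotypes[species].append(esv_id)
            truth.haplotype_sequences[esv_id] = hap_seqs[key]
            truth.haplotype_regions[esv_id] = detect[key][0]

    for i, (parent_key, (cell, reads)) in enumerate(zip(noise_parents, noise_cells)):
        for _attempt in range(200):
            cand = mutate_sequence(hap_seqs[parent_key], 1, seq_rng)
            if cand not in used_seqs:
                used_seqs.add(cand)
                break
        else:  # pragma: no cover - astronomically unlikely
            continue
        esv_id = f"NOISE_{i:03d}"
        records.append(
            EsvRecord(esv_id=esv_id, amplicon=cfg.amplicon, sequence=cand,
                      counts={cell: reads})
        )
        truth.noise_esvs.append(esv_id)

    return records, samples, truth
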