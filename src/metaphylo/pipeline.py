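"""End-to-end pipeline: table -> filters -> clustering -> matrices -> statistics.

Stage order follows the analysis flow: quality filtering, OTU clustering at
the ~3% threshold, the d-hierarchy with species-bound cluster search, region
grouping by k-means on coordinates, community Sørensen matrices per
representation (ESV / OTU / SBC), intraspecific mean matrices, scrambled
nulls, and the permutation-test battery.  Every run writes a machine-readable
manifest with parameters, seeds, and SHA-256 hashes of all outputs; a rerun
with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import betamatrix, core_io, permstats, qcfilter, sbcfind, scramblenull, swarmclust, synthdata

logger = logging.getLogger("metaphylo")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "filters": {"min_total_reads": 100, "min_replicate_reads": 5},
    "clustering": {"otu_percent": 0.03},
    "sbc": {"sbp_threshold": 0.8, "selection": "widest"},
    "regions": {"k": 4, "n_starts": 10, "stability_pairs": 1000, "k_range": [2, 20]},
    "intraspecific": {"min_haplotypes": 2, "min_regions": 2, "min_samples_per_region": 3},
    "stats": {"permutations": 9999, "alpha": 0.05},
    "null": {"scrambles": 1000},
}


def _merge(base: Mapping, override: Mapping) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), Mapping):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(config_path: str | Path) -> dict:
    with open(config_path) as fh:
        user = yaml.safe_load(fh) or {}
    if None in user:  # a bare `null:` key is YAML's null literal
        user["null"] = user.pop(None)
    cfg = _merge(DEFAULT_CONFIG, user)
    if "synthdata" in cfg and "inputs" in cfg:
        raise ValueError("config must name either real inputs or a synthdata block, not both")
    if "synthdata" not in cfg and "inputs" not in cfg:
        raise ValueError("config needs an 'inputs' or 'synthdata' block")
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(cfg: dict):
    if "synthdata" in cfg:
        synth_kwargs = dict(cfg["synthdata"])
        synth_kwargs.setdefault("seed", cfg["seed"])
        for key in ("haplotypes_per_species", "intraspecies_subs"):
            if key in synth_kwargs:
                synth_kwargs[key] = tuple(synth_kwargs[key])
        scfg = synthdata.SynthConfig(**synth_kwargs)
        records, samples, truth = synthdata.generate_dataset(scfg)
        return records, samples, truth
    paths = cfg["inputs"]
    records = core_io.read_esv_table(
        paths["table"], paths["fasta"], paths.get("taxonomy"),
        amplicon=paths.get("amplicon", ""),
    )
    samples = core_io.read_sample_metadata(paths["metadata"])
    return records, samples, None


def run_pipeline(config_path: str | Path, out_dir: str | Path) -> Path:
    """Execute every stage; returns the run directory containing all outputs."""
    cfg = load_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    rng = np.random.default_rng(seed)
    manifest: dict[str, Any] = {"config": cfg, "stages": {}, "outputs": {}}

    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(cfg, out, seed, rng, manifest)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(cfg, out: Path, seed: int, rng, manifest) -> Path:
    records, samples, truth = _load_inputs(cfg)
    logger.info("loaded %d ESVs, %d samples", len(records), len(samples))
    manifest["stages"]["load"] = {"n_esvs": len(records), "n_samples": len(samples)}

    # --- quality filters
    flog = qcfilter.FilterLog()
    sample_ids = [s.sample_id for s in samples]
    kept, presence = qcfilter.run_filter_chain(
        records,
        min_total=cfg["filters"]["min_total_reads"],
        min_replicate=cfg["filters"]["min_replicate_reads"],
        samples=sample_ids,
        log=flog,
    )
    for esv, reason in flog.removed:
        logger.info("removed %s (%s)", esv, reason)
    manifest["stages"]["filter"] = {
        "n_retained": len(kept),
        "n_removed": len(flog.removed),
    }

    # --- region groups (k-means on coordinates, wetlands out)
    non_wetland = [s for s in samples if not s.wetland]
    region_cfg = cfg["regions"]
    assignment = permstats.kmeans_regions(
        samples, k=region_cfg["k"], n_starts=region_cfg["n_starts"],
        seed=int(rng.integers(2**31)),
    )
    regions = assignment.labels
    presence = presence.restrict_samples([s.sample_id for s in non_wetland])
    manifest["stages"]["regions"] = {"k": assignment.k, "wss": assignment.wss}

    # --- clustering
    if not kept:
        raise RuntimeError("stage clustering failed: no ESVs survived filtering")
    modal_len = max(len(r.sequence) for r in kept)
    otu_d = swarmclust.select_otu_d(modal_len, cfg["clustering"]["otu_percent"])
    otus = swarmclust.cluster_at_d(kept, otu_d)
    hierarchy = swarmclust.build_hierarchy(kept)
    assign = sbcfind.assign_species(kept, threshold=cfg["sbc"]["sbp_threshold"])
    sbcs = sbcfind.find_sbcs(hierarchy, assign, selection=cfg["sbc"]["selection"])
    manifest["stages"]["cluster"] = {
        "otu_d": otu_d,
        "n_otus": otus.n_clusters,
        "d_single": hierarchy.d_single,
        **sbcfind.sbc_summary(assign, sbcs),
    }
    logger.info("OTU d=%d -> %d OTUs; %d SBCs", otu_d, otus.n_clusters, len(sbcs))

    # --- community matrices
    otu_presence = swarmclust.merge_presence_by_clusters(presence, otus.clusters)
    sbc_presence = sbcfind.merge_presence_by_sbc(presence, sbcs)
    community = {
        "esv": betamatrix.sorensen_matrix(presence),
        "otu": betamatrix.sorensen_matrix(otu_presence),
        "sbc": betamatrix.sorensen_matrix(sbc_presence),
    }
    for name, matrix in community.items():
        core_io.write_dist_matrix(betamatrix.complete_matrix(matrix), out / f"community_{name}.tsv")

    # --- intraspecific mean matrices (OTU and SBC representations)
    intra_cfg = cfg["intraspecific"]
    intraspecific = {}
    cluster_sets = {
        "otu": otus.clusters,
        "sbc": {r.species: sorted(r.members) for r in sbcs},
    }
    per_cluster_store: dict[str, list] = {}
    for rep, clusters in cluster_sets.items():
        chosen = betamatrix.select_intraspecific_clusters(
            clusters, presence, regions,
            min_haplotypes=intra_cfg["min_haplotypes"],
            min_regions=intra_cfg["min_regions"],
            min_samples_per_region=intra_cfg["min_samples_per_region"],
        )
        subset = {c: clusters[c] for c in chosen}
        per_cluster = betamatrix.per_cluster_matrices(presence, subset)
        per_cluster_store[rep] = per_cluster
        if per_cluster:
            mean = betamatrix.mean_dissimilarity([m for _, m in per_cluster])
            completed = betamatrix.complete_matrix(mean)
            intraspecific[rep] = (subset, completed)
            core_io.write_dist_matrix(completed, out / f"intraspecific_{rep}.tsv")
        manifest["stages"][f"intraspecific_{rep}"] = {
            "n_clusters": len(chosen),
            "n_samples": len(intraspecific[rep][1]) if rep in intraspecific else 0,
        }

    # --- statistics
    stats_cfg = cfg["stats"]
    n_perm = stats_cfg["permutations"]
    report: dict[str, Any] = {}
    for name, matrix in community.items():
        m = betamatrix.complete_matrix(matrix)
        res = permstats.permanova(m, regions, n_perm=n_perm, seed=int(rng.integers(2**31)))
        disp = permstats.beta_dispersion(m, regions, n_perm=n_perm, seed=int(rng.integers(2**31)))
        report[f"community_{name}"] = {
            "pseudo_F": res.pseudo_F, "p": res.p,
            "dispersion_F": disp.F, "dispersion_p": disp.p,
        }
    for rep, (subset, matrix) in intraspecific.items():
        counts: dict[str, int] = {}
        for s in matrix.ids:
            counts[regions[s]] = counts.get(regions[s], 0) + 1
        testable = [s for s in matrix.ids if counts[regions[s]] >= 2]
        res = permstats.permanova(
            matrix.submatrix(testable), regions, n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        report[f"intraspecific_{rep}"] = {"pseudo_F": res.pseudo_F, "p": res.p}
        percluster = permstats.per_cluster_permanova(
            per_cluster_store[rep], regions, n_perm=n_perm,
            seed=int(rng.integers(2**31)), alpha=stats_cfg["alpha"],
        )
        report[f"per_cluster_{rep}"] = {
            "n_tested": percluster["n_tested"],
            "n_significant": percluster["n_significant"],
            "fraction_significant": percluster["fraction_significant"],
        }

    # Mantel between geographic distance and dissimilarity, per region group
    geo = permstats.geodesic_matrix(non_wetland)
    for rep, (subset, matrix) in intraspecific.items():
        mantel_by_region = {}
        for region in sorted(set(regions.values())):
            ids = [s for s in matrix.ids if regions[s] == region]
            if len(ids) < 4:
                continue
            res = permstats.mantel_spearman(
                matrix.submatrix(ids), geo.submatrix(ids),
                n_perm=n_perm, seed=int(rng.integers(2**31)),
            )
            mantel_by_region[region] = {"rho": res.rho, "p": res.p}
        report[f"mantel_{rep}"] = mantel_by_region

    # --- scrambled null
    null_cfg = cfg["null"]
    for rep, (subset, matrix) in intraspecific.items():
        if not subset:
            continue
        null = scramblenull.null_statistic_distribution(
            presence, subset, regions=regions, statistic="pseudo_F",
            n_reps=null_cfg["scrambles"], seed=int(rng.integers(2**31)),
            observed_samples=matrix.ids,
        )
        observed = report[f"intraspecific_{rep}"]["pseudo_F"]
        np.savetxt(out / f"null_pseudoF_{rep}.tsv", null.values, fmt="%.10g")
        report[f"null_{rep}"] = {
            "observed_pseudo_F": observed,
            "percentile": null.percentile_of(observed),
            "n_excluded": null.n_excluded,
        }

    with open(out / "stats.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    manifest["stages"]["stats"] = {"written": "stats.json"}

    for path in sorted(out.glob("*.tsv")) + [out / "stats.json"]:
        manifest["outputs"][path.name] = _sha256(path)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    logger.info("run complete: %s", out)
    return out
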