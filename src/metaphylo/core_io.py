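"""Domain data model and readers/writers for the pipeline's external formats.

The pipeline's input currency is a table of exact sequence variants (ESVs):
denoised amplicon sequences with read counts per sample x field-replicate and
an optional species assignment with a species-level bootstrap proportion
(sBP).  Sample metadata carries WGS84 coordinates, collection year and a
wetland flag.  Dissimilarity matrices are square, symmetric, in [0, 1], and
may contain missing pairs (serialized as ``NA``).

Formats are plain text: FASTA for sequences (via Biopython), long-format TSV
for counts (one row per ESV x sample x replicate with reads > 0), TSV for
taxonomy and matrices, CSV for sample metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "EsvRecord",
    "SampleInfo",
    "PresenceMatrix",
    "DistMatrix",
    "read_esv_table",
    "write_esv_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_dist_matrix",
    "write_dist_matrix",
]

_DNA = set("ACGT")


@dataclass
class EsvRecord:
    """One exact sequence variant with its counts and optional taxonomy.

    ``counts`` maps (sample_id, replicate_id) to a non-negative read count;
    absent keys mean zero reads.  ``species``/``sbp`` are both present or
    both absent: an sBP only makes sense alongside the assignment it scores.
    """

    esv_id: str
    amplicon: str
    sequence: str
    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    species: str | None = None
    sbp: float | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"ESV {self.esv_id}: empty sequence")
        bad = set(self.sequence) - _DNA
        if bad:
            raise ValueError(f"ESV {self.esv_id}: non-ACGT characters {sorted(bad)}")
        for key, reads in self.counts.items():
            if reads < 0:
                raise ValueError(f"ESV {self.esv_id}: negative reads at {key}")
        if (self.species is None) != (self.sbp is None):
            raise ValueError(f"ESV {self.esv_id}: species and sbp must come together")
        if self.sbp is not None and not 0.0 <= self.sbp <= 1.0:
            raise ValueError(f"ESV {self.esv_id}: sbp {self.sbp} outside [0, 1]")

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class SampleInfo:
    """Sampling-site metadata: WGS84 coordinates, year, wetland designation."""

    sample_id: str
    lat: float
    lon: float
    year: int
    wetland: bool = False

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"sample {self.sample_id}: latitude {self.lat} out of range")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"sample {self.sample_id}: longitude {self.lon} out of range")


class PresenceMatrix:
    """Boolean samples x features incidence matrix.

    Thin wrapper over a boolean :class:`pandas.DataFrame` (index = sample
    ids, columns = feature ids) that enforces unique ids on both axes.
    """

    def __init__(self, df: pd.DataFrame):
        if df.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if df.columns.has_duplicates:
            raise ValueError("duplicate feature ids")
        self.df = df.astype(bool)

    @property
    def samples(self) -> list[str]:
        return list(self.df.index)

    @property
    def features(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    def restrict_samples(self, sample_ids: Sequence[str]) -> "PresenceMatrix":
        return PresenceMatrix(self.df.loc[list(sample_ids)])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PresenceMatrix) and self.df.equals(other.df)

    def __repr__(self) -> str:  # pragma: no cover
        return f"PresenceMatrix({len(self.samples)} samples x {len(self.features)} features)"


class DistMatrix:
    """Symmetric sample x sample dissimilarity matrix with optional missing pairs.

    Missing entries are ``NaN``; missingness must be symmetric and the
    diagonal, where defined, must be zero.  Values live in [0, 1] for
    Sørensen matrices but the container itself only requires symmetry, so it
    also holds geodesic distance matrices (``metric="geodesic_m"``).
    """

    def __init__(self, ids: Sequence[str], values: np.ndarray, metric: str = "sorensen"):
        ids = list(ids)
        values = np.asarray(values, dtype=float)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
        if values.shape != (len(ids), len(ids)):
            raise ValueError(f"matrix shape {values.shape} does not match {len(ids)} ids")
        mask = np.isnan(values)
        if not np.array_equal(mask, mask.T):
            raise ValueError("missingness is not symmetric")
        defined = ~mask
        if not np.allclose(values[defined], values.T[defined], rtol=0, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        diag = np.diagonal(values)
        if np.any(~np.isnan(diag) & (diag != 0.0)):
            raise ValueError("diagonal must be zero where defined")
        self.ids = ids
        self.values = values
        self.metric = metric

    # -- basic queries -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_missing_pairs(self) -> int:
        iu = np.triu_indices(len(self.ids), k=1)
        return int(np.isnan(self.values[iu]).sum())

    def is_complete(self) -> bool:
        return self.n_missing_pairs == 0

    def condensed(self) -> np.ndarray:
        """Off-diagonal upper-triangle values in row-major (i < j) order."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def submatrix(self, ids: Sequence[str]) -> "DistMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistMatrix(list(ids), self.values[np.ix_(idx, idx)], self.metric)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DistMatrix):
            return NotImplemented
        if self.ids != other.ids:
            return False
        a, b = self.values, other.values
        return np.array_equal(np.isnan(a), np.isnan(b)) and np.allclose(
            a[~np.isnan(a)], b[~np.isnan(b)], rtol=1e-12, atol=0
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"DistMatrix({len(self.ids)} samples, metric={self.metric!r})"


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_esv_table(
    table_path: str | Path,
    fasta_path: str | Path,
    taxonomy_path: str | Path | None = None,
    amplicon: str = "",
) -> list[EsvRecord]:
    """Assemble :class:`EsvRecord` objects from counts TSV + FASTA (+ taxonomy TSV).

    The counts TSV is long format with columns ``esv_id, sample_id,
    replicate_id, reads``; rows absent from the table mean zero reads.
    Every ESV must have a sequence in the FASTA; taxonomy rows are optional
    per ESV (a missing row leaves the species unassigned).
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicated esv_id in FASTA: {rec.id}")
        seqs[rec.id] = str(rec.seq).upper()

    taxonomy: dict[str, tuple[str, float]] = {}
    if taxonomy_path is not None:
        tax = pd.read_csv(taxonomy_path, sep="\t", dtype={"esv_id": str, "species": str})
        for row in tax.itertuples(index=False):
            if isinstance(row.species, str) and row.species:
                taxonomy[row.esv_id] = (row.species, float(row.sbp))

    table = pd.read_csv(
        table_path,
        sep="\t",
        dtype={"esv_id": str, "sample_id": str, "replicate_id": str, "reads": int},
    )
    counts: dict[str, dict[tuple[str, str], int]] = {e: {} for e in seqs}
    for row in table.itertuples(index=False):
        if row.esv_id not in seqs:
            raise ValueError(f"count row references unknown ESV {row.esv_id}")
        if row.reads < 0:
            raise ValueError(f"negative read count for ESV {row.esv_id}")
        counts[row.esv_id][(row.sample_id, row.replicate_id)] = int(row.reads)

    records = []
    for esv_id, seq in seqs.items():
        species, sbp = taxonomy.get(esv_id, (None, None))
        records.append(
            EsvRecord(
                esv_id=esv_id,
                amplicon=amplicon,
                sequence=seq,
                counts=counts[esv_id],
                species=species,
                sbp=sbp,
            )
        )
    return records


def write_esv_table(
    records: Iterable[EsvRecord],
    table_path: str | Path,
    fasta_path: str | Path,
    taxonomy_path: str | Path | None = None,
) -> None:
    """Write records to the long-format TSV + FASTA (+ taxonomy TSV) trio."""
    records = list(records)
    rows = []
    for r in records:
        for (sample, rep), reads in sorted(r.counts.items()):
            if reads > 0:
                rows.append((r.esv_id, sample, rep, reads))
    pd.DataFrame(rows, columns=["esv_id", "sample_id", "replicate_id", "reads"]).to_csv(
        table_path, sep="\t", index=False
    )
    with open(fasta_path, "w") as fh:
        for r in records:
            fh.write(f">{r.esv_id}\n{r.sequence}\n")
    if taxonomy_path is not None:
        tax_rows = [
            (r.esv_id, r.species, r.sbp) for r in records if r.species is not None
        ]
        pd.DataFrame(tax_rows, columns=["esv_id", "species", "sbp"]).to_csv(
            taxonomy_path, sep="\t", index=False
        )


def read_sample_metadata(path: str | Path) -> list[SampleInfo]:
    df = pd.read_csv(path, dtype={"sample_id": str})
    return [
        SampleInfo(
            sample_id=row.sample_id,
            lat=float(row.lat),
            lon=float(row.lon),
            year=int(row.year),
            wetland=bool(row.wetland),
        )
        for row in df.itertuples(index=False)
    ]


def write_sample_metadata(samples: Iterable[SampleInfo], path: str | Path) -> None:
    pd.DataFrame(
        [(s.sample_id, s.lat, s.lon, s.year, s.wetland) for s in samples],
        columns=["sample_id", "lat", "lon", "year", "wetland"],
    ).to_csv(path, index=False)


def write_dist_matrix(m: DistMatrix, path: str | Path) -> None:
    """TSV with a header row/column of sample ids; missing pairs as ``NA``."""
    df = pd.DataFrame(m.values, index=m.ids, columns=m.ids)
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g", index_label=m.metric)


def read_dist_matrix(path: str | Path) -> DistMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    metric = df.index.name or "sorensen"
    ids = [str(i) for i in df.index]
    if ids != [str(c) for c in df.columns]:
        raise ValueError("row and column sample ids differ")
    return DistMatrix(ids, df.to_numpy(dtype=float), metric=metric)


def presence_to_frame(m: PresenceMatrix) -> pd.DataFrame:
    """Integer 0/1 view of a presence matrix (for TSV export)."""
    return m.df.astype(int)
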