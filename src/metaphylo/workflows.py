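"""Convenience compositions of the pipeline stages used in analyses and tests."""

from __future__ import annotations

from typing import Mapping, Sequence

from .betamatrix import (
    complete_matrix,
    mean_dissimilarity,
    per_cluster_matrices,
    select_intraspecific_clusters,
)
from .core_io import DistMatrix, EsvRecord, PresenceMatrix, SampleInfo
from .permstats import PermanovaResult, permanova
from .qcfilter import run_filter_chain
from .swarmclust import cluster_at_d, select_otu_d
from .synthdata import SynthConfig, SynthTruth, generate_dataset


def simulate_filtered(cfg: SynthConfig):
    """Generate a synthetic dataset and push it through the QC chain.

    Returns (records, presence, samples, truth).
    """
    records, samples, truth = generate_dataset(cfg)
    kept, presence = run_filter_chain(records, samples=[s.sample_id for s in samples])
    return kept, presence, samples, truth


def otu_clusters(records: Sequence[EsvRecord], amplicon_length: int | None = None):
    """Cluster records at the d closest to 3% of the amplicon length."""
    if amplicon_length is None:
        amplicon_length = max(len(r.sequence) for r in records)
    return cluster_at_d(records, select_otu_d(amplicon_length))


def intraspecific_mean_matrix(
    presence: PresenceMatrix,
    clusters: Mapping[str, Sequence[str]],
    regions: Mapping[str, str],
    restrict_to_occupied: bool = True,
) -> tuple[DistMatrix, dict[str, list[str]]]:
    """Select qualifying clusters and build the completed mean matrix.

    Returns (completed mean matrix, selected clusters).  Raises ValueError
    when no cluster qualifies.
    """
    chosen = select_intraspecific_clusters(clusters, presence, regions)
    if not chosen:
        raise ValueError("no cluster qualifies for intraspecific analysis")
    subset = {c: list(clusters[c]) for c in chosen}
    per_cluster = per_cluster_matrices(
        presence, subset, restrict_to_occupied=restrict_to_occupied
    )
    mean = mean_dissimilarity([m for _, m in per_cluster])
    return complete_matrix(mean), subset


def permanova_on_regions(
    matrix: DistMatrix,
    regions: Mapping[str, str],
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """PERMANOVA against region groups, dropping groups left with < 2 samples."""
    counts: dict[str, int] = {}
    for s in matrix.ids:
        counts[regions[s]] = counts.get(regions[s], 0) + 1
    keep = [s for s in matrix.ids if counts[regions[s]] >= 2]
    if len({regions[s] for s in keep}) < 2:
        raise ValueError("fewer than 2 testable region groups")
    return permanova(matrix.submatrix(keep), regions, n_perm=n_perm, seed=seed)
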