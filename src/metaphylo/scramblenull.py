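"""Scrambled-cluster null model for the intraspecific mean matrix.

The intraspecific mean dissimilarity matrix averages many low-dimensional
per-cluster comparisons, which changes its scale relative to the
high-dimensional community matrix.  To ask whether an observed region
separation reflects genuine intraspecific signal rather than this averaging
construction, ESVs are shuffled among the selected clusters while preserving
the number of clusters and every cluster's size.  Scrambled clusters carry no
species identity, so their mean matrices sample community-level signal with
the intraspecific construction's dimensionality.

Each scramble rebuilds the mean matrix by the same method as the observed one
(per-cluster Sørensen, pairwise mean, greedy completion, restriction to the
observed intraspecific sample set) and records the requested statistic:
either the PERMANOVA pseudo-F against region groups, or the Mantel–Spearman
correlation with geodesic distance within one region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .betamatrix import complete_matrix, mean_dissimilarity, per_cluster_matrices
from .core_io import DistMatrix, PresenceMatrix
from .permstats import pseudo_f, _spearman_condensed

__all__ = ["NullDistribution", "scramble_clusters", "null_statistic_distribution"]

DEFAULT_SCRAMBLES = 1000


@dataclass
class NullDistribution:
    statistic: Literal["pseudo_F", "mantel_rho"]
    values: np.ndarray
    n_reps: int
    seed: int | None
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if len(self.values) + self.n_excluded != self.n_reps:
            raise ValueError("values + excluded reps must account for every rep")

    def percentile_of(self, observed: float) -> float:
        """Percentile of the observed value within the null (midrank)."""
        v = self.values
        below = np.sum(v < observed) + 0.5 * np.sum(v == observed)
        return 100.0 * below / len(v)


def scramble_clusters(
    clusters: Mapping[str, Sequence[str]], rng: np.random.Generator
) -> dict[str, list[str]]:
    """Uniformly permute member ESVs into the size-preserved cluster slots.

    The output keeps every cluster id and size; only membership moves.  Each
    labeled assignment of ESVs to slots is equally likely.
    """
    ids = sorted(clusters)
    all_members: list[str] = []
    for cid in ids:
        all_members.extend(clusters[cid])
    if len(set(all_members)) != len(all_members):
        raise ValueError("clusters are not disjoint")
    pool = list(rng.permutation(all_members))
    out: dict[str, list[str]] = {}
    pos = 0
    for cid in ids:
        size = len(clusters[cid])
        out[cid] = pool[pos : pos + size]
        pos += size
    return out


def _mean_matrix_for(
    esv_presence: PresenceMatrix,
    clusters: Mapping[str, Sequence[str]],
    restrict_to: Sequence[str] | None,
    restrict_to_occupied: bool = True,
) -> DistMatrix:
    per_cluster = per_cluster_matrices(
        esv_presence, clusters, restrict_to_occupied=restrict_to_occupied
    )
    mean = mean_dissimilarity([m for _, m in per_cluster])
    completed = complete_matrix(mean)
    if restrict_to is not None:
        keep = [s for s in completed.ids if s in set(restrict_to)]
        completed = completed.submatrix(keep)
    return completed


def null_statistic_distribution(
    esv_presence: PresenceMatrix,
    clusters: Mapping[str, Sequence[str]],
    regions: Mapping[str, str] | None = None,
    geo: DistMatrix | None = None,
    statistic: Literal["pseudo_F", "mantel_rho"] = "pseudo_F",
    n_reps: int = DEFAULT_SCRAMBLES,
    seed: int | None = None,
    observed_samples: Sequence[str] | None = None,
    restrict_to_occupied: bool = True,
) -> NullDistribution:
    """Null distribution of a statistic over scrambled-cluster mean matrices.

    Per rep: scramble -> per-cluster matrices -> mean -> completion ->
    restriction to ``observed_samples`` (the observed intraspecific sample
    set) -> statistic.  ``pseudo_F`` needs ``regions``; ``mantel_rho``
    needs ``geo`` (Spearman correlation of the condensed matrices, no
    permutation test per rep).  Reps whose completed matrix no longer
    supports the statistic (fewer than 2 samples in 2 groups, or < 3 samples)
    are excluded and counted.

    A master seed spawns one child seed per rep, so any rep can be reproduced
    in isolation.
    """
    if statistic == "pseudo_F" and regions is None:
        raise ValueError("pseudo_F requires region labels")
    if statistic == "mantel_rho" and geo is None:
        raise ValueError("mantel_rho requires a geodesic matrix")
    master = np.random.SeedSequence(seed)
    child_seeds = master.spawn(n_reps)
    universe = set(esv_presence.features)
    sizes = sorted(len(m) for m in clusters.values())
    values = []
    n_excluded = 0
    for child in child_seeds:
        rng = np.random.default_rng(child)
        scrambled = scramble_clusters(clusters, rng)
        assert sorted(len(m) for m in scrambled.values()) == sizes
        assert set(e for m in scrambled.values() for e in m) <= universe
        m = _mean_matrix_for(
            esv_presence, scrambled, observed_samples,
            restrict_to_occupied=restrict_to_occupied,
        )
        try:
            if statistic == "pseudo_F":
                counts: dict[str, int] = {}
                for s in m.ids:
                    counts[regions[s]] = counts.get(regions[s], 0) + 1
                ok = sum(1 for c in counts.values() if c >= 2) >= 2
                if not ok:
                    raise ValueError("insufficient groups after completion")
                keep = [s for s in m.ids if counts[regions[s]] >= 2]
                values.append(pseudo_f(m.submatrix(keep), regions))
            else:
                common = [s for s in m.ids if s in set(geo.ids)]
                if len(common) < 3:
                    raise ValueError("too few samples after completion")
                sub1 = m.submatrix(common)
                sub2 = geo.submatrix(common)
                iu = np.triu_indices(len(common), k=1)
                values.append(_spearman_condensed(sub1.values[iu], sub2.values[iu]))
        except ValueError:
            n_excluded += 1
    return NullDistribution(
        statistic=statistic,
        values=np.asarray(values, dtype=float),
        n_reps=n_reps,
        seed=seed,
        n_excluded=n_excluded,
    )
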