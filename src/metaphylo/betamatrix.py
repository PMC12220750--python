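"""Sørensen dissimilarity matrices at community and intraspecific level.

Community level: incidence-based Sørensen over all features of a presence
matrix.  Intraspecific level: one Sørensen matrix per species-proxy cluster,
computed only over samples where the cluster occurs, then averaged pair-wise
across clusters into a mean dissimilarity matrix.  Sample pairs never
co-observed in any cluster stay missing and are resolved by greedily removing
the sample with the most missing pairs.

For samples i, j with a shared present features and b, c features unique to
each, beta_sor = (b + c) / (2a + b + c); a pair where both samples are empty
is undefined (missing).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .core_io import DistMatrix, PresenceMatrix

__all__ = [
    "sorensen_matrix",
    "per_cluster_matrices",
    "select_intraspecific_clusters",
    "mean_dissimilarity",
    "complete_matrix",
]

MIN_HAPLOTYPES = 2
MIN_REGION_GROUPS = 2
MIN_SAMPLES_PER_REGION = 3


def sorensen_matrix(presence: PresenceMatrix, metric: str = "sorensen") -> DistMatrix:
    """Pairwise Sørensen dissimilarity over the feature columns.

    Vectorized via boolean matrix products: a = X X', row sums give a+b and
    a+c.  Pairs where both samples have zero present features are missing.
    """
    x = presence.values.astype(np.int64)
    a = x @ x.T
    richness = x.sum(axis=1)
    denom = richness[:, None] + richness[None, :]  # 2a + b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        values = (denom - 2 * a) / denom
    values[denom == 0] = np.nan
    np.fill_diagonal(values, np.where(richness > 0, 0.0, np.nan))
    return DistMatrix(presence.samples, values, metric=metric)


def per_cluster_matrices(
    esv_presence: PresenceMatrix,
    clusters: Mapping[str, Sequence[str]],
    restrict_to_occupied: bool = True,
) -> list[tuple[str, DistMatrix]]:
    """One Sørensen matrix per cluster on that cluster's member ESV columns.

    By default each matrix is restricted to samples where at least one member
    ESV is present: dissimilarity to a sample lacking the cluster entirely
    would be identically 1 and would conflate occupancy with intraspecific
    variation.  This restriction is what produces missing sample pairs in the
    mean matrix.  With ``restrict_to_occupied=False`` all samples enter and
    cluster-free samples contribute occupancy (community-level) signal.
    A cluster observed in fewer than 2 samples yields a pairless matrix and
    contributes nothing downstream.
    """
    out = []
    for cid in sorted(clusters):
        members = [m for m in clusters[cid] if m in esv_presence.df.columns]
        missing = set(clusters[cid]) - set(members)
        if missing:
            raise ValueError(f"cluster {cid}: members absent from presence matrix")
        sub = esv_presence.df[members]
        if restrict_to_occupied:
            sub = sub.loc[sub.index[sub.any(axis=1)]]
        out.append((cid, sorensen_matrix(PresenceMatrix(sub))))
    return out


def select_intraspecific_clusters(
    clusters: Mapping[str, Sequence[str]],
    esv_presence: PresenceMatrix,
    regions: Mapping[str, str],
    min_haplotypes: int = MIN_HAPLOTYPES,
    min_regions: int = MIN_REGION_GROUPS,
    min_samples_per_region: int = MIN_SAMPLES_PER_REGION,
) -> list[str]:
    """Clusters eligible for intraspecific analysis.

    A cluster qualifies when it holds >= 2 haplotypes (member ESVs) and is
    present in at least 3 samples in each of at least 2 region groups — i.e.
    in a minimum of 6 samples.  Region labels must cover every sample of the
    presence matrix.
    """
    unlabelled = set(esv_presence.samples) - set(regions)
    if unlabelled:
        raise ValueError(f"samples without a region label: {sorted(unlabelled)[:5]}")
    chosen = []
    for cid in sorted(clusters):
        members = [m for m in clusters[cid] if m in esv_presence.df.columns]
        if len(members) < min_haplotypes:
            continue
        occupied = esv_presence.df[members].any(axis=1)
        counts: dict[str, int] = {}
        for sample in esv_presence.df.index[occupied]:
            counts[regions[sample]] = counts.get(regions[sample], 0) + 1
        n_ok = sum(1 for c in counts.values() if c >= min_samples_per_region)
        if n_ok >= min_regions:
            chosen.append(cid)
    return chosen


def mean_dissimilarity(
    matrices: Sequence[DistMatrix], universe: Sequence[str] | None = None
) -> DistMatrix:
    """Entrywise mean over the matrices in which each sample pair is defined.

    ``universe`` fixes the output sample set (default: sorted union of all
    input ids).  A pair defined in no matrix remains missing.
    """
    matrices = list(matrices)
    if not matrices:
        raise ValueError("no matrices to average")
    if universe is None:
        universe = sorted({i for m in matrices for i in m.ids})
    universe = list(universe)
    n = len(universe)
    index = {s: i for i, s in enumerate(universe)}
    total = np.zeros((n, n))
    count = np.zeros((n, n), dtype=int)
    for m in matrices:
        idx = np.array([index[i] for i in m.ids if i in index])
        keep = [k for k, i in enumerate(m.ids) if i in index]
        vals = m.values[np.ix_(keep, keep)]
        defined = ~np.isnan(vals)
        sub_total = np.where(defined, vals, 0.0)
        total[np.ix_(idx, idx)] += sub_total
        count[np.ix_(idx, idx)] += defined
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return DistMatrix(universe, mean, metric=matrices[0].metric)


def complete_matrix(m: DistMatrix) -> DistMatrix:
    """Greedily drop samples until no pairwise value is missing.

    Repeatedly removes the sample with the greatest number of missing pairs;
    ties break toward the lexicographically smallest sample id (determinism).
    Samples whose diagonal itself is undefined count every pair as missing.
    """
    ids = list(m.ids)
    values = m.values.copy()
    while True:
        missing = np.isnan(values)
        np.fill_diagonal(missing, False)
        undefined_self = np.isnan(np.diagonal(values))
        per_sample = missing.sum(axis=1) + undefined_self * len(ids)
        if per_sample.sum() == 0:
            break
        worst = per_sample.max()
        candidates = [i for i, c in enumerate(per_sample) if c == worst]
        drop = min(candidates, key=lambda i: ids[i])
        keep = [i for i in range(len(ids)) if i != drop]
        values = values[np.ix_(keep, keep)]
        ids = [ids[i] for i in keep]
    return DistMatrix(ids, values, metric=m.metric)
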