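"""Single-linkage "no breaking" clustering of ESVs by sequence differences.

Two ESVs are linked when their Levenshtein edit distance (substitutions and
indels each costing 1) is at most *d*; clusters are the connected components
of that graph — the transitive closure a swarm-style clusterer produces with
OTU breaking disabled.  Raising *d* one step at a time yields a nested family
of partitions, from singletons at d = 0 up to a single cluster at d_single.

Distances are computed with edlib's banded alignment, abandoning a pair as
soon as its distance provably exceeds the working cap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import edlib
import numpy as np

from .core_io import EsvRecord, PresenceMatrix

__all__ = [
    "Partition",
    "PartitionHierarchy",
    "sequence_differences",
    "cluster_at_d",
    "select_otu_d",
    "build_hierarchy",
    "merge_presence_by_clusters",
]


def sequence_differences(a: str, b: str, max_d: int | None = None) -> int:
    """Levenshtein distance between two sequences.

    With ``max_d`` set, computation is banded and any distance > max_d is
    reported as ``max_d + 1`` (sufficient for thresholded clustering).
    """
    k = -1 if max_d is None else max_d
    d = edlib.align(a, b, task="distance", k=k)["editDistance"]
    if d == -1:
        return max_d + 1  # type: ignore[operator]
    return d


@dataclass
class Partition:
    """ESV -> cluster assignment at one difference threshold d.

    Cluster ids are the lexicographically smallest member esv_id, which makes
    partitions deterministic and stable across runs.
    """

    d: int
    assignment: dict[str, str]
    clusters: dict[str, list[str]]

    def __post_init__(self) -> None:
        rebuilt = {e: c for c, members in self.clusters.items() for e in members}
        if rebuilt != self.assignment:
            raise ValueError("assignment and clusters are inconsistent")
        for cid, members in self.clusters.items():
            if cid != min(members):
                raise ValueError(f"cluster id {cid} is not its smallest member")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def member_sets(self) -> set[frozenset[str]]:
        return {frozenset(m) for m in self.clusters.values()}


@dataclass
class PartitionHierarchy:
    """Nested partitions for d = 0 .. d_single (one cluster)."""

    partitions: list[Partition]

    def __post_init__(self) -> None:
        for i, p in enumerate(self.partitions):
            if p.d != i:
                raise ValueError("partitions must cover d = 0, 1, ... contiguously")
        for lo, hi in zip(self.partitions, self.partitions[1:]):
            for members in lo.clusters.values():
                parents = {hi.assignment[e] for e in members}
                if len(parents) != 1:
                    raise ValueError(f"partition at d={hi.d} does not coarsen d={lo.d}")
        if self.partitions[-1].n_clusters != 1:
            raise ValueError("hierarchy must end in a single cluster")

    @property
    def d_single(self) -> int:
        return self.partitions[-1].d

    def at(self, d: int) -> Partition:
        """Partition at threshold d (clamped to d_single beyond the top)."""
        if d < 0:
            raise ValueError("d must be non-negative")
        return self.partitions[min(d, self.d_single)]


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _pairwise_distances(records: Sequence[EsvRecord], max_d: int | None) -> np.ndarray:
    n = len(records)
    dist = np.zeros((n, n), dtype=int)
    seqs = [r.sequence for r in records]
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = sequence_differences(seqs[i], seqs[j], max_d)
    return dist


def _components_to_partition(ids: list[str], uf: _UnionFind, d: int) -> Partition:
    comp: dict[int, list[str]] = {}
    for idx, esv in enumerate(ids):
        comp.setdefault(uf.find(idx), []).append(esv)
    clusters = {min(members): sorted(members) for members in comp.values()}
    assignment = {e: c for c, members in clusters.items() for e in members}
    return Partition(d=d, assignment=assignment, clusters=clusters)


def cluster_at_d(records: Sequence[EsvRecord], d: int) -> Partition:
    """Connected components of the <= d differences graph.

    ESV ids must be unique; with d = 0 and distinct sequences this returns
    one singleton cluster per ESV.
    """
    if not records:
        raise ValueError("no records to cluster")
    ids = [r.esv_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate esv_ids")
    dist = _pairwise_distances(records, max_d=d)
    uf = _UnionFind(len(ids))
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if dist[i, j] <= d:
                uf.union(i, j)
    return _components_to_partition(ids, uf, d)


def select_otu_d(amplicon_length: int, target_fraction: float = 0.03) -> int:
    """Integer d >= 1 whose ratio to the amplicon length is closest to the target.

    For a 229 nt amplicon with the conventional 3% species-proxy threshold
    this picks d = 7 (7/229 = 3.06%); ties break toward the smaller d
    (more conservative clustering).
    """
    if amplicon_length <= 0:
        raise ValueError("amplicon_length must be positive")
    best_d, best_err = 1, abs(1.0 / amplicon_length - target_fraction)
    d = 1
    while True:
        d += 1
        err = abs(d / amplicon_length - target_fraction)
        if err < best_err:
            best_d, best_err = d, err
        if d / amplicon_length > target_fraction:
            break
    return best_d


def build_hierarchy(records: Sequence[EsvRecord]) -> PartitionHierarchy:
    """Partitions at every d from 0 up to the first d with a single cluster.

    Components are grown incrementally: edges enter in order of pairwise
    distance, so the nesting invariant holds by construction.
    """
    if not records:
        raise ValueError("no records to cluster")
    ids = [r.esv_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate esv_ids")
    n = len(ids)
    dist = _pairwise_distances(records, max_d=None)

    uf = _UnionFind(n)
    partitions = []
    d = 0
    while True:
        for i in range(n):
            for j in range(i + 1, n):
                if dist[i, j] == d:
                    uf.union(i, j)
        part = _components_to_partition(ids, uf, d)
        partitions.append(part)
        if part.n_clusters == 1:
            break
        d += 1
    return PartitionHierarchy(partitions)


def merge_presence_by_clusters(
    presence: PresenceMatrix, clusters: dict[str, list[str]]
) -> PresenceMatrix:
    """Collapse ESV presence columns to cluster columns by logical OR."""
    import pandas as pd

    cols = {}
    for cid, members in clusters.items():
        members_in = [m for m in members if m in presence.df.columns]
        if members_in:
            cols[cid] = presence.df[members_in].any(axis=1)
    return PresenceMatrix(pd.DataFrame(cols, index=presence.df.index))
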