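"""Permutation statistics for region-group comparisons.

Implements the test battery applied to the dissimilarity matrices:

* PERMANOVA with the pseudo-F statistic (among-group over within-group mean
  squared dissimilarity), overall and pairwise with Benjamini–Hochberg FDR;
* a betadisper-style homogeneity-of-dispersion test (principal-coordinates
  embedding with the imaginary-axis correction for negative eigenvalues,
  distance to the group spatial median, permutation F test);
* the Mantel test with Spearman rank correlation;
* k-means region grouping on raw (lat, lon) degrees with an adjusted-Rand
  stability scan and within-cluster sum-of-squares curve;
* geodesic distances on the WGS84 ellipsoid.

Permutation p-values use the add-one convention, p = (1 + #{T_perm >= T_obs})
/ (1 + n_perm), so p is never 0.  When the permutation space is no larger
than the requested number of permutations, exact enumeration engages and p is
the exact tail proportion (which includes the identity, so it is positive).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from .core_io import DistMatrix, SampleInfo

__all__ = [
    "PermanovaResult",
    "MantelResult",
    "DispersionResult",
    "RegionAssignment",
    "pseudo_f",
    "permanova",
    "pairwise_permanova",
    "beta_dispersion",
    "mantel_spearman",
    "adjusted_rand",
    "kmeans_regions",
    "kmeans_stability",
    "geodesic_matrix",
    "per_cluster_permanova",
]

DEFAULT_PERMUTATIONS = 9999
ALPHA = 0.05


@dataclass
class PermanovaResult:
    pseudo_F: float
    p: float
    df_among: int
    df_within: int
    n_perm: int
    seed: int | None
    exact: bool = False

    def __post_init__(self) -> None:
        # pseudo_F can be negative for semimetric dissimilarities (SS_among =
        # SS_total - SS_within is not sign-guaranteed), so only p is checked.
        if not 0.0 < self.p <= 1.0:
            raise ValueError("p outside (0, 1]")


@dataclass
class MantelResult:
    rho: float
    p: float
    n_perm: int
    seed: int | None
    exact: bool = False


@dataclass
class DispersionResult:
    F: float
    p: float
    group_dispersions: dict[str, float]
    n_perm: int
    seed: int | None


@dataclass
class RegionAssignment:
    labels: dict[str, str]
    k: int
    wss: float
    stability: float | None = None


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


def _group_vector(m: DistMatrix, groups: Mapping[str, str]) -> np.ndarray:
    missing = [s for s in m.ids if s not in groups]
    if missing:
        raise ValueError(f"samples without group labels: {missing[:5]}")
    return np.array([groups[s] for s in m.ids])


def _sums_of_squares(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return ss_total, ss_within


def pseudo_f(m: DistMatrix, groups: Mapping[str, str]) -> float:
    """PERMANOVA pseudo-F without a permutation test (used by the null model)."""
    if not m.is_complete():
        raise ValueError("matrix has missing pairs; complete it first")
    labels = _group_vector(m, groups)
    uniq, counts = np.unique(labels, return_counts=True)
    g, n = len(uniq), len(labels)
    if g < 2:
        raise ValueError("need at least 2 groups")
    d2 = m.values**2
    ss_t, ss_w = _sums_of_squares(d2, labels)
    ss_a = ss_t - ss_w
    with np.errstate(divide="ignore"):
        return float((ss_a / (g - 1)) / np.float64(ss_w / (n - g)))


def _distinct_label_arrangements(labels: np.ndarray) -> int:
    uniq, counts = np.unique(labels, return_counts=True)
    total = math.factorial(len(labels))
    for c in counts:
        total //= math.factorial(int(c))
    return total


def _enumerate_label_arrangements(labels: np.ndarray):
    """All distinct arrangements of a label multiset (multiset permutations)."""
    seen_prefix: list[np.ndarray] = []

    def rec(remaining: list, prefix: list):
        if not remaining:
            yield np.array(prefix)
            return
        used = set()
        for i, lab in enumerate(remaining):
            if lab in used:
                continue
            used.add(lab)
            yield from rec(remaining[:i] + remaining[i + 1 :], prefix + [lab])

    yield from rec(sorted(labels.tolist()), [])


def permanova(
    m: DistMatrix,
    groups: Mapping[str, str],
    n_perm: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA on a complete dissimilarity matrix.

    SS_total = sum_{i<j} d_ij^2 / n, SS_within sums the analogous per-group
    quantity, pseudo-F = (SS_among / (g-1)) / (SS_within / (n-g)).  The null
    distribution permutes group labels uniformly; when the number of distinct
    label arrangements is <= n_perm the test enumerates them exactly.
    """
    if not m.is_complete():
        raise ValueError("matrix has missing pairs; complete it first")
    labels = _group_vector(m, groups)
    uniq, counts = np.unique(labels, return_counts=True)
    g, n = len(uniq), len(labels)
    if g < 2 or np.any(counts < 2):
        raise ValueError("need >= 2 groups with >= 2 samples each")
    d2 = m.values**2

    def f_for(perm_labels: np.ndarray) -> float:
        _, ssw = _sums_of_squares(d2, perm_labels)
        with np.errstate(divide="ignore"):
            return float(((ss_t - ssw) / (g - 1)) / np.float64(ssw / (n - g)))

    ss_t, ss_w = _sums_of_squares(d2, labels)
    f_obs = f_for(labels)

    n_distinct = _distinct_label_arrangements(labels)
    if n_distinct <= n_perm:
        hits = sum(
            f_for(perm) >= f_obs - 1e-12
            for perm in _enumerate_label_arrangements(labels)
        )
        return PermanovaResult(
            pseudo_F=f_obs, p=hits / n_distinct, df_among=g - 1, df_within=n - g,
            n_perm=n_distinct, seed=seed, exact=True,
        )
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if f_for(rng.permutation(labels)) >= f_obs - 1e-12:
            hits += 1
    return PermanovaResult(
        pseudo_F=f_obs, p=(1 + hits) / (1 + n_perm), df_among=g - 1,
        df_within=n - g, n_perm=n_perm, seed=seed,
    )


def pairwise_permanova(
    m: DistMatrix,
    groups: Mapping[str, str],
    n_perm: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
) -> list[dict]:
    """One PERMANOVA per unordered group pair, BH-adjusted across pairs."""
    labels = _group_vector(m, groups)
    uniq = sorted(set(labels))
    results = []
    rng = np.random.default_rng(seed)
    for g1, g2 in itertools.combinations(uniq, 2):
        ids = [s for s in m.ids if groups[s] in (g1, g2)]
        sub = m.submatrix(ids)
        res = permanova(sub, groups, n_perm=n_perm, seed=int(rng.integers(2**31)))
        results.append({"pair": (g1, g2), "result": res})
    raw = [r["result"].p for r in results]
    adjusted = multipletests(raw, method="fdr_bh")[1] if raw else []
    for r, p_adj in zip(results, adjusted):
        r["p_adjusted"] = float(p_adj)
    return results


# ---------------------------------------------------------------------------
# dispersion homogeneity (betadisper-style)
# ---------------------------------------------------------------------------


def _pcoa_axes(m: DistMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate axes split into real and imaginary parts.

    Gower-centers -d^2/2 and eigendecomposes; axes with positive eigenvalues
    carry real coordinates scaled by sqrt(lambda), negative eigenvalues give
    imaginary axes scaled by sqrt(-lambda).  Squared distances in the full
    space are (real part) - (imaginary part).
    """
    n = len(m.ids)
    a = -0.5 * m.values**2
    centerer = np.eye(n) - np.ones((n, n)) / n
    gower = centerer @ a @ centerer
    eigvals, eigvecs = np.linalg.eigh((gower + gower.T) / 2)
    tol = 1e-8 * max(1.0, np.abs(eigvals).max())
    pos = eigvals > tol
    neg = eigvals < -tol
    real_axes = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    imag_axes = eigvecs[:, neg] * np.sqrt(-eigvals[neg])
    if real_axes.shape[1] == 0:
        raise ValueError("embedding failed: no positive eigenvalues")
    return real_axes, imag_axes


def _spatial_median(points: np.ndarray, max_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
    """Geometric (L1) median by Weiszfeld iteration with coincident-point guard."""
    median = points.mean(axis=0)
    for _ in range(max_iter):
        diff = points - median
        dist = np.linalg.norm(diff, axis=1)
        near = dist < 1e-12
        if near.any():
            dist[near] = 1e-12
        w = 1.0 / dist
        new = (points * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(new - median) < tol:
            return new
        median = new
    return median


def _anova_f(values: np.ndarray, labels: np.ndarray) -> float:
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    uniq = np.unique(labels)
    for g in uniq:
        v = values[labels == g]
        ss_between += len(v) * (v.mean() - grand) ** 2
        ss_within += ((v - v.mean()) ** 2).sum()
    df_b = len(uniq) - 1
    df_w = len(values) - len(uniq)
    if ss_within <= 0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / df_b) / (ss_within / df_w)


def beta_dispersion(
    m: DistMatrix,
    groups: Mapping[str, str],
    n_perm: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
) -> DispersionResult:
    """Homogeneity of multivariate dispersion across groups.

    Each sample's dispersion is its distance to the group's spatial median in
    the principal-coordinate space (imaginary axes subtract); group equality
    of mean dispersion is tested by a one-way F statistic whose null
    distribution permutes the group labels of the distances.  Single-sample
    groups contribute a zero distance and are excluded from the F test.
    """
    if not m.is_complete():
        raise ValueError("matrix has missing pairs; complete it first")
    labels = _group_vector(m, groups)
    real_axes, imag_axes = _pcoa_axes(m)
    dist = np.empty(len(labels))
    group_disp: dict[str, float] = {}
    multi_member = np.zeros(len(labels), dtype=bool)
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        med_r = _spatial_median(real_axes[idx])
        d2 = ((real_axes[idx] - med_r) ** 2).sum(axis=1)
        if imag_axes.shape[1]:
            med_i = _spatial_median(imag_axes[idx])
            d2 = d2 - ((imag_axes[idx] - med_i) ** 2).sum(axis=1)
        dist[idx] = np.sqrt(np.clip(d2, 0.0, None))
        group_disp[str(g)] = float(dist[idx].mean())
        if len(idx) > 1:
            multi_member[idx] = True
    test_vals = dist[multi_member]
    test_labels = labels[multi_member]
    if len(np.unique(test_labels)) < 2:
        raise ValueError("need >= 2 groups with >= 2 samples for the dispersion test")
    f_obs = _anova_f(test_vals, test_labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if _anova_f(test_vals, rng.permutation(test_labels)) >= f_obs - 1e-12:
            hits += 1
    return DispersionResult(
        F=float(f_obs), p=(1 + hits) / (1 + n_perm),
        group_dispersions=group_disp, n_perm=n_perm, seed=seed,
    )


# ---------------------------------------------------------------------------
# Mantel / Spearman
# ---------------------------------------------------------------------------


def _spearman_condensed(v1: np.ndarray, v2: np.ndarray) -> float:
    rho = stats.spearmanr(v1, v2).statistic
    return float(rho)


def mantel_spearman(
    m1: DistMatrix,
    m2: DistMatrix,
    n_perm: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
    alternative: Literal["greater", "two-sided"] = "greater",
) -> MantelResult:
    """Mantel test with Spearman rank correlation.

    rho is computed over the n(n-1)/2 off-diagonal pairs; the null
    distribution permutes the rows and columns of the second matrix
    simultaneously.  With n! <= n_perm all permutations are enumerated and
    the p-value is exact.
    """
    if m1.ids != m2.ids:
        if set(m1.ids) != set(m2.ids):
            raise ValueError("matrices cover different sample sets")
        m2 = m2.submatrix(m1.ids)
    if not (m1.is_complete() and m2.is_complete()):
        raise ValueError("matrices must be complete")
    n = len(m1.ids)
    iu = np.triu_indices(n, k=1)
    v1 = m1.values[iu]
    rho_obs = _spearman_condensed(v1, m2.values[iu])

    def tail(r: float) -> bool:
        if alternative == "greater":
            return r >= rho_obs - 1e-12
        return abs(r) >= abs(rho_obs) - 1e-12

    if math.factorial(n) <= n_perm:
        hits = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            p = np.array(perm)
            r = _spearman_condensed(v1, m2.values[np.ix_(p, p)][iu])
            hits += tail(r)
            total += 1
        return MantelResult(rho=rho_obs, p=hits / total, n_perm=total, seed=seed, exact=True)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        if tail(_spearman_condensed(v1, m2.values[np.ix_(p, p)][iu])):
            hits += 1
    return MantelResult(rho=rho_obs, p=(1 + hits) / (1 + n_perm), n_perm=n_perm, seed=seed)


def adjusted_rand(labels1: Sequence, labels2: Sequence) -> float:
    """Hubert–Arabie adjusted Rand index between two labelings."""
    if len(labels1) != len(labels2):
        raise ValueError("labelings cover different item counts")
    return float(adjusted_rand_score(list(labels1), list(labels2)))


# ---------------------------------------------------------------------------
# region grouping
# ---------------------------------------------------------------------------


def _coords(metadata: Sequence[SampleInfo], include_wetland: bool) -> tuple[list[str], np.ndarray]:
    kept = [s for s in metadata if include_wetland or not s.wetland]
    ids = [s.sample_id for s in kept]
    xy = np.array([[s.lat, s.lon] for s in kept])
    return ids, xy


def kmeans_regions(
    metadata: Sequence[SampleInfo],
    k: int,
    n_starts: int = 10,
    seed: int | None = None,
    include_wetland: bool = False,
) -> RegionAssignment:
    """k-means on raw (lat, lon) degrees; wetland samples excluded by default."""
    ids, xy = _coords(metadata, include_wetland)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(ids):
        raise ValueError(f"k={k} exceeds {len(ids)} samples")
    km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed).fit(xy)
    labels = {s: f"region_{lab}" for s, lab in zip(ids, km.labels_)}
    return RegionAssignment(labels=labels, k=k, wss=float(km.inertia_))


def kmeans_stability(
    metadata: Sequence[SampleInfo],
    k_range: Sequence[int] = range(2, 21),
    n_pairs: int = 1000,
    seed: int | None = None,
    include_wetland: bool = False,
) -> dict[int, dict]:
    """Adjusted-Rand stability and WSS per candidate k.

    For each k, ``n_pairs`` pairs of single-start k-means runs are compared
    by adjusted Rand index; a stable k reproduces the same partition from
    random initializations.  Returns {k: {"ari": array, "mean_ari": float,
    "wss": float}}.
    """
    ids, xy = _coords(metadata, include_wetland)
    rng = np.random.default_rng(seed)
    out: dict[int, dict] = {}
    for k in k_range:
        if k > len(ids):
            break
        aris = np.empty(n_pairs)
        for i in range(n_pairs):
            l1 = KMeans(n_clusters=k, n_init=1, random_state=int(rng.integers(2**31))).fit_predict(xy)
            l2 = KMeans(n_clusters=k, n_init=1, random_state=int(rng.integers(2**31))).fit_predict(xy)
            aris[i] = adjusted_rand_score(l1, l2)
        wss = float(KMeans(n_clusters=k, n_init=10, random_state=int(rng.integers(2**31))).fit(xy).inertia_)
        out[k] = {"ari": aris, "mean_ari": float(aris.mean()), "wss": wss}
    return out


# ---------------------------------------------------------------------------
# geodesic distances (WGS84)
# ---------------------------------------------------------------------------

_WGS84_A = 6378137.0
_WGS84_F = 1 / 298.257223563
_WGS84_B = _WGS84_A * (1 - _WGS84_F)


def _vincenty_inverse(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Geodesic distance in meters on the WGS84 ellipsoid (Vincenty inverse).

    Iterative solution of the inverse geodesic problem; accurate to well
    under a millimetre for non-near-antipodal points, which covers any
    regional sampling design.  Raises on non-convergence rather than fall
    back to a spherical approximation.
    """
    if (lat1, lon1) == (lat2, lon2):
        return 0.0
    u1 = math.atan((1 - _WGS84_F) * math.tan(math.radians(lat1)))
    u2 = math.atan((1 - _WGS84_F) * math.tan(math.radians(lat2)))
    ell = math.radians(lon2 - lon1)
    sin_u1, cos_u1 = math.sin(u1), math.cos(u1)
    sin_u2, cos_u2 = math.sin(u2), math.cos(u2)
    lam = ell
    for _ in range(200):
        sin_lam, cos_lam = math.sin(lam), math.cos(lam)
        sin_sigma = math.hypot(
            cos_u2 * sin_lam, cos_u1 * sin_u2 - sin_u1 * cos_u2 * cos_lam
        )
        if sin_sigma == 0.0:
            return 0.0
        cos_sigma = sin_u1 * sin_u2 + cos_u1 * cos_u2 * cos_lam
        sigma = math.atan2(sin_sigma, cos_sigma)
        sin_alpha = cos_u1 * cos_u2 * sin_lam / sin_sigma
        cos2_alpha = 1 - sin_alpha**2
        cos_2sigma_m = 0.0 if cos2_alpha == 0 else cos_sigma - 2 * sin_u1 * sin_u2 / cos2_alpha
        c = _WGS84_F / 16 * cos2_alpha * (4 + _WGS84_F * (4 - 3 * cos2_alpha))
        lam_prev = lam
        lam = ell + (1 - c) * _WGS84_F * sin_alpha * (
            sigma + c * sin_sigma * (cos_2sigma_m + c * cos_sigma * (-1 + 2 * cos_2sigma_m**2))
        )
        if abs(lam - lam_prev) < 1e-12:
            break
    else:
        raise ValueError("Vincenty iteration did not converge (near-antipodal points)")
    u_sq = cos2_alpha * (_WGS84_A**2 - _WGS84_B**2) / _WGS84_B**2
    big_a = 1 + u_sq / 16384 * (4096 + u_sq * (-768 + u_sq * (320 - 175 * u_sq)))
    big_b = u_sq / 1024 * (256 + u_sq * (-128 + u_sq * (74 - 47 * u_sq)))
    delta_sigma = big_b * sin_sigma * (
        cos_2sigma_m
        + big_b / 4 * (
            cos_sigma * (-1 + 2 * cos_2sigma_m**2)
            - big_b / 6 * cos_2sigma_m * (-3 + 4 * sin_sigma**2) * (-3 + 4 * cos_2sigma_m**2)
        )
    )
    return _WGS84_B * big_a * (sigma - delta_sigma)


def geodesic_matrix(metadata: Sequence[SampleInfo], include_wetland: bool = True) -> DistMatrix:
    """Pairwise WGS84 geodesic distance matrix in meters."""
    kept = [s for s in metadata if include_wetland or not s.wetland]
    n = len(kept)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _vincenty_inverse(kept[i].lat, kept[i].lon, kept[j].lat, kept[j].lon)
            values[i, j] = values[j, i] = d
    return DistMatrix([s.sample_id for s in kept], values, metric="geodesic_m")


# ---------------------------------------------------------------------------
# per-cluster PERMANOVA
# ---------------------------------------------------------------------------


def per_cluster_permanova(
    cluster_matrices: Sequence[tuple[str, DistMatrix]],
    regions: Mapping[str, str],
    n_perm: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
    alpha: float = ALPHA,
) -> dict:
    """PERMANOVA per species-proxy cluster with BH-FDR across clusters.

    Each cluster's matrix is completed individually (samples with missing
    pairs dropped); clusters left without >= 2 region groups of >= 2 samples
    are recorded as untestable and excluded from the FDR family.
    """
    from .betamatrix import complete_matrix

    rng = np.random.default_rng(seed)
    rows = []
    untestable = []
    for cid, m in cluster_matrices:
        mc = complete_matrix(m)
        labels = [regions.get(s) for s in mc.ids]
        counts: dict[str, int] = {}
        for lab in labels:
            counts[lab] = counts.get(lab, 0) + 1
        ok = sum(1 for v in counts.values() if v >= 2) >= 2
        samples_ok = [s for s in mc.ids if counts[regions[s]] >= 2]
        if not ok or len(samples_ok) < 4:
            untestable.append(cid)
            continue
        res = permanova(
            mc.submatrix(samples_ok), regions, n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        rows.append({"cluster": cid, "pseudo_F": res.pseudo_F, "p": res.p})
    raw = [r["p"] for r in rows]
    if raw:
        adjusted = multipletests(raw, method="fdr_bh")[1]
        for r, p_adj in zip(rows, adjusted):
            r["p_adjusted"] = float(p_adj)
    n_sig = sum(1 for r in rows if r.get("p_adjusted", 1.0) < alpha)
    return {
        "results": rows,
        "untestable": untestable,
        "n_tested": len(rows),
        "n_significant": n_sig,
        "fraction_significant": n_sig / len(rows) if rows else float("nan"),
    }
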