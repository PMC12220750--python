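"""Permutation statistics against exhaustive oracles and reference values."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from metaphylo.core_io import DistMatrix, SampleInfo
from metaphylo.permstats import (
    adjusted_rand,
    beta_dispersion,
    geodesic_matrix,
    kmeans_regions,
    kmeans_stability,
    mantel_spearman,
    pairwise_permanova,
    per_cluster_permanova,
    permanova,
    pseudo_f,
)

from conftest import random_dist_matrix


def brute_force_pseudo_f(values, labels):
    n = len(labels)
    d2 = values**2
    ss_t = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
    ss_w = 0.0
    for g in set(labels):
        idx = [i for i, lab in enumerate(labels) if lab == g]
        ss_w += sum(d2[i, j] for i in idx for j in idx if i < j) / len(idx)
    g = len(set(labels))
    return ((ss_t - ss_w) / (g - 1)) / (ss_w / (n - g))


class TestPermanova:
    def four_sample_matrix(self):
        values = np.full((4, 4), 0.9)
        np.fill_diagonal(values, 0.0)
        values[0, 1] = values[1, 0] = 0.1
        values[2, 3] = values[3, 2] = 0.1
        return DistMatrix(list("wxyz"), values)

    def test_hand_computed_f_and_exact_p(self):
        m = self.four_sample_matrix()
        groups = {"w": "A", "x": "A", "y": "B", "z": "B"}
        res = permanova(m, groups, n_perm=999, seed=0)
        # SS_T = (2*0.01 + 4*0.81)/4 = 0.815; SS_W = 0.01; F = 0.805/0.005
        assert res.pseudo_F == pytest.approx(161.0)
        assert res.exact
        assert res.p == pytest.approx(1 / 3)

    def test_exchangeable_groups_give_large_p(self, rng):
        # two groups that are mirror images: no location difference
        n = 8
        m = random_dist_matrix(n, rng)
        groups = {s: ("A" if i % 2 == 0 else "B") for i, s in enumerate(m.ids)}
        res = permanova(m, groups, n_perm=999, seed=1)
        assert res.p > 0.05 or res.pseudo_F < 5  # no planted signal

    def test_permuted_f_values_match_oracle(self, rng):
        m = random_dist_matrix(8, rng)
        labels = ["A"] * 4 + ["B"] * 4
        groups = dict(zip(m.ids, labels))
        res = permanova(m, groups, n_perm=10**6, seed=0)  # forces exact mode
        # oracle: enumerate all distinct label arrangements directly
        f_obs = brute_force_pseudo_f(m.values, labels)
        hits = 0
        arrangements = set(itertools.permutations(labels))
        for arr in arrangements:
            if brute_force_pseudo_f(m.values, list(arr)) >= f_obs - 1e-12:
                hits += 1
        assert res.pseudo_F == pytest.approx(f_obs)
        assert res.p == pytest.approx(hits / len(arrangements))

    def test_matches_skbio_statistic(self, rng):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        m = random_dist_matrix(10, rng)
        labels = ["A"] * 3 + ["B"] * 4 + ["C"] * 3
        groups = dict(zip(m.ids, labels))
        ours = pseudo_f(m, groups)
        dm = skbio_distance.DistanceMatrix(m.values, ids=m.ids)
        theirs = skbio_distance.permanova(dm, grouping=labels, permutations=9)
        assert ours == pytest.approx(theirs["test statistic"], rel=1e-10)

    def test_invariant_to_reordering_and_relabeling(self, rng):
        m = random_dist_matrix(8, rng)
        labels = ["A"] * 4 + ["B"] * 4
        groups = dict(zip(m.ids, labels))
        order = list(rng.permutation(m.ids))
        renamed = {s: {"A": "G2", "B": "G1"}[g] for s, g in groups.items()}
        assert pseudo_f(m.submatrix(order), renamed) == pytest.approx(pseudo_f(m, groups))

    def test_missing_entries_rejected(self, rng):
        m = random_dist_matrix(6, rng, missing_pairs=1)
        groups = {s: ("A" if i < 3 else "B") for i, s in enumerate(m.ids)}
        with pytest.raises(ValueError, match="missing"):
            permanova(m, groups)


class TestPairwisePermanova:
    def test_two_groups_single_test(self, rng):
        m = random_dist_matrix(8, rng)
        groups = {s: ("A" if i < 4 else "B") for i, s in enumerate(m.ids)}
        results = pairwise_permanova(m, groups, n_perm=99, seed=0)
        assert len(results) == 1
        assert results[0]["p_adjusted"] == pytest.approx(results[0]["result"].p)

    def test_four_groups_give_six_tests(self, rng):
        m = random_dist_matrix(12, rng)
        groups = {s: f"G{i // 3}" for i, s in enumerate(m.ids)}
        assert len(pairwise_permanova(m, groups, n_perm=49, seed=0)) == 6

    def test_bh_adjustment_by_hand(self):
        from statsmodels.stats.multitest import multipletests

        adjusted = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        assert list(np.round(adjusted, 10)) == [0.03, 0.03, 0.03]


class TestBetaDispersion:
    def test_congruent_groups_not_significant(self, rng):
        # group B is a mirrored copy of group A in a Euclidean configuration
        pts = rng.normal(size=(6, 2))
        all_pts = np.vstack([pts, pts * -1 + 10])
        n = 12
        values = np.sqrt(((all_pts[:, None] - all_pts[None]) ** 2).sum(-1))
        m = DistMatrix([f"s{i}" for i in range(n)], values, metric="euclidean")
        groups = {f"s{i}": ("A" if i < 6 else "B") for i in range(n)}
        res = beta_dispersion(m, groups, n_perm=499, seed=0)
        assert res.group_dispersions["A"] == pytest.approx(res.group_dispersions["B"], rel=1e-6)
        assert res.p > 0.5

    def test_different_spreads_detected(self, rng):
        tight = rng.normal(0, 0.05, size=(8, 2))
        wide = rng.normal(0, 2.0, size=(8, 2))
        all_pts = np.vstack([tight, wide])
        values = np.sqrt(((all_pts[:, None] - all_pts[None]) ** 2).sum(-1))
        m = DistMatrix([f"s{i}" for i in range(16)], values, metric="euclidean")
        groups = {f"s{i}": ("A" if i < 8 else "B") for i in range(16)}
        res = beta_dispersion(m, groups, n_perm=999, seed=0)
        assert res.p < 0.05
        assert res.group_dispersions["B"] > res.group_dispersions["A"]

    def test_single_sample_group_excluded(self, rng):
        m = random_dist_matrix(7, rng)
        groups = {s: g for s, g in zip(m.ids, ["A"] * 3 + ["B"] * 3 + ["C"])}
        res = beta_dispersion(m, groups, n_perm=99, seed=0)
        assert res.group_dispersions["C"] == 0.0


class TestMantelSpearman:
    def test_identical_matrices_give_rho_one(self, rng):
        m = random_dist_matrix(6, rng)
        res = mantel_spearman(m, m, n_perm=99, seed=0)
        assert res.rho == pytest.approx(1.0)

    def test_monotone_transform_gives_rho_one(self, rng):
        m1 = random_dist_matrix(6, rng)
        m2 = DistMatrix(m1.ids, m1.values**2, metric=m1.metric)
        assert mantel_spearman(m1, m2, n_perm=99, seed=0).rho == pytest.approx(1.0)

    def test_anti_monotone_gives_rho_minus_one(self, rng):
        m1 = random_dist_matrix(6, rng)
        flipped = 1.0 - m1.values
        np.fill_diagonal(flipped, 0.0)
        m2 = DistMatrix(m1.ids, flipped, metric=m1.metric)
        assert mantel_spearman(m1, m2, n_perm=99, seed=0).rho == pytest.approx(-1.0)

    def test_exact_p_matches_exhaustive_enumeration(self, rng):
        m1 = random_dist_matrix(4, rng)
        m2 = random_dist_matrix(4, rng)
        res = mantel_spearman(m1, m2, n_perm=10**5, seed=0)
        assert res.exact and res.n_perm == 24
        iu = np.triu_indices(4, k=1)
        rho_obs = stats.spearmanr(m1.values[iu], m2.values[iu]).statistic
        hits = 0
        for perm in itertools.permutations(range(4)):
            p = np.array(perm)
            rho = stats.spearmanr(m1.values[iu], m2.values[np.ix_(p, p)][iu]).statistic
            hits += rho >= rho_obs - 1e-12
        assert res.p == pytest.approx(hits / 24)

    def test_matches_skbio_statistic(self, rng):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        m1 = random_dist_matrix(7, rng)
        m2 = random_dist_matrix(7, rng)
        ours = mantel_spearman(m1, m2, n_perm=99, seed=0)
        corr, _, _ = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(m1.values, ids=m1.ids),
            skbio_distance.DistanceMatrix(m2.values, ids=m2.ids),
            method="spearman", permutations=9,
        )
        assert ours.rho == pytest.approx(corr, rel=1e-10)

    def test_sample_set_mismatch_rejected(self, rng):
        m1 = random_dist_matrix(4, rng)
        m2 = DistMatrix(["q1", "q2"], np.array([[0, 0.5], [0.5, 0]]))
        with pytest.raises(ValueError):
            mantel_spearman(m1, m2)


class TestAdjustedRand:
    def test_identical_labelings(self):
        assert adjusted_rand([1, 1, 2, 2], [1, 1, 2, 2]) == 1.0

    def test_label_name_invariance(self):
        assert adjusted_rand(["a", "a", "b"], ["x", "x", "y"]) == 1.0

    def test_hand_computed_contingency(self):
        # {1,1,2,2} vs {1,2,1,2}: all n_ij = 1 -> index 0, expected 2/3, max 2
        assert adjusted_rand([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(-0.5)


def four_blob_metadata(n_per=10, sigma=0.05, seed=0):
    rng = np.random.default_rng(seed)
    samples = []
    lats = np.linspace(49.5, 51.5, 4)
    lons = np.linspace(-117.5, -113.5, 4)
    for b in range(4):
        for i in range(n_per):
            samples.append(SampleInfo(
                f"b{b}_s{i}",
                float(lats[b] + rng.normal(0, sigma)),
                float(lons[b] + rng.normal(0, sigma)),
                2021,
            ))
    return samples


class TestKmeans:
    def test_separable_blobs_recovered(self):
        samples = four_blob_metadata()
        res = kmeans_regions(samples, k=4, seed=0)
        truth = [s.sample_id.split("_")[0] for s in samples]
        assert adjusted_rand([res.labels[s.sample_id] for s in samples], truth) == 1.0

    def test_k_equals_n_gives_zero_wss(self):
        samples = four_blob_metadata(n_per=2)
        res = kmeans_regions(samples, k=len(samples), seed=0)
        assert res.wss == pytest.approx(0.0, abs=1e-12)

    def test_k_larger_than_n_rejected(self):
        samples = four_blob_metadata(n_per=1)
        with pytest.raises(ValueError):
            kmeans_regions(samples, k=5, seed=0)

    def test_wetland_samples_excluded(self):
        samples = four_blob_metadata(n_per=3)
        wet = SampleInfo("wet", 50.0, -115.0, 2021, wetland=True)
        res = kmeans_regions(samples + [wet], k=4, seed=0)
        assert "wet" not in res.labels

    def test_stability_deterministic_given_seed(self):
        samples = four_blob_metadata(n_per=4)
        s1 = kmeans_stability(samples, k_range=[2, 3], n_pairs=5, seed=7)
        s2 = kmeans_stability(samples, k_range=[2, 3], n_pairs=5, seed=7)
        for k in s1:
            np.testing.assert_array_equal(s1[k]["ari"], s2[k]["ari"])

    def test_stability_perfect_at_true_k(self):
        samples = four_blob_metadata()
        out = kmeans_stability(samples, k_range=[4], n_pairs=20, seed=0)
        assert out[4]["mean_ari"] == pytest.approx(1.0)


class TestGeodesic:
    # references computed with an independent implementation of the
    # Karney geodesic on the WGS84 ellipsoid
    REFERENCES = [
        ((0.0, 0.0), (0.0, 1.0), 111319.490793),  # 1 deg lon on the equator
        ((0.0, 0.0), (1.0, 0.0), 110574.388558),  # 1 deg lat on the meridian
        ((50.0, -115.0), (51.0, -114.0), 131935.962781),
        ((49.0, -118.0), (52.0, -113.0), 486835.071138),
    ]

    @pytest.mark.parametrize("p1,p2,expected", REFERENCES)
    def test_reference_distances(self, p1, p2, expected):
        samples = [SampleInfo("a", *p1, 2021), SampleInfo("b", *p2, 2021)]
        m = geodesic_matrix(samples)
        assert m.values[0, 1] == pytest.approx(expected, abs=1e-3)

    def test_identical_coordinates_zero(self):
        samples = [SampleInfo("a", 50.0, -115.0, 2021),
                   SampleInfo("b", 50.0, -115.0, 2021)]
        assert geodesic_matrix(samples).values[0, 1] == 0.0

    def test_triangle_inequality(self, rng):
        for _ in range(10):
            pts = [SampleInfo(f"s{i}", float(rng.uniform(45, 55)),
                              float(rng.uniform(-120, -110)), 2021) for i in range(3)]
            m = geodesic_matrix(pts).values
            assert m[0, 2] <= m[0, 1] + m[1, 2] + 1e-6


class TestPerClusterPermanova:
    def test_identical_structured_clusters_all_significant(self, rng):
        values = np.full((12, 12), 0.9)
        np.fill_diagonal(values, 0.0)
        for i in range(6):
            for j in range(6):
                if i != j:
                    values[i, j] = 0.1
                    values[i + 6, j + 6] = 0.1
        ids = [f"s{i:02d}" for i in range(12)]
        m = DistMatrix(ids, values)
        regions = {s: ("A" if i < 6 else "B") for i, s in enumerate(ids)}
        report = per_cluster_permanova([("c1", m), ("c2", m), ("c3", m)],
                                       regions, n_perm=999, seed=0)
        assert report["n_tested"] == 3
        assert report["fraction_significant"] == 1.0

    def test_untestable_cluster_reported(self, rng):
        m = random_dist_matrix(4, rng)
        regions = {s: "A" for s in m.ids}  # single region: untestable
        report = per_cluster_permanova([("c1", m)], regions, n_perm=99, seed=0)
        assert report["untestable"] == ["c1"]
        assert report["n_tested"] == 0
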