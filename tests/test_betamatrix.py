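"""Sørensen matrices, intraspecific selection, mean matrix, completion."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import dice

from metaphylo.betamatrix import (
    complete_matrix,
    mean_dissimilarity,
    per_cluster_matrices,
    select_intraspecific_clusters,
    sorensen_matrix,
)
from metaphylo.core_io import DistMatrix, PresenceMatrix

from conftest import random_dist_matrix, random_presence


def pm(data, samples, features):
    return PresenceMatrix(pd.DataFrame(data, index=samples, columns=features, dtype=bool))


class TestSorensen:
    def test_identical_rows_are_zero(self):
        m = sorensen_matrix(pm([[1, 1, 0], [1, 1, 0]], ["x", "y"], list("abc")))
        assert m.values[0, 1] == 0.0

    def test_disjoint_rows_are_one(self):
        m = sorensen_matrix(pm([[1, 1, 0], [0, 0, 1]], ["x", "y"], list("abc")))
        assert m.values[0, 1] == 1.0

    def test_shared_and_unique_counts(self):
        # a = 2 shared, b = c = 1 unique each: (1+1)/(4+1+1) = 1/3
        m = sorensen_matrix(pm([[1, 1, 1, 0], [1, 1, 0, 1]], ["x", "y"], list("abcd")))
        assert m.values[0, 1] == pytest.approx(1 / 3)

    def test_empty_pair_is_missing(self):
        m = sorensen_matrix(pm([[0, 0], [0, 0], [1, 0]], ["x", "y", "z"], list("ab")))
        assert np.isnan(m.values[0, 1])
        assert m.values[0, 2] == 1.0

    def test_matches_scipy_dice_oracle(self, rng):
        for _ in range(10):
            presence = random_presence(8, 12, rng, p=0.4)
            m = sorensen_matrix(presence)
            x = presence.values
            for i in range(8):
                for j in range(i + 1, 8):
                    if x[i].any() or x[j].any():
                        assert m.values[i, j] == pytest.approx(
                            dice(x[i], x[j]), abs=1e-12
                        )


class TestPerClusterMatrices:
    def test_restriction_and_values(self):
        presence = pm(
            [[1, 0, 1], [0, 1, 0], [0, 0, 1]], ["X", "Y", "Z"], ["e1", "e2", "e3"]
        )
        [(cid, m)] = per_cluster_matrices(presence, {"c1": ["e1", "e2"]})
        assert m.ids == ["X", "Y"]  # Z has no member ESV
        assert m.values[0, 1] == 1.0

    def test_both_members_shared_is_zero(self):
        presence = pm([[1, 1], [1, 1]], ["X", "Y"], ["e1", "e2"])
        [(_, m)] = per_cluster_matrices(presence, {"c1": ["e1", "e2"]})
        assert m.values[0, 1] == 0.0

    def test_unrestricted_includes_cluster_free_samples(self):
        presence = pm([[1, 0], [0, 1], [0, 0]], ["X", "Y", "Z"], ["e1", "e2"])
        [(_, m)] = per_cluster_matrices(
            presence, {"c1": ["e1", "e2"]}, restrict_to_occupied=False
        )
        assert m.ids == ["X", "Y", "Z"]
        assert m.values[0, 2] == 1.0


class TestIntraspecificSelection:
    regions = {f"s{i}": ("north" if i < 5 else "south") for i in range(10)}

    def _presence(self, rows):
        return pm(rows, [f"s{i}" for i in range(10)], ["e1", "e2"])

    def test_single_esv_cluster_excluded(self):
        presence = self._presence([[1, 0]] * 10)
        assert select_intraspecific_clusters({"c": ["e1"]}, presence, self.regions) == []

    def test_three_plus_three_across_two_regions_included(self):
        rows = [[1, 0]] * 3 + [[0, 0]] * 2 + [[0, 1]] * 3 + [[0, 0]] * 2
        presence = self._presence(rows)
        assert select_intraspecific_clusters(
            {"c": ["e1", "e2"]}, presence, self.regions
        ) == ["c"]

    def test_single_region_occupancy_excluded(self):
        rows = [[1, 1]] * 5 + [[0, 0]] * 5
        presence = self._presence(rows)
        assert select_intraspecific_clusters(
            {"c": ["e1", "e2"]}, presence, self.regions
        ) == []

    def test_minimum_qualifying_sample_count_is_six(self):
        # any occupancy over < 6 samples fails; 3+3 across two regions passes
        for n_north, n_south in [(3, 2), (2, 3), (5, 0), (4, 1)]:
            rows = (
                [[1, 1]] * n_north + [[0, 0]] * (5 - n_north)
                + [[1, 1]] * n_south + [[0, 0]] * (5 - n_south)
            )
            assert select_intraspecific_clusters(
                {"c": ["e1", "e2"]}, self._presence(rows), self.regions
            ) == []
        rows = [[1, 1]] * 3 + [[0, 0]] * 2 + [[1, 1]] * 3 + [[0, 0]] * 2
        assert select_intraspecific_clusters(
            {"c": ["e1", "e2"]}, self._presence(rows), self.regions
        ) == ["c"]


class TestMeanDissimilarity:
    def test_single_matrix_identity(self, rng):
        m = random_dist_matrix(5, rng)
        assert mean_dissimilarity([m]) == m

    def test_pairwise_mean(self):
        m1 = DistMatrix(["a", "b"], np.array([[0, 0.2], [0.2, 0]]))
        m2 = DistMatrix(["a", "b"], np.array([[0, 0.6], [0.6, 0]]))
        assert mean_dissimilarity([m1, m2]).values[0, 1] == pytest.approx(0.4)

    def test_pair_defined_in_one_matrix_only(self):
        m1 = DistMatrix(["a", "b"], np.array([[0, 0.7], [0.7, 0]]))
        m2 = DistMatrix(["a", "c"], np.array([[0, 0.3], [0.3, 0]]))
        mean = mean_dissimilarity([m1, m2])
        i, j = mean.ids.index("a"), mean.ids.index("b")
        assert mean.values[i, j] == pytest.approx(0.7)
        assert np.isnan(mean.values[mean.ids.index("b"), mean.ids.index("c")])

    def test_entries_bounded_by_contributions(self, rng):
        mats = [random_dist_matrix(6, rng) for _ in range(4)]
        mean = mean_dissimilarity(mats)
        stack = np.array([m.values for m in mats])
        iu = np.triu_indices(6, k=1)
        assert np.all(mean.values[iu] >= stack.min(axis=0)[iu] - 1e-12)
        assert np.all(mean.values[iu] <= stack.max(axis=0)[iu] + 1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            mean_dissimilarity([])


class TestCompleteMatrix:
    def test_complete_input_unchanged(self, rng):
        m = random_dist_matrix(5, rng)
        assert complete_matrix(m) == m

    def test_sample_missing_all_pairs_removed(self, rng):
        m = random_dist_matrix(5, rng)
        values = m.values.copy()
        values[2, :] = np.nan
        values[:, 2] = np.nan
        values[2, 2] = 0.0
        broken = DistMatrix(m.ids, values)
        completed = complete_matrix(broken)
        assert completed.ids == [s for i, s in enumerate(m.ids) if i != 2]
        assert completed.is_complete()

    def test_mutual_missing_pair_removes_exactly_one(self, rng):
        m = random_dist_matrix(4, rng)
        values = m.values.copy()
        values[0, 1] = values[1, 0] = np.nan
        completed = complete_matrix(DistMatrix(m.ids, values))
        # tie broken toward removing the lexicographically smallest id
        assert completed.ids == m.ids[1:]
        assert completed.is_complete()

    def test_greedy_keeps_fully_defined_samples(self, rng):
        for _ in range(5):
            m = random_dist_matrix(8, rng, missing_pairs=int(rng.integers(1, 8)))
            complete_ids = {
                s for i, s in enumerate(m.ids)
                if not np.isnan(np.delete(m.values[i], i)).any()
            }
            completed = complete_matrix(m)
            assert completed.is_complete()
            assert complete_ids <= set(completed.ids)
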