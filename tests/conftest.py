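import numpy as np
import pytest

from metaphylo.core_io import DistMatrix, EsvRecord, PresenceMatrix


def make_esv(esv_id, sequence, counts=None, species=None, sbp=None, amplicon="F230R"):
    return EsvRecord(
        esv_id=esv_id,
        amplicon=amplicon,
        sequence=sequence,
        counts=counts or {},
        species=species,
        sbp=sbp,
    )


def random_dist_matrix(n, rng, missing_pairs=0, metric="sorensen"):
    """Random symmetric dissimilarity matrix in [0, 1] with optional missing pairs."""
    values = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    vals = rng.uniform(0.05, 0.95, size=len(iu[0]))
    values[iu] = vals
    values = values + values.T
    if missing_pairs:
        pick = rng.choice(len(iu[0]), size=missing_pairs, replace=False)
        for p in pick:
            i, j = iu[0][p], iu[1][p]
            values[i, j] = values[j, i] = np.nan
    ids = [f"s{i:02d}" for i in range(n)]
    return DistMatrix(ids, values, metric=metric)


def random_presence(n_samples, n_features, rng, p=0.5):
    import pandas as pd

    values = rng.random((n_samples, n_features)) < p
    return PresenceMatrix(
        pd.DataFrame(
            values,
            index=[f"s{i:02d}" for i in range(n_samples)],
            columns=[f"e{j:02d}" for j in range(n_features)],
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
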