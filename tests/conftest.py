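import numpy as np
import pandas as pd
import pytest

from cernakit.config import SimulationConfig
from cernakit.matrix import ExpressionMatrix
from cernakit.preprocess import filter_expressed, size_factors, transform
from cernakit.synthetic import simulate_cohort


@pytest.fixture(scope="session")
def small_sim() -> SimulationConfig:
    """A small but fully structured cohort configuration."""
    return SimulationConfig(
        n_pairs=8,
        n_features_by_biotype={
            "mRNA": 200, "lncRNA": 60, "circRNA": 40, "miRNA": 150,
        },
        n_sponge_triplets=4,
        seed=123,
    )


@pytest.fixture(scope="session")
def small_cohort(small_sim):
    return simulate_cohort(small_sim)


@pytest.fixture(scope="session")
def logged_cohort(small_cohort):
    filtered = filter_expressed(small_cohort.counts)
    return transform(filtered, size_factors(filtered))


def make_matrix(values, conditions=None, biotypes=None, **kw):
    """Small helper to build an ExpressionMatrix from a 2-D array."""
    values = np.asarray(values)
    n_feat, n_samp = values.shape
    feats = [f"f{i}" for i in range(n_feat)]
    samps = [f"s{j}" for j in range(n_samp)]
    df = pd.DataFrame(values, index=feats, columns=samps)
    sample_meta = None
    if conditions is not None:
        sample_meta = pd.DataFrame({"condition": conditions}, index=samps)
    feature_meta = None
    if biotypes is not None:
        feature_meta = pd.DataFrame({"biotype": biotypes}, index=feats)
    return ExpressionMatrix(df, feature_meta, sample_meta, **kw)


@pytest.fixture
def matrix_factory():
    return make_matrix
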