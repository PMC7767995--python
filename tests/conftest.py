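import numpy as np
import pytest

from codatsne import AitchisonTSNE, SyntheticConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(7)


def random_compositions(rng, n, p):
    """Strictly positive random compositions (rows sum to 1)."""
    x = rng.gamma(2.0, size=(n, p))
    return x / x.sum(axis=1, keepdims=True)


@pytest.fixture
def two_cluster_table():
    """Well-separated two-cluster compositional table, 30 + 30 samples."""
    return generate(SyntheticConfig(
        n_case=30, n_control=30, p=40, effect=8.0, within_sd=0.8,
        sparsity=0.2, depth=10_000, seed=11,
    ))


@pytest.fixture
def small_table():
    return generate(SyntheticConfig(
        n_case=10, n_control=12, p=25, effect=5.0, within_sd=1.0,
        sparsity=0.2, depth=5_000, seed=3,
    ))


@pytest.fixture
def fitted_mapper(small_table):
    return AitchisonTSNE(
        n_components=2, perplexity=6, max_iter=250, random_state=5
    ).fit_table(small_table)
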