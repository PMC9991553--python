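import numpy as np
import pytest

from stuntmsm import build_analysis_table, default_config, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size calibrated cohort (complete data) plus its truth."""
    cfg = default_config().replace(seed=1)
    table, truth = generate_cohort(cfg, truth_n_mc=200_000)
    return cfg, table, truth


@pytest.fixture(scope="session")
def analysis_table(default_cohort):
    _, table, _ = default_cohort
    return build_analysis_table(table, scenario="all_waves")


@pytest.fixture()
def rng():
    return np.random.default_rng(20250928)


def random_logit_data(rng, n=500, k=4, clusters=60):
    """Random binary-outcome regression data for oracle comparisons."""
    X = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
    beta = rng.normal(scale=0.7, size=k)
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-X @ beta))).astype(float)
    w = rng.uniform(0.5, 2.0, n)
    g = rng.integers(0, clusters, n)
    return X, y, w, g
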