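import numpy as np
import pytest

from kcqi.index import add_kcqi_column
from kcqi.simulate import SimConfig, simulate_quality_table


@pytest.fixture(scope="session")
def default_config():
    return SimConfig(seed=42)


@pytest.fixture(scope="session")
def default_table(default_config):
    """Default 240-fruit study table (2 cultivars x 4 days x 30)."""
    return simulate_quality_table(default_config)


@pytest.fixture(scope="session")
def default_table_kcqi(default_table):
    return add_kcqi_column(default_table)


@pytest.fixture(scope="session")
def big_table():
    """10,000-fruit table for tight correlation checks (1250 per group)."""
    return simulate_quality_table(SimConfig(n_per_group=1250, seed=7))


@pytest.fixture(scope="session")
def planted_dataset():
    """Regression problem with 5 truly informative bands out of 60.

    y depends only on bands [5, 17, 29, 41, 53] plus small noise; the
    remaining bands are smooth distractors correlated within a neighborhood
    (so selection is nontrivial but solvable).
    """
    rng = np.random.default_rng(123)
    n, p = 90, 60
    latent = rng.normal(size=(n, 12))
    mix = rng.normal(size=(12, p)) * 0.15
    X = latent @ mix + rng.normal(size=(n, p))
    true_bands = np.array([5, 17, 29, 41, 53])
    coef = np.array([1.5, -1.2, 1.0, 1.3, -1.1])
    y = X[:, true_bands] @ coef + 0.1 * rng.normal(size=n)
    return X, y, true_bands
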