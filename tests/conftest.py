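import numpy as np
import pandas as pd
import pytest

from esfilter import SimulationConfig, StationSet, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_xy(rng):
    """Ten well-separated planar points."""
    return rng.uniform(0, 100, size=(10, 2))


@pytest.fixture(scope="session")
def small_truth():
    """A 50-station synthetic scene with a 3-eigenvector spatial filter."""
    return simulate_dataset(SimulationConfig(seed=7, n_stations=50, sigma=1.0))


@pytest.fixture(scope="session")
def medium_truth():
    """A 120-station scene used by the heavier regression/diagnostic tests."""
    return simulate_dataset(SimulationConfig(seed=11, n_stations=120, sigma=1.5))


def make_stations(n=12, seed=0, n_cov=2, beta=None, sigma=0.0, intercept=10.0):
    """Small hand-rolled station set: y linear in iid covariates plus noise."""
    g = np.random.default_rng(seed)
    xy = g.uniform(0, 50, size=(n, 2))
    X = pd.DataFrame({f"c{k}": g.normal(size=n) for k in range(n_cov)})
    beta = np.ones(n_cov) if beta is None else np.asarray(beta, dtype=float)
    y = intercept + X.to_numpy() @ beta + sigma * g.normal(size=n)
    return StationSet(
        ids=np.array([f"s{i}" for i in range(n)]), xy=xy, values=y, covariates=X
    )


@pytest.fixture
def linear_stations():
    return make_stations(n=15, seed=3, n_cov=2, beta=[2.0, -1.0])
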