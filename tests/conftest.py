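import numpy as np
import pytest

from mliv import IVDataset, SimulationConfig, gen_valid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def valid_data():
    """Medium valid-instrument draw shared across tests."""
    return gen_valid(SimulationConfig(dgp="valid", n=400, seed=7))


@pytest.fixture
def tiny_dataset(rng):
    """Small generic dataset with 2 covariates and 2 instruments."""
    n = 60
    X = rng.standard_normal((n, 2))
    Z = rng.standard_normal((n, 2))
    t = X[:, 0] + Z[:, 0] + rng.standard_normal(n)
    y = X[:, 0] + t + rng.standard_normal(n)
    return IVDataset(X=X, Z=Z, t=t, y=y)
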