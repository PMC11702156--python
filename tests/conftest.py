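import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from eaic.glm import Dataset

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)


@pytest.fixture()
def linear_data(rng):
    """Small linear dataset with three active variables among twenty."""
    n, p = 120, 20
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    beta[[2, 7, 11]] = [1.0, -0.8, 0.6]
    y = X @ beta + rng.standard_normal(n)
    return Dataset(X=X, y=y, family="linear")


@pytest.fixture()
def logistic_data(rng):
    """Small logistic dataset with two active variables among fifteen."""
    n, p = 150, 15
    X = rng.standard_normal((n, p))
    eta = 1.2 * X[:, 3] - 0.9 * X[:, 8]
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    return Dataset(X=X, y=y, family="logistic")
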