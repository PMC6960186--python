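import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_membership(rng):
    """Random row-stochastic membership matrix, L=6, c=3."""
    U = rng.random((6, 3))
    return U / U.sum(axis=1, keepdims=True)


@pytest.fixture
def two_clouds(rng):
    """Two tight, far-separated Gaussian clouds (separation >> spread)."""
    a = rng.normal(0.0, 0.05, size=(30, 3))
    b = rng.normal(10.0, 0.05, size=(30, 3))
    X = np.vstack([a, b])
    labels = np.array([0] * 30 + [1] * 30)
    return X, labels
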