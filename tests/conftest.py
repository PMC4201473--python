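import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_regression(rng, n=50, p=8, beta=None, noise=0.3, weights=None):
    """Small dense regression instance with known coefficients."""
    X = rng.standard_normal((n, p))
    if beta is None:
        beta = np.zeros(p)
        beta[: min(3, p)] = [2.0, -1.5, 1.0][: min(3, p)]
    y = X @ beta + noise * rng.standard_normal(n)
    u = np.ones(n) if weights is None else weights
    return X, y, u, beta
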