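import numpy as np
import pytest
from scipy.special import expit

from mtpen import GroupedDataset


def make_logistic_data(seed, n=40, p1=4, p2=4, beta_scale=1.0):
    """Small seeded two-platform dataset with a few informative features."""
    rng = np.random.default_rng(seed)
    p = p1 + p2
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    beta[0] = 1.2 * beta_scale
    beta[1] = -0.8 * beta_scale
    beta[p1] = 0.9 * beta_scale
    y = (rng.random(n) < expit(X @ beta)).astype(float)
    if y.min() == y.max():  # pragma: no cover - seeds below avoid this
        y[0] = 1.0 - y[0]
    return GroupedDataset(X, y, (p1, p2))


@pytest.fixture
def small_data():
    return make_logistic_data(seed=3)
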