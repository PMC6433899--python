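import numpy as np
import pytest

from rfvarsel import Dataset, RFParams


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_regression(n=60, p=20, strong=0, noise_sd=0.2, seed=0):
    """Small regression dataset where column ``strong`` drives the outcome."""
    r = np.random.default_rng(seed)
    X = r.uniform(size=(n, p))
    y = 3.0 * X[:, strong] + r.normal(0, noise_sd, n)
    return Dataset(X, y, [f"v{i}" for i in range(p)], "regression")


def make_classification(n=60, p=20, informative=0, flip=0.0, seed=0):
    """Binary classification dataset driven by column ``informative``."""
    r = np.random.default_rng(seed)
    X = r.uniform(size=(n, p))
    y = (X[:, informative] > 0.5).astype(int)
    if flip:
        mask = r.random(n) < flip
        y[mask] = 1 - y[mask]
    if len(np.unique(y)) < 2:  # pragma: no cover - guards tiny n
        y[0] = 1 - y[0]
    return Dataset(X, y, [f"v{i}" for i in range(p)], "classification")


def make_null_classification(n=60, p=20, seed=0):
    r = np.random.default_rng(seed)
    X = r.uniform(size=(n, p))
    y = np.repeat([0, 1], n // 2)
    return Dataset(X, r.permutation(y), [f"v{i}" for i in range(p)], "classification")


@pytest.fixture
def small_params():
    return RFParams(ntree=100, seed=7)
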