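import numpy as np
import pytest

from gmnsc import ExpressionData, compute_statistics


def make_data(values, labels, prefix="s"):
    """ExpressionData from raw arrays with generated IDs."""
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    return ExpressionData(
        values=values,
        variable_ids=[f"v{j}" for j in range(p)],
        sample_ids=[f"{prefix}{i}" for i in range(n)],
        labels=np.asarray(labels, dtype=int),
    )


@pytest.fixture
def toy2():
    """Two-class dataset, 12 variables x 20 samples, generic values."""
    rng = np.random.default_rng(101)
    labels = np.r_[np.ones(12, int), np.full(8, 2)]
    X = rng.normal(size=(12, 20))
    X[:3, labels == 2] += 1.5     # a few informative variables
    return make_data(X, labels)


@pytest.fixture
def toy3():
    """Three-class dataset with unequal within-class spreads."""
    rng = np.random.default_rng(202)
    labels = np.r_[np.ones(6, int), np.full(5, 2), np.full(7, 3)]
    X = rng.normal(size=(15, 18))
    X[:, labels == 2] *= 1.7
    X[:4, labels == 3] += 2.0
    return make_data(X, labels)


@pytest.fixture
def stats2(toy2):
    return compute_statistics(toy2)


@pytest.fixture
def stats3(toy3):
    return compute_statistics(toy3)
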