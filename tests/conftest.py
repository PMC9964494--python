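import numpy as np
import pytest

from connstats import Connectome


def random_connectome(rng, n, density=0.5, max_w=10, labels=None):
    """Small random weighted graph for oracle tests (may be disconnected)."""
    W = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    present = rng.random(len(iu[0])) < density
    weights = rng.integers(1, max_w + 1, size=len(iu[0])).astype(float)
    W[iu] = np.where(present, weights, 0.0)
    W = W + W.T
    if labels is None:
        labels = tuple(f"n{i}" for i in range(n))
    return Connectome(labels=labels, W=W)


@pytest.fixture
def rng():
    return np.random.default_rng(20230227)


@pytest.fixture
def triangle():
    """Uniform-weight triangle: every clustering coefficient is exactly 1."""
    W = np.array([[0, 3, 3], [3, 0, 3], [3, 3, 0]], dtype=float)
    return Connectome(labels=("a", "b", "c"), W=W)


@pytest.fixture
def star5():
    """Unit-weight star K_{1,5}; node 0 is the hub."""
    n = 6
    W = np.zeros((n, n))
    W[0, 1:] = 1.0
    W[1:, 0] = 1.0
    return Connectome(labels=tuple(f"n{i}" for i in range(n)), W=W)
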