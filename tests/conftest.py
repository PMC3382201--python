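import numpy as np
import pytest

from hierconn.io import SubjectStack


def block_matrix(sizes, w_in=1.0, w_out=0.0):
    """Exact block-diagonal-plus-background matrix with zero diagonal."""
    n = sum(sizes)
    w = np.full((n, n), float(w_out))
    start = 0
    for s in sizes:
        w[start:start + s, start:start + s] = w_in
        start += s
    np.fill_diagonal(w, 0.0)
    return w


def random_weighted_matrix(n, rng, density=0.5, scale=1.0):
    """Random symmetric non-negative matrix with zero diagonal."""
    iu, ju = np.triu_indices(n, k=1)
    vals = rng.exponential(scale, size=iu.size)
    vals[rng.random(iu.size) >= density] = 0.0
    w = np.zeros((n, n))
    w[iu, ju] = vals
    w[ju, iu] = vals
    return w


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_stack():
    """Three subjects, five nodes, hand-checkable weights."""
    rng = np.random.default_rng(7)
    mats = np.stack([random_weighted_matrix(5, rng, density=0.8) for _ in range(3)])
    return SubjectStack(mats, [f"R{i}" for i in range(5)])
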