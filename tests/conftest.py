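import numpy as np
import pytest

from poistopics import CountMatrix, simulate_pnmf_data


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_counts(rng):
    """Random 5x4 counts with some zeros, as (CountMatrix, dense array)."""
    dense = rng.poisson(1.5, size=(5, 4))
    dense[0, 0] = 0
    dense[2] = [0, 3, 0, 1]
    if dense.sum() == 0:  # pragma: no cover - vanishingly unlikely
        dense[0, 1] = 1
    X = CountMatrix(dense)
    return X, X.toarray()


def random_instance(seed, n=30, m=40, K=5, scale=2.0):
    """Counts plus strictly positive random (H, W) of the right shapes."""
    X, _, _ = simulate_pnmf_data(n, m, K, scale=scale, seed=seed)
    r = np.random.default_rng(seed + 1_000_000)
    H = r.gamma(2.0, 1.0, size=(n, K)) + 1e-3
    W = r.gamma(2.0, 1.0, size=(m, K)) + 1e-3
    return X, H, W
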