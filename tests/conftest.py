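import numpy as np
import pytest

import lssd


@pytest.fixture
def toy_matrix():
    """Small deterministic expression matrix (6 cells x 4 genes)."""
    rng = np.random.default_rng(123)
    values = rng.poisson(5.0, size=(6, 4)).astype(float)
    return lssd.ExpressionMatrix(
        values, [f"c{i}" for i in range(6)], [f"g{j}" for j in range(4)]
    )


@pytest.fixture
def two_blobs():
    """Two moderately separated Gaussian blobs (40 cells, 5 features) + labels."""
    rng = np.random.default_rng(7)
    a = rng.normal(0.0, 0.6, size=(20, 5))
    b = rng.normal(2.0, 0.6, size=(20, 5))
    X = np.vstack([a, b])
    labels = np.repeat([0, 1], 20)
    return X, labels


def block_affinity(n_blocks: int, block_size: int = 20, seed: int = 42) -> np.ndarray:
    """Exact block-diagonal affinity: random positive weights within blocks."""
    rng = np.random.default_rng(seed)
    n = n_blocks * block_size
    W = np.zeros((n, n))
    for b in range(n_blocks):
        sl = slice(b * block_size, (b + 1) * block_size)
        blk = rng.uniform(0.5, 1.0, size=(block_size, block_size))
        W[sl, sl] = (blk + blk.T) / 2.0
    np.fill_diagonal(W, 1.0)
    return W
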