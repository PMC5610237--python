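import numpy as np
import pytest


def brute_force_two_nearest(X, box=None):
    """Exhaustive O(N^2) two-nearest-neighbor oracle (minimum image if box)."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    r1 = np.empty(n)
    r2 = np.empty(n)
    for i in range(n):
        delta = np.abs(X - X[i])
        if box is not None:
            sides = np.asarray(box, dtype=float)
            delta = np.minimum(delta, sides - delta)
        dist = np.sqrt((delta**2).sum(axis=1))
        dist[i] = np.inf
        smallest = np.sort(dist)[:2]
        r1[i], r2[i] = smallest[0], smallest[1]
    return r1, r2


def pairwise_euclidean(X):
    """Dense symmetric Euclidean distance matrix (exact zero diagonal)."""
    from scipy.spatial.distance import squareform, pdist

    return squareform(pdist(np.asarray(X, dtype=float)))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_cloud(rng):
    """Modest 3-D cloud for exact-oracle comparisons."""
    return rng.normal(size=(120, 3))
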