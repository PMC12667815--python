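import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_distance_matrix():
    """Distance matrix of the 1-D points [0, 3, 4]; medoid is index 1."""
    return np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 1.0], [4.0, 1.0, 0.0]])


def random_distance_matrix(rng, s):
    X = rng.random((s, rng.integers(1, 6)))
    from scipy.spatial.distance import pdist, squareform

    return squareform(pdist(X))


def brute_force_greedy(D, n, start, criterion):
    """Independent greedy oracle recomputing the criterion from scratch."""
    s = D.shape[0]
    selected = list(start)
    while len(selected) < n:
        best, best_val = None, -np.inf
        for i in range(s):
            if i in selected:
                continue
            vals = [D[i, j] for j in selected]
            val = min(vals) if criterion == "maxmin" else sum(vals)
            if val > best_val:
                best, best_val = i, val
        selected.append(best)
    return selected
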