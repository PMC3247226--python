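import numpy as np
import pytest

from regnann import AdjacencyMatrix, CorrelationMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_adjacency(rng, n, p=0.3):
    """Random symmetric binary adjacency with zero diagonal."""
    a = np.zeros((n, n), dtype=np.int8)
    iu = np.triu_indices(n, k=1)
    a[iu] = rng.random(iu[0].size) < p
    a += a.T
    return AdjacencyMatrix(a)


def random_scores(rng, n):
    """Random symmetric-free score matrix in [-1, 1], zero diagonal."""
    s = rng.uniform(-1.0, 1.0, size=(n, n))
    np.fill_diagonal(s, 0.0)
    return CorrelationMatrix(s)
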