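import numpy as np
import pytest

from ecoweb.network_io import BipartiteNetwork, DirectedNetwork


@pytest.fixture
def staircase():
    """Perfectly nested 3x3 matrix (NODF = 100)."""
    return BipartiteNetwork(("p1", "p2", "p3"), ("a1", "a2", "a3"), [[1, 1, 1], [1, 1, 0], [1, 0, 0]])


@pytest.fixture
def two_blocks():
    """Two disconnected complete 2x2 bipartite blocks (Barber M = 0.5)."""
    return BipartiteNetwork(
        tuple("abcd"),
        tuple("wxyz"),
        [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]],
    )


@pytest.fixture
def two_cycles():
    """Two disconnected directed 3-cycles (directed M = 0.5)."""
    adj = np.zeros((6, 6), dtype=int)
    for i, j in [(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3)]:
        adj[i, j] = 1
    return DirectedNetwork(tuple("abcdef"), adj)


def random_bipartite(rng, n_rows, n_cols, p=0.45):
    """Random valid bipartite fixture (no empty rows/columns)."""
    while True:
        mat = (rng.random((n_rows, n_cols)) < p).astype(int)
        if mat.sum() >= 2 and mat.sum(axis=1).min() > 0 and mat.sum(axis=0).min() > 0:
            return BipartiteNetwork(
                tuple(f"p{i}" for i in range(n_rows)),
                tuple(f"a{j}" for j in range(n_cols)),
                mat,
            )


def random_directed(rng, n, p=0.3):
    """Random valid directed fixture with at least one edge."""
    while True:
        adj = (rng.random((n, n)) < p).astype(int)
        np.fill_diagonal(adj, 0)
        if adj.sum() >= 2:
            return DirectedNetwork(tuple(f"s{i}" for i in range(n)), adj)
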