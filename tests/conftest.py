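import numpy as np
import pytest

from fcnet.connectivity import BinaryNetwork, ConnectivityMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def net_from_edges(n, edges):
    """BinaryNetwork from an explicit undirected edge list."""
    A = np.zeros((n, n), dtype=np.uint8)
    for i, j in edges:
        A[i, j] = A[j, i] = 1
    m = int(A.sum()) // 2
    return BinaryNetwork(adjacency=A, density=2 * m / (n * (n - 1)))


def random_network(rng, n, p):
    """Erdos-Renyi G(n, p) instance as a BinaryNetwork."""
    A = (rng.random((n, n)) < p).astype(np.uint8)
    A = np.triu(A, k=1)
    A = A + A.T
    m = int(A.sum()) // 2
    return BinaryNetwork(adjacency=A, density=2 * m / (n * (n - 1)))


def cm_from_r(r, p=None, n_samples=100):
    """ConnectivityMatrix from an explicit symmetric r matrix (diag zeroed)."""
    r = np.asarray(r, dtype=float).copy()
    np.fill_diagonal(r, 0.0)
    if p is None:
        p = np.full_like(r, 0.5)
    else:
        p = np.asarray(p, dtype=float).copy()
    np.fill_diagonal(p, np.nan)
    return ConnectivityMatrix(r=r, p=p, n_samples=n_samples)


def to_networkx(net):
    import networkx as nx

    return nx.from_numpy_array(np.asarray(net.adjacency))
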