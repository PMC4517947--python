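import numpy as np
import pytest

from prunenet.graph_core import RoutingNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def net_from_edges(n, edges):
    net = RoutingNetwork(n)
    for u, v in edges:
        net.add_edge(u, v)
    return net


@pytest.fixture
def toy5():
    """5-node toy with a unique 2-hop route 0 -> 4 and a 3-hop alternative."""
    return net_from_edges(5, [(0, 1), (1, 4), (0, 2), (2, 3), (3, 4)])


def random_digraph(n, m, rng):
    """Uniform simple digraph with m directed edges on n nodes."""
    total = n * (n - 1)
    idx = rng.choice(total, size=m, replace=False)
    edges = []
    for k in idx:
        u, r = divmod(int(k), n - 1)
        edges.append((u, r if r < u else r + 1))
    return net_from_edges(n, edges)
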