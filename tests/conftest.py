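import networkx as nx
import numpy as np
import pytest

from scprank.datatypes import (CompartmentAnnotation, EssentialSet,
                               PPINetwork, ScoreVector)


def make_network(edges, weights=None, extra_nodes=()):
    g = nx.Graph()
    g.add_nodes_from(extra_nodes)
    for e in edges:
        g.add_edge(*e)
    if weights is not None:
        for e, w in weights.items():
            g.edges[e]["weight"] = w
    return PPINetwork(g)


def random_connected_weighted(rng, n_max=50):
    """A random connected graph with uniform(0.1, 1) edge weights and a
    random positive IPSC-like prior; used by the eigenvector-oracle tests."""
    n = int(rng.integers(5, n_max + 1))
    while True:
        g = nx.gnp_random_graph(n, min(1.0, 3.0 / n), seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            break
    net = PPINetwork(nx.relabel_nodes(g, {i: f"P{i}" for i in g.nodes}))
    for u, v in net.graph.edges:
        net.graph.edges[u, v]["weight"] = float(rng.uniform(0.1, 1.0))
    prior = ScoreVector({p: float(rng.uniform(0.1, 1.0)) for p in net.graph.nodes})
    return net, prior


def dominant_eigenvector(matrix):
    """Dense dominant-eigenvector oracle: largest-|eigenvalue| eigenvector,
    sign-fixed to non-negative, L1-normalized."""
    vals, vecs = np.linalg.eig(matrix)
    v = np.real(vecs[:, np.argmax(np.abs(vals))])
    if v.sum() < 0:
        v = -v
    return v / np.abs(v).sum()


@pytest.fixture
def toy_annotation():
    # C1 is large (10 members), C2 medium (5), C3 small (2); sizes are given
    # explicitly rather than recomputed from the three listed proteins.
    return CompartmentAnnotation(
        scl={"P1": frozenset({"C1", "C2"}),
             "P2": frozenset({"C2", "C3"}),
             "P3": frozenset({"C3"})},
        sizes={"C1": 10, "C2": 5, "C3": 2},
    )


@pytest.fixture
def path_network():
    return make_network([("A", "B"), ("B", "C")])


@pytest.fixture
def essential_ab():
    return EssentialSet(frozenset({"E1", "E2"}))
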