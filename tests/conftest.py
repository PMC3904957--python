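"""Shared fixtures: small hand-built networks with known structure."""

import pytest

from linknmf import Network


def clique_edges(nodes):
    return [
        (nodes[a], nodes[b], 1.0)
        for a in range(len(nodes))
        for b in range(a + 1, len(nodes))
    ]


@pytest.fixture
def two_clique_network():
    """Two 5-node cliques sharing one node: 9 nodes, 20 edges.

    Nodes are labelled "1".."9"; node "5" (index 4) is the shared node.
    The planted link communities are the two cliques' edge sets.
    """
    edges = clique_edges([0, 1, 2, 3, 4]) + clique_edges([4, 5, 6, 7, 8])
    return Network([str(i + 1) for i in range(9)], edges)


@pytest.fixture
def two_clique_truth(two_clique_network):
    """Planted link partition of the shared-node two-clique network."""
    from linknmf import LinkPartition

    assignment = {}
    for i, j, _ in two_clique_network.edges:
        assignment[(i, j)] = 1 if j <= 4 else 2
    return LinkPartition(assignment)


@pytest.fixture
def disjoint_cliques():
    """Two disjoint 5-node cliques: 10 nodes, 20 edges."""
    edges = clique_edges([0, 1, 2, 3, 4]) + clique_edges([5, 6, 7, 8, 9])
    return Network([str(i) for i in range(10)], edges)


@pytest.fixture
def single_clique():
    """One 5-node clique."""
    return Network(list("abcde"), clique_edges([0, 1, 2, 3, 4]))


@pytest.fixture
def path_network():
    """A 5-node path (a tree with 4 edges)."""
    return Network(list("abcde"), [(i, i + 1, 1.0) for i in range(4)])
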