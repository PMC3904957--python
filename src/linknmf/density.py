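"""Link-partition quality and benchmark accuracy metrics.

Partition density scores a partition of a network's links.  A community
with ``m_z`` links (or total weight) touching ``n_z`` nodes has link
density

    D_z = (m_z - (n_z - 1)) / (n_z (n_z - 1) / 2 - (n_z - 1)),

i.e. ``m_z`` normalized between the minimum (tree, ``n_z - 1``) and
maximum (clique, ``n_z (n_z - 1) / 2``) link counts among ``n_z``
connected nodes: 1 for a clique, 0 for a tree.  Communities touching
fewer than three nodes are assigned density 0 by convention.  The
partition density ``D`` is the link-weighted average of the ``D_z``, and
the change of ``D`` under a bipartition of one community depends only on
that community — the property that makes recursive bipartition
order-independent.

FVCC (fraction of vertices classified correctly) and the Jaccard index
of the overlapping-node sets score recovered overlapping memberships
against a planted truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Set

import numpy as np
from scipy.optimize import linear_sum_assignment

from .network import LinkPartition, Network

__all__ = [
    "CommunityStats",
    "link_density",
    "partition_density",
    "community_stats",
    "delta_partition_density",
    "fvcc",
    "jaccard_overlap",
]


@dataclass(frozen=True)
class CommunityStats:
    """Link weight ``m_z`` and induced node count ``n_z`` of one community."""

    m_z: float
    n_z: int


def link_density(m_z: float, n_z: int) -> float:
    """Density of one link community; 0 for degenerate ``n_z < 3``.

    Multigraph or weighted communities denser than a simple clique yield
    values above 1; these are reported raw, with a warning.
    """
    if m_z < 0 or n_z < 0:
        raise ValueError("m_z and n_z must be nonnegative")
    if n_z < 3:
        return 0.0
    max_links = n_z * (n_z - 1) / 2.0
    d = (m_z - (n_z - 1)) / (max_links - (n_z - 1))
    if d > 1.0:
        warnings.warn(
            f"community denser than a simple clique (m_z={m_z:g}, n_z={n_z}); "
            "density exceeds 1",
            RuntimeWarning,
            stacklevel=2,
        )
    return d


def community_stats(edges: Iterable[tuple[int, int, float]]) -> CommunityStats:
    """Stats of a community given its ``(i, j, w)`` link triples."""
    nodes: set[int] = set()
    total = 0.0
    for i, j, w in edges:
        nodes.update((i, j))
        total += w
    return CommunityStats(m_z=total, n_z=len(nodes))


def _per_community_stats(
    partition: LinkPartition, network: Network
) -> dict[int, CommunityStats]:
    groups: dict[int, list[tuple[int, int, float]]] = {
        z: [] for z in range(1, partition.c + 1)
    }
    for i, j, w in network.edges:
        groups[partition.assignment[(i, j)]].append((i, j, w))
    return {z: community_stats(g) for z, g in groups.items()}


def partition_density(partition: LinkPartition, network: Network) -> float:
    """Link-weighted average density, ``D = sum_z (m_z / m) D_z``."""
    partition.validate_against(network)
    m = network.m
    if m <= 0:
        return 0.0
    stats = _per_community_stats(partition, network)
    return sum((st.m_z / m) * link_density(st.m_z, st.n_z) for st in stats.values())


def delta_partition_density(
    parent: CommunityStats,
    child1: CommunityStats,
    child2: CommunityStats,
    m: float,
) -> float:
    """Change in global partition density when *parent* splits into the children.

    Only the split community contributes:
    ``dD = (m_1 D_1 + m_2 D_2 - m_r D_r) / m``.  A degenerate split with
    an empty child leaves ``D`` unchanged.
    """
    if abs(child1.m_z + child2.m_z - parent.m_z) > 1e-9 * max(parent.m_z, 1.0):
        raise ValueError(
            f"children's link weight {child1.m_z + child2.m_z:g} does not match "
            f"the parent's {parent.m_z:g}"
        )
    if child1.m_z == 0 or child2.m_z == 0:
        return 0.0
    if m <= 0:
        raise ValueError("total link weight m must be positive")
    gain = (
        child1.m_z * link_density(child1.m_z, child1.n_z)
        + child2.m_z * link_density(child2.m_z, child2.n_z)
        - parent.m_z * link_density(parent.m_z, parent.n_z)
    )
    return gain / m


# ---------------------------------------------------------------------------
# accuracy against a planted truth
# ---------------------------------------------------------------------------


def _match_labels(
    predicted: Mapping[int, Set[int]], truth: Mapping[int, Set[int]]
) -> dict[int, int]:
    """Optimal predicted->true label map by maximum total node overlap."""
    pred_labels = sorted({z for s in predicted.values() for z in s})
    true_labels = sorted({z for s in truth.values() for z in s})
    if not pred_labels or not true_labels:
        return {}
    overlap = np.zeros((len(pred_labels), len(true_labels)))
    p_idx = {z: k for k, z in enumerate(pred_labels)}
    t_idx = {z: k for k, z in enumerate(true_labels)}
    for node, pset in predicted.items():
        tset = truth.get(node, set())
        for a in pset:
            for b in tset:
                overlap[p_idx[a], t_idx[b]] += 1.0
    rows, cols = linear_sum_assignment(overlap, maximize=True)
    return {pred_labels[r]: true_labels[c] for r, c in zip(rows, cols)}


def fvcc(
    predicted: Mapping[int, Set[int]], truth: Mapping[int, Set[int]]
) -> float:
    """Fraction of vertices whose full membership set is recovered.

    Predicted community labels are first matched to planted labels by
    optimal assignment on the node-overlap confusion matrix; a node then
    counts as correct only if its mapped predicted set equals its planted
    set exactly.  Predicted labels left unmatched make their nodes
    incorrect.
    """
    if set(predicted) != set(truth):
        raise ValueError("predicted and truth must cover the same node universe")
    if not truth:
        return 1.0
    mapping = _match_labels(predicted, truth)
    correct = 0
    for node, pset in predicted.items():
        if any(z not in mapping for z in pset):
            continue
        if {mapping[z] for z in pset} == truth[node]:
            correct += 1
    return correct / len(truth)


def jaccard_overlap(predicted_overlap: Set[int], true_overlap: Set[int]) -> float:
    """Jaccard index ``|S n V| / |S u V|`` of the overlapping-node sets."""
    V, S = set(predicted_overlap), set(true_overlap)
    union = S | V
    if not union:
        return 1.0
    return len(S & V) / len(union)
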