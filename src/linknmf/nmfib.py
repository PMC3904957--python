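"""NMFIB: recursive bipartition of link sets with automatic community count.

The driver repeatedly splits a set of links in two by fitting the
generative model with ``c = 2`` on the subnetwork those links induce
(isolated from the rest of the network) and hard-assigning each link.
A split is kept only if it strictly increases partition density; because
the density change of a split depends only on the community being split,
the acceptance decisions are independent of the order in which
communities are visited, and the number of communities emerges on its
own.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable

from . import sym_nmf
from .density import CommunityStats, community_stats, delta_partition_density
from .generative import hard_partition, soft_membership
from .network import Edge, LinkPartition, Network

__all__ = ["BipartitionNode", "bipartition", "run_nmfib", "community_count"]


@dataclass
class BipartitionNode:
    """One node of the bipartition decision tree."""

    link_set: list[Edge]
    stats: CommunityStats
    accepted: bool = False
    delta_D: float = 0.0
    children: list["BipartitionNode"] = field(default_factory=list)

    def leaves(self) -> list["BipartitionNode"]:
        if not self.accepted:
            return [self]
        out: list[BipartitionNode] = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out

    def to_dict(self) -> dict:
        d = {
            "m_z": self.stats.m_z,
            "n_z": self.stats.n_z,
            "links": len(self.link_set),
            "delta_D": self.delta_D,
            "accepted": self.accepted,
        }
        if self.children:
            d["children"] = [ch.to_dict() for ch in self.children]
        return d


def _child_seed(parent_seed: int, link_set: Iterable[Edge]) -> int:
    """Deterministic sub-seed from the parent seed and the link set."""
    h = hashlib.blake2b(digest_size=4)
    h.update(str(int(parent_seed)).encode())
    for i, j in sorted(link_set):
        h.update(f"{i},{j};".encode())
    return int.from_bytes(h.digest(), "big") % (2**31)


def bipartition(
    link_set: Iterable[Edge],
    network: Network,
    seed: int,
    **fit_options,
) -> tuple[list[Edge], list[Edge]]:
    """Split a link set in two by a ``c = 2`` model fit on its subnetwork.

    One side may come back empty when the fit collapses onto a single
    community (e.g. a single link).
    """
    link_set = list(link_set)
    if not link_set:
        raise ValueError("cannot bipartition an empty link set")
    sub, back = network.subnetwork(link_set)
    try:
        result = sym_nmf.fit(sub, c=2, seed=seed, **fit_options)
    except Exception as exc:  # propagate with context on the subproblem
        raise RuntimeError(
            f"c=2 fit failed on subnetwork with {sub.n} nodes, "
            f"{sub.n_edges} links (m={sub.m:g})"
        ) from exc
    part = hard_partition(soft_membership(result.params, sub))
    side1: list[Edge] = []
    side2: list[Edge] = []
    for (i, j), z in part.assignment.items():
        a, b = back[i], back[j]
        edge = (a, b) if a <= b else (b, a)
        (side1 if z == 1 else side2).append(edge)
    return side1, side2


def run_nmfib(
    network: Network,
    seed: int = 0,
    min_links: int = 2,
    **fit_options,
) -> tuple[LinkPartition, BipartitionNode]:
    """Recursive bipartition of the whole network.

    Returns the final link partition (communities numbered 1..c in
    depth-first leaf order) and the full decision tree.  A split is
    accepted iff both sides are non-empty and the partition-density gain
    is strictly positive; communities with fewer than ``min_links`` links
    are never split.
    """
    if network.n_edges == 0:
        raise ValueError("cannot partition an empty network")
    m = network.m

    def stats_of(links: list[Edge]) -> CommunityStats:
        return community_stats(
            (i, j, network.weight(i, j)) for i, j in links
        )

    def recurse(links: list[Edge], seed_here: int) -> BipartitionNode:
        node = BipartitionNode(link_set=links, stats=stats_of(links))
        if len(links) < min_links:
            return node
        s1, s2 = bipartition(links, network, seed=seed_here, **fit_options)
        if not s1 or not s2:
            return node
        st1, st2 = stats_of(s1), stats_of(s2)
        node.delta_D = delta_partition_density(node.stats, st1, st2, m)
        if node.delta_D > 0.0:
            node.accepted = True
            node.children = [
                recurse(s1, _child_seed(seed_here, s1)),
                recurse(s2, _child_seed(seed_here, s2)),
            ]
        return node

    root = recurse(list(network.edge_keys), int(seed))
    assignment: dict[Edge, int] = {}
    for z, leaf in enumerate(root.leaves(), start=1):
        for e in leaf.link_set:
            assignment[e] = z
    partition = LinkPartition(assignment)
    partition.validate_against(network)
    return partition, root


def community_count(partition: LinkPartition) -> int:
    """Number of non-empty communities in a partition."""
    return len({z for z in partition.assignment.values()})
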