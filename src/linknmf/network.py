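"""Undirected weighted networks and link partitions.

A :class:`Network` stores an undirected multigraph that has been collapsed
to a weighted simple graph with optional self-loops: parallel edges are
merged by summing their weights.  External node labels (arbitrary strings)
are preserved in first-appearance order and mapped to contiguous 0-based
internal indices.

Conventions
-----------
* ``m`` is the total edge weight (= edge count for unweighted graphs).
* The sparse adjacency puts ``A[i, j] = A[j, i] = w`` for ``i != j`` and
  ``A[i, i] = 2 * w`` for a self-loop of weight ``w``, so that
  ``A.sum() == 2 * m`` always holds — the convention of random-multigraph
  models, where the diagonal counts both stubs of a self-loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Network",
    "LinkPartition",
    "EdgeListError",
    "read_edge_list",
    "write_link_partition",
    "read_link_partition",
    "write_node_memberships",
]

Edge = tuple[int, int]


class EdgeListError(ValueError):
    """Malformed or invalid edge-list input."""


def _canon(i: int, j: int) -> Edge:
    return (i, j) if i <= j else (j, i)


class Network:
    """An undirected, nonnegatively weighted network.

    Parameters
    ----------
    node_labels
        Unique external identifiers, in the order that defines the
        internal 0-based indexing.
    edges
        Iterable of ``(i, j, w)`` with internal indices and positive
        weights.  Duplicate (unordered) pairs are merged by weight
        summation; self-loops ``(i, i, w)`` are allowed.
    """

    def __init__(self, node_labels: Sequence[str], edges: Iterable[tuple[int, int, float]]):
        self.node_labels: list[str] = [str(x) for x in node_labels]
        if len(set(self.node_labels)) != len(self.node_labels):
            raise EdgeListError("node labels must be unique")
        self.n = len(self.node_labels)
        if self.n < 1:
            raise EdgeListError("a network needs at least one node")
        weights: dict[Edge, float] = {}
        for i, j, w in edges:
            if not (0 <= i < self.n and 0 <= j < self.n):
                raise EdgeListError(f"edge ({i}, {j}) references an unknown node index")
            if not w > 0:
                raise EdgeListError(f"edge ({i}, {j}) has non-positive weight {w}")
            key = _canon(int(i), int(j))
            weights[key] = weights.get(key, 0.0) + float(w)
        self._weights = weights

    # -- basic accessors -------------------------------------------------

    @property
    def edges(self) -> list[tuple[int, int, float]]:
        """Canonical ``(i, j, w)`` triples with ``i <= j``, insertion order."""
        return [(i, j, w) for (i, j), w in self._weights.items()]

    @property
    def edge_keys(self) -> list[Edge]:
        return list(self._weights.keys())

    @property
    def m(self) -> float:
        """Total edge weight (edge count when unweighted)."""
        return float(sum(self._weights.values()))

    @property
    def n_edges(self) -> int:
        """Number of distinct (merged) edges."""
        return len(self._weights)

    def weight(self, i: int, j: int) -> float:
        return self._weights.get(_canon(i, j), 0.0)

    def has_edge(self, i: int, j: int) -> bool:
        return _canon(i, j) in self._weights

    def index_of(self, label: str) -> int:
        try:
            return self.node_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown node label {label!r}") from None

    # -- adjacency -------------------------------------------------------

    def adjacency(self) -> sp.csr_array:
        """Symmetric sparse adjacency; ``A.sum() == 2 * m``.

        Self-loops appear on the diagonal with twice their weight.
        """
        rows, cols, vals = [], [], []
        for (i, j), w in self._weights.items():
            if i == j:
                rows.append(i)
                cols.append(i)
                vals.append(2.0 * w)
            else:
                rows.extend((i, j))
                cols.extend((j, i))
                vals.extend((w, w))
        return sp.csr_array(
            (np.asarray(vals, dtype=float), (rows, cols)), shape=(self.n, self.n)
        )

    def degrees(self) -> np.ndarray:
        """Weighted degree of every node (self-loops count twice)."""
        return np.asarray(self.adjacency().sum(axis=1)).ravel()

    # -- subnetworks (used by the recursive bipartitioner) ---------------

    def subnetwork(self, edge_keys: Iterable[Edge]) -> tuple["Network", dict[int, int]]:
        """Isolate the subgraph induced by a set of edges.

        Returns the compacted subnetwork together with a map from local
        node indices back to indices in ``self``.
        """
        keys = [_canon(*e) for e in edge_keys]
        local: dict[int, int] = {}
        for i, j in keys:
            if (i, j) not in self._weights:
                raise KeyError(f"edge ({i}, {j}) is not in the network")
            for v in (i, j):
                if v not in local:
                    local[v] = len(local)
        labels = [self.node_labels[v] for v in local]
        edges = [(local[i], local[j], self._weights[(i, j)]) for i, j in keys]
        back = {loc: glob for glob, loc in local.items()}
        return Network(labels, edges), back

    def __repr__(self) -> str:  # pragma: no cover
        return f"Network(n={self.n}, edges={self.n_edges}, m={self.m:g})"


@dataclass
class LinkPartition:
    """Assignment of every edge to exactly one community (ids ``1..c``)."""

    assignment: dict[Edge, int]
    c: int = field(default=0)

    def __post_init__(self) -> None:
        self.assignment = {_canon(*e): int(z) for e, z in self.assignment.items()}
        ids = sorted(set(self.assignment.values()))
        if self.assignment:
            if ids[0] != 1 or ids != list(range(1, len(ids) + 1)):
                raise ValueError("community ids must form the contiguous range 1..c")
        self.c = len(ids)

    def community_of(self, i: int, j: int) -> int:
        return self.assignment[_canon(i, j)]

    def communities(self) -> dict[int, list[Edge]]:
        """Edges grouped by community id."""
        out: dict[int, list[Edge]] = {z: [] for z in range(1, self.c + 1)}
        for e, z in self.assignment.items():
            out[z].append(e)
        return out

    def validate_against(self, network: Network) -> None:
        keys = set(network.edge_keys)
        got = set(self.assignment)
        if got != keys:
            missing = keys - got
            extra = got - keys
            raise ValueError(
                f"partition does not cover the network: "
                f"{len(missing)} edges missing, {len(extra)} unknown"
            )

    @classmethod
    def from_labels(cls, edge_keys: Sequence[Edge], labels: Iterable[int]) -> "LinkPartition":
        """Build from per-edge raw labels, relabelled contiguously from 1.

        Relabelling preserves the numeric order of the distinct raw labels.
        """
        labels = list(labels)
        if len(labels) != len(edge_keys):
            raise ValueError("one label per edge required")
        remap = {z: k + 1 for k, z in enumerate(sorted(set(labels)))}
        return cls({e: remap[z] for e, z in zip(edge_keys, labels)})


# ---------------------------------------------------------------------------
# edge-list and partition I/O
# ---------------------------------------------------------------------------


def read_edge_list(path, weighted: bool = False) -> Network:
    """Read a whitespace-separated edge list into a :class:`Network`.

    Lines hold ``node_a node_b`` (or ``node_a node_b weight`` when
    *weighted*); ``#`` starts a comment line and blank lines are skipped.
    Duplicate undirected edges are merged by summing weights, and node
    order is first appearance.
    """
    labels: dict[str, int] = {}
    edges: list[tuple[int, int, float]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            want = 3 if weighted else 2
            if len(parts) != want:
                raise EdgeListError(
                    f"{path}:{ln}: expected {want} fields, got {len(parts)}: {line!r}"
                )
            a, b = parts[0], parts[1]
            if weighted:
                try:
                    w = float(parts[2])
                except ValueError:
                    raise EdgeListError(f"{path}:{ln}: bad weight {parts[2]!r}") from None
            else:
                w = 1.0
            if not w > 0:
                raise EdgeListError(f"{path}:{ln}: weight must be positive, got {w}")
            for lab in (a, b):
                if lab not in labels:
                    labels[lab] = len(labels)
            edges.append((labels[a], labels[b], w))
    if not labels:
        raise EdgeListError(f"{path}: no edges found")
    return Network(list(labels), edges)


def write_edge_list(network: Network, path, weighted: bool = False) -> None:
    """Write the merged edge list back out (inverse of :func:`read_edge_list`)."""
    with open(path, "wt", encoding="utf-8") as fh:
        for i, j, w in network.edges:
            a, b = network.node_labels[i], network.node_labels[j]
            if weighted:
                fh.write(f"{a}\t{b}\t{w:g}\n")
            else:
                # an unweighted merged edge of weight k is k parallel lines
                reps = int(round(w))
                for _ in range(max(reps, 1)):
                    fh.write(f"{a}\t{b}\n")


def write_link_partition(partition: LinkPartition, network: Network, path) -> None:
    """Write ``label_i<TAB>label_j<TAB>community`` lines; round-trips."""
    partition.validate_against(network)
    with open(path, "wt", encoding="utf-8") as fh:
        for (i, j), z in partition.assignment.items():
            fh.write(f"{network.node_labels[i]}\t{network.node_labels[j]}\t{z}\n")


def read_link_partition(path, network: Network) -> LinkPartition:
    assignment: dict[Edge, int] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 3:
                raise EdgeListError(f"{path}:{ln}: expected 3 fields, got {len(parts)}")
            i = network.index_of(parts[0])
            j = network.index_of(parts[1])
            assignment[_canon(i, j)] = int(parts[2])
    part = LinkPartition(assignment)
    part.validate_against(network)
    return part


def write_node_memberships(
    memberships: Mapping[int, Mapping[int, float] | Iterable[int]],
    network: Network,
    path,
) -> None:
    """Write ``label<TAB>community<TAB>score`` lines.

    *memberships* maps node index to either a set of community ids
    (score written as 1) or a ``{community: score}`` mapping.
    """
    with open(path, "wt", encoding="utf-8") as fh:
        for i in range(network.n):
            entry = memberships.get(i, ())
            if isinstance(entry, Mapping):
                items = sorted(entry.items())
            else:
                items = [(z, 1.0) for z in sorted(entry)]
            for z, score in items:
                fh.write(f"{network.node_labels[i]}\t{z}\t{score:g}\n")
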