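"""The generative model of link communities.

Each of ``c`` link communities ``z`` has a size ``omega_z`` — twice the
expected number (or weight) of links it generates — and a probability
vector ``phi[:, z]`` over nodes (its column sums to 1).  An edge is born
by first choosing a community ``z`` with probability proportional to
``omega_z`` and then drawing both endpoints independently from
``phi[:, z]``.  The expected number of links community ``z`` places
between the ordered pair ``(i, j)`` is therefore

    omega_z * phi[i, z] * phi[j, z]

and the expected adjacency of the whole network is the sum over
communities.  Multi-edges and self-loops are allowed, as usual for this
family of random multigraph models.

Given parameters and an observed edge, Bayes' rule yields the soft
membership vector ``R_ij`` (the fraction by which the edge belongs to
each community); the hard link partition takes the argmax.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .network import LinkPartition, Network

__all__ = [
    "ModelParams",
    "SoftMembership",
    "expected_adjacency",
    "soft_membership",
    "hard_partition",
    "node_memberships",
    "sample_network",
]


@dataclass
class ModelParams:
    """Community sizes ``omega`` (length c) and node probabilities ``phi`` (n x c)."""

    omega: np.ndarray
    phi: np.ndarray

    def __post_init__(self) -> None:
        self.omega = np.atleast_1d(np.asarray(self.omega, dtype=float))
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.ndim != 2:
            raise ValueError("phi must be a 2-d (n x c) array")
        if self.phi.shape[1] != self.omega.shape[0]:
            raise ValueError("phi must have one column per omega entry")
        if np.any(self.omega < 0) or np.any(self.phi < 0):
            raise ValueError("omega and phi must be nonnegative")

    @property
    def n(self) -> int:
        return self.phi.shape[0]

    @property
    def c(self) -> int:
        return self.omega.shape[0]

    def column_sums(self) -> np.ndarray:
        return self.phi.sum(axis=0)

    def to_factor(self) -> np.ndarray:
        """The auxiliary factor ``X`` with ``X[i, z] = sqrt(omega_z) * phi[i, z]``."""
        return self.phi * np.sqrt(self.omega)


@dataclass
class SoftMembership:
    """Per-edge community probability vectors ``R_ij`` (rows sum to 1)."""

    edge_keys: list[tuple[int, int]]
    R: np.ndarray  # n_edges x c

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        if self.R.shape[0] != len(self.edge_keys):
            raise ValueError("one membership row per edge required")

    @property
    def c(self) -> int:
        return self.R.shape[1]


def expected_adjacency(params: ModelParams) -> np.ndarray:
    """Expected adjacency ``A_hat[i, j] = sum_z omega_z phi[i,z] phi[j,z]``."""
    return (params.phi * params.omega) @ params.phi.T


def soft_membership(params: ModelParams, network: Network) -> SoftMembership:
    """Posterior community fractions for every observed edge.

    An edge the model gives zero probability receives the uniform vector
    ``1/c`` and triggers a warning.
    """
    keys = network.edge_keys
    idx = np.asarray(keys, dtype=int).reshape(-1, 2)
    contrib = params.omega * params.phi[idx[:, 0]] * params.phi[idx[:, 1]]
    totals = contrib.sum(axis=1)
    dead = totals <= 0.0
    if np.any(dead):
        warnings.warn(
            f"{int(dead.sum())} edge(s) have zero probability under the model; "
            "assigning uniform membership",
            RuntimeWarning,
            stacklevel=2,
        )
        contrib[dead] = 1.0 / params.c
        totals[dead] = 1.0
    return SoftMembership(keys, contrib / totals[:, None])


def hard_partition(soft: SoftMembership) -> LinkPartition:
    """Argmax assignment of each edge; ties go to the lowest community index.

    Communities that receive no edge are relabelled away so that ids are
    contiguous from 1.
    """
    winners = np.argmax(soft.R, axis=1) + 1  # argmax takes the first maximum
    return LinkPartition.from_labels(soft.edge_keys, winners.tolist())


def node_memberships(
    partition: LinkPartition,
    network: Network,
    threshold: float = 0.0,
) -> dict[int, set[int]]:
    """Derive overlapping node memberships from a link partition.

    Node ``i`` belongs to community ``z`` iff the weight of its incident
    links assigned to ``z`` exceeds ``threshold`` times its weighted
    degree (strictly).  The default ``threshold=0`` grants membership for
    any incident link.  Isolated nodes get the empty set.  Self-loops
    count twice, matching the adjacency diagonal convention.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must lie in [0, 1)")
    partition.validate_against(network)
    strength = np.zeros((network.n, partition.c + 1))
    for i, j, w in network.edges:
        z = partition.assignment[(i, j)]
        if i == j:
            strength[i, z] += 2.0 * w
        else:
            strength[i, z] += w
            strength[j, z] += w
    degrees = strength.sum(axis=1)
    out: dict[int, set[int]] = {}
    for i in range(network.n):
        if degrees[i] <= 0:
            out[i] = set()
            continue
        frac = strength[i] / degrees[i]
        out[i] = {z for z in range(1, partition.c + 1) if frac[z] > threshold}
    return out


def sample_network(
    params: ModelParams,
    rng_seed: int,
    node_labels: list[str] | None = None,
    fixed_m: bool = False,
) -> tuple[Network, LinkPartition]:
    """Draw a network from the model, with its planted link partition.

    The total number of generated links is Poisson with mean
    ``sum(omega) / 2`` (or exactly ``round(sum(omega) / 2)`` when
    ``fixed_m``); each link picks its community with probability
    ``omega_z / sum(omega)`` and then its two endpoints independently
    from ``phi[:, z]``.  Parallel draws of the same node pair are merged
    into one weighted edge whose planted community is the pair's modal
    generating community (ties to the lowest id).
    """
    rng = np.random.default_rng(rng_seed)
    total = float(params.omega.sum())
    if node_labels is None:
        node_labels = [str(i) for i in range(params.n)]
    if total <= 0:
        return Network(node_labels, []), LinkPartition({})
    mean_links = total / 2.0
    n_links = int(round(mean_links)) if fixed_m else int(rng.poisson(mean_links))
    if n_links == 0:
        return Network(node_labels, []), LinkPartition({})

    comm = rng.choice(params.c, size=n_links, p=params.omega / total)
    # per-pair counts keyed by (canonical pair, community)
    counts: dict[tuple[int, int, int], int] = {}
    for z in range(params.c):
        k = int(np.sum(comm == z))
        if k == 0:
            continue
        col = params.phi[:, z]
        s = col.sum()
        if s <= 0:
            raise ValueError(f"community {z + 1} has zero total selection probability")
        p = col / s
        ends = rng.choice(params.n, size=(k, 2), p=p)
        for i, j in ends:
            a, b = (int(i), int(j)) if i <= j else (int(j), int(i))
            key = (a, b, z)
            counts[key] = counts.get(key, 0) + 1

    per_pair: dict[tuple[int, int], dict[int, int]] = {}
    for (a, b, z), k in counts.items():
        per_pair.setdefault((a, b), {})[z] = k
    edges = []
    assignment = {}
    for (a, b), by_comm in per_pair.items():
        w = float(sum(by_comm.values()))
        edges.append((a, b, w))
        best = min(by_comm, key=lambda z: (-by_comm[z], z))
        assignment[(a, b)] = best + 1
    network = Network(node_labels, edges)
    truth = LinkPartition.from_labels(
        list(assignment), [assignment[e] for e in assignment]
    )
    return network, truth
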