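"""High-level modelling interface.

:class:`LinkCommunityModel` wraps a network and fits the link-community
generative model to it, either with a fixed community count ``c``
(penalized symmetric NMF) or, when ``n_communities`` is left ``None``,
with the community count selected automatically by recursive bipartition
(NMFIB).  ``fit()`` returns a :class:`LinkCommunityResults` carrying the
estimated parameters, the link partition, diagnostics and a
``summary()`` table.

Example
-------
>>> from linknmf import LinkCommunityModel
>>> model = LinkCommunityModel.from_edgelist("edges.tsv", n_communities=2)
>>> res = model.fit(seed=1)
>>> print(res.summary())                              # doctest: +SKIP
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import density, generative, nmfib, sym_nmf
from .generative import ModelParams
from .network import LinkPartition, Network, read_edge_list

__all__ = ["LinkCommunityModel", "LinkCommunityResults"]


class LinkCommunityModel:
    """Generative link-community model bound to an observed network.

    Parameters
    ----------
    network
        The observed undirected network.
    n_communities
        Number of link communities ``c``; ``None`` selects it
        automatically via recursive bipartition on fitting.
    """

    def __init__(self, network: Network, n_communities: int | None = None):
        if n_communities is not None and n_communities < 1:
            raise ValueError("n_communities must be positive or None")
        self.network = network
        self.n_communities = n_communities

    @classmethod
    def from_edgelist(
        cls, path, weighted: bool = False, n_communities: int | None = None
    ) -> "LinkCommunityModel":
        """Build from a whitespace-separated edge-list file."""
        return cls(read_edge_list(path, weighted=weighted), n_communities)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        source: str = "source",
        target: str = "target",
        weight: str | None = None,
        n_communities: int | None = None,
    ) -> "LinkCommunityModel":
        """Build from a DataFrame of edges (labels taken as strings)."""
        labels: dict[str, int] = {}
        edges = []
        for _, row in df.iterrows():
            a, b = str(row[source]), str(row[target])
            w = float(row[weight]) if weight is not None else 1.0
            for lab in (a, b):
                if lab not in labels:
                    labels[lab] = len(labels)
            edges.append((labels[a], labels[b], w))
        return cls(Network(list(labels), edges), n_communities)

    def fit(
        self,
        seed: int = 0,
        restarts: int = 10,
        lam: float = 1000.0,
        tol: float = 1e-6,
        max_iter: int = 500,
        eta: float = 0.25,
    ) -> "LinkCommunityResults":
        """Fit the model; dispatches to NMFIB when ``n_communities`` is None."""
        opts = dict(restarts=restarts, lam=lam, tol=tol, max_iter=max_iter, eta=eta)
        if self.n_communities is None:
            partition, tree = nmfib.run_nmfib(self.network, seed=seed, **opts)
            return LinkCommunityResults(
                self, partition=partition, tree=tree, seed=seed
            )
        raw = sym_nmf.fit(self.network, c=self.n_communities, seed=seed, **opts)
        soft = generative.soft_membership(raw.params, self.network)
        partition = generative.hard_partition(soft)
        return LinkCommunityResults(
            self, partition=partition, raw=raw, soft=soft, seed=seed
        )


class LinkCommunityResults:
    """Fitted link-community structure with diagnostics.

    Attributes
    ----------
    partition : LinkPartition
        Hard assignment of every link to one community.
    params : ModelParams or None
        Estimated ``(omega, phi)`` — ``None`` for NMFIB results, whose
        communities come from nested two-community fits.
    tree : BipartitionNode or None
        NMFIB decision tree, when applicable.
    """

    def __init__(
        self,
        model: LinkCommunityModel,
        partition: LinkPartition,
        raw: sym_nmf.FitResult | None = None,
        soft: generative.SoftMembership | None = None,
        tree: nmfib.BipartitionNode | None = None,
        seed: int = 0,
    ):
        self.model = model
        self.network = model.network
        self.partition = partition
        self.raw = raw
        self.soft = soft
        self.tree = tree
        self.seed = seed

    # -- estimates -------------------------------------------------------

    @property
    def method(self) -> str:
        return "NMF (fixed c)" if self.raw is not None else "NMFIB (automatic c)"

    @property
    def n_communities(self) -> int:
        return self.partition.c

    @property
    def params(self) -> ModelParams | None:
        return self.raw.params if self.raw is not None else None

    @property
    def omega(self) -> np.ndarray | None:
        return self.params.omega if self.params is not None else None

    @property
    def phi(self) -> pd.DataFrame | None:
        """Node-selection probabilities as a labelled DataFrame (n x c)."""
        if self.params is None:
            return None
        return pd.DataFrame(
            self.params.phi,
            index=self.network.node_labels,
            columns=[f"community_{z + 1}" for z in range(self.params.c)],
        )

    @property
    def converged(self) -> bool | None:
        return self.raw.converged if self.raw is not None else None

    @property
    def objective_trace(self) -> np.ndarray | None:
        return self.raw.objective_trace if self.raw is not None else None

    # -- derived structure ----------------------------------------------

    def expected_adjacency(self) -> np.ndarray | None:
        if self.params is None:
            return None
        return generative.expected_adjacency(self.params)

    def node_memberships(self, threshold: float = 0.0) -> dict[int, set[int]]:
        """Overlapping node membership sets derived from the link partition."""
        return generative.node_memberships(self.partition, self.network, threshold)

    def node_membership_frame(self, threshold: float = 0.0) -> pd.DataFrame:
        rows = [
            {"node": self.network.node_labels[i], "community": z}
            for i, comms in self.node_memberships(threshold).items()
            for z in sorted(comms)
        ]
        return pd.DataFrame(rows, columns=["node", "community"])

    def partition_density(self) -> float:
        return density.partition_density(self.partition, self.network)

    def community_table(self) -> pd.DataFrame:
        """Per-community link weight, induced node count, density and size."""
        stats = density._per_community_stats(self.partition, self.network)
        rows = []
        for z in range(1, self.partition.c + 1):
            st = stats[z]
            row = {
                "community": z,
                "links_m_z": st.m_z,
                "nodes_n_z": st.n_z,
                "density_D_z": density.link_density(st.m_z, st.n_z),
            }
            if self.omega is not None and z <= len(self.omega):
                row["omega_z"] = float(self.omega[z - 1])
            rows.append(row)
        return pd.DataFrame(rows)

    def sample(self, seed: int) -> tuple[Network, LinkPartition]:
        """Draw a replicate network from the fitted parameters."""
        if self.params is None:
            raise ValueError("sampling needs fitted (omega, phi) parameters")
        return generative.sample_network(
            self.params, rng_seed=seed, node_labels=list(self.network.node_labels)
        )

    # -- reporting -------------------------------------------------------

    def summary(self) -> str:
        net = self.network
        lines = [
            "Link community model results",
            "=" * 46,
            f"method:            {self.method}",
            f"nodes (n):         {net.n}",
            f"total link weight: {net.m:g}  ({net.n_edges} distinct edges)",
            f"communities (c):   {self.n_communities}",
            f"partition density: {self.partition_density():.4f}",
            f"seed:              {self.seed}",
        ]
        if self.raw is not None:
            total = float(np.sum(self.raw.params.omega))
            lines += [
                f"converged:         {self.raw.converged} "
                f"({self.raw.iterations} iterations, lambda={self.raw.lambda_used:g})",
                f"final objective:   {self.raw.final_objective:.6g}",
                f"sum(omega):        {total:.4f}  (target 2m = {2 * net.m:g})",
            ]
        lines.append("-" * 46)
        table = self.community_table()
        lines.append(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<LinkCommunityResults: {self.method}, c={self.n_communities}, "
            f"D={self.partition_density():.4f}>"
        )
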