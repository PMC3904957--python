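"""Planted two-community benchmark with overlapping nodes.

The benchmark plants two link communities on ``n`` nodes: ``x`` nodes
exclusive to community 1, ``y`` exclusive to community 2, and
``z = n - x - y`` shared.  Every node has the same expected degree
``<k>``, with shared nodes splitting theirs equally between the two
communities.  Solving the degree-balance equations under the generative
model gives

    omega_1 = <k> (x + z/2),        omega_2 = <k> (y + z/2),
    phi_i1  = <k> / omega_1          for community-1 exclusive nodes,
    phi_i1  = <k> / (2 omega_1)      for shared nodes,

(and symmetrically for community 2), so the expected edge total is
``n <k> / 2``.  Networks are then sampled from the generative model.

Three experiment designs vary, respectively, the expected degree, the
size ratio between the exclusive sets, and the amount of overlap,
scoring a detector by FVCC and the Jaccard index of the recovered
overlapping-node set over replicate networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence, Set

import numpy as np
import pandas as pd

from . import sym_nmf
from .density import fvcc, jaccard_overlap
from .generative import (
    ModelParams,
    hard_partition,
    node_memberships,
    sample_network,
    soft_membership,
)
from .network import LinkPartition, Network

__all__ = [
    "BenchmarkSpec",
    "make_benchmark",
    "nmf_detector",
    "run_experiment",
    "DESIGNS",
]

DESIGNS = ("vary_k", "vary_ratio", "vary_overlap")

#: node -> set of planted community ids
Memberships = Mapping[int, Set[int]]
Detector = Callable[[Network, int], Memberships]


@dataclass(frozen=True)
class BenchmarkSpec:
    """Parameters of one planted-overlap benchmark network."""

    n: int
    x: int
    y: int
    z_overlap: int
    k_expected: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0 or self.z_overlap < 0:
            raise ValueError("x, y and z_overlap must be nonnegative")
        if self.x + self.y + self.z_overlap != self.n:
            raise ValueError("x + y + z_overlap must equal n")
        if not self.k_expected > 0:
            raise ValueError("k_expected must be positive")
        if self.x + self.z_overlap == 0 or self.y + self.z_overlap == 0:
            raise ValueError("each community needs at least one member node")

    def params(self) -> ModelParams:
        """Model parameters realizing the planted design exactly."""
        k = self.k_expected
        omega1 = k * (self.x + self.z_overlap / 2.0)
        omega2 = k * (self.y + self.z_overlap / 2.0)
        phi = np.zeros((self.n, 2))
        # node order: community-1 exclusives, shared, community-2 exclusives
        sl = slice(self.x, self.x + self.z_overlap)
        phi[: self.x, 0] = k / omega1
        phi[sl, 0] = k / (2.0 * omega1)
        phi[sl, 1] = k / (2.0 * omega2)
        phi[self.x + self.z_overlap :, 1] = k / omega2
        return ModelParams(omega=np.array([omega1, omega2]), phi=phi)

    def truth(self) -> dict[int, set[int]]:
        """Planted per-node membership sets."""
        out: dict[int, set[int]] = {}
        for i in range(self.n):
            if i < self.x:
                out[i] = {1}
            elif i < self.x + self.z_overlap:
                out[i] = {1, 2}
            else:
                out[i] = {2}
        return out


def make_benchmark(
    spec: BenchmarkSpec,
) -> tuple[Network, dict[int, set[int]], LinkPartition]:
    """Sample one benchmark network with its planted truth.

    Returns the network, the per-node planted membership sets, and the
    planted link partition (the community that generated each link).
    """
    network, planted = sample_network(spec.params(), rng_seed=spec.seed)
    return network, spec.truth(), planted


def nmf_detector(restarts: int = 10, threshold: float = 0.0, **fit_options) -> Detector:
    """The default detector: a ``c = 2`` model fit, as in the benchmark design
    where the true community count is given a priori.

    Returns node membership sets derived from the hard link partition.
    """

    def detect(network: Network, seed: int) -> dict[int, set[int]]:
        result = sym_nmf.fit(network, c=2, seed=seed, restarts=restarts, **fit_options)
        part = hard_partition(soft_membership(result.params, network))
        return node_memberships(part, network, threshold=threshold)

    return detect


def _overlap_set(memberships: Memberships) -> set[int]:
    return {node for node, comms in memberships.items() if len(comms) >= 2}


def _chance_fvcc(truth: Memberships) -> float:
    """Fraction of nodes whose planted set is the modal set (guess-the-mode baseline)."""
    counts: dict[frozenset, int] = {}
    for s in truth.values():
        counts[frozenset(s)] = counts.get(frozenset(s), 0) + 1
    return max(counts.values()) / len(truth) if truth else 1.0


def _spec_for(design: str, value: float, n: int, z_overlap: int, k: float, seed: int) -> BenchmarkSpec:
    if design == "vary_k":
        rest = n - z_overlap
        x = rest // 2 + rest % 2
        return BenchmarkSpec(n=n, x=x, y=rest - x, z_overlap=z_overlap,
                             k_expected=float(value), seed=seed)
    if design == "vary_ratio":
        # value = x / (x + y), the share of the larger exclusive set
        rest = n - z_overlap
        x = int(round(value * rest))
        return BenchmarkSpec(n=n, x=x, y=rest - x, z_overlap=z_overlap,
                             k_expected=k, seed=seed)
    if design == "vary_overlap":
        z = int(value)
        rest = n - z
        x = rest // 2 + rest % 2
        return BenchmarkSpec(n=n, x=x, y=rest - x, z_overlap=z,
                             k_expected=k, seed=seed)
    raise ValueError(f"unknown design {design!r}; choose one of {DESIGNS}")


def run_experiment(
    design: str,
    grid: Sequence[float],
    replicates: int = 50,
    detector: Detector | None = None,
    base_seed: int = 0,
    n: int = 10000,
    z_overlap: int = 500,
    k_expected: float = 10.0,
) -> pd.DataFrame:
    """Run one benchmark design over a parameter grid.

    For every grid point and replicate a network is sampled, the detector
    run (default: the ``c = 2`` model fit) and FVCC / Jaccard recorded.
    Returns one row per grid point with means, standard errors, the
    chance-level FVCC baseline, and the replicate count.  A detector
    failure on an instance is recorded as missing rather than fatal.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; choose one of {DESIGNS}")
    if detector is None:
        detector = nmf_detector()
    rows = []
    for gi, value in enumerate(grid):
        fv, jc, chance = [], [], []
        for r in range(int(replicates)):
            seed = int(base_seed) + 100_000 * gi + r
            spec = _spec_for(design, value, n=n, z_overlap=z_overlap,
                             k=k_expected, seed=seed)
            try:
                network, truth, _ = make_benchmark(spec)
                predicted = detector(network, seed)
                fv.append(fvcc(predicted, truth))
                jc.append(jaccard_overlap(_overlap_set(predicted), _overlap_set(truth)))
                chance.append(_chance_fvcc(truth))
            except Exception as exc:
                warnings.warn(
                    f"detector failed at {design}={value} replicate {r}: {exc}",
                    RuntimeWarning,
                    stacklevel=2,
                )
        def _mean(v):
            return float(np.mean(v)) if v else float("nan")
        def _se(v):
            return float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
        rows.append(
            {
                "design": design,
                "value": value,
                "fvcc_mean": _mean(fv),
                "fvcc_se": _se(fv),
                "jaccard_mean": _mean(jc),
                "jaccard_se": _se(jc),
                "fvcc_chance": _mean(chance),
                "replicates": len(fv),
            }
        )
    return pd.DataFrame(rows)
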