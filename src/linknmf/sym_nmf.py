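"""Penalized symmetric NMF fitting of the link-community model.

Fitting minimizes, over nonnegative n x c factors ``X``,

    O(X) = || A - X X^T ||_F^2  +  lam * (1^T X X^T 1 - 2m)^2

where ``A`` is the observed adjacency and ``m`` the total edge weight.
The penalty encodes the size constraint ``sum_z omega_z = 2m`` through
``1^T X X^T 1 = sum_z (column-sum_z)^2``.  The optimum maps back to model
parameters via ``omega_z = (column-sum_z)^2`` and
``phi[:, z] = X[:, z] / column-sum_z``.

The optimizer is a multiplicative update.  Writing ``s = X^T 1`` (the
vector of column sums), the gradient splits into a nonnegative
"attraction" part ``A X + 2 m lam 1 s^T`` and a nonnegative "repulsion"
part ``X (X^T X) + lam (s^T s) 1 s^T``, and each entry of ``X`` is
multiplied by the ratio of the two raised to a power ``eta``:

    X <- X * ( (A X + 2 m lam 1 s^T) / (X X^T X + lam (s^T s) 1 s^T) )^eta

``eta = 1/4`` is the exact minimizer of the standard majorizing auxiliary
function for this quartic objective (Jensen bound on the fourth-order
terms, log bound on the second-order terms), which makes the objective
provably non-increasing at every step; it is the default.  ``eta = 1``
gives the bare fixed-point form of the KKT conditions.  Both share the
same fixed points: stationary points of ``O`` on the nonnegative orthant.

Optimization runs in two phases: an unpenalized phase (``lam = 0``) from
a random start finds a good factorization shape, then the penalized phase
(``lam = 1000`` by default) tightens the size constraint starting from
the phase-1 solution.  Several random restarts are made and the lowest
final objective wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .generative import ModelParams
from .network import Network

__all__ = ["FitResult", "objective", "update_step", "extract_params", "fit"]

_EPS = 1e-12
_PRUNE = 1e-8


@dataclass
class FitResult:
    """Outcome of a penalized symmetric-NMF fit."""

    X: np.ndarray
    params: ModelParams
    objective_trace: np.ndarray
    phase_boundary: int  # index of the first phase-2 entry in the trace
    iterations: int
    converged: bool
    lambda_used: float
    seed: int
    restart_objectives: list[float] = field(default_factory=list)

    @property
    def final_objective(self) -> float:
        return float(self.objective_trace[-1])


def _as_sparse(A) -> sp.csr_array:
    if sp.issparse(A):
        return sp.csr_array(A)
    return sp.csr_array(np.asarray(A, dtype=float))


def objective(X: np.ndarray, A, lam: float, m: float) -> float:
    """Evaluate ``O(X)`` in O(mc + nc^2) time.

    Uses ``||A - XX^T||_F^2 = ||A||_F^2 - 2 tr(X^T A X) + ||X^T X||_F^2``
    so the n x n product is never formed.
    """
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    A = _as_sparse(A)
    X = np.asarray(X, dtype=float)
    AX = A @ X
    gram = X.T @ X
    loss = float((A.data**2).sum() - 2.0 * np.sum(AX * X) + np.sum(gram**2))
    s = X.sum(axis=0)
    penalty = lam * (float(s @ s) - 2.0 * m) ** 2
    return loss + penalty


def update_step(
    X: np.ndarray,
    A,
    lam: float,
    m: float,
    eta: float = 0.25,
    eps: float = _EPS,
) -> np.ndarray:
    """One multiplicative update; preserves nonnegativity.

    Denominator entries are floored at ``eps`` and the updated factor is
    floored at ``eps`` so zeros never become absorbing during the search.
    """
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    A = _as_sparse(A)
    X = np.asarray(X, dtype=float)
    s = X.sum(axis=0)  # length-c column sums, s = X^T 1
    num = A @ X
    den = X @ (X.T @ X)
    if lam > 0:
        num = num + (2.0 * m * lam) * s
        den = den + (lam * float(s @ s)) * s
    ratio = num / np.maximum(den, eps)
    Xn = X * np.power(ratio, eta)
    return np.maximum(Xn, eps)


def extract_params(X: np.ndarray, prune: float = _PRUNE) -> ModelParams:
    """Map a factor to model parameters: ``omega = colsum^2``, ``phi = col/colsum``.

    Columns whose sum does not exceed ``prune`` are dropped (empty
    communities); remaining communities keep their relative order.
    """
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("X must be nonnegative")
    sums = X.sum(axis=0)
    keep = sums > prune
    if not np.any(keep):
        raise ValueError("all factor columns are (numerically) zero")
    Xk = X[:, keep]
    sums = sums[keep]
    return ModelParams(omega=sums**2, phi=Xk / sums)


def _init_factor(n: int, c: int, m: float, rng: np.random.Generator) -> np.ndarray:
    """Uniform (0, 1] entries rescaled so the size constraint starts satisfied."""
    X = 1.0 - rng.random((n, c))
    s = X.sum(axis=0)
    total = float(s @ s)
    if total > 0 and m > 0:
        X *= np.sqrt(2.0 * m / total)
    return X


def _run_phase(
    X: np.ndarray,
    A,
    lam: float,
    m: float,
    tol: float,
    max_iter: int,
    eta: float,
) -> tuple[np.ndarray, list[float], bool]:
    trace = [objective(X, A, lam, m)]
    converged = False
    for _ in range(max_iter):
        X = update_step(X, A, lam, m, eta=eta)
        obj = objective(X, A, lam, m)
        prev = trace[-1]
        trace.append(obj)
        denom = max(abs(prev), _EPS)
        if abs(prev - obj) / denom < tol:
            converged = True
            break
    return X, trace, converged


def fit(
    network: Network,
    c: int,
    seed: int = 0,
    restarts: int = 10,
    lam: float = 1000.0,
    tol: float = 1e-6,
    max_iter: int = 500,
    eta: float = 0.25,
) -> FitResult:
    """Two-phase penalized symmetric-NMF fit with random restarts.

    Phase 1 optimizes with ``lam = 0`` to convergence; phase 2 restarts
    from that factor with the full penalty weight.  Among ``restarts``
    seeded initializations the result with the strictly lowest final
    objective is kept (earlier restarts win ties).
    """
    if c < 1:
        raise ValueError("c must be a positive integer")
    if network.n_edges == 0:
        raise ValueError("cannot fit an empty network")
    if c > network.m:
        warnings.warn(
            f"requested {c} communities for total edge weight {network.m:g}",
            RuntimeWarning,
            stacklevel=2,
        )
    A = network.adjacency()
    m = network.m
    best: FitResult | None = None
    finals: list[float] = []
    for r in range(max(int(restarts), 1)):
        rng = np.random.default_rng([seed, r])
        X = _init_factor(network.n, c, m, rng)
        X, trace1, conv1 = _run_phase(X, A, 0.0, m, tol, max_iter, eta)
        if lam > 0:
            X, trace2, conv2 = _run_phase(X, A, lam, m, tol, max_iter, eta)
        else:
            trace2, conv2 = [], True
        trace = np.asarray(trace1 + trace2)
        Xr = np.where(X > _PRUNE, X, 0.0)
        result = FitResult(
            X=Xr,
            params=extract_params(X),
            objective_trace=trace,
            phase_boundary=len(trace1),
            iterations=len(trace) - 1,
            converged=conv1 and conv2,
            lambda_used=lam,
            seed=seed,
        )
        finals.append(result.final_objective)
        if best is None or result.final_objective < best.final_objective:
            best = result
    assert best is not None
    best.restart_objectives = finals
    return best
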