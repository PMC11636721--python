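"""Objective evaluation, deterministic references, and theory-check utilities.

The deterministic PDHG reference implemented here uses dual extrapolation
(primal step against ``A*(2 y^k - y^{k-1})``, then a plain dual prox step),
i.e. exactly the ``n = 1`` specialization of the stochastic loop, so the two
can be compared trajectory-by-trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .operators import LinearMap, MatrixMap
from .proximal import L1Norm, L21Norm, Proximable
from .solver import SaddleProblem

__all__ = [
    "primal_objective",
    "fullbatch_residuals",
    "pdhg",
    "reference_solution",
    "normal_equations_solution",
    "quasi_increasing_check",
    "metric_dominance_check",
    "audit_runlog_condition",
    "audit_runlog_quasi_increasing",
]


def primal_objective(
    x: np.ndarray,
    A: LinearMap,
    b: np.ndarray,
    D: LinearMap | None = None,
    lam: float = 0.0,
    tv_flavor: str = "aniso",
) -> float:
    """TV-regularized least-squares value ``0.5||Ax - b||^2 + lam TV(x)``."""
    r = A.apply(x).ravel() - np.asarray(b).ravel()
    val = 0.5 * float(np.sum(r**2))
    if D is not None and lam > 0:
        tv = L1Norm(lam) if tv_flavor == "aniso" else L21Norm(lam)
        val += tv(D.apply(x))
    return val


def fullbatch_residuals(
    x_prev: np.ndarray,
    x_curr: np.ndarray,
    y_prev: np.ndarray,
    y_curr: np.ndarray,
    tau: float,
    sigma: float,
    A: LinearMap,
) -> tuple[float, float]:
    """Deterministic primal/dual optimality residuals of one PDHG step.

    ``v* = ||(x_prev - x_curr)/tau - A*(y_prev - y_curr)||_1`` and
    ``d* = ||(y_prev - y_curr)/sigma - A(x_prev - x_curr)||_1``.  For a
    PDHG step with ``g = 0`` the primal residual collapses exactly to
    ``||A* y_curr||_1`` (the prox optimality condition cancels the rest).
    """
    dx = x_prev - x_curr
    dy = y_prev - y_curr
    v = float(np.sum(np.abs(dx / tau - A.adjoint(dy))))
    d = float(np.sum(np.abs(dy.ravel() / sigma - A.apply(dx).ravel())))
    return v, d


def pdhg(
    A: LinearMap,
    prox_g: Callable[[np.ndarray, float], np.ndarray],
    conj_prox_f: Callable[[np.ndarray, float], np.ndarray],
    x0: np.ndarray,
    tau: float,
    sigma: float,
    n_iterations: int,
    record: Callable[[int, np.ndarray, np.ndarray], None] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic PDHG with dual extrapolation; returns final ``(x, y)``.

    Iterates ``x <- prox_g(x - tau A*(2y - y_prev), tau)`` then
    ``y <- conj_prox_f(y + sigma A x, sigma)``, starting from ``y = y_prev = 0``.
    """
    x = np.asarray(x0, dtype=float).copy()
    y = np.zeros(A.range_shape)
    y_prev = y.copy()
    for k in range(n_iterations):
        ybar = 2.0 * y - y_prev
        x = prox_g(x - tau * A.adjoint(ybar), tau)
        y_prev = y
        y = conj_prox_f(y + sigma * A.apply(x), sigma)
        if not np.all(np.isfinite(x)):
            raise RuntimeError(f"PDHG diverged at iteration {k}")
        if record is not None:
            record(k, x, y)
    return x, y


def reference_solution(
    problem: SaddleProblem,
    n_iterations: int = 50000,
    objective_fn: Callable[[np.ndarray], float] | None = None,
    beta: float = 0.99,
    ratio: float = 1.0,
) -> tuple[np.ndarray, float]:
    """High-accuracy deterministic PDHG solve of the full problem.

    Runs the full-batch iteration on the stacked operator with blockwise
    conjugate prox steps and constant steps ``tau sigma ||A||^2 = beta``.
    Deterministic and repeatable; serves as the ground-truth for convergence
    tests (for ``lam = 0`` it matches the normal-equations solution).
    """
    from .operators import BlockRowMap, estimate_norm

    stacked = BlockRowMap([blk.op for blk in problem.blocks])
    L = float(estimate_norm(stacked, seed=0))
    sigma = float(np.sqrt(beta / ratio) / L)
    tau = ratio * sigma
    slices = stacked.block_slices

    def conj_prox_full(y: np.ndarray, s: float) -> np.ndarray:
        out = np.empty_like(y)
        for blk, sl in zip(problem.blocks, slices):
            out[sl] = blk.conj_prox(y[sl].reshape(blk.op.range_shape), s).ravel()
        return out

    x0 = np.zeros(problem.domain_shape)
    x, _ = pdhg(stacked, problem.g.prox, conj_prox_full, x0, tau, sigma, n_iterations)
    obj = float(objective_fn(x)) if objective_fn is not None else np.nan
    return x, obj


def normal_equations_solution(A: LinearMap, b: np.ndarray) -> np.ndarray:
    """Dense least-squares oracle ``argmin 0.5||Ax - b||^2`` via lstsq."""
    mat = getattr(A, "matrix", None)
    if mat is None:
        raise ValueError("normal-equations oracle needs a matrix-backed operator")
    dense = mat.toarray() if sp.issparse(mat) else np.asarray(mat)
    sol, *_ = np.linalg.lstsq(dense, np.asarray(b).ravel(), rcond=None)
    return sol.reshape(A.domain_shape)


def quasi_increasing_check(
    sequence: Sequence[float],
    eps_schedule: Sequence[float] | Callable[[int], float],
    rtol: float = 1e-12,
) -> tuple[bool, int | None]:
    """Check ``u^{k+1} >= (1 - eps^k) u^k`` index by index.

    Returns ``(passed, first_violation_index)``; the index is that of the
    first failing transition, or None when the whole sequence passes.
    """
    u = np.asarray(sequence, dtype=float)
    if np.any(u <= 0):
        raise ValueError("sequence must be positive")
    eps = eps_schedule if callable(eps_schedule) else lambda k: eps_schedule[k]
    for k in range(u.size - 1):
        if u[k + 1] < (1.0 - eps(k)) * u[k] * (1.0 - rtol):
            return False, k
    return True, None


@dataclass
class DominanceResult:
    """Both sides of the metric-dominance equivalence, plus the eigen margin."""

    norm_condition: bool  # (ab)^{-1/2} ||P|| <= beta
    dominance: bool  # [[aI, P*], [P, bI]] >= (1-beta) diag(aI, bI)
    min_eig: float

    @property
    def equivalent(self) -> bool:
        return self.norm_condition == self.dominance


def metric_dominance_check(
    a: float, b: float, P: np.ndarray, beta: float, tol: float = 1e-10
) -> DominanceResult:
    """Verify the saddle-metric dominance equivalence by eigenvalues.

    For positive scalars ``a, b`` and an operator ``P``:
    ``(ab)^{-1/2} ||P|| <= beta`` iff the block matrix
    ``[[a I, P^T], [P, b I]]`` dominates ``(1 - beta) diag(a I, b I)``.
    This is the algebraic fact behind the step-size condition
    ``tau sigma ||A||^2 / p <= beta`` guaranteeing positive definiteness of
    the step-size-induced primal-dual metric.
    """
    if a <= 0 or b <= 0:
        raise ValueError("a and b must be positive")
    P = np.atleast_2d(np.asarray(P, dtype=float))
    m, d = P.shape
    norm_P = np.linalg.norm(P, 2)
    lhs = norm_P / np.sqrt(a * b) <= beta + tol
    M = np.block([[a * np.eye(d), P.T], [P, b * np.eye(m)]])
    N = np.diag(np.concatenate([np.full(d, a), np.full(m, b)]))
    min_eig = float(np.linalg.eigvalsh(M - (1.0 - beta) * N).min())
    return DominanceResult(norm_condition=bool(lhs), dominance=min_eig >= -tol, min_eig=min_eig)


def audit_runlog_condition(
    log: pd.DataFrame, norms: np.ndarray, probs: np.ndarray, beta: float
) -> bool:
    """Check ``tau sigma L_i^2 / p_i <= beta`` on every logged iteration.

    Uses the shared dual step-size column, hence applies to shared-mode runs.
    """
    worst = float(np.max(norms**2 / probs))
    cond = log["tau"].to_numpy() * log["sigma_shared"].to_numpy() * worst
    return bool(np.all(cond <= beta * (1 + 1e-9)))


def audit_runlog_quasi_increasing(
    log: pd.DataFrame, eps_schedule: Callable[[int], float]
) -> tuple[bool, bool]:
    """Quasi-increasing audit of both step-size columns of a run log."""
    tau_ok, _ = quasi_increasing_check(log["tau"].to_numpy(), eps_schedule)
    sig_ok, _ = quasi_increasing_check(log["sigma_shared"].to_numpy(), eps_schedule)
    return tau_ok, sig_ok
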