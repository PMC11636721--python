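"""Online step-size controllers for A-SPDHG.

Two concrete adaptation rules are provided, both of the ratio-only form
``tau <- tau / gamma``, ``sigma_i <- gamma sigma_i`` (so the products
``tau sigma_i`` — and with them the convergence condition
``tau sigma_i ||A_i||^2 / p_i <= beta`` — are preserved exactly):

* **Residual balancing** (rule "a"): per-pass primal and dual optimality
  residuals ``v`` and ``d`` are measured in the l1 norm; when one
  persistently dominates the other (beyond a gap ``delta`` after scaling the
  dual residual by ``s``), the step-size ratio is nudged to rebalance them.
  The dual residual may be estimated on a uniform row subsample, reweighted
  to be unbiased, which reduces the per-pass overhead from one extra block
  application to a fraction ``q`` of it.
* **Angle alignment** (rule "b"): the cosine between the primal update
  direction and the estimated primal subgradient triggers a primal boost
  when the two are nearly parallel (cosine above ``c``, with ``c`` very
  close to 1) and a primal shrink when badly aligned.

Each change of the step sizes shrinks the adaptation amplitude ``alpha`` by
``eta`` in (0,1), so the total adaptation is finite.  In ``certified`` mode
the proposed factor is additionally clipped into
``[1 - eps_k, 1/(1 - eps_k)]`` with the deterministic summable schedule
``eps_k = eps0 * zeta^k``, which makes the step-size sequences
quasi-increasing with a deterministic control and hence certifies almost-sure
convergence of the run.  ``paper`` mode (used for experiment replication)
applies the raw rule; its control is random but still summable since
``alpha`` shrinks geometrically per change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .operators import BlockRowMap, LinearMap, estimate_norm, row_subset
from .solver import SaddleProblem, SolverState, StepController

__all__ = [
    "BalancingConfig",
    "AngleConfig",
    "EnvelopeSchedule",
    "ResidualBalancingController",
    "AngleAlignmentController",
    "residuals_rule_a",
    "residuals_rule_a_subsampled",
    "decide_gamma_rule_a",
    "cosine_rule_b",
    "decide_gamma_rule_b",
    "clip_gamma_envelope",
    "apply_gamma",
]


@dataclass
class BalancingConfig:
    """Hyperparameters of the residual-balancing rule.

    alpha0 : initial adaptation amplitude in (0, 1).
    eta : amplitude shrink factor in (0, 1) applied on every change.
    delta : trigger gap >= 1; residuals within a factor delta are "balanced".
    s : scale applied to the dual residual before comparison; defaults to
        the full operator norm ``||A||`` of the problem when left None.
    subsample_fraction : fraction q in (0, 1] of dual-block rows used for
        the dual-residual estimate (1 = exact).
    mode : "certified" (deterministic envelope clip; the library default) or
        "paper" (raw rule, used for experiment replication).
    """

    alpha0: float = 0.5
    eta: float = 0.995
    delta: float = 1.5
    s: float | None = None
    subsample_fraction: float = 0.1
    mode: str = "certified"

    def __post_init__(self):
        if not (0 < self.alpha0 < 1):
            raise ValueError("alpha0 must be in (0, 1)")
        if not (0 < self.eta < 1):
            raise ValueError("eta must be in (0, 1)")
        if self.delta < 1:
            raise ValueError("delta must be >= 1")
        if self.s is not None and self.s <= 0:
            raise ValueError("s must be positive")
        if not (0 < self.subsample_fraction <= 1):
            raise ValueError("subsample_fraction must be in (0, 1]")
        if self.mode not in ("paper", "certified"):
            raise ValueError("mode must be 'paper' or 'certified'")


@dataclass
class AngleConfig:
    """Hyperparameters of the angle-alignment rule."""

    c: float = 0.999
    c_low: float = 0.9
    alpha0: float = 0.5
    eta: float = 0.995
    mode: str = "certified"

    def __post_init__(self):
        if not (0 <= self.c_low < self.c <= 1):
            raise ValueError("thresholds must satisfy 0 <= c_low < c <= 1")
        if not (0 < self.alpha0 < 1):
            raise ValueError("alpha0 must be in (0, 1)")
        if not (0 < self.eta < 1):
            raise ValueError("eta must be in (0, 1)")
        if self.mode not in ("paper", "certified"):
            raise ValueError("mode must be 'paper' or 'certified'")


@dataclass
class EnvelopeSchedule:
    """Deterministic summable control ``eps_k = eps0 * zeta^k``."""

    eps0: float = 0.5
    zeta: float = 0.995

    def __post_init__(self):
        if not (0 < self.eps0 < 1):
            raise ValueError("eps0 must be in (0, 1)")
        if not (0 < self.zeta < 1):
            raise ValueError("zeta must be in (0, 1)")

    def eps(self, k: int) -> float:
        return self.eps0 * self.zeta**k


def residuals_rule_a(
    x_prev: np.ndarray,
    x_curr: np.ndarray,
    y_prev_i: np.ndarray,
    y_curr_i: np.ndarray,
    tau: float,
    sigma: float,
    p_i: float,
    A_i: LinearMap,
    at_dy: np.ndarray | None = None,
) -> tuple[float, float]:
    """Minibatch primal/dual optimality residuals (l1 lengths).

    ``v = || (x_prev - x_curr)/tau - (1/p_i) A_i*(y_prev_i - y_curr_i) ||_1``
    and ``d = (1/p_i) || (y_prev_i - y_curr_i)/sigma - A_i(x_prev - x_curr) ||_1``.
    ``at_dy`` may pass the solver's cached ``A_i*(y_curr_i - y_prev_i)`` so
    no extra adjoint is computed; the single extra cost is ``A_i`` applied
    to the primal change.
    """
    if tau <= 0 or sigma <= 0 or p_i <= 0:
        raise ValueError("tau, sigma and p_i must be positive")
    dx = x_prev - x_curr
    if at_dy is None:
        at_dy = A_i.adjoint(y_curr_i - y_prev_i)
    v = float(np.sum(np.abs(dx / tau + at_dy / p_i)))
    dy = y_prev_i - y_curr_i
    d = float(np.sum(np.abs(dy / sigma - A_i.apply(dx)))) / p_i
    return v, d


def residuals_rule_a_subsampled(
    x_prev: np.ndarray,
    x_curr: np.ndarray,
    y_prev_i: np.ndarray,
    y_curr_i: np.ndarray,
    tau: float,
    sigma: float,
    p_i: float,
    A_i: LinearMap,
    rows: np.ndarray,
) -> float:
    """Unbiased subsampled estimate of the dual residual ``d``.

    ``rows`` is a sorted uniform subset of the block's rows, drawn without
    replacement; every selected coordinate's absolute residual is reweighted
    by the inverse inclusion fraction ``1/q_eff`` with ``q_eff = |rows|/m_i``,
    so the expectation over the subset equals the full-row residual.
    """
    rows = np.asarray(rows, dtype=int)
    if rows.size == 0:
        raise ValueError("row subset must be non-empty")
    m = A_i.range_size
    q_eff = rows.size / m
    dx = x_prev - x_curr
    dy = (y_prev_i - y_curr_i).ravel()[rows]
    sub = row_subset(A_i, rows)
    resid = dy / sigma - sub.apply(dx)
    return float(np.sum(np.abs(resid))) / (q_eff * p_i)


def decide_gamma_rule_a(
    v: float, d: float, cfg: BalancingConfig, alpha_k: float
) -> tuple[float, float]:
    """Residual-balancing decision: returns ``(gamma, alpha_next)``.

    With the scaled dual residual ``d' = s d``: a dominant primal residual
    (``v > delta d'``) boosts the primal step (``gamma = 1 - alpha``, so
    ``tau / gamma`` grows); a dominant dual residual shrinks it
    (``gamma = 1/(1 - alpha)``); inside the dead zone nothing changes.  The
    amplitude shrinks to ``eta alpha`` exactly when a change is made.
    """
    if v < 0 or d < 0:
        raise ValueError("residuals must be nonnegative")
    if not (0 < alpha_k < 1):
        raise ValueError("alpha_k must be in (0, 1)")
    s = 1.0 if cfg.s is None else cfg.s
    d_scaled = s * d
    if v > cfg.delta * d_scaled and v > 0:
        return 1.0 - alpha_k, cfg.eta * alpha_k
    if d_scaled > cfg.delta * v and d_scaled > 0:
        return 1.0 / (1.0 - alpha_k), cfg.eta * alpha_k
    return 1.0, alpha_k


def cosine_rule_b(
    x_prev: np.ndarray,
    x_curr: np.ndarray,
    y_prev_i: np.ndarray,
    y_curr_i: np.ndarray,
    tau: float,
    p_i: float,
    A_i: LinearMap,
    at_dy: np.ndarray | None = None,
) -> tuple[np.ndarray, float | None]:
    """Primal subgradient estimate ``q`` and its cosine with the update direction.

    ``q = (x_prev - x_curr)/tau - (1/p_i) A_i*(y_prev_i - y_curr_i)``;
    ``w = <x_prev - x_curr, q> / (||x_prev - x_curr||_2 ||q||_2)``, or None
    when either vector vanishes (degenerate, flagged rather than raised).
    """
    if tau <= 0 or p_i <= 0:
        raise ValueError("tau and p_i must be positive")
    dx = x_prev - x_curr
    if at_dy is None:
        at_dy = A_i.adjoint(y_curr_i - y_prev_i)
    q = dx / tau + at_dy / p_i
    ndx = np.linalg.norm(dx)
    nq = np.linalg.norm(q)
    if ndx == 0 or nq == 0:
        return q, None
    w = float(np.vdot(dx, q) / (ndx * nq))
    return q, float(np.clip(w, -1.0, 1.0))


def decide_gamma_rule_b(
    w: float | None, cfg: AngleConfig, alpha_k: float
) -> tuple[float, float]:
    """Angle-alignment decision: returns ``(gamma, alpha_next)``."""
    if not (0 < alpha_k < 1):
        raise ValueError("alpha_k must be in (0, 1)")
    if w is None:
        return 1.0, alpha_k
    if w >= cfg.c:
        return 1.0 - alpha_k, cfg.eta * alpha_k
    if w < cfg.c_low:
        return 1.0 / (1.0 - alpha_k), cfg.eta * alpha_k
    return 1.0, alpha_k


def clip_gamma_envelope(gamma: float, eps_k: float) -> float:
    """Clip ``gamma`` into ``[1 - eps_k, 1/(1 - eps_k)]``.

    Guarantees ``min{gamma, 1/gamma} >= 1 - eps_k``, the deterministic
    control that certifies quasi-increasing step sizes.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if not (0 <= eps_k < 1):
        raise ValueError("eps_k must be in [0, 1)")
    lo = 1.0 - eps_k
    return float(np.clip(gamma, lo, 1.0 / lo))


def apply_gamma(tau: float, sigmas: np.ndarray, gamma: float) -> tuple[float, np.ndarray]:
    """Ratio update ``tau' = tau/gamma``, ``sigma_i' = gamma sigma_i``."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return tau / gamma, gamma * np.asarray(sigmas, dtype=float)


class _AdaptiveBase(StepController):
    """Shared propose/observe plumbing of the two adaptive rules."""

    def __init__(self, alpha0: float, eta: float, mode: str):
        self.alpha = alpha0
        self._alpha0 = alpha0
        self._eta = eta
        self.mode = mode
        self.envelope = EnvelopeSchedule(alpha0, eta) if mode == "certified" else None
        self._pending = None  # observables digest from the last completed pass

    def _decide(self, state: SolverState) -> tuple[float, float]:  # pragma: no cover
        raise NotImplementedError

    def propose(self, state: SolverState) -> float:
        if self._pending is None:
            return 1.0
        gamma, alpha_next = self._decide(state)
        self._pending = None
        if self.envelope is not None:
            gamma = clip_gamma_envelope(gamma, self.envelope.eps(state.k))
        self.alpha = alpha_next
        return gamma


class ResidualBalancingController(_AdaptiveBase):
    """Rule (a): balance the l1 primal/dual optimality residuals online.

    Uses one shared dual step size across blocks (enforced by the solver's
    ``shared`` initialization).  When ``cfg.s`` is None the dual-residual
    scale defaults to the stacked operator norm ``||A||``, estimated once on
    first use.
    """

    def __init__(self, cfg: BalancingConfig | None = None):
        cfg = cfg or BalancingConfig()
        super().__init__(cfg.alpha0, cfg.eta, cfg.mode)
        self.cfg = cfg
        self._s_resolved = cfg.s

    def _resolve_s(self, problem: SaddleProblem) -> float:
        if self._s_resolved is None:
            stacked = BlockRowMap([blk.op for blk in problem.blocks])
            self._s_resolved = float(estimate_norm(stacked, seed=0))
        return self._s_resolved

    def observe(self, state: SolverState, problem: SaddleProblem) -> None:
        last = state.last
        blk = problem.blocks[last.block_index]
        dx = last.x_prev - last.x_curr
        v = float(np.sum(np.abs(dx / last.tau + last.at_dy / blk.p)))
        q = self.cfg.subsample_fraction
        # only flat-range blocks can be row-subsampled; others (e.g. the
        # image-gradient block, whose application is cheap) get the exact d
        if q >= 1.0 or len(blk.op.range_shape) != 1:
            dy = -last.dy
            d = float(np.sum(np.abs(dy / last.sigma - blk.op.apply(dx)))) / blk.p
        else:
            m = blk.op.range_size
            r = max(1, int(np.ceil(q * m)))
            rows = np.sort(state.rngs["subsample"].choice(m, size=r, replace=False))
            d = residuals_rule_a_subsampled(
                last.x_prev, last.x_curr,
                state.ys[last.block_index] - last.dy, state.ys[last.block_index],
                last.tau, last.sigma, blk.p, blk.op, rows,
            )
        self._resolve_s(problem)
        self._pending = (v, d)
        self.last_v, self.last_d = v, d

    def _decide(self, state: SolverState) -> tuple[float, float]:
        v, d = self._pending
        cfg = self.cfg
        eff = BalancingConfig(
            alpha0=cfg.alpha0, eta=cfg.eta, delta=cfg.delta,
            s=self._s_resolved, subsample_fraction=cfg.subsample_fraction,
            mode=cfg.mode,
        )
        return decide_gamma_rule_a(v, d, eff, self.alpha)


class AngleAlignmentController(_AdaptiveBase):
    """Rule (b): adapt on the alignment of update direction and subgradient."""

    def __init__(self, cfg: AngleConfig | None = None):
        cfg = cfg or AngleConfig()
        super().__init__(cfg.alpha0, cfg.eta, cfg.mode)
        self.cfg = cfg

    def observe(self, state: SolverState, problem: SaddleProblem) -> None:
        last = state.last
        blk = problem.blocks[last.block_index]
        _, w = cosine_rule_b(
            last.x_prev, last.x_curr,
            state.ys[last.block_index] - last.dy, state.ys[last.block_index],
            last.tau, blk.p, blk.op, at_dy=last.at_dy,
        )
        self._pending = w
        self.last_w = np.nan if w is None else w

    def _decide(self, state: SolverState) -> tuple[float, float]:
        return decide_gamma_rule_b(self._pending, self.cfg, self.alpha)


def make_controller(name: str, **kwargs) -> StepController:
    """Controller factory: ``constant``, ``rule_a`` or ``rule_b``."""
    from .solver import ConstantController

    if name == "constant":
        return ConstantController()
    if name == "rule_a":
        return ResidualBalancingController(BalancingConfig(**kwargs))
    if name == "rule_b":
        return AngleAlignmentController(AngleConfig(**kwargs))
    raise ValueError(f"unknown controller {name!r}")
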