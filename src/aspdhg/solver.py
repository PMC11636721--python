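"""Adaptive stochastic primal-dual hybrid gradient (A-SPDHG) core loop.

Solves the composite saddle-point problem

    min_x max_y  sum_i <A_i x, y_i> - f_i*(y_i) + g(x)

by serial randomized dual updates: each iteration proposes new step sizes
(tau, sigma) from the observable history, takes one primal proximal step
against the extrapolated dual transform ``z = A* ybar``, samples one dual
block ``i`` with probability ``p_i``, updates its dual variable by a
conjugate proximal step, and refreshes the two maintained domain-space
transforms ``h = A* y`` and ``z = A* ybar`` incrementally — the extrapolated
dual ``ybar`` itself is never stored.

Vanilla SPDHG is the special case of a constant step controller; the
deterministic PDHG iteration is the further special case ``n = 1, p_1 = 1``.

Convergence requires (i) step sizes for pass k+1 measurable with respect to
the history up to pass k, (ii) ``tau^k sigma_i^k ||A_i||^2 / p_i <= beta < 1``
at every k, and (iii) quasi-increasing step-size sequences.  The loop
enforces (i) by construction (controllers propose before the primal update,
from the previous pass's observables) and audits (ii) every iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .operators import LinearMap
from .proximal import Proximable, Zero

__all__ = [
    "Block",
    "SaddleProblem",
    "SolverState",
    "StepController",
    "ConstantController",
    "IterationObservables",
    "DivergenceError",
    "init_step_sizes",
    "sample_index",
    "aspdhg_iteration",
    "run",
    "RUNLOG_COLUMNS",
]

RUNLOG_COLUMNS = [
    "k",
    "epoch",
    "tau",
    "sigma_shared",
    "gamma",
    "v",
    "d",
    "w",
    "sampled_block",
    "objective",
]

_DIVERGENCE_NORM = 1e12


class DivergenceError(RuntimeError):
    """Raised when an iterate becomes non-finite or explodes."""

    def __init__(self, iteration: int, message: str):
        super().__init__(f"divergence at iteration {iteration}: {message}")
        self.iteration = iteration


@dataclass
class Block:
    """One dual block: operator, conjugate prox, sampling weight, norm."""

    op: LinearMap
    conj_prox: Callable[[np.ndarray, float], np.ndarray]
    p: float
    L: float
    b: np.ndarray | None = None
    name: str = ""


@dataclass
class SaddleProblem:
    """The composite saddle-point problem handed to the solver."""

    g: Proximable
    blocks: list[Block]
    domain_shape: tuple[int, ...]

    def __post_init__(self):
        if len(self.blocks) < 1:
            raise ValueError("problem needs at least one block")
        p = np.array([blk.p for blk in self.blocks], dtype=float)
        if np.any(p <= 0):
            raise ValueError("sampling must be proper: all p_i > 0")
        if abs(p.sum() - 1.0) > 1e-10:
            raise ValueError(f"sampling probabilities must sum to 1, got {p.sum()}")
        for blk in self.blocks:
            if blk.L <= 0:
                raise ValueError("all block norms L_i must be positive")
            if blk.op.domain_shape != tuple(self.domain_shape):
                raise ValueError("block operator domain mismatch")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def probabilities(self) -> np.ndarray:
        return np.array([blk.p for blk in self.blocks], dtype=float)

    @property
    def norms(self) -> np.ndarray:
        return np.array([blk.L for blk in self.blocks], dtype=float)


@dataclass
class IterationObservables:
    """Everything a completed pass exposes to the step controller.

    Holds only pass-k quantities, so a controller that proposes from these is
    automatically measurable with respect to the pass-k history.  ``at_dy``
    caches ``A_i*(y_i^{k+1} - y_i^k)`` from the bookkeeping update so rule
    evaluation costs no extra adjoint.
    """

    x_prev: np.ndarray
    x_curr: np.ndarray
    dy: np.ndarray
    at_dy: np.ndarray
    block_index: int
    tau: float
    sigma: float
    gamma: float


@dataclass
class SolverState:
    """Mutable solver state: iterates, maintained transforms, step sizes."""

    x: np.ndarray
    ys: list[np.ndarray]
    h: np.ndarray  # A* y, maintained incrementally
    z: np.ndarray  # A* ybar, maintained incrementally
    tau: float
    sigmas: np.ndarray
    beta: float
    k: int = 0
    rngs: dict = field(default_factory=dict)
    last: IterationObservables | None = None

    def recompute_h(self, problem: SaddleProblem) -> np.ndarray:
        """From-scratch ``A* y`` (test/diagnostic use)."""
        out = np.zeros(self.x.shape)
        for blk, y in zip(problem.blocks, self.ys):
            out += blk.op.adjoint(y)
        return out

    def recompute_z(self, problem: SaddleProblem) -> np.ndarray:
        """From-scratch ``A* ybar`` using the cached last-pass dual change."""
        out = self.recompute_h(problem)
        if self.last is not None:
            i = self.last.block_index
            out += problem.blocks[i].op.adjoint(self.last.dy) / problem.blocks[i].p
        return out


class StepController:
    """Contract for online step-size adaptation.

    ``propose`` is called at the start of pass k+1 and must return the ratio
    factor ``gamma^k`` computed only from quantities observed up to pass k;
    the loop then sets ``tau^{k+1} = tau^k / gamma`` and
    ``sigma^{k+1} = gamma sigma^k``.  ``observe`` is called at the end of
    each pass with the pass observables.
    """

    def propose(self, state: SolverState) -> float:
        return 1.0

    def observe(self, state: SolverState, problem: SaddleProblem) -> None:
        pass

    # diagnostics recorded into the run log, refreshed by observe()
    last_v: float = np.nan
    last_d: float = np.nan
    last_w: float = np.nan


class ConstantController(StepController):
    """Vanilla SPDHG: the step sizes never change (``gamma = 1``)."""


def init_step_sizes(
    problem: SaddleProblem,
    ratio: float,
    beta: float = 0.99,
    mode: str = "shared",
) -> tuple[float, np.ndarray]:
    """Initial step sizes with ``tau/sigma = ratio`` satisfying the product bound.

    ``shared`` mode uses one dual step size for every block (the setting of
    the residual-balancing rule): ``sigma = min_i sqrt(beta p_i / ratio)/L_i``
    and ``tau = ratio * sigma``.  ``per_block`` mode instead fixes
    ``tau = min_i sqrt(beta ratio p_i)/L_i`` and saturates
    ``sigma_i = beta p_i / (tau L_i^2)`` per block.  Both guarantee
    ``max_i tau sigma_i L_i^2 / p_i <= beta < 1``.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if not (0 < beta < 1):
        raise ValueError("beta must lie strictly in (0, 1)")
    p = problem.probabilities
    L = problem.norms
    if mode == "shared":
        sigma = float(np.min(np.sqrt(beta * p / ratio) / L))
        tau = ratio * sigma
        sigmas = np.full(problem.n_blocks, sigma)
    elif mode == "per_block":
        tau = float(np.min(np.sqrt(beta * ratio * p) / L))
        sigmas = beta * p / (tau * L**2)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return tau, sigmas


def sample_index(p: Sequence[float], rng: np.random.Generator) -> int:
    """Draw a block index with probabilities ``p`` by inverse-CDF sampling."""
    p = np.asarray(p, dtype=float)
    if abs(p.sum() - 1.0) > 1e-12:
        raise ValueError(f"probabilities must sum to 1, got {p.sum()}")
    u = rng.random()
    return int(np.searchsorted(np.cumsum(p), u))


def _check_condition(state: SolverState, problem: SaddleProblem, tau: float, sigmas: np.ndarray):
    cond = tau * sigmas * problem.norms**2 / problem.probabilities
    if np.any(cond > state.beta * (1 + 1e-9)):
        raise RuntimeError(
            f"step-size safeguard violated at k={state.k}: "
            f"max tau*sigma_i*L_i^2/p_i = {cond.max():.6g} > beta = {state.beta}"
        )


def aspdhg_iteration(
    problem: SaddleProblem,
    state: SolverState,
    controller: StepController,
) -> SolverState:
    """Execute one A-SPDHG pass in place and return the state.

    Order of operations within pass k: (1) controller proposes ``gamma^k``
    from pass-<k observables and the step sizes for this pass are formed;
    (2) primal prox step against the maintained ``z = A* ybar``; (3) one
    block is sampled; (4) its dual variable takes a conjugate prox step;
    (5) ``h`` and ``z`` are refreshed incrementally from the adjoint of the
    dual change; (6) the controller observes the pass.
    """
    gamma = float(controller.propose(state))
    if gamma <= 0:
        raise ValueError("controller proposed a nonpositive gamma")
    tau = state.tau / gamma
    sigmas = gamma * state.sigmas
    _check_condition(state, problem, tau, sigmas)

    x_new = problem.g.prox(state.x - tau * state.z, tau)

    i = sample_index(problem.probabilities, state.rngs["index"])
    blk = problem.blocks[i]
    ax = blk.op.apply(x_new)
    y_new = blk.conj_prox(state.ys[i] + sigmas[i] * ax, sigmas[i])
    dy = y_new - state.ys[i]
    delta = blk.op.adjoint(dy)

    state.h = state.h + delta
    state.z = state.h + delta / blk.p

    if not (np.all(np.isfinite(x_new)) and np.all(np.isfinite(y_new))):
        raise DivergenceError(state.k, "non-finite iterate")
    if np.linalg.norm(x_new) > _DIVERGENCE_NORM:
        raise DivergenceError(state.k, "primal iterate norm exceeded 1e12")

    state.last = IterationObservables(
        x_prev=state.x,
        x_curr=x_new,
        dy=dy,
        at_dy=delta,
        block_index=i,
        tau=tau,
        sigma=float(sigmas[i]),
        gamma=gamma,
    )
    state.x = x_new
    state.ys[i] = y_new
    state.tau = tau
    state.sigmas = sigmas
    state.k += 1
    controller.observe(state, problem)
    return state


def make_state(
    problem: SaddleProblem,
    init_x: np.ndarray,
    tau: float,
    sigmas: np.ndarray,
    beta: float,
    seed: int,
    init_ys: list[np.ndarray] | None = None,
) -> SolverState:
    """Assemble a fresh solver state with named, independent RNG streams."""
    init_x = np.asarray(init_x, dtype=float)
    if init_x.shape != tuple(problem.domain_shape):
        raise ValueError("init_x shape mismatch")
    if init_ys is None:
        ys = [np.zeros(blk.op.range_shape) for blk in problem.blocks]
        h = np.zeros(init_x.shape)
    else:
        ys = [np.asarray(y, dtype=float).copy() for y in init_ys]
        h = np.zeros(init_x.shape)
        for blk, y in zip(problem.blocks, ys):
            h += blk.op.adjoint(y)
    streams = np.random.SeedSequence(seed).spawn(3)
    rngs = {
        "index": np.random.default_rng(streams[0]),
        "subsample": np.random.default_rng(streams[1]),
        "noise": np.random.default_rng(streams[2]),
    }
    return SolverState(
        x=init_x.copy(),
        ys=ys,
        h=h,
        z=h.copy(),
        tau=float(tau),
        sigmas=np.asarray(sigmas, dtype=float).copy(),
        beta=float(beta),
        rngs=rngs,
    )


def run(
    problem: SaddleProblem,
    init_x: np.ndarray,
    controller: StepController,
    n_iterations: int,
    seed: int,
    ratio: float = 1.0,
    beta: float = 0.99,
    mode: str = "shared",
    objective_fn: Callable[[np.ndarray], float] | None = None,
    log_every: int = 1,
    callbacks: Sequence[Callable[[SolverState], None]] = (),
) -> tuple[SolverState, pd.DataFrame]:
    """Run A-SPDHG for ``n_iterations`` and return (state, run log).

    The run log has one row per iteration with fixed columns
    ``k, epoch, tau, sigma_shared, gamma, v, d, w, sampled_block, objective``;
    the objective (when an ``objective_fn`` is given) is evaluated every
    ``log_every`` iterations and on the final one, and is NaN elsewhere.
    Fully reproducible: all randomness flows from ``seed``.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    tau0, sigmas0 = init_step_sizes(problem, ratio=ratio, beta=beta, mode=mode)
    state = make_state(problem, init_x, tau0, sigmas0, beta, seed)
    n = problem.n_blocks
    records = []
    for k in range(n_iterations):
        aspdhg_iteration(problem, state, controller)
        obj = np.nan
        if objective_fn is not None and (k % log_every == 0 or k == n_iterations - 1):
            obj = float(objective_fn(state.x))
        last = state.last
        records.append(
            {
                "k": k,
                "epoch": k / n,
                "tau": last.tau,
                "sigma_shared": float(state.sigmas[0]),
                "gamma": last.gamma,
                "v": controller.last_v,
                "d": controller.last_d,
                "w": controller.last_w,
                "sampled_block": last.block_index,
                "objective": obj,
            }
        )
        for cb in callbacks:
            cb(state)
    log = pd.DataFrame.from_records(records, columns=RUNLOG_COLUMNS)
    return state, log
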