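"""Independent straight-line reference implementations used as test oracles.

These deliberately do not call the solver loop; they re-code the iterations
directly from their mathematical definitions so trajectory comparisons are a
genuine cross-check.
"""

import numpy as np


def vanilla_spdhg(problem, x0, tau, sigmas, n_iterations, seed):
    """Straight-line serial-sampling SPDHG with constant step sizes.

    Standard implementation layout: the extrapolated dual transform
    ``z = A* ybar`` is maintained incrementally from the adjoint of the
    sampled block's dual change; indices are drawn by inverse-CDF from the
    first spawned stream of ``seed``.  Returns the primal trajectory.
    """
    p = np.array([blk.p for blk in problem.blocks])
    cum = np.cumsum(p)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[0])
    x = np.asarray(x0, dtype=float).copy()
    ys = [np.zeros(blk.op.range_shape) for blk in problem.blocks]
    h = np.zeros(x.shape)
    z = h.copy()
    traj = []
    for _ in range(n_iterations):
        x = problem.g.prox(x - tau * z, tau)
        i = int(np.searchsorted(cum, rng.random()))
        blk = problem.blocks[i]
        y_new = blk.conj_prox(ys[i] + sigmas[i] * blk.op.apply(x), sigmas[i])
        dy = y_new - ys[i]
        delta = blk.op.adjoint(dy)
        h = h + delta
        z = h + delta / blk.p
        ys[i] = y_new
        traj.append(x.copy())
    return traj


def pdhg_dual_extrapolated(A_apply, A_adjoint, conj_prox, x0, y0, tau, sigma, n_iterations):
    """Deterministic PDHG, dual-extrapolated form, g = 0; primal trajectory."""
    x = np.asarray(x0, dtype=float).copy()
    y = np.asarray(y0, dtype=float).copy()
    y_prev = y.copy()
    traj = []
    for _ in range(n_iterations):
        x = x - tau * A_adjoint(2.0 * y - y_prev)
        y_prev = y
        y = conj_prox(y + sigma * A_apply(x), sigma)
        traj.append(x.copy())
    return traj
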