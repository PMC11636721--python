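"""Adaptive-rule semantics: residuals, triggers, envelopes, unbiasedness."""

import itertools

import numpy as np
import pytest

from aspdhg import (
    AngleAlignmentController,
    AngleConfig,
    BalancingConfig,
    ConstantController,
    EnvelopeSchedule,
    L2Squared,
    MatrixMap,
    ResidualBalancingController,
    run,
)
from aspdhg.adaptive import (
    apply_gamma,
    clip_gamma_envelope,
    cosine_rule_b,
    decide_gamma_rule_a,
    decide_gamma_rule_b,
    residuals_rule_a,
    residuals_rule_a_subsampled,
)
from aspdhg.diagnostics import fullbatch_residuals, quasi_increasing_check
from aspdhg.solver import init_step_sizes, make_state, aspdhg_iteration
from aspdhg import SaddleProblem, Zero, Block

from conftest import random_ls_problem


class TestResidualsRuleA:
    def test_stationary_pair_is_zero(self):
        A = MatrixMap(np.eye(2))
        x = np.array([1.0, 2.0])
        y = np.array([0.3, -0.7])
        v, d = residuals_rule_a(x, x, y, y, 0.5, 0.5, 1.0, A)
        assert v == 0.0 and d == 0.0

    def test_hand_case(self):
        # dx=(1,0), tau=1, p=1, A=I2, y_curr - y_prev = (0,1), sigma=1
        A = MatrixMap(np.eye(2))
        x_prev, x_curr = np.array([1.0, 0.0]), np.array([0.0, 0.0])
        y_prev, y_curr = np.array([0.0, 0.0]), np.array([0.0, 1.0])
        v, d = residuals_rule_a(x_prev, x_curr, y_prev, y_curr, 1.0, 1.0, 1.0, A)
        assert v == pytest.approx(2.0)
        assert d == pytest.approx(2.0)

    def test_equals_fullbatch_residuals_at_n1(self, rng):
        """The minibatch residuals reduce to the deterministic ones at n=1, p=1."""
        A = MatrixMap(rng.standard_normal((6, 4)))
        xp, xc = rng.standard_normal(4), rng.standard_normal(4)
        yp, yc = rng.standard_normal(6), rng.standard_normal(6)
        v1, d1 = residuals_rule_a(xp, xc, yp, yc, 0.3, 0.7, 1.0, A)
        v2, d2 = fullbatch_residuals(xp, xc, yp, yc, 0.3, 0.7, A)
        assert v1 == pytest.approx(v2, abs=1e-14)
        assert d1 == pytest.approx(d2, abs=1e-14)

    def test_fullbatch_g_zero_collapse(self, rng):
        """On a first solver pass with g=0, n=1: v = ||A* y^1||_1 exactly.

        The primal prox optimality with g = 0 makes the update direction
        equal the extrapolated dual transform, which on the first pass is
        A* y^0, so the residual telescopes to the new dual transform alone.
        """
        A = MatrixMap(rng.standard_normal((5, 5)))
        b = rng.standard_normal(5)
        from aspdhg.operators import estimate_norm

        blk = Block(A, L2Squared(b).conj_prox, 1.0, float(estimate_norm(A)), b)
        prob = SaddleProblem(Zero(), [blk], (5,))
        tau, sig = init_step_sizes(prob, ratio=1.3, beta=0.9)
        y0 = rng.standard_normal(5)
        st = make_state(prob, rng.standard_normal(5), tau, sig, 0.9, seed=0, init_ys=[y0])
        aspdhg_iteration(prob, st, ConstantController())
        last = st.last
        v, _ = residuals_rule_a(
            last.x_prev, last.x_curr, st.ys[0] - last.dy, st.ys[0],
            last.tau, last.sigma, 1.0, A,
        )
        assert v == pytest.approx(np.sum(np.abs(A.adjoint(st.ys[0]))), rel=1e-12)


class TestSubsampledEstimator:
    def _setup(self, rng, m=4):
        A = MatrixMap(rng.standard_normal((m, 3)))
        xp, xc = rng.standard_normal(3), rng.standard_normal(3)
        yp, yc = rng.standard_normal(m), rng.standard_normal(m)
        return A, xp, xc, yp, yc

    def test_full_subset_is_exact(self, rng):
        A, xp, xc, yp, yc = self._setup(rng)
        _, d = residuals_rule_a(xp, xc, yp, yc, 0.4, 0.9, 0.5, A)
        d_hat = residuals_rule_a_subsampled(
            xp, xc, yp, yc, 0.4, 0.9, 0.5, A, np.arange(4)
        )
        assert d_hat == pytest.approx(d, rel=1e-14)

    def test_exhaustive_two_subsets_of_four_rows(self, rng):
        """Mean over all size-2 subsets equals the full dual residual."""
        for trial in range(3):
            A, xp, xc, yp, yc = self._setup(rng)
            if trial == 0:
                # one-hot residual: only row 2 contributes
                yc = yp.copy()
                xc = xp.copy()
                yc[2] += 1.7
            _, d = residuals_rule_a(xp, xc, yp, yc, 0.4, 0.9, 0.5, A)
            ests = [
                residuals_rule_a_subsampled(
                    xp, xc, yp, yc, 0.4, 0.9, 0.5, A, np.array(rows)
                )
                for rows in itertools.combinations(range(4), 2)
            ]
            assert np.mean(ests) == pytest.approx(d, rel=1e-12)

    def test_monte_carlo_unbiased_on_fifty_rows(self, rng):
        A, xp, xc, yp, yc = self._setup(rng, m=50)
        _, d = residuals_rule_a(xp, xc, yp, yc, 0.4, 0.9, 0.5, A)
        n_draws = 10000
        ests = np.empty(n_draws)
        for t in range(n_draws):
            rows = np.sort(rng.choice(50, size=5, replace=False))
            ests[t] = residuals_rule_a_subsampled(
                xp, xc, yp, yc, 0.4, 0.9, 0.5, A, rows
            )
        se = ests.std(ddof=1) / np.sqrt(n_draws)
        assert abs(ests.mean() - d) <= 3.0 * se

    def test_empty_rows_rejected(self, rng):
        A, xp, xc, yp, yc = self._setup(rng)
        with pytest.raises(ValueError):
            residuals_rule_a_subsampled(
                xp, xc, yp, yc, 0.4, 0.9, 0.5, A, np.array([], dtype=int)
            )


class TestDecisionRuleA:
    def test_balanced_dead_zone(self):
        cfg = BalancingConfig(s=1.0, delta=1.5)
        gamma, alpha = decide_gamma_rule_a(1.0, 1.0, cfg, 0.5)
        assert gamma == 1.0 and alpha == 0.5

    def test_primal_residual_dominant_boosts_tau(self):
        cfg = BalancingConfig(s=1.0, delta=1.5, eta=0.9)
        gamma, alpha = decide_gamma_rule_a(10.0, 1.0, cfg, 0.5)
        assert gamma == pytest.approx(0.5)
        assert alpha == pytest.approx(0.45)

    def test_dual_residual_dominant_shrinks_tau(self):
        cfg = BalancingConfig(s=1.0, delta=1.5, eta=0.9)
        gamma, alpha = decide_gamma_rule_a(1.0, 10.0, cfg, 0.5)
        assert gamma == pytest.approx(2.0)
        assert alpha == pytest.approx(0.45)

    def test_degenerate_zero_residuals(self):
        gamma, alpha = decide_gamma_rule_a(0.0, 0.0, BalancingConfig(s=1.0), 0.3)
        assert gamma == 1.0 and alpha == 0.3

    def test_s_scaling_enters_dual_side(self):
        # with s=10, d=1 acts like 10: dual side dominates v=2
        cfg = BalancingConfig(s=10.0, delta=1.5)
        gamma, _ = decide_gamma_rule_a(2.0, 1.0, cfg, 0.5)
        assert gamma == pytest.approx(2.0)


class TestRuleB:
    def test_parallel_vectors_give_one(self, rng):
        A = MatrixMap(np.eye(3))
        xp, xc = np.array([1.0, 1.0, 0.0]), np.zeros(3)
        y = np.zeros(3)
        # dy = 0 -> q = dx / tau, perfectly aligned with dx
        _, w = cosine_rule_b(xp, xc, y, y, 0.7, 1.0, A)
        assert w == pytest.approx(1.0)

    def test_orthogonal_gives_zero(self):
        A = MatrixMap(np.eye(2))
        xp, xc = np.array([1.0, 0.0]), np.zeros(2)
        # choose dy so that q = dx/tau - A* dy_flip is orthogonal to dx
        # q = (1, 0) + A*(y_curr - y_prev); pick the change to make q = (0, 1)
        y_prev, y_curr = np.zeros(2), np.array([-1.0, 1.0])
        _, w = cosine_rule_b(xp, xc, y_prev, y_curr, 1.0, 1.0, A)
        assert w == pytest.approx(0.0, abs=1e-14)

    def test_degenerate_flagged(self):
        A = MatrixMap(np.eye(2))
        x = np.ones(2)
        _, w = cosine_rule_b(x, x, np.zeros(2), np.zeros(2), 1.0, 1.0, A)
        assert w is None

    def test_decision_thresholds(self):
        cfg = AngleConfig(c=0.999, c_low=0.9, eta=0.9)
        g, a = decide_gamma_rule_b(1.0, cfg, 0.5)
        assert g == pytest.approx(0.5) and a == pytest.approx(0.45)
        g, a = decide_gamma_rule_b(0.95, cfg, 0.5)
        assert g == 1.0 and a == 0.5
        g, a = decide_gamma_rule_b(0.1, cfg, 0.5)
        assert g == pytest.approx(2.0)
        g, a = decide_gamma_rule_b(None, cfg, 0.5)
        assert g == 1.0 and a == 0.5


class TestEnvelope:
    def test_clip_values(self):
        assert clip_gamma_envelope(0.5, 0.1) == pytest.approx(0.9)
        assert clip_gamma_envelope(3.0, 0.1) == pytest.approx(1.0 / 0.9)
        assert clip_gamma_envelope(1.0, 0.3) == 1.0
        with pytest.raises(ValueError):
            clip_gamma_envelope(-1.0, 0.1)

    def test_schedule_summable(self):
        sch = EnvelopeSchedule(eps0=0.5, zeta=0.9)
        total = sum(sch.eps(k) for k in range(10000))
        assert total == pytest.approx(0.5 / 0.1, rel=1e-6)
        assert all(0 <= sch.eps(k) < 1 for k in range(100))

    def test_apply_gamma(self):
        tau, sig = apply_gamma(1.0, np.array([2.0, 4.0]), 0.5)
        assert tau == 2.0
        assert np.array_equal(sig, [1.0, 2.0])
        t2, s2 = apply_gamma(tau, sig, 1.0)
        assert t2 == tau and np.array_equal(s2, sig)
        assert tau * sig[0] == 1.0 * 2.0  # product preserved exactly


class TestControllersOnRuns:
    @pytest.mark.parametrize("make", [
        lambda: ResidualBalancingController(BalancingConfig(s=1.0, subsample_fraction=1.0)),
        lambda: AngleAlignmentController(AngleConfig()),
    ])
    def test_product_invariance(self, rng, make):
        """Ratio-only controllers keep tau*sigma constant to 1e-14 relative."""
        prob = random_ls_problem(rng, n_blocks=3)
        _, log = run(prob, np.zeros(4), make(), 300, seed=2, ratio=0.5, beta=0.9)
        prod = log["tau"].to_numpy() * log["sigma_shared"].to_numpy()
        assert np.all(np.abs(prod - prod[0]) <= 1e-14 * prod[0])
        assert (log["gamma"] != 1.0).any()  # the rule actually adapted

    def test_certified_mode_respects_envelope(self, rng):
        prob = random_ls_problem(rng, n_blocks=2)
        cfg = BalancingConfig(s=1.0, mode="certified", subsample_fraction=1.0)
        ctrl = ResidualBalancingController(cfg)
        _, log = run(prob, np.zeros(4), ctrl, 400, seed=7, ratio=0.3, beta=0.9)
        gam = log["gamma"].to_numpy()
        eps = cfg.alpha0 * cfg.eta ** np.arange(len(gam))
        assert np.all(np.minimum(gam, 1.0 / gam) >= 1.0 - eps - 1e-12)
        # and the step-size sequences are quasi-increasing with that control
        ok_tau, _ = quasi_increasing_check(log["tau"].to_numpy(), lambda k: eps[k])
        ok_sig, _ = quasi_increasing_check(log["sigma_shared"].to_numpy(), lambda k: eps[k])
        assert ok_tau and ok_sig

    def test_paper_mode_amplitude_shrinks_per_change(self, rng):
        prob = random_ls_problem(rng, n_blocks=2)
        cfg = BalancingConfig(s=1.0, mode="paper", subsample_fraction=1.0)
        ctrl = ResidualBalancingController(cfg)
        _, log = run(prob, np.zeros(4), ctrl, 400, seed=7, ratio=0.3, beta=0.9)
        gam = log["gamma"].to_numpy()
        changes = 0
        for g in gam:
            if g != 1.0:
                bound = 1.0 - cfg.alpha0 * cfg.eta**changes
                assert min(g, 1.0 / g) >= bound - 1e-12
                changes += 1
        assert changes > 0

    def test_condition_holds_every_iteration(self, rng):
        from aspdhg.diagnostics import audit_runlog_condition

        prob = random_ls_problem(rng, n_blocks=3)
        for ctrl in (
            ConstantController(),
            ResidualBalancingController(BalancingConfig(s=1.0, subsample_fraction=1.0)),
            AngleAlignmentController(),
        ):
            _, log = run(prob, np.zeros(4), ctrl, 500, seed=11, ratio=1.0, beta=0.9)
            assert audit_runlog_condition(log, prob.norms, prob.probabilities, 0.9)
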