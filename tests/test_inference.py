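"""Loss functions, optimizer, confidence intervals, and the synthetic
benchmark protocol."""

import numpy as np
import pytest

from diffgillespie import _ad
from diffgillespie.dga_core import DGAConfig, simulate_dga
from diffgillespie.inference import (
    ConfidenceInterval,
    DivergenceError,
    MomentTargets,
    SimSettings,
    batch_mean_std,
    confidence_interval,
    fit,
    generate_synthetic,
    landscape,
    loss_multi,
    loss_single,
    single_loss_and_grad,
    standard_halfwidth,
)
from diffgillespie.promoters import TWO_STATE_X0, build_two_state, two_state_mean_fano

FAST = SimSettings(T=10.0, config=DGAConfig(n_traj=300))


class TestLossSingle:
    def test_self_consistency_is_zero(self, two_state_net, x0):
        theta = {"kon_r": 1.0, "koff_r": 1.0, "r": 4.0, "gamma": 1.0}
        batch = simulate_dga(
            two_state_net, x0, theta, FAST.T, FAST.smoothing, FAST.config, seed=5
        )
        mean, std = batch_mean_std(batch)
        tg = MomentTargets(mean=float(mean), std=float(std))
        assert loss_single(theta, tg, FAST, seed=5) == pytest.approx(0.0, abs=1e-18)

    def test_quadratic_in_each_residual(self, two_state_net, x0):
        theta = {"kon_r": 1.0, "koff_r": 1.0, "r": 4.0, "gamma": 1.0}
        batch = simulate_dga(
            two_state_net, x0, theta, FAST.T, FAST.smoothing, FAST.config, seed=5
        )
        mean, std = batch_mean_std(batch)
        l1 = loss_single(theta, MomentTargets(float(mean) + 1.0, float(std)), FAST, 5)
        l2 = loss_single(theta, MomentTargets(float(mean) + 2.0, float(std)), FAST, 5)
        assert l2 / l1 == pytest.approx(4.0, rel=1e-9)

    def test_small_at_generating_parameters(self):
        p_mean, p_fano = two_state_mean_fano(
            __import__("diffgillespie.promoters", fromlist=["TwoStateParams"]).TwoStateParams(
                kon_r=1.0, r=4.0, gamma=1.0
            )
        )
        tg = MomentTargets.from_mean_fano(p_mean, p_fano)
        theta = {"kon_r": 1.0, "koff_r": 1.0, "r": 4.0, "gamma": 1.0}
        L = float(_ad.value(loss_single(theta, tg, FAST, seed=3)))
        assert 0.0 < L < 1.0  # small but nonzero: Monte-Carlo + smoothing bias


class TestLossMulti:
    def _targets(self, n):
        return [MomentTargets.from_mean_fano(3.0 + i, 1.5) for i in range(n)]

    def test_condition_count_mismatch(self):
        with pytest.raises(ValueError):
            loss_multi({"r": 4.0, "gamma": 1.0}, [1.0], self._targets(2), FAST)

    def test_permutation_invariance(self):
        tgts = self._targets(3)
        kons = [0.5, 1.0, 2.0]
        a = float(_ad.value(loss_multi({"r": 4.0, "gamma": 1.0}, kons, tgts, FAST, seed=1)))
        perm = [2, 0, 1]
        b = float(
            _ad.value(
                loss_multi(
                    {"r": 4.0, "gamma": 1.0},
                    [kons[i] for i in perm],
                    [tgts[i] for i in perm],
                    FAST,
                    seed=1,
                )
            )
        )
        assert a == pytest.approx(b, rel=1e-12)

    def test_truth_beats_perturbed_shared_rate(self):
        """On multi-condition synthetic data the generating (r, gamma) score
        better than r perturbed 3x, with matched seeds."""
        ds = generate_synthetic(n_sets=1, conditions=5, seed=3, n_traj=800)
        ps = ds.true_params[0]
        tgts = ds.targets[0]
        kons = [p.kon_r for p in ps]
        shared = {"r": ps[0].r, "gamma": ps[0].gamma}
        cfg = SimSettings(T=10.0, config=DGAConfig(n_traj=600))
        l_true = float(_ad.value(loss_multi(shared, kons, tgts, cfg, seed=11)))
        l_bad = float(
            _ad.value(
                loss_multi(dict(shared, r=3 * shared["r"]), kons, tgts, cfg, seed=11)
            )
        )
        assert l_true < l_bad


class TestFit:
    def test_convex_quadratic_converges(self):
        def lag(theta, free, seed):
            th = theta["x"]
            L = (th - 2.0) ** 2
            return L, {"x": 2 * (th - 2.0) * th}  # log-space gradient

        res = fit(lag, {"x": 10.0}, ["x"], n_iter=400, lr=0.05, seed=0, average_tail=0.1)
        assert res.theta_hat["x"] == pytest.approx(2.0, abs=1e-2)
        assert res.loss_trace[-1] <= res.loss_trace[0]

    def test_divergence_aborts_with_trace(self):
        calls = {"n": 0}

        def lag(theta, free, seed):
            calls["n"] += 1
            return float(calls["n"]), {"x": 0.0}  # strictly increasing loss

        with pytest.raises(DivergenceError) as err:
            fit(lag, {"x": 1.0}, ["x"], n_iter=200, seed=0)
        assert len(err.value.trace) >= 50

    def test_positivity_preserved_in_log_space(self):
        def lag(theta, free, seed):
            th = theta["x"]
            return th, {"x": th}  # push x down hard

        res = fit(lag, {"x": 1.0}, ["x"], n_iter=100, lr=0.2, seed=0)
        assert res.theta_hat["x"] > 0


class TestGradientFidelity:
    def test_loss_gradient_is_exact_derivative_of_fixed_noise_loss(self, two_state_net, x0):
        """Raw pathwise gradient vs frozen-step matched-seed central FD."""
        from diffgillespie.promoters import TwoStateParams

        p = TwoStateParams(kon_r=0.7, r=4.0, gamma=1.3)
        tg = MomentTargets.from_mean_fano(*two_state_mean_fano(p))
        st = SimSettings(T=10.0, config=DGAConfig(n_traj=500))
        theta = {"kon_r": 1.2, "koff_r": 1.0, "r": 3.0, "gamma": 1.0}
        base = simulate_dga(two_state_net, x0, theta, st.T, st.smoothing, st.config, 42)
        fro = base.step_counts
        dual = _ad.seed_duals(theta, ["kon_r", "r", "gamma"], log_space=True)
        out = loss_single(dual, tg, st, 42, frozen_steps=fro)
        for j, name in enumerate(["kon_r", "r", "gamma"]):
            h = 1e-8 * theta[name]
            tp, tm = dict(theta), dict(theta)
            tp[name] += h
            tm[name] -= h
            Lp = float(_ad.value(loss_single(tp, tg, st, 42, frozen_steps=fro)))
            Lm = float(_ad.value(loss_single(tm, tg, st, 42, frozen_steps=fro)))
            fd = (Lp - Lm) / (2 * h) * theta[name]
            assert out.tan[j] == pytest.approx(fd, rel=1e-2)


class TestConfidenceInterval:
    def test_quadratic_loss_as_printed(self):
        """L=(th-2)^2: curvature 2, delta = 1/2, CI = [1.5, 2.98]."""
        ci = confidence_interval(lambda t, s: (t["x"] - 2.0) ** 2, {"x": 2.0}, "x")
        assert ci.delta == pytest.approx(0.5, rel=1e-6)
        assert ci.lo == pytest.approx(1.5, rel=1e-6)
        assert ci.hi == pytest.approx(2.0 + 1.96 * 0.5, rel=1e-6)

    def test_flatter_loss_widens_interval(self):
        ci = confidence_interval(lambda t, s: 0.01 * (t["x"] - 2.0) ** 2, {"x": 2.0}, "x")
        assert ci.delta == pytest.approx(50.0, rel=1e-4)

    def test_negative_curvature_is_unbounded(self):
        ci = confidence_interval(lambda t, s: -((t["x"] - 2.0) ** 2), {"x": 2.0}, "x")
        assert not ci.bounded
        assert ci.lo == -np.inf and ci.hi == np.inf

    def test_standard_halfwidth(self):
        ci = ConfidenceInterval(0, 0, delta=0.5, curvature=2.0)
        assert standard_halfwidth(ci) == pytest.approx(1.96)


class TestLandscape:
    def test_quadratic_surface_minimum(self):
        def loss(t, s):
            return (t["x"] - 1.0) ** 2 + (t["y"] - 2.0) ** 2

        xs, ys, L = landscape(
            loss, {"x": 1.0, "y": 2.0}, ("x", "y"),
            {"x": np.linspace(0, 2, 11), "y": np.linspace(1, 3, 11)},
        )
        i, j = np.unravel_index(L.argmin(), L.shape)
        assert xs[i] == pytest.approx(1.0)
        assert ys[j] == pytest.approx(2.0)

    def test_single_cell_grid(self):
        def loss(t, s):
            return t["x"] + t["y"]

        xs, ys, L = landscape(loss, {"x": 1.0, "y": 2.0}, ("x", "y"), {"x": [1.0], "y": [2.0]})
        assert L.shape == (1, 1)
        assert L[0, 0] == pytest.approx(3.0)


class TestGenerateSynthetic:
    def test_draws_in_range_and_deterministic(self):
        a = generate_synthetic(n_sets=3, seed=5, n_traj=200)
        b = generate_synthetic(n_sets=3, seed=5, n_traj=200)
        for p, q in zip(a.true_params, b.true_params):
            assert p == q
            for v in (p.kon_r, p.r, p.gamma):
                assert 0.1 <= v <= 10.0
            assert p.koff_r == 1.0
        for t, u in zip(a.targets, b.targets):
            assert t.mean == u.mean and t.std == u.std

    def test_targets_match_closed_form(self):
        ds = generate_synthetic(n_sets=4, seed=2, n_traj=1500)
        for p, tg in zip(ds.true_params, ds.targets):
            mean, fano = two_state_mean_fano(p)
            se = tg.std / np.sqrt(1500)
            assert abs(tg.mean - mean) < 5 * se
            assert tg.std == pytest.approx(np.sqrt(fano * mean), rel=0.2)

    def test_multi_condition_shares_r_gamma(self):
        ds = generate_synthetic(n_sets=2, conditions=3, seed=1, n_traj=100)
        for ps in ds.true_params:
            assert len({p.r for p in ps}) == 1
            assert len({p.gamma for p in ps}) == 1
            assert len({p.kon_r for p in ps}) == 3

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            generate_synthetic(low=5.0, high=1.0)
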