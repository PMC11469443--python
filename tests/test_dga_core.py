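"""Smoothed stepper: closed-form examples, exact-limit equivalence, gradient
contracts, and batch invariants."""

import numpy as np
import pytest
from scipy.special import expit

from diffgillespie import _ad
from diffgillespie.dga_core import (
    DGAConfig,
    SmoothingParams,
    dga_step,
    gradient_of,
    simulate_dga,
    soft_index,
    soft_stoich_weights,
    waiting_time,
)
from diffgillespie.exact_ssa import ensemble_final_states, step_exact
from diffgillespie.network import RateLaw, ReactionNetwork

FIG_PARAMS = {"kon_r": 0.5, "koff_r": 1.0, "r": 10.0, "gamma": 1.0}
DEFAULTS = SmoothingParams()  # 1/a=200, 1/b=20


def birth_network():
    return ReactionNetwork(
        species_names=("x",),
        stoichiometry=np.array([[1]]),
        rate_laws=(RateLaw("constant", "k"),),
    )


class TestWaitingTime:
    def test_log_one_is_zero(self):
        assert waiting_time(3.0, 1.0) == 0.0

    def test_known_value(self):
        assert waiting_time(2.0, np.exp(-2.0)) == pytest.approx(1.0)

    def test_invalid_draw_rejected(self):
        with pytest.raises(ValueError):
            waiting_time(2.0, 0.0)

    def test_derivative_in_R_matches_finite_difference(self):
        R0, u = 2.0, np.exp(-2.0)
        d = _ad.Dual(np.array(R0), np.array([1.0]))
        tau = waiting_time(d, u)
        h = 1e-4
        fd = (waiting_time(R0 + h, u) - waiting_time(R0 - h, u)) / (2 * h)
        assert tau.tan[0] == pytest.approx(fd, rel=1e-6)
        # analytic: d tau / dR = ln(u)/R^2
        assert tau.tan[0] == pytest.approx(np.log(u) / R0**2, rel=1e-9)


class TestSoftIndex:
    def test_interior_draw_recovers_integer_index(self):
        # q = (0.2, 0.5); u'=0.35 sits 30 sigmoid widths from both boundaries
        i = soft_index(np.array([2.0, 3.0, 5.0]), 0.35, DEFAULTS.a)
        expected = 1.0 + expit(30.0) + expit(-30.0)
        assert i == pytest.approx(expected, abs=1e-12)
        assert i == pytest.approx(2.0, abs=1e-6)

    def test_draw_on_boundary_contributes_half(self):
        i = soft_index(np.array([2.0, 3.0, 5.0]), 0.2, DEFAULTS.a)
        assert i == pytest.approx(1.5 + expit((0.2 - 0.5) / DEFAULTS.a), abs=1e-9)

    def test_heaviside_limit(self):
        i = soft_index(np.array([2.0, 3.0, 5.0]), 0.35, 1e-9)
        assert i == pytest.approx(2.0, abs=1e-12)

    def test_range_is_open_interval(self, rng):
        r = rng.uniform(0.1, 5.0, size=(50, 4))
        up = rng.random(50)
        i = soft_index(r, up, DEFAULTS.a)
        assert ((i > 1.0 - 1e-12) & (i < 4.0 + 1e-12)).all()


class TestSoftStoichWeights:
    def test_integer_index_is_nearly_one_hot(self):
        w = soft_stoich_weights(2.0, 3, DEFAULTS.b)
        np.testing.assert_allclose(w, [np.exp(-20.0), 1.0, np.exp(-20.0)])

    def test_kronecker_limit(self):
        w = soft_stoich_weights(2.0, 3, 1e-9)
        np.testing.assert_allclose(w, [0.0, 1.0, 0.0], atol=1e-300)

    def test_half_index_is_symmetric(self):
        w = soft_stoich_weights(1.5, 3, 0.37)
        assert w[0] == pytest.approx(w[1])


class TestStepLimitEquivalence:
    def test_step_matches_exact_for_off_boundary_draws(self, two_state_net, rng):
        """With draws > 10a from every cumulative fraction, the smoothed step
        must reproduce the exact one to tight tolerances at defaults."""
        state = np.array([1.0, 0.0, 3.0])
        checked = 0
        for _ in range(200):
            u, up = 1 - rng.random(), rng.random()
            r = np.array([0.5, 0.0, 10.0, 3.0])
            q = np.cumsum(r) / r.sum()
            if np.min(np.abs(up - q[:-1])) < 10 * DEFAULTS.a:
                continue
            sx, st, si = step_exact(two_state_net, state.astype(int), 0.0, FIG_PARAMS, u, up)
            dx, dt, di, _ = dga_step(
                two_state_net, state[None, :], 0.0, FIG_PARAMS, DEFAULTS,
                np.array([u]), np.array([up]),
            )
            assert abs(float(di[0]) - si) < 1e-4
            np.testing.assert_allclose(dx[0], sx, atol=1e-3)
            assert dt[0] == pytest.approx(st)
            checked += 1
        assert checked > 150

    def test_single_step_gradient_matches_finite_difference(self, two_state_net):
        """d(m after one step)/dr via duals vs central differences."""
        up, u = 0.97, 0.3  # transcription region
        params = dict(FIG_PARAMS)

        def m_after(rv):
            p = dict(params, r=rv)
            x, *_ = dga_step(
                two_state_net, np.array([[1.0, 0.0, 0.0]]), 0.0, p, DEFAULTS,
                np.array([u]), np.array([up]),
            )
            return float(_ad.value(x)[0, 2])

        d = _ad.seed_duals(params, ["r"])
        x, *_ = dga_step(
            two_state_net, _ad.Dual(np.array([[1.0, 0.0, 0.0]]), np.zeros((1, 3, 1))),
            0.0, d, DEFAULTS, np.array([u]), np.array([up]),
        )
        ad = x.tan[0, 2, 0]
        h = 1e-5
        fd = (m_after(10.0 + h) - m_after(10.0 - h)) / (2 * h)
        assert ad == pytest.approx(fd, rel=1e-3, abs=1e-9)


class TestSimulateDGA:
    def test_rerun_is_bit_identical(self, two_state_net, x0):
        kw = dict(config=DGAConfig(n_traj=100), seed=9)
        a = simulate_dga(two_state_net, x0, FIG_PARAMS, 30.0, **kw)
        b = simulate_dga(two_state_net, x0, FIG_PARAMS, 30.0, **kw)
        np.testing.assert_array_equal(a.final_states, b.final_states)
        np.testing.assert_array_equal(a.occupancy, b.occupancy)
        np.testing.assert_array_equal(a.step_counts, b.step_counts)

    def test_occupancy_rows_normalized(self, two_state_net, x0):
        b = simulate_dga(
            two_state_net, x0, FIG_PARAMS, 50.0, config=DGAConfig(n_traj=200), seed=3
        )
        np.testing.assert_allclose(_ad.value(b.occupancy).sum(axis=1), 1.0, atol=1e-6)

    def test_elapsed_times_cover_horizon(self, two_state_net, x0):
        b = simulate_dga(
            two_state_net, x0, FIG_PARAMS, 25.0, config=DGAConfig(n_traj=64), seed=4
        )
        assert (_ad.value(b.elapsed_times) >= 25.0).all()

    def test_indicator_mass_is_conserved(self, two_state_net, x0):
        b = simulate_dga(
            two_state_net, x0, FIG_PARAMS, 100.0, config=DGAConfig(n_traj=64), seed=5
        )
        gene = _ad.value(b.final_states)[:, :2].sum(axis=1)
        np.testing.assert_allclose(gene, 1.0, atol=1e-9)

    def test_birth_process_mean_tracks_exact(self, x0):
        """Constant-rate birth: the smoothed final count matches k*T up to the
        one-event overshoot convention (the final step is applied)."""
        net = birth_network()
        k, T, n = 2.0, 50.0, 400
        b = simulate_dga(net, [0.0], {"k": k}, T, config=DGAConfig(n_traj=n), seed=8)
        mean_dga = float(_ad.value(b.final_states)[:, 0].mean())
        fs = ensemble_final_states(net, [0], {"k": k}, T, n, seed=9)
        se = np.sqrt(k * T / n)
        # exact ensemble discards the overshoot event; the smoothed one keeps it
        assert abs(mean_dga - 1.0 - fs[:, 0].mean()) < 4 * np.sqrt(2) * se

    def test_max_steps_overrun_warns(self, two_state_net, x0):
        with pytest.warns(RuntimeWarning, match="max_steps"):
            simulate_dga(
                two_state_net, x0, FIG_PARAMS, 1e4,
                config=DGAConfig(n_traj=16, max_steps=50), seed=2,
            )

    def test_frozen_steps_reproduce_base_run(self, two_state_net, x0):
        base = simulate_dga(
            two_state_net, x0, FIG_PARAMS, 10.0, config=DGAConfig(n_traj=64), seed=12
        )
        again = simulate_dga(
            two_state_net, x0, FIG_PARAMS, 10.0, config=DGAConfig(n_traj=64), seed=12,
            frozen_steps=base.step_counts,
        )
        np.testing.assert_allclose(
            _ad.value(base.final_states), _ad.value(again.final_states)
        )


class TestGradientOf:
    def test_unreferenced_parameter_has_zero_gradient(self, two_state_net, x0):
        params = dict(FIG_PARAMS, unused=3.0)
        _, g = gradient_of(
            lambda b: _ad.amean(b.final_states[(slice(None), 2)]),
            two_state_net, x0, params, ["unused"], T=5.0,
            config=DGAConfig(n_traj=32), seed=0,
        )
        assert g["unused"] == 0.0

    def test_batch_loss_gradient_matches_frozen_step_fd(self, two_state_net, x0):
        """The pathwise gradient is the exact derivative of the fixed-noise
        loss: frozen event counts, matched seeds, tiny step."""
        theta = {"kon_r": 1.2, "koff_r": 1.0, "r": 3.0, "gamma": 1.0}
        cfg = DGAConfig(n_traj=400)
        base = simulate_dga(two_state_net, x0, theta, 10.0, DEFAULTS, cfg, seed=42)
        fro = base.step_counts

        def mean_m(th):
            b = simulate_dga(
                two_state_net, x0, th, 10.0, DEFAULTS, cfg, seed=42, frozen_steps=fro
            )
            return float(_ad.value(b.final_states)[:, 2].mean())

        dual = _ad.seed_duals(theta, ["r"])
        b = simulate_dga(
            two_state_net, x0, dual, 10.0, DEFAULTS, cfg, seed=42, frozen_steps=fro
        )
        ad = float(b.final_states.tan[:, 2, 0].mean())
        h = 1e-8 * theta["r"]
        fd = (mean_m(dict(theta, r=theta["r"] + h)) - mean_m(dict(theta, r=theta["r"] - h))) / (2 * h)
        assert ad == pytest.approx(fd, rel=1e-4)
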