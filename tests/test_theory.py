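"""Transfer-operator density, averaging and fixed-point analysis."""

import numpy as np
import pytest

from stochsync.phase_core import TWO_PI, KickGain, PhaseDensity, PRCSpec
from stochsync.reduced import GFunctional, GMode
from stochsync.theory import (
    AveragedDynamics,
    averaged_G,
    averaged_rhs,
    find_fixed_points,
    l1_distance,
    lambda_from_q,
    mc_stationary_density,
    order_parameter_of_density,
    q_from_lambda,
    stationary_density,
    transfer_operator,
)


class TestTransferOperator:
    def test_columns_are_stochastic(self, sin_prc, default_gain):
        for q in (0.0, 0.3, 0.8):
            P = transfer_operator(q, sin_prc, default_gain, n_grid=128)
            assert np.allclose(P.sum(axis=0), 1.0, atol=1e-12)
            assert np.all(P >= 0)

    def test_q_zero_density_is_uniform(self, sin_prc, default_gain):
        d = stationary_density(0.0, sin_prc, default_gain)
        assert np.max(np.abs(d.rho - 1 / TWO_PI)) < 1e-8

    def test_density_is_normalized_and_even(self, sin_prc, default_gain):
        d = stationary_density(0.5, sin_prc, default_gain)
        assert d.integral() == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(d.rho, d.rho[::-1], atol=1e-9)  # even in phi

    def test_more_common_input_gives_more_synchrony(self, sin_prc, small_gain):
        m_low = order_parameter_of_density(
            stationary_density(0.3, sin_prc, small_gain)
        )
        m_high = order_parameter_of_density(
            stationary_density(0.9, sin_prc, small_gain)
        )
        assert m_high > m_low

    def test_density_matches_monte_carlo_map(self, sin_prc, default_gain):
        d_op = stationary_density(0.5, sin_prc, default_gain)
        d_mc = mc_stationary_density(
            0.5, sin_prc, default_gain, n_events=400_000, seed=4
        )
        assert l1_distance(d_op, d_mc) < 0.05

    def test_invalid_inputs_rejected(self, sin_prc, default_gain):
        with pytest.raises(ValueError):
            stationary_density(1.0, sin_prc, default_gain)
        with pytest.raises(ValueError):
            stationary_density(0.5, sin_prc, default_gain, n_grid=32)


class TestOrderParameterOfDensity:
    def test_uniform_density_gives_zero(self):
        n = 128
        grid = -np.pi + (np.arange(n) + 0.5) * TWO_PI / n
        rho = PhaseDensity(grid, np.full(n, 1 / TWO_PI))
        assert order_parameter_of_density(rho) == pytest.approx(0.0, abs=1e-12)

    def test_concentrating_density_approaches_one(self):
        n = 256
        grid = -np.pi + (np.arange(n) + 0.5) * TWO_PI / n
        width = TWO_PI / n
        last = 0.0
        for kappa in (2.0, 10.0, 50.0):
            vals = np.exp(kappa * (np.cos(grid) - 1))
            rho = PhaseDensity(grid, vals / (vals.sum() * width))
            m = order_parameter_of_density(rho)
            assert m > last
            last = m
        assert last > 0.98

    def test_unnormalized_density_rejected(self):
        n = 64
        grid = -np.pi + (np.arange(n) + 0.5) * TWO_PI / n
        with pytest.raises(ValueError, match="normalized"):
            order_parameter_of_density(PhaseDensity(grid, np.ones(n)))

    def test_m_of_q_nondecreasing_and_linear_at_small_q(self, sin_prc, small_gain):
        qs = np.linspace(0.0, 0.9, 10)
        ms = [
            order_parameter_of_density(stationary_density(q, sin_prc, small_gain))
            for q in qs
        ]
        assert np.all(np.diff(ms) > 0)
        qs_small = np.linspace(0.0, 0.05, 6)
        ms_small = np.array(
            [
                order_parameter_of_density(stationary_density(q, sin_prc, small_gain))
                for q in qs_small
            ]
        )
        coef = np.polyfit(qs_small, ms_small, 1)
        resid = ms_small - np.polyval(coef, qs_small)
        r2 = 1 - resid @ resid / np.sum((ms_small - ms_small.mean()) ** 2)
        assert r2 > 0.99


class TestAveragedG:
    def test_constant_functional_averages_to_itself(self):
        # direct G with kappa=0 is constant = amplitude
        gf = GFunctional(GMode.DIRECT, amplitude=3.3, kappa=0.0)
        d = stationary_density(0.4)
        assert averaged_G(gf, d) == pytest.approx(3.3, abs=1e-10)

    def test_direct_average_at_q0_matches_quadrature_oracle(self, sin_prc):
        gf = GFunctional(GMode.DIRECT, amplitude=7.0, kappa=5.0)
        d = stationary_density(0.0, sin_prc, KickGain(0.3))
        # quadrature on the same grid: uniform density 1/(2pi)
        oracle = np.sum(gf.direct_value(d.grid) / TWO_PI) * d.bin_width
        assert averaged_G(gf, d) == pytest.approx(oracle, abs=1e-10)

    def test_order_mode_vanishes_at_q0(self):
        gf = GFunctional(GMode.ORDER_PARAMETER, amplitude=50.0, p=2.0)
        d = stationary_density(0.0)
        assert averaged_G(gf, d) == pytest.approx(0.0, abs=1e-12)

    def test_bounded_by_amplitude(self):
        gf = GFunctional(GMode.DIRECT, amplitude=5.0, kappa=3.0)
        for q in (0.0, 0.5, 0.9):
            val = averaged_G(gf, stationary_density(q))
            assert 0 <= val <= 5.0 + 1e-12


class TestQLambdaMaps:
    def test_equal_rates_give_half(self):
        assert q_from_lambda(30.0, 15.0, 15.0) == pytest.approx(0.5)

    def test_round_trip_identity(self, rng):
        for _ in range(200):
            lam = rng.uniform(0, 100)
            l1, l2 = rng.uniform(0.1, 30, 2)
            q = q_from_lambda(lam, l1, l2)
            assert lambda_from_q(q, l1, l2) == pytest.approx(lam, abs=1e-9)

    def test_q_one_asymptote_rejected(self):
        with pytest.raises(ValueError):
            lambda_from_q(1.0, 5.0, 5.0)


class TestFixedPoints:
    def test_zero_feedback_gives_unique_point_at_lam_min(self):
        params = AveragedDynamics(
            g_func=GFunctional(GMode.DIRECT, amplitude=0.0), lam_min=2.0
        )
        fps = find_fixed_points(params)
        assert len(fps) == 1
        assert fps.stable[0].lam == pytest.approx(2.0, abs=1e-5)

    def test_direct_feedback_always_single_stable_point(self):
        # the paper's monostability property of the instantaneous functional
        for amp in (5.0, 20.0, 80.0, 200.0):
            params = AveragedDynamics(
                g_func=GFunctional(GMode.DIRECT, amplitude=amp)
            )
            fps = find_fixed_points(params)
            assert len(fps) == 1
            assert fps.points[0].stable

    def test_order_parameter_feedback_is_bistable_at_shipped_amplitude(self):
        params = AveragedDynamics(
            g_func=GFunctional(GMode.ORDER_PARAMETER, amplitude=80.0, p=2.0),
            lam1=5.0,
            lam2=5.0,
            lam_min=0.3,
            gain=KickGain(0.5),
        )
        fps = find_fixed_points(params)
        assert len(fps) == 3
        stability = [p.stable for p in fps.points]
        assert stability == [True, False, True]

    def test_root_count_odd_with_alternating_stability(self):
        for amp, mode in [(20.0, GMode.DIRECT), (80.0, GMode.ORDER_PARAMETER)]:
            params = AveragedDynamics(
                g_func=GFunctional(mode, amplitude=amp, p=2.0),
                lam1=5.0,
                lam2=5.0,
                lam_min=0.3,
                gain=KickGain(0.5),
            )
            fps = find_fixed_points(params)
            assert len(fps) % 2 == 1
            flags = [p.stable for p in fps.points]
            assert flags == [i % 2 == 0 for i in range(len(flags))]
            assert flags[0] is True

    def test_rhs_sign_changes_bracket_roots(self):
        params = AveragedDynamics(g_func=GFunctional(GMode.DIRECT, amplitude=20.0))
        fps = find_fixed_points(params)
        for p in fps.points:
            lo = averaged_rhs(max(p.q - 1e-3, 1e-6), params)
            hi = averaged_rhs(min(p.q + 1e-3, 0.999), params)
            assert lo * hi < 0

    def test_averaged_map_shapes(self):
        # direct-mode <G>(q) rises from its uniform-density baseline and
        # saturates toward the peak value as the density approaches a delta
        # at zero; order-mode <G>(q) starts quadratically
        qs = np.linspace(0.0, 0.9, 12)
        direct = AveragedDynamics(g_func=GFunctional(GMode.DIRECT, amplitude=1.0))
        vals = np.array([direct.averaged_G(q) for q in qs])
        assert np.all(np.diff(vals) > 0)  # increasing
        assert vals[0] == pytest.approx(np.exp(-5) * np.i0(5), rel=1e-6)
        assert direct.averaged_G(0.995) > 0.8  # delta limit -> peak value
        order = AveragedDynamics(
            g_func=GFunctional(GMode.ORDER_PARAMETER, amplitude=1.0, p=2.0)
        )
        small_q = np.array([0.01, 0.02, 0.04])
        g_small = np.array([order.averaged_G(q) for q in small_q])
        ratio = g_small[2] / g_small[0]
        assert ratio == pytest.approx(16.0, rel=0.25)  # ~ q^2 scaling
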