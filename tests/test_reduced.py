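"""Event-driven reduced map: Gillespie selection, phase map, feedback."""

import numpy as np
import pytest

from stochsync.phase_core import TWO_PI, KickGain, PRCSpec
from stochsync.reduced import (
    EventKind,
    GFunctional,
    GMode,
    MapState,
    ReducedConfig,
    _OrderParamWindow,
    evaluate_G,
    map_step,
    relax_lambda,
    run_reduced,
    sample_interval,
    select_event,
)
from stochsync.theory import l1_distance, stationary_density
from stochsync.phase_core import phase_difference_histogram


class TestSampleInterval:
    def test_mean_matches_exponential(self, rng):
        draws = np.array([sample_interval(2.0, rng) for _ in range(100_000)])
        se = 0.5 / np.sqrt(len(draws))
        assert abs(draws.mean() - 0.5) < 4 * se
        assert np.all(draws > 0)

    def test_doubling_rate_halves_mean(self, rng):
        d1 = np.array([sample_interval(1.0, rng) for _ in range(50_000)])
        d2 = np.array([sample_interval(2.0, rng) for _ in range(50_000)])
        assert d1.mean() / d2.mean() == pytest.approx(2.0, rel=0.05)

    def test_nonpositive_rate_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_interval(0.0, rng)


class TestSelectEvent:
    def test_equal_split_probability(self, rng):
        kinds = [select_event(1.0, 0.5, 0.5, rng) for _ in range(20_000)]
        shared = sum(k is EventKind.SHARED for k in kinds)
        # P(shared) = 1/2; binomial 4 sigma band
        assert abs(shared - 10_000) < 4 * np.sqrt(20_000 * 0.25)

    def test_zero_shared_rate_never_selects_shared(self, rng):
        assert all(
            select_event(0.0, 1.0, 1.0, rng) is not EventKind.SHARED
            for _ in range(2000
            )
        )

    def test_multinomial_frequencies_within_4_sigma(self, rng):
        lam, lam1, lam2 = 3.0, 1.0, 2.0
        total = lam + lam1 + lam2
        n = 100_000
        counts = {"shared": 0, "indep1": 0, "indep2": 0}
        for _ in range(n):
            counts[select_event(lam, lam1, lam2, rng).kind] += 1
        for key, rate in [("shared", lam), ("indep1", lam1), ("indep2", lam2)]:
            p = rate / total
            assert abs(counts[key] - n * p) < 4 * np.sqrt(n * p * (1 - p))

    def test_all_zero_rates_rejected(self, rng):
        with pytest.raises(ValueError):
            select_event(0.0, 0.0, 0.0, rng)


class TestMapStep:
    def test_full_period_drift_without_kick_is_identity(self, sin_prc):
        st = MapState(1.0, 2.5, 5.0)
        ev = EventKind("none", 0, 0)
        omega = TWO_PI * 40
        out = map_step(st, 1 / 40.0, ev, sin_prc, KickGain(0.3), omega=omega)
        assert out.theta1 == pytest.approx(1.0, abs=1e-9)
        assert out.theta2 == pytest.approx(2.5, abs=1e-9)

    def test_shared_kick_preserves_synchrony(self, sin_prc, rng):
        th = rng.uniform(0, TWO_PI)
        st = MapState(th, th, 5.0)
        out = map_step(st, 0.013, EventKind.SHARED, sin_prc, KickGain(0.7))
        assert out.theta1 == pytest.approx(out.theta2, abs=1e-12)

    def test_independent_kick_leaves_other_oscillator_drifting_only(self, sin_prc):
        st = MapState(0.3, 1.1, 5.0)
        omega = TWO_PI * 40
        dt = 0.004
        out = map_step(st, dt, EventKind.INDEP1, sin_prc, KickGain(0.5), omega=omega)
        assert out.theta2 == pytest.approx((1.1 + omega * dt) % TWO_PI, abs=1e-12)
        assert out.theta1 != pytest.approx((0.3 + omega * dt) % TWO_PI, abs=1e-9)


class TestEvaluateG:
    def test_direct_peak_at_zero_is_amplitude(self):
        gf = GFunctional(GMode.DIRECT, amplitude=13.0, kappa=5.0)
        assert evaluate_G(gf, phi=0.0) == pytest.approx(13.0)
        assert evaluate_G(gf, phi=np.pi) == pytest.approx(13.0 * np.exp(-10.0))

    def test_direct_is_even_in_phi(self):
        gf = GFunctional(GMode.DIRECT, amplitude=2.0)
        for phi in (0.3, 1.2, 2.9):
            assert evaluate_G(gf, phi=phi) == evaluate_G(gf, phi=-phi)

    def test_order_parameter_with_coherent_window(self):
        gf = GFunctional(GMode.ORDER_PARAMETER, amplitude=10.0, p=2.0, tau_avg=1.0)
        win = _OrderParamWindow(1.0)
        for _ in range(2000):
            win.push(0.0, 0.05)
        assert evaluate_G(gf, window=win) == pytest.approx(10.0, rel=1e-6)

    def test_order_parameter_with_dispersed_window(self):
        gf = GFunctional(GMode.ORDER_PARAMETER, amplitude=10.0, p=2.0, tau_avg=1.0)
        win = _OrderParamWindow(1.0)
        for phi in np.tile(np.arange(8) * TWO_PI / 8, 400):
            win.push(phi, 0.01)
        assert evaluate_G(gf, window=win) < 0.05

    def test_empty_window_warns_and_returns_zero(self):
        gf = GFunctional(GMode.ORDER_PARAMETER, amplitude=10.0)
        with pytest.warns(UserWarning, match="empty window"):
            assert evaluate_G(gf, window=_OrderParamWindow(1.0)) == 0.0


class TestRelaxLambda:
    def test_fixed_point_at_lam_min_with_zero_G(self):
        assert relax_lambda(0.5, 0.0, 3.0, 1.0, 0.5) == pytest.approx(0.5)

    def test_long_time_limit_is_lam_min_plus_G(self):
        assert relax_lambda(10.0, 7.0, 1e6, 1.0, 0.5) == pytest.approx(7.5)

    def test_exact_update_matches_euler_oracle(self):
        lam, g_val, tau, lam_min = 3.0, 4.0, 2.0, 0.5
        dt = tau / 10_000
        n = 100
        lam_euler = lam
        for _ in range(n):
            lam_euler += dt * (lam_min + g_val - lam_euler) / tau
        exact = relax_lambda(lam, g_val, n * dt, tau, lam_min)
        assert abs(exact - lam_euler) < 1e-6

    def test_clipping_at_lam_max(self):
        assert relax_lambda(1.0, 100.0, 50.0, 1.0, 0.5, lam_max=20.0) == 20.0


class TestRunReduced:
    def test_seed_determinism_bit_identical(self):
        cfg = ReducedConfig()
        init = MapState(0.5, 1.5, 2.0)
        a = run_reduced(cfg, 5000, 77, initial=init)
        b = run_reduced(cfg, 5000, 77, initial=init)
        assert np.array_equal(a.phi, b.phi)
        assert np.array_equal(a.lam, b.lam)
        assert np.array_equal(a.t, b.t)

    def test_lambda_stays_within_feedback_band(self):
        cfg = ReducedConfig(g_func=GFunctional(GMode.DIRECT, amplitude=30.0))
        tr = run_reduced(cfg, 50_000, 3)
        assert np.all(tr.lam >= cfg.lam_min - 1e-12)
        assert np.all(tr.lam <= cfg.lam_min + 30.0 + 1e-9)

    def test_shared_kicks_only_preserve_synchrony_forever(self):
        # lam1 = lam2 = 0: every event is shared; phi stays exactly 0
        cfg = ReducedConfig(lam1=0.0, lam2=0.0, gain=KickGain(0.8))
        tr = run_reduced(cfg, 20_000, 5, initial=MapState(1.0, 1.0, 2.0))
        assert np.max(np.abs(tr.phi)) == 0.0

    def test_frozen_lambda_histogram_matches_stationary_density(self):
        # amplitude 0 freezes lambda at lam_min; q = lam_min/(lam_min+lam1+lam2)
        cfg = ReducedConfig(
            lam1=5.0,
            lam2=5.0,
            lam_min=10.0,
            g_func=GFunctional(GMode.DIRECT, amplitude=0.0),
        )
        q = 10.0 / 20.0
        tr = run_reduced(cfg, 1_000_000, 9)
        hist = phase_difference_histogram(tr.phi[5000:], 256)
        rho = stationary_density(q, cfg.prc, cfg.gain, n_grid=256)
        assert l1_distance(hist, rho) < 0.05

    def test_time_rescaling_invariance(self):
        # multiplying all rates (and the feedback amplitude) by c and dividing
        # all time constants by c rescales the same realization exactly;
        # c = 8 is a power of two so the rescaling is bitwise on floats
        c = 8.0
        base = ReducedConfig(
            lam1=5.0, lam2=5.0, lam_min=1.0, lam_max=100.0, tau_lam=2.0,
            g_func=GFunctional(GMode.DIRECT, amplitude=8.0, kappa=5.0),
        )
        scaled = ReducedConfig(
            lam1=5.0 * c, lam2=5.0 * c, lam_min=1.0 * c, lam_max=100.0 * c,
            tau_lam=2.0 / c,
            g_func=GFunctional(GMode.DIRECT, amplitude=8.0 * c, kappa=5.0),
            omega=base.omega * c,
        )
        init1 = MapState(0.7, 2.0, 3.0)
        init2 = MapState(0.7, 2.0, 3.0 * c)
        tr1 = run_reduced(base, 20_000, 21, initial=init1)
        tr2 = run_reduced(scaled, 20_000, 21, initial=init2)
        assert np.allclose(tr1.phi, tr2.phi, atol=1e-9)
        assert np.allclose(tr2.lam, c * tr1.lam, rtol=1e-9)
        assert np.allclose(tr2.t, tr1.t / c, rtol=1e-9)
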