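"""Closed-loop spiking network: LIF, synapses, kick streams, bookkeeping."""

import numpy as np
import pytest

from stochsync.phase_core import KickGain
from stochsync.spiking import (
    IndependentRates,
    LIFParams,
    SharedRateState,
    SpikingConfig,
    SynapseState,
    Topology,
    decay_and_jump_synapse,
    draw_kick_events,
    granule_rate_vs_phase,
    integrate_lif,
    run_spiking,
    update_shared_rate,
)


class TestLIF:
    def test_leak_only_decays_monotonically_without_spikes(self):
        p = LIFParams(sigma=0.0)
        v, spikes = integrate_lif(p, np.zeros(5000), 1e-4, 0, v0=0.5)
        assert len(spikes) == 0
        assert np.all(np.diff(v) < 0)
        assert v[-1] < 0.01

    def test_suprathreshold_period_matches_closed_form(self):
        # with constant drive I > threshold: T = tau_m * ln(I/(I-1))
        p = LIFParams(sigma=0.0, bias=2.0, tau_m=0.01)
        dt = 1e-6
        v, spikes = integrate_lif(p, np.zeros(int(0.2 / dt)), dt, 0)
        isis = np.diff(spikes)
        expected = p.tau_m * np.log(2.0 / (2.0 - 1.0))
        assert np.mean(isis) == pytest.approx(expected, rel=0.01)

    def test_firing_rate_nondecreasing_in_noise(self):
        rates = []
        for sigma in (0.5, 1.5, 3.0):
            total = 0
            for seed in range(10):
                p = LIFParams(sigma=sigma, bias=0.8)
                _, spikes = integrate_lif(p, np.zeros(20_000), 1e-4, seed)
                total += len(spikes)
            rates.append(total)
        assert rates[0] <= rates[1] <= rates[2]

    def test_nan_drive_aborts(self):
        with pytest.raises(ValueError, match="NaN|inf"):
            integrate_lif(LIFParams(), np.array([0.0, np.nan]), 1e-4, 0)

    def test_coarse_dt_warns(self):
        with pytest.warns(UserWarning, match="coarse"):
            integrate_lif(LIFParams(tau_m=0.01), np.zeros(10), 0.005, 0)


class TestSynapse:
    def test_exponential_decay_over_one_time_constant(self):
        s = SynapseState(s=1.0, tau_s=0.005)
        out = decay_and_jump_synapse(s, 0.005, 0, KickGain(1.0))
        assert out.s == pytest.approx(np.exp(-1), abs=1e-12)

    def test_jump_scaled_by_coupling(self):
        s = SynapseState(s=0.0, tau_s=0.005)
        assert decay_and_jump_synapse(s, 0.0, 1, 2.0).s == pytest.approx(2.0)

    def test_exact_update_matches_euler_oracle(self):
        tau_s = 0.005
        dt = tau_s / 1000
        s_exact = decay_and_jump_synapse(SynapseState(1.0, tau_s), dt, 0, 0.0).s
        s_euler = 1.0 - dt / tau_s * 1.0
        assert abs(s_exact - s_euler) < 1e-6


class TestSharedRate:
    def test_lam_min_is_a_fixed_point(self):
        st = SharedRateState(lam=1.5, lam_min=1.5)
        assert update_shared_rate(st, 0.7, 0).lam == pytest.approx(1.5)

    def test_exponential_relaxation_from_lam_max(self):
        st = SharedRateState(lam=200.0, lam_min=1.5, lam_max=200.0, tau_lam=1.0)
        out = update_shared_rate(st, 1.0, 0)
        assert out.lam == pytest.approx(1.5 + 198.5 * np.exp(-1), rel=1e-9)

    def test_rapid_spiking_saturates_at_lam_max(self):
        st = SharedRateState(lam=1.5, lam_min=1.5, lam_max=200.0, jump_a=5.0)
        for _ in range(100):
            st = update_shared_rate(st, 0.001, 3)
        assert st.lam == 200.0


class TestDrawKickEvents:
    def test_zero_rates_give_empty_record(self):
        ev = draw_kick_events(0.0, IndependentRates(np.zeros(2)), 10.0, 0)
        assert len(ev) == 0

    def test_poisson_count_within_4_sigma(self):
        ev = draw_kick_events(100.0, IndependentRates(np.zeros(2)), 10.0, 1)
        assert abs(len(ev) - 1000) < 4 * np.sqrt(1000)

    def test_shared_fraction_matches_thinning_probability(self):
        lam, li = 30.0, 10.0
        ev = draw_kick_events(lam, IndependentRates(np.array([li, li])), 50.0, 2)
        frac = np.mean(ev.code == 2)
        p = lam / (lam + 2 * li)
        assert abs(frac - p) < 4 * np.sqrt(p * (1 - p) / len(ev))

    def test_events_time_sorted(self):
        ev = draw_kick_events(20.0, IndependentRates(np.array([5.0, 5.0])), 5.0, 3)
        assert np.all(np.diff(ev.t) >= 0)


class TestTopology:
    def test_single_input_granule_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            Topology(n_mitral=2, granule_inputs=[(0, 0)])

    def test_unknown_mitral_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            Topology(n_mitral=2, granule_inputs=[(0, 5)])

    def test_reciprocity_of_feedback(self):
        topo = Topology.triple_ring()
        fb = topo.mitral_feedback
        for k, inputs in enumerate(topo.granule_inputs):
            for i in inputs:
                assert k in fb[i]

    def test_all_pairs_counts(self):
        topo = Topology.all_pairs(4)
        assert topo.n_granule == 6
        assert topo.n_mitral == 4


class TestClosedLoop:
    def test_seed_determinism_bit_identical(self):
        topo = Topology.pair_single_granule()
        cfg = SpikingConfig(g_coupling=1.0)
        a = run_spiking(topo, cfg, 5.0, 1e-4, 99)
        b = run_spiking(topo, cfg, 5.0, 1e-4, 99)
        assert np.array_equal(a.events.t, b.events.t)
        assert np.array_equal(a.events.code, b.events.code)
        assert np.array_equal(a.events.target, b.events.target)
        assert np.array_equal(a.lam, b.lam)

    def test_kick_count_conservation(self):
        # kicks applied to mitral i = shared events routed to i + its own
        # independent events; shared events each kick the whole pool
        topo = Topology.triple_ring()
        cfg = SpikingConfig(
            g_coupling=1.0, indep=IndependentRates(np.full(3, 15.0))
        )
        res = run_spiking(topo, cfg, 20.0, 1e-4, 5)
        assert np.array_equal(
            res.kick_counts, res.shared_routed + res.indep_counts
        )
        n_shared_events = np.sum(res.events.code == 2)
        assert res.shared_routed.sum() == 2 * n_shared_events  # pools of 2

    def test_lambda_trace_respects_bounds(self):
        topo = Topology.pair_single_granule()
        cfg = SpikingConfig(g_coupling=2.0)
        res = run_spiking(topo, cfg, 30.0, 1e-4, 7)
        assert np.all(res.lam >= cfg.rate.lam_min - 1e-12)
        assert np.all(res.lam <= cfg.rate.lam_max + 1e-12)

    def test_uncoupled_granule_matches_open_loop_rate(self):
        # with g = 0 the granule cell sees zero synaptic input, so its rate
        # equals that of the same LIF driven by nothing (Monte-Carlo band)
        sigma = 3.5  # noisy enough to fire spontaneously
        topo = Topology.pair_single_granule()
        cfg = SpikingConfig(g_coupling=0.0, lif=LIFParams(sigma=sigma))
        t_total = 50.0
        closed = run_spiking(topo, cfg, t_total, 1e-4, 11)
        n_closed = closed.granule_spike_counts[0]
        n_open = 0
        n_rep = 4
        for seed in range(n_rep):
            _, spikes = integrate_lif(
                LIFParams(sigma=sigma), np.zeros(int(t_total / 1e-4)), 1e-4, 200 + seed
            )
            n_open += len(spikes)
        mean_open = n_open / n_rep
        assert abs(n_closed - mean_open) < 4 * np.sqrt(max(mean_open, 1.0))

    def test_mismatched_independent_rates_rejected(self):
        topo = Topology.triple_ring()
        cfg = SpikingConfig()  # two independent rates but three mitral cells
        with pytest.raises(ValueError, match="independent-rate"):
            run_spiking(topo, cfg, 1.0, 1e-4, 0)


class TestCoincidenceCurve:
    def test_symmetry_in_phi(self):
        counts_pos = [
            granule_rate_vs_phase(1.0, 0.55, 0.004, window=5.0, rng_seed=s)
            for s in range(12)
        ]
        counts_neg = [
            granule_rate_vs_phase(-1.0, 0.55, 0.004, window=5.0, rng_seed=100 + s)
            for s in range(12)
        ]
        m_pos, m_neg = np.mean(counts_pos), np.mean(counts_neg)
        pooled_se = np.sqrt(np.var(counts_pos) / 12 + np.var(counts_neg) / 12)
        assert abs(m_pos - m_neg) < 4 * max(pooled_se, 1.0)

    def test_antiphase_kills_weak_fast_detector(self):
        f0 = np.mean(
            [granule_rate_vs_phase(0.0, 0.5, 0.003, rng_seed=s) for s in range(5)]
        )
        fpi = np.mean(
            [granule_rate_vs_phase(np.pi, 0.5, 0.003, rng_seed=50 + s) for s in range(5)]
        )
        assert fpi < 0.1 * f0
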