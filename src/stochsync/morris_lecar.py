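"""Morris-Lecar mitral cells in the closed feedback loop (times in ms).

The phase oscillators of the spiking model are replaced by two
conductance-based Morris-Lecar cells in a limit-cycle (Hopf) regime.  Phase
is no longer explicit, so synchrony is quantified by the Pearson correlation
of the two voltage traces over a moving window.  Inhibitory kicks cannot be
instantaneous phase shifts here: each Poisson event injects a brief square
hyperpolarizing current pulse instead, and a calibration routine relates the
pulse amplitude to the phase shift it causes at mid-cycle (an effective PRC
amplitude).  The granule LIF, synapse and shared-rate dynamics are the same
as in the spiking module, expressed in ms.

In the bistable regime the shared rate switches between long epochs of high
λ (voltages tightly correlated) and low λ (uncorrelated), with the windowed
correlation tracking λ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _kernels

log = logging.getLogger(__name__)


@dataclass
class MLParams:
    """Morris-Lecar membrane parameters (Hopf regime defaults).

    Units: capacitance µF/cm², conductances mS/cm², potentials mV, currents
    µA/cm², rates 1/ms.  The default set places the cell on a stable limit
    cycle (period ≈ 83 ms) at the default applied current; construction of a
    network run verifies sustained firing and raises otherwise.
    """

    c: float = 20.0
    g_l: float = 2.0
    e_l: float = -60.0
    g_ca: float = 4.4
    e_ca: float = 120.0
    g_k: float = 8.0
    e_k: float = -84.0
    v1: float = -1.2
    v2: float = 18.0
    v3: float = 2.0
    v4: float = 30.0
    phi_w: float = 0.04
    i_app: float = 100.0

    def __post_init__(self):
        if min(self.g_l, self.g_ca, self.g_k) < 0:
            raise ValueError("conductances must be >= 0")

    def as_tuple(self):
        return (
            self.c,
            self.g_l,
            self.e_l,
            self.g_ca,
            self.e_ca,
            self.g_k,
            self.e_k,
            self.v1,
            self.v2,
            self.v3,
            self.v4,
            self.phi_w,
        )


@dataclass
class MLState:
    """Membrane potential (mV) and recovery gating variable w ∈ [0, 1]."""

    v: float = -26.0
    w: float = 0.12

    def __post_init__(self):
        self.w = float(np.clip(self.w, 0.0, 1.0))


@dataclass
class CorrelationWindow:
    """Moving window for the voltage cross-correlation (ms)."""

    width: float = 500.0
    stride: float = 100.0

    def __post_init__(self):
        if self.width <= 0 or self.stride <= 0:
            raise ValueError("window width and stride must be > 0")


def ml_derivatives(state: MLState, params: MLParams, i_syn: float = 0.0):
    """Right-hand side (dV/dt, dw/dt) of the Morris-Lecar equations.

    m gates instantaneously (m = m_∞(V)); w relaxes toward w_∞(V) at the
    voltage-dependent rate φ_w·cosh((V−v3)/(2 v4)).  ``i_syn`` is added to
    the applied current.  Pure function of its arguments.
    """
    if not (np.isfinite(state.v) and np.isfinite(state.w)):
        raise ValueError("non-finite Morris-Lecar state")
    return _kernels._ml_rhs(
        state.v, state.w, params.i_app + i_syn, *params.as_tuple()
    )


def ml_free_run(
    params: MLParams,
    t_total: float,
    dt: float = 0.02,
    state0: MLState | None = None,
    spike_threshold: float = 0.0,
    refractory: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Unperturbed single-cell run; returns (V trace, spike times in ms)."""
    s0 = state0 or MLState()
    return _kernels.ml_free_run(
        s0.v,
        s0.w,
        params.i_app,
        t_total,
        dt,
        *params.as_tuple(),
        spike_threshold,
        refractory,
    )


def ml_period(params: MLParams, dt: float = 0.02) -> float:
    """Limit-cycle period (ms), from late spike intervals of a free run.

    Raises if the cell does not fire periodically at the configured drive.
    """
    _, spikes = ml_free_run(params, t_total=3000.0, dt=dt)
    if len(spikes) < 8:
        raise RuntimeError(
            "Morris-Lecar cell is not firing periodically at the configured "
            f"drive (only {len(spikes)} spikes in 3 s); adjust i_app"
        )
    isis = np.diff(spikes[-6:])
    if np.std(isis) / np.mean(isis) > 0.01:
        raise RuntimeError("Morris-Lecar firing is not periodic (ISI CV > 1%)")
    return float(np.mean(isis))


def calibrate_pulse_phase_shift(
    params: MLParams,
    pulse_amp: float,
    pulse_dur: float = 2.0,
    dt: float = 0.02,
) -> float:
    """Phase shift (radians) a single inhibitory pulse causes at mid-cycle.

    Runs the deterministic cell, injects one hyperpolarizing square pulse
    half a period after a reference spike, and converts the shift of the
    next spike time into radians.  Positive = delay.  Used to pick the
    pulse amplitude that mimics a target PRC kick magnitude.
    """
    period = ml_period(params, dt)
    t_total = 2000.0
    _, spikes0 = ml_free_run(params, t_total, dt)
    anchor = spikes0[len(spikes0) // 2]
    t_pulse = anchor + 0.5 * period
    s0 = MLState()
    spikes1 = _kernels.ml_single_pulse_run(
        s0.v,
        s0.w,
        params.i_app,
        t_total,
        dt,
        *params.as_tuple(),
        0.0,
        2.0,
        t_pulse,
        pulse_amp,
        pulse_dur,
    )
    after = spikes1[spikes1 > t_pulse + pulse_dur]
    base_after = spikes0[spikes0 > t_pulse + pulse_dur]
    if len(after) == 0 or len(base_after) == 0:
        raise RuntimeError("calibration run produced no spikes after the pulse")
    shift_ms = after[0] - base_after[0]
    return float(shift_ms / period * 2.0 * np.pi)


@dataclass
class MLNetworkConfig:
    """Closed-loop 2M–1G configuration with Morris-Lecar mitral cells.

    All times in ms, rates in events/ms.  The granule LIF matches the
    spiking module's coincidence-detector regime; shared kicks arrive as
    square inhibitory current pulses of amplitude ``pulse_amp`` (µA/cm²)
    and duration ``pulse_dur`` (ms) to both cells.
    """

    ml: MLParams = field(default_factory=MLParams)
    spike_threshold: float = 0.0
    refractory: float = 2.0
    pulse_amp: float = 25.0
    pulse_dur: float = 2.0
    g_coupling: float = 0.6
    tau_s: float = 4.0
    beta: float = 4.0
    tau_m: float = 10.0
    bias: float = 0.0
    sigma: float = 0.057  # 1/sqrt(ms); ≈ 1.8 in 1/sqrt(s)
    lam_min: float = 0.0005  # /ms = 0.5/s
    lam_max: float = 0.04  # /ms = 40/s
    tau_lam: float = 1500.0
    jump_a: float = 0.004  # /ms = 4/s per granule spike
    lam_indep: float = 0.01  # /ms = 10/s per cell


@dataclass
class MLResult:
    """Sampled traces of a closed-loop Morris-Lecar run (times ms)."""

    t: np.ndarray
    v: np.ndarray  # (n_samples, 2)
    lam: np.ndarray  # events/ms
    granule_spikes: np.ndarray
    config: MLNetworkConfig
    sample_dt: float


def run_ml_network(
    config: MLNetworkConfig,
    t_total: float,
    dt: float = 0.025,
    rng_seed: int = 0,
    sample_interval: float = 1.0,
    state0: tuple[MLState, MLState] | None = None,
    check_oscillation: bool = True,
) -> MLResult:
    """Closed-loop simulation of the ML pair + granule LIF.

    ML cells advance by fixed-step RK4 with pulse currents held constant
    within a step; spikes are upward crossings of the threshold with a
    refractory hysteresis; the rest of the loop matches the spiking module.
    Raises at startup if the base ML parameter set is not oscillating.
    """
    if check_oscillation:
        ml_period(config.ml, dt=max(dt, 0.02))  # raises if not periodic
    if state0 is None:
        # desynchronized start: one cell at rest phase, one mid-cycle
        state0 = (MLState(-26.0, 0.12), MLState(10.0, 0.3))
    sample_every = max(1, int(round(sample_interval / dt)))
    t_s, v_s, lam_s, g_spk = _kernels.ml_network_run(
        np.array([state0[0].v, state0[1].v]),
        np.array([state0[0].w, state0[1].w]),
        config.ml.i_app,
        t_total,
        dt,
        *config.ml.as_tuple(),
        config.spike_threshold,
        config.refractory,
        config.pulse_amp,
        config.pulse_dur,
        config.g_coupling,
        config.tau_s,
        config.beta,
        config.tau_m,
        config.bias,
        config.sigma,
        config.lam_min,
        config.lam_max,
        config.tau_lam,
        config.jump_a,
        config.lam_indep,
        sample_every,
        int(rng_seed) % 2**31,
    )
    return MLResult(
        t=t_s,
        v=v_s,
        lam=lam_s,
        granule_spikes=g_spk,
        config=config,
        sample_dt=sample_every * dt,
    )


def sliding_correlation(
    v1: np.ndarray,
    v2: np.ndarray,
    win: CorrelationWindow,
    dt: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of two equal-dt traces over a moving window.

    Returns (window-center times, correlation values).  A window in which
    either trace has zero variance yields correlation 0 (logged).
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError("traces must have equal length")
    w = int(round(win.width / dt))
    stride = max(1, int(round(win.stride / dt)))
    if w >= len(v1):
        raise ValueError("window must be shorter than the traces")
    starts = np.arange(0, len(v1) - w + 1, stride)
    # cumulative sums give O(n) windowed moments
    c1 = np.concatenate([[0.0], np.cumsum(v1)])
    c2 = np.concatenate([[0.0], np.cumsum(v2)])
    c11 = np.concatenate([[0.0], np.cumsum(v1 * v1)])
    c22 = np.concatenate([[0.0], np.cumsum(v2 * v2)])
    c12 = np.concatenate([[0.0], np.cumsum(v1 * v2)])
    e = starts + w
    n = float(w)
    s1 = c1[e] - c1[starts]
    s2 = c2[e] - c2[starts]
    var1 = (c11[e] - c11[starts]) - s1 * s1 / n
    var2 = (c22[e] - c22[starts]) - s2 * s2 / n
    cov = (c12[e] - c12[starts]) - s1 * s2 / n
    denom = np.sqrt(np.clip(var1, 0, None) * np.clip(var2, 0, None))
    zero_var = denom <= 0
    if np.any(zero_var):
        log.warning("%d zero-variance correlation windows set to 0", zero_var.sum())
    corr = np.where(zero_var, 0.0, cov / np.where(zero_var, 1.0, denom))
    centers = (starts + w / 2) * dt
    return centers, np.clip(corr, -1.0, 1.0)


def classify_epochs(
    lam: np.ndarray, lam_lo: float, lam_hi: float
) -> tuple[np.ndarray, int]:
    """Hysteresis classification of a λ trace into low (0) / high (1) epochs.

    A sample switches the state only when λ crosses the far threshold, which
    suppresses chatter around a single cut.  Returns the per-sample state
    and the number of transitions.
    """
    state = np.empty(len(lam), dtype=np.int8)
    cur = 1 if lam[0] >= lam_hi else 0
    n_trans = 0
    for i, x in enumerate(lam):
        if cur == 0 and x >= lam_hi:
            cur = 1
            n_trans += 1
        elif cur == 1 and x <= lam_lo:
            cur = 0
            n_trans += 1
        state[i] = cur
    return state, n_trans
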