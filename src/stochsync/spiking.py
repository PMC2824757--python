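"""Closed-loop spiking feedback network.

Mitral cells are phase oscillators whose 2π crossings are spikes; each spike
increments the synaptic drive s of every postsynaptic granule cell by the
coupling g.  The granule cell is a noisy leaky integrate-and-fire unit

    dV = (bias + β·s − V) dt/τ_m + σ √dt ξ,   V ≥ 1 → spike, V ← 0

whose spikes raise the rate λ of a shared Poisson process (λ decays back
toward λ_min with time constant τ_λ and is clipped at λ_max).  Shared events
kick every mitral cell wired to that granule pool through the PRC;
independent Poisson streams with fixed rates kick each mitral cell alone.
The loop closes because synchronous mitral spiking drives the
coincidence-detecting granule cell harder, raising λ, which raises the
common-input fraction q = λ/(λ+λ1+λ2) and hence the synchrony itself.

With the shipped defaults the granule cell is a coincidence detector: a
single mitral volley is subthreshold, a synchronous pair is near threshold,
so granule firing (and therefore λ) reports mitral synchrony.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .phase_core import TWO_PI, KickGain, PRCSpec, wrap_to_pi
from .reduced import _prc_args

log = logging.getLogger(__name__)


@dataclass
class LIFParams:
    """Noisy leaky integrate-and-fire granule cell.

    Threshold 1, reset 0 (dimensionless voltage).  ``beta`` is the input
    gain on the summed synaptic drive; with τ_m = 10 ms, τ_s of a few ms and
    β = 4 a single mitral volley peaks well below threshold while a
    coincident pair reaches it.  σ is the white-noise intensity in
    units of 1/√s (the Euler–Maruyama step adds σ√dt·N(0,1)).
    """

    threshold: float = 1.0
    reset: float = 0.0
    tau_m: float = 0.010
    bias: float = 0.0
    sigma: float = 1.8
    beta: float = 4.0

    def __post_init__(self):
        if self.threshold <= self.reset:
            raise ValueError("threshold must exceed reset")
        if self.tau_m <= 0:
            raise ValueError("tau_m must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class SynapseState:
    """Per-granule synaptic drive: exponential decay plus unit jumps scaled
    by the mitral→granule coupling g."""

    s: float = 0.0
    tau_s: float = 0.005
    increment: float = 1.0

    def __post_init__(self):
        if self.s < 0:
            raise ValueError("synaptic drive must be >= 0")


@dataclass
class SharedRateState:
    """Shared Poisson rate λ with slow relaxation toward λ_min and a jump of
    ``jump_a`` per granule spike, clipped to [λ_min, λ_max]."""

    lam: float = 1.5
    lam_min: float = 1.5
    lam_max: float = 200.0
    tau_lam: float = 1.0
    jump_a: float = 5.0

    def __post_init__(self):
        if not self.lam_min <= self.lam <= self.lam_max:
            raise ValueError("lam must lie in [lam_min, lam_max]")
        if self.tau_lam <= 0:
            raise ValueError("tau_lam must be > 0")


@dataclass
class IndependentRates:
    """Fixed rates of the per-mitral independent Poisson kick streams."""

    lam_i: np.ndarray = field(default_factory=lambda: np.array([15.0, 15.0]))

    def __post_init__(self):
        self.lam_i = np.asarray(self.lam_i, dtype=float)
        if np.any(self.lam_i < 0):
            raise ValueError("independent rates must be >= 0")


@dataclass
class Topology:
    """Wiring of the mitral/granule network.

    ``granule_inputs[k]`` lists the presynaptic mitral cells of granule k
    (at least two — a granule cell reads out coincidences); feedback is
    reciprocal: every mitral cell driving a granule cell receives that
    granule cell's shared Poisson kicks, as dendrodendritic synapses are.
    """

    n_mitral: int
    granule_inputs: list[tuple[int, ...]]

    def __post_init__(self):
        for k, inputs in enumerate(self.granule_inputs):
            if len(set(inputs)) < 2:
                raise ValueError(f"granule {k} must have >= 2 distinct mitral inputs")
            if any(i < 0 or i >= self.n_mitral for i in inputs):
                raise ValueError(f"granule {k} references an unknown mitral cell")

    @property
    def n_granule(self) -> int:
        return len(self.granule_inputs)

    @property
    def mitral_feedback(self) -> list[tuple[int, ...]]:
        """Granule cells feeding back onto each mitral cell (reciprocity)."""
        fb = [[] for _ in range(self.n_mitral)]
        for k, inputs in enumerate(self.granule_inputs):
            for i in inputs:
                fb[i].append(k)
        return [tuple(v) for v in fb]

    def adjacency(self) -> tuple[np.ndarray, np.ndarray]:
        """(W_mg, W_fb): granule←mitral and mitral←granule 0/1 matrices."""
        w_mg = np.zeros((self.n_granule, self.n_mitral), dtype=np.int8)
        for k, inputs in enumerate(self.granule_inputs):
            for i in inputs:
                w_mg[k, i] = 1
        w_fb = w_mg.T.copy()
        return w_mg, w_fb

    @classmethod
    def pair_single_granule(cls) -> "Topology":
        """The 2M–1G network: one granule cell shared by a mitral pair."""
        return cls(n_mitral=2, granule_inputs=[(0, 1)])

    @classmethod
    def triple_ring(cls) -> "Topology":
        """The 3M–3G network: granule k reads mitral pair {k, k+1 mod 3},
        so every mitral cell shares a granule cell with both others."""
        return cls(n_mitral=3, granule_inputs=[(0, 1), (0, 2), (1, 2)])

    @classmethod
    def all_pairs(cls, n_mitral: int) -> "Topology":
        """Generalized N-mitral network with one granule cell per pair."""
        inputs = [
            (i, j) for i in range(n_mitral) for j in range(i + 1, n_mitral)
        ]
        return cls(n_mitral=n_mitral, granule_inputs=inputs)


@dataclass
class SpikingConfig:
    """All parameters of the closed-loop spiking model."""

    omega: float = TWO_PI * 40.0
    prc: PRCSpec = field(default_factory=PRCSpec)
    kick: KickGain = field(default_factory=lambda: KickGain(0.3))
    g_coupling: float = 2.0  # mitral→granule synapse strength (0 … 2)
    tau_s: float = 0.005
    lif: LIFParams = field(default_factory=LIFParams)
    rate: SharedRateState = field(default_factory=SharedRateState)
    indep: IndependentRates = field(default_factory=IndependentRates)


@dataclass
class EventRecord:
    """Time-stamped events of one run.  Codes: 0 mitral spike, 1 granule
    spike, 2 shared kick (target = granule), 3 independent kick (target =
    mitral)."""

    t: np.ndarray
    code: np.ndarray
    target: np.ndarray

    CODE_NAMES = {0: "mitral_spike", 1: "granule_spike", 2: "shared_kick", 3: "indep_kick"}

    def __len__(self):
        return len(self.t)

    def of_kind(self, code: int) -> np.ndarray:
        return self.t[self.code == code]


@dataclass
class SpikingResult:
    """Sampled traces and event bookkeeping of a closed-loop run."""

    t: np.ndarray
    theta: np.ndarray  # (n_samples, n_mitral)
    lam: np.ndarray  # (n_samples, n_granule)
    v: np.ndarray  # (n_samples, n_granule)
    events: EventRecord
    kick_counts: np.ndarray
    shared_routed: np.ndarray
    indep_counts: np.ndarray
    mitral_spike_counts: np.ndarray
    granule_spike_counts: np.ndarray
    config: SpikingConfig

    def phase_differences(self, i: int = 0, j: int = 1) -> np.ndarray:
        """Sampled phase differences θ_j − θ_i wrapped to (−π, π]."""
        return wrap_to_pi(self.theta[:, j] - self.theta[:, i])


def integrate_lif(
    params: LIFParams,
    drive: np.ndarray,
    dt: float,
    rng_seed: int,
    v0: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Euler–Maruyama integration of the LIF for a given drive trace.

    Returns (V trace, spike times).  The drive is the synaptic input
    multiplied into the membrane equation as (bias + drive − V)/τ_m; the
    caller supplies β·s if gain is wanted.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if dt > params.tau_m / 10:
        warnings.warn(
            f"dt={dt} is coarse relative to tau_m={params.tau_m}; "
            "expect integration bias"
        )
    drive = np.asarray(drive, dtype=float)
    if np.any(~np.isfinite(drive)):
        raise ValueError("drive contains NaN/inf")
    v, spike_idx = _kernels.lif_integrate(
        drive, dt, params.tau_m, params.bias, params.sigma, v0, int(rng_seed) % 2**31
    )
    return v, (spike_idx + 1) * dt


def decay_and_jump_synapse(
    state: SynapseState, dt: float, n_mitral_spikes: int, g: KickGain | float
) -> SynapseState:
    """Exact update over dt: s ← s·exp(−dt/τ_s) + g·(number of spikes)."""
    if dt < 0:
        raise ValueError("dt must be >= 0")
    gv = g.g if isinstance(g, KickGain) else float(g)
    s_new = state.s * np.exp(-dt / state.tau_s) + gv * n_mitral_spikes
    return SynapseState(s=s_new, tau_s=state.tau_s, increment=state.increment)


def update_shared_rate(
    state: SharedRateState, dt: float, n_granule_spikes: int
) -> SharedRateState:
    """λ relaxes toward λ_min over dt, jumps by jump_a per granule spike,
    then is clipped to [λ_min, λ_max]."""
    if dt < 0:
        raise ValueError("dt must be >= 0")
    lam = state.lam_min + (state.lam - state.lam_min) * np.exp(-dt / state.tau_lam)
    lam += state.jump_a * n_granule_spikes
    lam = float(np.clip(lam, state.lam_min, state.lam_max))
    return SharedRateState(
        lam=lam,
        lam_min=state.lam_min,
        lam_max=state.lam_max,
        tau_lam=state.tau_lam,
        jump_a=state.jump_a,
    )


def draw_kick_events(
    lam: float,
    lam_indep: IndependentRates,
    t_window: float,
    rng_seed: int,
) -> EventRecord:
    """Merged, time-sorted Poisson events over a window at frozen rates.

    Shared events carry code 2 (they kick every mitral cell of the pool);
    independent events carry code 3 with the mitral index as target.
    """
    if lam < 0 or np.any(lam_indep.lam_i < 0):
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(rng_seed)
    ts, codes, targets = [], [], []
    n_shared = rng.poisson(lam * t_window)
    ts.append(rng.uniform(0, t_window, n_shared))
    codes.append(np.full(n_shared, 2, dtype=np.int8))
    targets.append(np.full(n_shared, 0, dtype=np.int32))
    for i, li in enumerate(lam_indep.lam_i):
        n_i = rng.poisson(li * t_window)
        ts.append(rng.uniform(0, t_window, n_i))
        codes.append(np.full(n_i, 3, dtype=np.int8))
        targets.append(np.full(n_i, i, dtype=np.int32))
    t = np.concatenate(ts)
    order = np.argsort(t, kind="stable")
    return EventRecord(
        t=t[order],
        code=np.concatenate(codes)[order],
        target=np.concatenate(targets)[order],
    )


def run_spiking(
    topology: Topology,
    config: SpikingConfig,
    t_total: float,
    dt: float,
    rng_seed: int,
    sample_interval: float = 0.002,
    theta0: np.ndarray | None = None,
    event_cap: int | None = None,
) -> SpikingResult:
    """Full closed-loop simulation (compiled fixed-step hybrid scheme).

    Per step: phases drift; Poisson kicks (thinning at the current rates)
    shift phases through the PRC; upward 2π crossings are mitral spikes and
    increment the synapses; the LIF advances by Euler–Maruyama; granule
    spikes jump λ.  Synapses and λ use exact exponential decay between
    events.  Bit-reproducible for a fixed seed.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    min_rate = min(
        [config.rate.lam_min] + [r for r in config.indep.lam_i if r > 0] or [1.0]
    )
    if t_total < 10.0 / max(min_rate, 1e-9):
        warnings.warn(
            f"t_total={t_total}s is short relative to the slowest rate; "
            "histograms may be far from stationary"
        )
    w_mg, w_fb = topology.adjacency()
    if len(config.indep.lam_i) != topology.n_mitral:
        raise ValueError("independent-rate vector does not match n_mitral")
    rng = np.random.default_rng(rng_seed)
    if theta0 is None:
        theta0 = rng.uniform(0, TWO_PI, topology.n_mitral)
    theta0 = np.mod(np.asarray(theta0, dtype=float), TWO_PI)
    if event_cap is None:
        mean_rate = (
            config.rate.lam_max * topology.n_granule
            + float(np.sum(config.indep.lam_i))
            + (config.omega / TWO_PI + 50.0) * (topology.n_mitral + topology.n_granule)
        )
        event_cap = int(mean_rate * t_total * 1.3) + 10_000
    out = _kernels.phase_network_run(
        theta0,
        config.omega,
        t_total,
        dt,
        *_prc_args(config.prc),
        config.kick.g,
        config.g_coupling,
        config.tau_s,
        config.lif.beta,
        config.lif.tau_m,
        config.lif.bias,
        config.lif.sigma,
        config.rate.lam_min,
        config.rate.lam_max,
        config.rate.tau_lam,
        config.rate.jump_a,
        config.indep.lam_i,
        w_mg,
        w_fb,
        max(1, int(round(sample_interval / dt))),
        int(rng_seed) % 2**31,
        event_cap,
    )
    (
        t_s,
        theta_s,
        lam_s,
        v_s,
        ev_t,
        ev_code,
        ev_target,
        kick_counts,
        shared_routed,
        indep_counts,
        m_spikes,
        g_spikes,
        overflow,
    ) = out
    if overflow:
        warnings.warn("event log capacity exceeded; EventRecord is truncated")
    return SpikingResult(
        t=t_s,
        theta=theta_s,
        lam=lam_s,
        v=v_s,
        events=EventRecord(ev_t, ev_code, ev_target),
        kick_counts=kick_counts,
        shared_routed=shared_routed,
        indep_counts=indep_counts,
        mitral_spike_counts=m_spikes,
        granule_spike_counts=g_spikes,
        config=config,
    )


def granule_rate_vs_phase(
    phi: float,
    g_coupling: float,
    tau_s: float,
    lif: LIFParams | None = None,
    window: float = 10.0,
    frequency: float = 40.0,
    dt: float = 1e-4,
    rng_seed: int = 0,
) -> int:
    """Open-loop granule spike count at a clamped mitral phase difference.

    The feedback loop is opened: the two mitral cells are replaced by
    periodic spike trains at the oscillation frequency with the second
    train delayed by φ/2π of a period, so the phase difference stays
    clamped.  Returns the LIF spike count over the window — the
    coincidence-detection curve F(φ), a decreasing function of |φ| that for
    weak couplings and fast synapses drops to almost nothing beyond a
    fraction of a radian.
    """
    lif = lif or LIFParams()
    period = 1.0 / frequency
    lag = (wrap_to_pi(phi) / TWO_PI) * period
    return int(
        _kernels.lif_two_pulse_trains(
            period,
            lag % period,
            window,
            dt,
            g_coupling,
            tau_s,
            lif.beta,
            lif.tau_m,
            lif.bias,
            lif.sigma,
            int(rng_seed) % 2**31,
        )
    )
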