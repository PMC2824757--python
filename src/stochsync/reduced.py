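"""Event-driven reduced model of the mitral-pair / granule feedback loop.

Instead of simulating the granule cell explicitly, the pair of phase
oscillators is advanced only at kick times.  Waiting times between kicks are
exponential with the total rate λ + λ1 + λ2 and the kick source (shared,
independent-1, independent-2) is chosen Gillespie-style in proportion to the
rates.  At each event the phases drift by ω·Δt and the kicked oscillator(s)
are shifted through the PRC:

    θ_i(n+1) = θ_i(n) + ω·Δt_n + k_i · g · Δ(θ_i(n))   (mod 2π)

with k_i = 1 when oscillator i receives the kick.  The shared rate λ then
relaxes on a slow time scale τ_λ toward λ_min + G, where the feedback
functional G stands in for the granule firing rate: either a direct peaked
function of the instantaneous phase difference φ, or a nonlinear function of
a trailing temporal average of exp(iφ) (the empirical order parameter).  The
direct functional gives a single stable steady state of λ; the
order-parameter functional can produce bistability between an asynchronous
(low λ) and a synchronous (high λ) state.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .phase_core import TWO_PI, KickGain, PRCFamily, PRCSpec, wrap_to_pi

log = logging.getLogger(__name__)

_PRC_CODE = {PRCFamily.TYPE1: 1, PRCFamily.TYPE2: 2, PRCFamily.TABULATED: 3}
_EMPTY_TABLE = np.zeros(2)


def _prc_args(prc: PRCSpec):
    code = _PRC_CODE[prc.family]
    table = prc.table if prc.family is PRCFamily.TABULATED else _EMPTY_TABLE
    # amplitude is folded into the kernel's amp argument for analytic families
    return code, prc.amplitude, np.asarray(table, dtype=float)


class GMode(enum.Enum):
    DIRECT = "direct"
    ORDER_PARAMETER = "order_parameter"


class KickEval(enum.Enum):
    """Where the PRC is evaluated in the event map: at the pre-drift phase
    (as the discrete map is written) or at the drifted phase.  The
    difference is O(g·ω·Δt) and immaterial for the stationary statistics
    because the drift uniformizes the base phase either way."""

    PRE_DRIFT = "pre_drift"
    POST_DRIFT = "post_drift"


@dataclass
class MapState:
    """State of the reduced map: two phases, the shared rate, and time."""

    theta1: float
    theta2: float
    lam: float
    t: float = 0.0

    def __post_init__(self):
        self.theta1 = float(np.mod(self.theta1, TWO_PI))
        self.theta2 = float(np.mod(self.theta2, TWO_PI))

    @property
    def phi(self) -> float:
        return wrap_to_pi(self.theta2 - self.theta1)


@dataclass(frozen=True)
class EventKind:
    """Which Poisson stream produced a kick; k_i = 1 if oscillator i is hit."""

    kind: str  # "shared" | "indep1" | "indep2"
    k1: int
    k2: int

    SHARED = None  # filled in below
    INDEP1 = None
    INDEP2 = None


EventKind.SHARED = EventKind("shared", 1, 1)
EventKind.INDEP1 = EventKind("indep1", 1, 0)
EventKind.INDEP2 = EventKind("indep2", 0, 1)


@dataclass
class GFunctional:
    """Feedback functional G mapping synchrony to added shared rate (events/s).

    direct mode
        G(φ) = amplitude · exp(κ (cos φ − 1)) — an even bump peaked at φ = 0,
        mimicking the granule cell's coincidence-detection curve; κ sets how
        sharply the granule rate falls off with phase difference.
    order-parameter mode
        G = amplitude · m̂^p with m̂ the (clipped-positive) cosine part of a
        trailing exponentially-weighted average of exp(iφ) — the empirical
        order parameter of the pair over a window of time constant
        ``tau_avg``.  The stationary density of φ is even, so its first
        circular moment is real and the signed cosine moment estimates the
        order parameter without the rectification bias the modulus |⟨e^{iφ}⟩|
        would pick up from window noise in the asynchronous state.  With
        p = 2 the averaged feedback grows like q² for small common-input
        fraction q — the super-linear onset needed for bistability.
    """

    mode: GMode = GMode.DIRECT
    amplitude: float = 20.0
    kappa: float = 5.0
    p: float = 2.0
    tau_avg: float = 0.5

    def __post_init__(self):
        if isinstance(self.mode, str):
            self.mode = GMode(self.mode)
        if self.amplitude < 0:
            raise ValueError("G amplitude must be >= 0")

    def direct_value(self, phi) -> np.ndarray | float:
        return self.amplitude * np.exp(self.kappa * (np.cos(np.asarray(phi)) - 1.0))


def sample_interval(total_rate: float, rng: np.random.Generator) -> float:
    """Exponential waiting time with mean 1/total_rate (Gillespie step 1)."""
    if total_rate <= 0:
        raise ValueError(f"total rate must be > 0, got {total_rate}")
    return float(rng.exponential(1.0 / total_rate))


def select_event(
    lam: float, lam1: float, lam2: float, rng: np.random.Generator
) -> EventKind:
    """Choose the kick source in proportion to the three rates."""
    if lam < 0 or lam1 < 0 or lam2 < 0:
        raise ValueError("rates must be >= 0")
    total = lam + lam1 + lam2
    if total <= 0:
        raise ValueError("cannot select an event when all rates are zero")
    u = rng.random() * total
    if u < lam:
        return EventKind.SHARED
    if u < lam + lam1:
        return EventKind.INDEP1
    return EventKind.INDEP2


def map_step(
    state: MapState,
    dt: float,
    ev: EventKind,
    prc: PRCSpec,
    gain: KickGain,
    omega: float = TWO_PI * 40.0,
    kick_eval: KickEval = KickEval.PRE_DRIFT,
) -> MapState:
    """One event of the reduced map: drift by ω·dt, then kick through the PRC."""
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    d = omega * dt
    if kick_eval is KickEval.PRE_DRIFT:
        d1, d2 = prc(state.theta1), prc(state.theta2)
    else:
        d1, d2 = prc(state.theta1 + d), prc(state.theta2 + d)
    th1 = np.mod(state.theta1 + d + ev.k1 * gain.g * d1, TWO_PI)
    th2 = np.mod(state.theta2 + d + ev.k2 * gain.g * d2, TWO_PI)
    return MapState(th1, th2, state.lam, state.t + dt)


class _OrderParamWindow:
    """Trailing exponentially-weighted first circular moment of φ."""

    def __init__(self, tau_avg: float):
        self.tau_avg = tau_avg
        self.c = 0.0
        self.s = 0.0
        self.w_total = 0.0  # total normalized weight seen so far

    def push(self, phi: float, dt: float) -> None:
        b = 1.0 - np.exp(-dt / self.tau_avg)
        self.c = (1 - b) * self.c + b * np.cos(phi)
        self.s = (1 - b) * self.s + b * np.sin(phi)
        self.w_total = (1 - b) * self.w_total + b

    @property
    def empty(self) -> bool:
        return self.w_total <= 0.0


def evaluate_G(
    spec: GFunctional,
    phi: float | None = None,
    window: _OrderParamWindow | None = None,
) -> float:
    """Evaluate the feedback functional.

    direct mode needs the instantaneous ``phi``; order-parameter mode needs
    the trailing ``window`` (an empty window yields G = 0 with a warning).
    """
    if spec.mode is GMode.DIRECT:
        if phi is None:
            raise ValueError("direct-mode G requires the instantaneous phi")
        return float(spec.direct_value(phi))
    if window is None or window.empty:
        warnings.warn("order-parameter G evaluated on an empty window; returning 0")
        return 0.0
    m_hat = max(window.c, 0.0)
    return float(spec.amplitude * m_hat**spec.p)


def relax_lambda(
    lam: float,
    g_val: float,
    dt: float,
    tau_lam: float,
    lam_min: float,
    lam_max: float = np.inf,
) -> float:
    """Exact exponential relaxation of λ toward λ_min + G over dt, clipped."""
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    target = lam_min + g_val
    lam_new = target + (lam - target) * np.exp(-dt / tau_lam)
    return float(np.clip(lam_new, lam_min, lam_max))


@dataclass
class ReducedConfig:
    """Full parameter set of the reduced feedback model.

    Rates are events per second; the defaults put the pair in the regime
    where unshared background kicks (λ1 = λ2 = 15/s) dominate the baseline
    shared rate (λ_min = 1/s), so that the uncoupled system is nearly
    asynchronous and the feedback must bootstrap any synchrony.
    """

    omega: float = TWO_PI * 40.0
    prc: PRCSpec = field(default_factory=PRCSpec)
    gain: KickGain = field(default_factory=lambda: KickGain(0.3))
    lam1: float = 15.0
    lam2: float = 15.0
    lam_min: float = 1.0
    lam_max: float = 500.0
    tau_lam: float = 1.0
    g_func: GFunctional = field(default_factory=GFunctional)
    kick_eval: KickEval = KickEval.PRE_DRIFT


@dataclass
class ReducedTrajectory:
    """Recorded (t, φ, λ) samples of one reduced-model run plus final state."""

    t: np.ndarray
    phi: np.ndarray
    lam: np.ndarray
    final_state: MapState

    def terminal_lambda(self, tail_fraction: float = 0.1) -> float:
        """Mean λ over the trailing fraction of recorded events."""
        n = max(1, int(len(self.lam) * tail_fraction))
        return float(np.mean(self.lam[-n:]))


def run_reduced(
    config: ReducedConfig,
    n_events: int,
    rng_seed: int,
    initial: MapState | None = None,
    record_every: int = 1,
) -> ReducedTrajectory:
    """Iterate the reduced map for ``n_events`` kicks (compiled loop).

    The Gillespie cycle per event is: draw the exponential waiting time at
    the current total rate, select the kick source, apply the phase map,
    evaluate G on the new phase difference, and relax λ toward λ_min + G
    with the exact exponential update.  λ is held constant within each
    inter-event interval for rate purposes.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = np.random.default_rng(rng_seed)
    if initial is None:
        initial = MapState(
            rng.uniform(0, TWO_PI), rng.uniform(0, TWO_PI), config.lam_min
        )
    code, amp, table = _prc_args(config.prc)
    gf = config.g_func
    t, phi, lam, th1, th2, lam_f, t_f = _kernels.reduced_map_run(
        initial.theta1,
        initial.theta2,
        float(np.clip(initial.lam, config.lam_min, config.lam_max)),
        config.omega,
        code,
        amp,
        table,
        config.gain.g,
        config.lam1,
        config.lam2,
        config.lam_min,
        config.lam_max,
        config.tau_lam,
        0 if gf.mode is GMode.DIRECT else 1,
        gf.amplitude,
        gf.kappa,
        gf.p,
        gf.tau_avg,
        config.kick_eval is KickEval.PRE_DRIFT,
        int(n_events),
        int(record_every),
        int(rng_seed) % 2**31,
    )
    return ReducedTrajectory(t, phi, lam, MapState(th1, th2, lam_f, t_f))


def run_trials(
    config: ReducedConfig,
    n_trials: int,
    n_events: int,
    rng_seed: int,
    lam_init_range: tuple[float, float] | None = None,
    record_every: int = 10,
) -> list[ReducedTrajectory]:
    """Run many trials from random uniform initial phases and initial λ.

    Initial λ values are uniform on ``lam_init_range`` (default: the full
    [λ_min, λ_min + amplitude] band the feedback can reach).
    """
    rng = np.random.default_rng(rng_seed)
    if lam_init_range is None:
        lam_init_range = (config.lam_min, config.lam_min + config.g_func.amplitude)
    out = []
    for k in range(n_trials):
        init = MapState(
            rng.uniform(0, TWO_PI),
            rng.uniform(0, TWO_PI),
            rng.uniform(*lam_init_range),
        )
        seed_k = int(rng.integers(0, 2**31 - 1))
        out.append(
            run_reduced(config, n_events, seed_k, initial=init, record_every=record_every)
        )
    return out
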