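"""Phase-oscillator representation of mitral cells.

Mitral cells firing in the gamma band are treated as limit-cycle oscillators,
each carried by a single phase variable θ ∈ [0, 2π) advancing at a natural
angular frequency ω.  Brief inhibitory inputs shift the phase through a phase
resetting curve (PRC) Δ(θ): an event arriving at phase θ moves the oscillator
to θ + g·Δ(θ), where g is the kick magnitude.  This module holds the phase
arithmetic, the PRC families, and the circular statistics used to quantify
synchrony between a pair of oscillators.

Conventions
-----------
* phases live in [0, 2π); every operation wraps back into that interval
* phase differences φ = θ2 − θ1 live in (−π, π]; the tie at ±π maps to +π
* the order parameter is R = |⟨exp(iφ)⟩| ∈ [0, 1]
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

log = logging.getLogger(__name__)

TWO_PI = 2.0 * np.pi


class PRCFamily(enum.Enum):
    """Shape families for the phase resetting curve Δ(θ)."""

    TYPE1 = "type1"  #: amplitude · (1 − cos θ) — strictly non-negative
    TYPE2 = "type2"  #: amplitude · sin θ — biphasic, near-sinusoidal
    TABULATED = "tabulated"  #: periodic interpolation of sampled values


@dataclass(frozen=True)
class PRCSpec:
    """A phase resetting curve Δ(θ), 2π-periodic.

    Mitral-cell PRCs measured experimentally are close to sinusoidal, so the
    shipped default is the type-2 (sin) family with unit amplitude; the kick
    magnitude is carried separately by :class:`KickGain`.

    Parameters
    ----------
    family:
        One of :class:`PRCFamily`.
    amplitude:
        Dimensionless scale multiplying the base shape.
    table:
        For ``TABULATED`` only: Δ sampled on a uniform θ grid covering
        [0, 2π) (the point at 2π is identified with 0).
    """

    family: PRCFamily = PRCFamily.TYPE2
    amplitude: float = 1.0
    table: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.family is PRCFamily.TABULATED:
            if self.table is None or len(np.atleast_1d(self.table)) < 2:
                raise ValueError("tabulated PRC requires a table with >= 2 samples")
            object.__setattr__(self, "table", np.asarray(self.table, dtype=float))

    def __call__(self, theta: np.ndarray | float) -> np.ndarray | float:
        """Evaluate Δ(θ) (vectorized, 2π-periodic)."""
        th = np.mod(theta, TWO_PI)
        if self.family is PRCFamily.TYPE1:
            return self.amplitude * (1.0 - np.cos(th))
        if self.family is PRCFamily.TYPE2:
            return self.amplitude * np.sin(th)
        tab = self.table
        n = len(tab)
        grid = np.arange(n + 1) * (TWO_PI / n)
        vals = np.append(tab, tab[0])  # close the circle
        return self.amplitude * np.interp(th, grid, vals)

    def to_csv(self, path, n_grid: int = 256) -> None:
        """Write the PRC as two-column CSV (theta, delta) on a uniform grid."""
        theta = np.arange(n_grid) * (TWO_PI / n_grid)
        arr = np.column_stack([theta, np.asarray(self(theta), dtype=float)])
        np.savetxt(path, arr, delimiter=",", header="theta_rad,delta", comments="")

    @classmethod
    def from_csv(cls, path, amplitude: float = 1.0) -> "PRCSpec":
        """Read a tabulated PRC from two-column CSV (theta, delta)."""
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        theta, delta = arr[:, 0], arr[:, 1]
        if not np.allclose(np.diff(theta), theta[1] - theta[0]):
            raise ValueError("PRC table must use a uniform theta grid")
        return cls(PRCFamily.TABULATED, amplitude=amplitude, table=delta)


@dataclass(frozen=True)
class KickGain:
    """Dimensionless magnitude g of a single inhibitory kick."""

    g: float = 0.3

    def __post_init__(self):
        if self.g < 0:
            raise ValueError(f"kick gain must be >= 0, got {self.g}")


@dataclass
class PhaseState:
    """Phases of N oscillators plus their common natural frequency.

    ``theta`` is kept wrapped into [0, 2π); ``omega`` is in rad/s and must be
    positive.  The default ω = 2π·40 rad/s corresponds to gamma-band firing
    at 40 Hz.
    """

    theta: np.ndarray
    omega: float = TWO_PI * 40.0

    def __post_init__(self):
        if self.omega <= 0:
            raise ValueError(f"omega must be > 0, got {self.omega}")
        self.theta = np.mod(np.asarray(self.theta, dtype=float), TWO_PI)


@dataclass(frozen=True)
class PhaseDiffSample:
    """A phase difference wrapped to (−π, π] with an optional weight."""

    phi: float
    weight: float = 1.0


@dataclass
class PhaseDensity:
    """Discretized probability density on the circle of phase differences.

    ``grid`` holds bin centers on (−π, π]; ``rho`` the density values
    (mass per radian).  ``q`` optionally records the common-input fraction
    the density was computed for.
    """

    grid: np.ndarray
    rho: np.ndarray
    q: float | None = None

    @property
    def bin_width(self) -> float:
        return TWO_PI / len(self.grid)

    def integral(self) -> float:
        return float(np.sum(self.rho) * self.bin_width)

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.grid, self.rho])
        np.savetxt(
            path, arr, delimiter=",", header="phi_rad,density_per_rad", comments=""
        )


def advance_phase(state: PhaseState, dt: float) -> PhaseState:
    """Advance every oscillator by ω·dt and wrap into [0, 2π).

    Raises ``ValueError`` for negative dt; dt = 0 is a no-op.
    """
    if dt < 0:
        raise ValueError(f"cannot advance phases by a negative time step dt={dt}")
    return PhaseState(np.mod(state.theta + state.omega * dt, TWO_PI), state.omega)


def apply_kick(theta, prc: PRCSpec, gain: KickGain):
    """Apply one inhibitory kick: θ → (θ + g·Δ(θ)) mod 2π.

    Accepts scalars or arrays.  Inputs outside [0, 2π) are wrapped first (a
    convenience; logged at debug level).
    """
    th = np.asarray(theta, dtype=float)
    if np.any(th < 0) or np.any(th >= TWO_PI):
        log.debug("apply_kick received phases outside [0, 2pi); wrapping")
        th = np.mod(th, TWO_PI)
    out = np.mod(th + gain.g * np.asarray(prc(th)), TWO_PI)
    return float(out) if np.isscalar(theta) else out


def wrap_phase_difference(theta1: float, theta2: float) -> PhaseDiffSample:
    """Return θ2 − θ1 wrapped into (−π, π]; the boundary maps to +π."""
    d = np.mod(theta2 - theta1, TWO_PI)  # in [0, 2π)
    phi = d if d <= np.pi else d - TWO_PI
    return PhaseDiffSample(phi=float(phi))


def wrap_to_pi(phi: np.ndarray | float):
    """Vectorized wrap of arbitrary angles into (−π, π] (tie → +π)."""
    d = np.mod(np.asarray(phi, dtype=float), TWO_PI)
    out = np.where(d <= np.pi, d, d - TWO_PI)
    return float(out) if np.isscalar(phi) else out


def phase_difference_histogram(
    samples: Sequence[PhaseDiffSample] | np.ndarray, n_bins: int
) -> PhaseDensity:
    """Weighted histogram of phase differences as a normalized density.

    Bins partition (−π, π] uniformly; returned values are probability mass
    per radian, so the trapezoid/Riemann integral over the circle is 1.
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    arr = np.asarray(samples, dtype=object)
    if arr.size == 0:
        raise ValueError("cannot build a histogram from zero samples")
    if isinstance(arr.flat[0], PhaseDiffSample):
        phis = np.array([s.phi for s in samples])
        weights = np.array([s.weight for s in samples])
    else:
        phis = np.asarray(samples, dtype=float)
        weights = None
    phis = wrap_to_pi(phis)
    # (−π, π]: shift the left-closed numpy convention by binning −φ
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    counts, _ = np.histogram(-phis, bins=edges, weights=weights)
    counts = counts[::-1].astype(float)
    width = TWO_PI / n_bins
    rho = counts / (counts.sum() * width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return PhaseDensity(grid=centers, rho=rho)


def circular_order_parameter(phis: Sequence[float] | np.ndarray) -> float:
    """Kuramoto order parameter R = |⟨exp(iφ)⟩| ∈ [0, 1].

    R = 1 means all angles coincide; R = 0 indicates complete phase
    dispersion (e.g. uniform or antipodal samples).
    """
    arr = np.asarray(phis, dtype=float)
    if arr.size == 0:
        raise ValueError("order parameter of an empty sample set is undefined")
    return float(np.abs(np.exp(1j * arr).mean()))


def phase_to_time(phi: float, frequency: float) -> float:
    """Convert a phase offset (rad) to a spike-time offset in milliseconds.

    For oscillators at 40 Hz, a phase difference of 0.75 rad corresponds to
    about 3 ms.
    """
    if frequency <= 0:
        raise ValueError(f"frequency must be > 0 Hz, got {frequency}")
    return phi / TWO_PI * 1000.0 / frequency
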