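# Methods

This note documents the models, the shipped parameter values and why they
were chosen, the numerical schemes, and the known limitations.  All defaults
live in dataclasses (`SpikingConfig`, `ReducedConfig`, `MLNetworkConfig`,
`GFunctional`) and in the YAML files under `src/stochsync/configs/`.

## 1. Phase model and PRC

Mitral cells are phase oscillators, θ̇ = ω, with ω = 2π·40 rad/s (gamma-band
firing; the package's conversion helper maps a 0.75 rad offset at 40 Hz to
≈ 3 ms of spike-time difference).  An impulsive inhibitory input at phase θ
shifts the oscillator to θ + g·Δ(θ).  Three PRC families are supported —
type 1 (1 − cos θ), type 2 (sin θ) and tabulated (periodic linear
interpolation of a CSV table).  The shipped default is the type-2 sine PRC
with unit amplitude, because measured mitral-cell PRCs are close to
sinusoidal; the kick magnitude g is a separate config value (0.3 in the
spiking and direct-feedback configs, 0.5 in the bistability config, where a
slightly stronger kick shortens the phase-mixing time and tightens the
match between simulation and averaged theory at no cost to the weak-kick
assumption).

Conventions: phases live in [0, 2π); phase differences in (−π, π] with the
tie at ±π mapped to +π.  Mitral spikes are upward crossings of 2π.  A kick
arriving in the same time step as a crossing is applied first, then the
crossing is tested; a negative kick that pushes a phase below zero does not
"un-spike" the cell.

## 2. Spiking feedback network

State per granule cell: synaptic drive s (decay τ_s, jump g_coupling per
presynaptic mitral spike), LIF voltage V with

    dV = (bias + β·s − V) dt/τ_m + σ √dt ξ,  V ≥ 1 → spike, V ← 0,

and shared kick rate λ (exponential relaxation to λ_min with time constant
τ_λ, jump `jump_a` per granule spike, clipped at λ_max).  Topologies: the
two-mitral/one-granule pair (`2m1g`), the three-mitral/three-granule ring
(`3m3g`, every pair of mitral cells shares one granule cell), and the
generalized all-pairs network.  Feedback wiring is reciprocal, as
dendrodendritic synapses are.

Shipped values and rationale:

| parameter | value | why |
|---|---|---|
| τ_m | 10 ms | fast granule membrane; sets the coincidence window together with τ_s |
| τ_s | 3–10 ms (default 5) | brief unitary IPSC-scale synapse; shorter = sharper coincidence detection |
| β | 4 | input gain placing a *single* mitral volley below threshold and a *coincident pair* at/above it for couplings g ≲ 1 — the coincidence-detector regime |
| σ | 1.8 s^(−1/2) | large enough that near-threshold volleys fire probabilistically, small enough that the free LIF almost never fires (so λ = λ_min exactly when uncoupled) |
| λ₁ = λ₂ | 15 /s | unshared background IPSC rate; dominates the baseline so the uncoupled pair is nearly asynchronous, and sets a phase-mixing time (~1 s) short enough for histograms to equilibrate in desk-scale runs |
| λ_min | 1.5 /s | baseline shared rate, well below the unshared rate (q ≈ 0.05 uncoupled, giving a nearly flat phase-difference histogram) |
| λ_max | 200 /s | ceiling of the shared population rate (q ≈ 0.87 when saturated) |
| jump_a, τ_λ | 5 /s, 1 s | a granule cell firing every gamma cycle drives λ to its ceiling within a few τ_λ |
| g_coupling | swept 0–2 | the experiment's control parameter |

The small-kick diffusion picture explains the uncoupled-histogram shape: the
stationary density is approximately ∝ 1/(q(1−cos φ) + (1−q)/2), so the
peak-to-trough ratio is ≈ 1 + 4q/(1−q) *independent of kick size*.  Keeping
the baseline q below ~0.1 is therefore what keeps the uncoupled histogram
nearly flat; at q = 1/3 (equal shared and unshared rates) the ratio would
already be 3.

Integration is a fixed-step hybrid scheme (numba-compiled): Euler–Maruyama
for the LIF, exact exponential decay for s and λ, Poisson kicks by thinning
on the step grid (dt = 0.1 ms, so λ_max·dt = 0.02), phases advanced exactly.
One integer seed makes a run bit-reproducible; independent simulation stages
derive their streams from a numpy `SeedSequence` spawn of the root seed.
Inside a single compiled kernel all noise sources draw from one counter
stream in a fixed order (per-source named streams would require separate
RNG states in the kernel; the run-level spawning preserves the
toggle-one-component-without-perturbing-others property at the granularity
of whole simulation calls).

The open-loop coincidence probe (`granule_rate_vs_phase`) replaces the
oscillators with two periodic pulse trains at the oscillation frequency, the
second delayed by φ/2π of a period, so the phase difference stays clamped
without disabling ω.  The shipped (g, τ_s) ladder — (0.5, 3 ms),
(0.55, 4 ms), (0.6, 5 ms) — spans the regime from strict coincidence
detection (antiphase count < 5 % of the in-phase count) to a shallower
dependence, while keeping a single volley subthreshold so the curve remains
monotone decreasing.  At couplings ≳ 1 with longer synapses a single volley
fires the cell by itself and the count becomes nearly independent of φ
(the closed-loop sweep uses that saturated regime deliberately at g = 2).

## 3. Morris–Lecar variant (times in ms)

The standard two-variable Morris–Lecar model with instantaneous Ca²⁺
activation and recovery variable w.  The shipped set (C = 20 µF/cm²,
g_L = 2, g_Ca = 4.4, g_K = 8 mS/cm², E_L = −60, E_Ca = 120, E_K = −84 mV,
v1 = −1.2, v2 = 18, v3 = 2, v4 = 30 mV, φ_w = 0.04 /ms) is the canonical
Hopf-regime parameterization; at the default drive I = 100 µA/cm² the cell
sits on a stable limit cycle of period ≈ 85 ms.  (The oscillation onset is
near I ≈ 94; network construction verifies sustained periodic firing and
raises otherwise.)

Kicks are square hyperpolarizing current pulses (25 µA/cm², 2 ms) rather
than instantaneous state jumps — the ML state is two-dimensional, so a
current pulse is the physical analogue of an IPSC.
`calibrate_pulse_phase_shift` measures the phase shift a single pulse causes
at mid-cycle (≈ 0.08 rad at the shipped amplitude) to relate pulse strength
to an equivalent PRC kick.  Spike detection: upward crossing of 0 mV with a
2 ms refractory hysteresis and linear interpolation of the crossing time
inside the step.

Integration is fixed-step RK4 (dt = 0.025 ms) with pulse currents held
constant within a step.  An order-consistency test verifies that halving dt
moves spike times by < 1 % of a period.  Fixed-step RK4 was chosen over an
adaptive integrator because the impulsive inputs arrive on the thinning
grid anyway and the dynamics are non-stiff at this dt; the convergence test
is the guard.

The closed loop uses the same granule machinery in ms units (τ_m = 10 ms,
β = 4, σ = 0.057 ms^(−1/2), τ_s = 4 ms, g_coupling = 0.6, λ_min = 0.5 /s,
λ_max = 40 /s, jump 4 /s, τ_λ = 1.5 s, independent pulse rate 10 /s per
cell).  In this regime the network is genuinely bistable: shared pulses at
the λ ceiling entrain the pair (voltage correlation → 1) which keeps the
coincidence-detecting granule cell firing, while at the λ floor the
independent pulses decorrelate the cells and the granule cell falls nearly
silent.  Noise flips the system between the two states every few seconds to
tens of seconds; a hysteresis classifier (switch up at 0.7·λ_max, down at
0.3·λ_max) counts the transitions.

## 4. Reduced event-driven map

Per event: waiting time Δt ~ Exp(λ+λ₁+λ₂); source chosen in proportion to
the rates (Gillespie); phases drift by ω·Δt and the kicked oscillator(s)
shift by g·Δ(θ).  The PRC is evaluated at the pre-drift phase by default
(`kick_eval = pre_drift`, matching the discrete map as written; a
`post_drift` switch exists because the difference is O(g·ω·Δt) and should be
explicit).  λ is held constant within an inter-event interval for rate
purposes and relaxed with the exact exponential formula at event boundaries.

Feedback functionals:

* **direct**: G(φ) = A·exp(κ(cos φ − 1)) with κ = 5 — a smooth even bump
  peaked at zero, standing in for the measured coincidence curve of the
  granule cell.
* **order parameter**: G = A·m̂^p with p = 2 and m̂ the cosine part of a
  trailing exponentially-weighted average of e^{iφ} (time constant
  τ_avg), clipped at zero.  The stationary φ density is even, so its first
  circular moment is real and m̂ is an unbiased estimator of the order
  parameter m = ∫cos(φ)ρ(φ)dφ; the modulus |⟨e^{iφ}⟩| was rejected as the
  estimator because its rectification bias (≈ 1/N_window in m²) acts as a
  spurious feedback floor that destroys the asynchronous state in exactly
  the regime the bistability analysis cares about.

Shipped regimes:

* direct (`fig5` analogue): λ₁ = λ₂ = 15 /s, λ_min = 1 /s, g = 0.3,
  τ_λ = 1 s, amplitude swept 5–80 /s.  The averaged theory has one stable
  fixed point at every amplitude and the simulated terminal-λ median matches
  it to a few per cent.
* order parameter (`fig6` analogue): λ₁ = λ₂ = 5 /s, λ_min = 0.3 /s,
  g = 0.5, A = 80 /s, τ_avg = 4800 s, τ_λ = 2400 s, initial λ uniform on
  [0.3, 25].  The averaged flow has three fixed points
  (0.40 / 2.43 / 20.09 per s, stable/unstable/stable).  The long averaging
  window is a deliberate choice deep in the averaging limit: the sampling
  variance of m̂ scales as τ_φ/τ_avg (τ_φ ≈ 1.5 s is the phase-mixing time at
  the low state), and because G amplifies m̂², window noise biases the
  asynchronous state upward unless τ_avg ≫ τ_φ·A/λ_low.  τ_avg = 4800 s puts
  that bias below ~10 %; τ_λ = τ_avg/2 keeps λ fast enough that trials
  starting above the unstable point are captured by the synchronous state
  before their window statistic has equilibrated.  These constants are
  abstract-model values chosen for a clean quantitative theory/simulation
  comparison, not biological time constants.

Event rates were also kept low relative to ω on purpose: the transfer
operator assumes the base phase is uniform and independent between events,
which holds when each waiting time wraps many periods (ω/rate ≫ 2π).  At
total rates ≳ 100 /s the residual phase correlation between events biases
the operator's order parameter by a few per cent, which the flat averaged
flow then amplifies into tens of per cent in the fixed-point location — the
shipped configs stay in the slow-rate regime where the measured
operator-vs-map mismatch in m is < 1 %.

## 5. Stationary density and averaging machinery

ρ(φ; q) is the fixed vector of the discretized transfer operator on a
midpoint grid of 256 bins over (−π, π]: for each source bin the three kick
moves (both kicked with probability q; each alone with probability (1−q)/2)
are marginalized over a uniform 256-point base-phase grid and scattered with
periodic linear interpolation, which conserves mass exactly (column sums
1 ± 1e−12).  The fixed vector is found by a direct null-space solve,
polished by power iteration until the L1 residual is below 1e−12 (an error
is raised otherwise).  At q = 0 the operator is circulant and the density is
uniform to 1e−8, an exact structural check.  A numba Monte-Carlo simulation
of the explicit two-phase map (1e6 events) cross-checks the operator to
L1 < 0.05 for q up to 0.9.

⟨G⟩(q) integrates the direct functional against ρ on the grid, or evaluates
A·m(q)^p in order-parameter mode.  Fixed points of
(λ_min − λ(q) + ⟨G⟩(q))/τ_λ are bracketed on a 400-point q grid capped at
q = 0.999 (the q → 1 asymptote of λ(q) = q(λ₁+λ₂)/(1−q) guarantees the flow
is eventually negative, so roots come in odd numbers with alternating
stability and at least one stable point — violations raise an internal
error).  Brackets are bisected to 1e−10 in q; stability is the sign of a
central-difference slope (h = 1e−5).

One empirical note: for the shipped bump functional the averaged map
⟨G⟩(q) is *convex* increasing over most of [0, 0.9] before saturating toward
its peak value in the delta-density limit, yet the direct mode remains
monostable at every amplitude tested because λ(q) diverges at q = 1 faster
than ⟨G⟩ can grow.  The tests assert monotone growth, saturation, and
monostability rather than concavity.

## 6. What the simulations do and do not show

The synthetic setting deliberately idealizes the biology: identical
oscillator frequencies (phase differences have no deterministic drift),
Poisson input streams, a single effective granule population summarized by
one rate variable λ, and no synaptic depression, facilitation, adaptation or
top-down modulation.  Passing tests therefore demonstrate the *mechanism* —
coincidence-detecting feedback amplifies stochastic synchrony, with
monostability under instantaneous feedback and bistability under
time-averaged order-parameter feedback — not a quantitative fit to any
recorded circuit.  Heterogeneous frequencies, conductance-based granule
cells and plastic synapses are out of scope.

Numerical edge cases: all-zero event rates are rejected; an empty
order-parameter window yields G = 0 with a warning; zero-variance
correlation windows are defined as 0 with a log message; λ is clipped to
[λ_min, λ_max] after every update; the event log preallocates from the rate
bounds and flags truncation rather than growing unboundedly.

## 7. Problem sizes

The test suite and the acceptance script run at desk scale on one CPU:
transfer operators on 256-point grids, 1e6-event Monte-Carlo densities,
closed-loop spiking runs of 250–700 s of simulated time (three seeds per
coupling), 100-trial reduced-map ensembles of 3e4 events (direct mode) and
50-trial ensembles of 3e6 events (order-parameter mode, whose time constants
are long), and a 300 s Morris–Lecar run.  These sizes were chosen so that
every Monte-Carlo comparison has sampling error comfortably below the
tolerance it is tested against.
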