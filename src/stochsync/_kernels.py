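"""Compiled inner loops (numba) shared by the simulation modules.

Everything here is deliberately free of Python objects: plain floats, ints
and ndarrays in, ndarrays out.  The public modules wrap these kernels with
typed dataclasses, unit handling and validation.  All kernels take an
explicit integer seed and are bit-reproducible for a fixed seed.

PRC codes: 1 = type1 (1 − cos θ), 2 = type2 (sin θ), 3 = tabulated.
Event codes in event logs: 0 = mitral spike, 1 = granule spike,
2 = shared kick (target = granule index), 3 = independent kick
(target = mitral index).
"""

import math

import numpy as np
from numba import njit

TWO_PI = 2.0 * math.pi


@njit(cache=False)
def _prc_eval(code, amp, table, theta):
    th = theta % TWO_PI
    if code == 1:
        return amp * (1.0 - math.cos(th))
    if code == 2:
        return amp * math.sin(th)
    # tabulated, periodic linear interpolation
    n = table.shape[0]
    x = th / TWO_PI * n
    i0 = int(x)
    frac = x - i0
    i1 = i0 + 1
    if i1 >= n:
        i1 = 0
    if i0 >= n:
        i0 = 0
    return amp * (table[i0] * (1.0 - frac) + table[i1] * frac)


@njit(cache=False)
def _wrap_pi(phi):
    """Wrap an angle into (−π, π]; the tie at ±π maps to +π."""
    d = phi % TWO_PI
    if d > math.pi:
        d -= TWO_PI
    return d


# ---------------------------------------------------------------------------
# Reduced event-driven map (Gillespie selection among three Poisson streams)
# ---------------------------------------------------------------------------


@njit(cache=False)
def reduced_map_run(
    th1,
    th2,
    lam,
    omega,
    prc_code,
    prc_amp,
    prc_table,
    kick_g,
    lam1,
    lam2,
    lam_min,
    lam_max,
    tau_lam,
    g_mode,  # 0 = direct peaked functional, 1 = order-parameter functional
    amplitude,
    kappa,
    p_exp,
    tau_avg,
    kick_pre_drift,
    n_events,
    record_every,
    seed,
):
    np.random.seed(seed)
    n_rec = n_events // record_every
    t_rec = np.empty(n_rec)
    phi_rec = np.empty(n_rec)
    lam_rec = np.empty(n_rec)
    t = 0.0
    # trailing exponentially-weighted first circular moment of φ; for the
    # even stationary densities of this map its cosine part is the order
    # parameter, and using the signed moment (rather than the modulus)
    # keeps the estimator unbiased in the asynchronous state
    ew_c = 0.0
    ew_s = 0.0
    j = 0
    for n in range(n_events):
        total = lam + lam1 + lam2
        dt = np.random.exponential(1.0 / total)
        u = np.random.random() * total
        if u < lam:
            k1 = 1.0
            k2 = 1.0
        elif u < lam + lam1:
            k1 = 1.0
            k2 = 0.0
        else:
            k1 = 0.0
            k2 = 1.0
        d = omega * dt
        if kick_pre_drift:
            d1 = _prc_eval(prc_code, prc_amp, prc_table, th1)
            d2 = _prc_eval(prc_code, prc_amp, prc_table, th2)
        else:
            d1 = _prc_eval(prc_code, prc_amp, prc_table, th1 + d)
            d2 = _prc_eval(prc_code, prc_amp, prc_table, th2 + d)
        th1 = (th1 + d + k1 * kick_g * d1) % TWO_PI
        th2 = (th2 + d + k2 * kick_g * d2) % TWO_PI
        phi = _wrap_pi(th2 - th1)
        if g_mode == 0:
            g_val = amplitude * math.exp(kappa * (math.cos(phi) - 1.0))
        else:
            bw = 1.0 - math.exp(-dt / tau_avg)
            ew_c = (1.0 - bw) * ew_c + bw * math.cos(phi)
            ew_s = (1.0 - bw) * ew_s + bw * math.sin(phi)
            m_hat = ew_c if ew_c > 0.0 else 0.0
            g_val = amplitude * m_hat**p_exp
        target = lam_min + g_val
        lam = target + (lam - target) * math.exp(-dt / tau_lam)
        if lam < lam_min:
            lam = lam_min
        elif lam > lam_max:
            lam = lam_max
        t += dt
        if (n + 1) % record_every == 0:
            t_rec[j] = t
            phi_rec[j] = phi
            lam_rec[j] = lam
            j += 1
    return t_rec[:j], phi_rec[:j], lam_rec[:j], th1, th2, lam, t


# ---------------------------------------------------------------------------
# Monte-Carlo sampler of the phase-difference chain at frozen common-input
# fraction q (used as an independent check of the transfer-operator density)
# ---------------------------------------------------------------------------


@njit(cache=False)
def mc_phase_difference_counts(
    q,
    prc_code,
    prc_amp,
    prc_table,
    kick_g,
    omega,
    total_rate,
    n_events,
    n_burn,
    n_bins,
    seed,
):
    np.random.seed(seed)
    th1 = np.random.random() * TWO_PI
    th2 = np.random.random() * TWO_PI
    counts = np.zeros(n_bins, dtype=np.int64)
    width = TWO_PI / n_bins
    for n in range(n_events + n_burn):
        dt = np.random.exponential(1.0 / total_rate)
        u = np.random.random()
        if u < q:
            k1 = 1.0
            k2 = 1.0
        elif u < q + 0.5 * (1.0 - q):
            k1 = 1.0
            k2 = 0.0
        else:
            k1 = 0.0
            k2 = 1.0
        d = omega * dt
        th1 = (th1 + d + k1 * kick_g * _prc_eval(prc_code, prc_amp, prc_table, th1)) % TWO_PI
        th2 = (th2 + d + k2 * kick_g * _prc_eval(prc_code, prc_amp, prc_table, th2)) % TWO_PI
        if n >= n_burn:
            phi = _wrap_pi(th2 - th1)
            idx = int((phi + math.pi) / width)
            if idx >= n_bins:
                idx = n_bins - 1
            if idx < 0:
                idx = 0
            counts[idx] += 1
    return counts


# ---------------------------------------------------------------------------
# Leaky integrate-and-fire granule cell
# ---------------------------------------------------------------------------


@njit(cache=False)
def lif_integrate(drive, dt, tau_m, bias, sigma, v0, seed):
    """Euler–Maruyama LIF driven by a precomputed input trace.

    dV = (−V + bias + drive) dt/τ_m + σ √dt ξ;  V ≥ 1 → spike, V ← 0.
    Returns the voltage trace and the spike step indices.
    """
    np.random.seed(seed)
    n = drive.shape[0]
    v = np.empty(n)
    spikes = np.empty(n, dtype=np.int64)
    n_spk = 0
    vv = v0
    sq = sigma * math.sqrt(dt)
    for i in range(n):
        vv += (bias + drive[i] - vv) * dt / tau_m + sq * np.random.normal()
        if vv >= 1.0:
            spikes[n_spk] = i
            n_spk += 1
            vv = 0.0
        v[i] = vv
    return v, spikes[:n_spk]


@njit(cache=False)
def lif_two_pulse_trains(
    period,
    lag,
    t_total,
    dt,
    jump,
    tau_s,
    beta,
    tau_m,
    bias,
    sigma,
    seed,
):
    """Open-loop coincidence-detection probe of the granule LIF.

    Two periodic input trains (period ``period`` s, second delayed by
    ``lag`` s) each increment their synaptic variable by ``jump``; the LIF
    integrates β(s1+s2).  Returns the spike count over ``t_total``.
    """
    np.random.seed(seed)
    n = int(t_total / dt)
    decay = math.exp(-dt / tau_s)
    sq = sigma * math.sqrt(dt)
    s1 = 0.0
    s2 = 0.0
    vv = 0.0
    count = 0
    next1 = 0.0
    next2 = lag % period
    t = 0.0
    for _ in range(n):
        s1 *= decay
        s2 *= decay
        if t >= next1:
            s1 += jump
            next1 += period
        if t >= next2:
            s2 += jump
            next2 += period
        vv += (bias + beta * (s1 + s2) - vv) * dt / tau_m + sq * np.random.normal()
        if vv >= 1.0:
            count += 1
            vv = 0.0
        t += dt
    return count


# ---------------------------------------------------------------------------
# Full spiking feedback network: phase-oscillator mitral cells, LIF granule
# cells, shared + independent Poisson kick streams
# ---------------------------------------------------------------------------


@njit(cache=False)
def phase_network_run(
    theta0,  # (nM,) initial phases
    omega,
    t_total,
    dt,
    prc_code,
    prc_amp,
    prc_table,
    kick_a,  # kick magnitude applied through the PRC
    g_coupling,  # mitral→granule synaptic increment
    tau_s,
    beta,  # LIF input gain on the summed synaptic drive
    tau_m,
    bias,
    sigma,
    lam_min,
    lam_max,
    tau_lam,
    jump_a,
    lam_indep,  # (nM,)
    w_mg,  # (nG, nM) granule ← mitral adjacency (0/1)
    w_fb,  # (nM, nG) mitral ← granule feedback (0/1)
    sample_every,
    seed,
    event_cap,
):
    np.random.seed(seed)
    n_m = theta0.shape[0]
    n_g = w_mg.shape[0]
    n_steps = int(t_total / dt)
    n_samp = n_steps // sample_every

    theta = theta0.copy()
    s = np.zeros(n_g)
    v = np.zeros(n_g)
    lam = np.full(n_g, lam_min)

    theta_samp = np.empty((n_samp, n_m))
    lam_samp = np.empty((n_samp, n_g))
    v_samp = np.empty((n_samp, n_g))
    t_samp = np.empty(n_samp)

    ev_t = np.empty(event_cap)
    ev_code = np.empty(event_cap, dtype=np.int8)
    ev_target = np.empty(event_cap, dtype=np.int32)
    n_ev = 0
    overflow = False

    kick_counts = np.zeros(n_m, dtype=np.int64)
    shared_routed = np.zeros(n_m, dtype=np.int64)
    indep_counts = np.zeros(n_m, dtype=np.int64)
    mitral_spikes = np.zeros(n_m, dtype=np.int64)
    granule_spikes = np.zeros(n_g, dtype=np.int64)

    s_decay = math.exp(-dt / tau_s)
    lam_decay = math.exp(-dt / tau_lam)
    sq = sigma * math.sqrt(dt)
    j = 0
    t = 0.0
    for step in range(n_steps):
        t += dt
        # 1) deterministic drift
        for i in range(n_m):
            theta[i] += omega * dt
        # 2) Poisson kick events (thinning on the step grid), applied to the
        #    drifted phase; a kick coinciding with a 2π crossing acts first
        for k in range(n_g):
            if np.random.random() < lam[k] * dt:
                if n_ev < event_cap:
                    ev_t[n_ev] = t
                    ev_code[n_ev] = 2
                    ev_target[n_ev] = k
                    n_ev += 1
                else:
                    overflow = True
                for i in range(n_m):
                    if w_fb[i, k] != 0:
                        theta[i] += kick_a * _prc_eval(
                            prc_code, prc_amp, prc_table, theta[i]
                        )
                        kick_counts[i] += 1
                        shared_routed[i] += 1
        for i in range(n_m):
            if np.random.random() < lam_indep[i] * dt:
                theta[i] += kick_a * _prc_eval(prc_code, prc_amp, prc_table, theta[i])
                kick_counts[i] += 1
                indep_counts[i] += 1
                if n_ev < event_cap:
                    ev_t[n_ev] = t
                    ev_code[n_ev] = 3
                    ev_target[n_ev] = i
                    n_ev += 1
                else:
                    overflow = True
        # 3) synaptic decay, then mitral spike detection (upward 2π crossing)
        for k in range(n_g):
            s[k] *= s_decay
        for i in range(n_m):
            if theta[i] >= TWO_PI:
                theta[i] -= TWO_PI
                if theta[i] >= TWO_PI:  # guard against pathological kicks
                    theta[i] = theta[i] % TWO_PI
                mitral_spikes[i] += 1
                if n_ev < event_cap:
                    ev_t[n_ev] = t
                    ev_code[n_ev] = 0
                    ev_target[n_ev] = i
                    n_ev += 1
                else:
                    overflow = True
                for k in range(n_g):
                    if w_mg[k, i] != 0:
                        s[k] += g_coupling
            elif theta[i] < 0.0:  # inhibitory kick past zero: no "uncrossing"
                theta[i] = theta[i] % TWO_PI
        # 4) LIF granule cells and shared-rate relaxation
        for k in range(n_g):
            v[k] += (bias + beta * s[k] - v[k]) * dt / tau_m + sq * np.random.normal()
            lam[k] = lam_min + (lam[k] - lam_min) * lam_decay
            if v[k] >= 1.0:
                v[k] = 0.0
                granule_spikes[k] += 1
                lam[k] += jump_a
                if n_ev < event_cap:
                    ev_t[n_ev] = t
                    ev_code[n_ev] = 1
                    ev_target[n_ev] = k
                    n_ev += 1
                else:
                    overflow = True
            if lam[k] > lam_max:
                lam[k] = lam_max
        # 5) sampling
        if (step + 1) % sample_every == 0 and j < n_samp:
            t_samp[j] = t
            for i in range(n_m):
                theta_samp[j, i] = theta[i]
            for k in range(n_g):
                lam_samp[j, k] = lam[k]
                v_samp[j, k] = v[k]
            j += 1
    return (
        t_samp[:j],
        theta_samp[:j],
        lam_samp[:j],
        v_samp[:j],
        ev_t[:n_ev],
        ev_code[:n_ev],
        ev_target[:n_ev],
        kick_counts,
        shared_routed,
        indep_counts,
        mitral_spikes,
        granule_spikes,
        overflow,
    )


# ---------------------------------------------------------------------------
# Morris-Lecar pair + LIF granule cell (all times in milliseconds)
# ---------------------------------------------------------------------------


@njit(cache=False)
def _ml_rhs(v, w, i_ext, c, g_l, e_l, g_ca, e_ca, g_k, e_k, v1, v2, v3, v4, phi_w):
    m_inf = 0.5 * (1.0 + math.tanh((v - v1) / v2))
    w_inf = 0.5 * (1.0 + math.tanh((v - v3) / v4))
    lam_w = phi_w * math.cosh((v - v3) / (2.0 * v4))
    dv = (i_ext - g_l * (v - e_l) - g_ca * m_inf * (v - e_ca) - g_k * w * (v - e_k)) / c
    dw = lam_w * (w_inf - w)
    return dv, dw


@njit(cache=False)
def ml_step_rk4(v, w, i_ext, dt, c, g_l, e_l, g_ca, e_ca, g_k, e_k, v1, v2, v3, v4, phi_w):
    """One fixed-step RK4 update of a Morris-Lecar cell (input held constant)."""
    k1v, k1w = _ml_rhs(v, w, i_ext, c, g_l, e_l, g_ca, e_ca, g_k, e_k, v1, v2, v3, v4, phi_w)
    k2v, k2w = _ml_rhs(v + 0.5 * dt * k1v, w + 0.5 * dt * k1w, i_ext, c, g_l, e_l, g_ca, e_ca, g_k, e_k, v1, v2, v3, v4, phi_w)
    k3v, k3w = _ml_rhs(v + 0.5 * dt * k2v, w + 0.5 * dt * k2w, i_ext, c, g_l, e_l, g_ca, e_ca, g_k, e_k, v1, v2, v3, v4, phi_w)
    k4v, k4w = _ml_rhs(v + dt * k3v, w + dt * k3w, i_ext, c, g_l, e_l, g_ca, e_ca, g_k, e_k, v1, v2, v3, v4, phi_w)
    vn = v + dt / 6.0 * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
    wn = w + dt / 6.0 * (k1w + 2.0 * k2w + 2.0 * k3w + k4w)
    if wn < 0.0:
        wn = 0.0
    elif wn > 1.0:
        wn = 1.0
    return vn, wn


@njit(cache=False)
def ml_free_run(v0, w0, i_app, t_total, dt, c, g_l, e_l, g_ca, e_ca, g_k, e_k, v1, v2, v3, v4, phi_w, thr, refrac):
    """Unperturbed ML cell; returns V trace and spike times (upward threshold
    crossings with a refractory hysteresis)."""
    n = int(t_total / dt)
    v_tr = np.empty(n)
    spikes = np.empty(n, dtype=np.float64)
    n_spk = 0
    v = v0
    w = w0
    last = -1e18
    t = 0.0
    for i in range(n):
        vp = v
        v, w = ml_step_rk4(v, w, i_app, dt, c, g_l, e_l, g_ca, e_ca, g_k, e_k, v1, v2, v3, v4, phi_w)
        t += dt
        if vp < thr <= v and t - last > refrac:
            # linear interpolation of the crossing inside the step
            t_cross = t - dt + dt * (thr - vp) / (v - vp)
            spikes[n_spk] = t_cross
            n_spk += 1
            last = t_cross
        v_tr[i] = v
    return v_tr, spikes[:n_spk]


@njit(cache=False)
def ml_single_pulse_run(
    v0,
    w0,
    i_app,
    t_total,
    dt,
    c,
    g_l,
    e_l,
    g_ca,
    e_ca,
    g_k,
    e_k,
    v1,
    v2,
    v3,
    v4,
    phi_w,
    thr,
    refrac,
    pulse_t,
    pulse_amp,
    pulse_dur,
):
    """Deterministic single ML cell with one square inhibitory pulse;
    returns spike times."""
    n = int(t_total / dt)
    spikes = np.empty(n, dtype=np.float64)
    n_spk = 0
    v = v0
    w = w0
    last = -1e18
    t = 0.0
    for _ in range(n):
        i_ext = i_app
        if pulse_t <= t < pulse_t + pulse_dur:
            i_ext -= pulse_amp
        vp = v
        v, w = ml_step_rk4(v, w, i_ext, dt, c, g_l, e_l, g_ca, e_ca, g_k, e_k, v1, v2, v3, v4, phi_w)
        t += dt
        if vp < thr <= v and t - last > refrac:
            t_cross = t - dt + dt * (thr - vp) / (v - vp)
            spikes[n_spk] = t_cross
            n_spk += 1
            last = t_cross
    return spikes[:n_spk]


@njit(cache=False)
def ml_network_run(
    v_init,  # (2,)
    w_init,  # (2,)
    i_app,
    t_total,
    dt,
    # ML parameters
    c,
    g_l,
    e_l,
    g_ca,
    e_ca,
    g_k,
    e_k,
    v1,
    v2,
    v3,
    v4,
    phi_w,
    thr,
    refrac,
    # inhibitory kick pulses
    pulse_amp,
    pulse_dur,
    # granule LIF (ms units)
    g_coupling,
    tau_s,
    beta,
    tau_m,
    bias,
    sigma,
    # shared rate dynamics (per ms)
    lam_min,
    lam_max,
    tau_lam,
    jump_a,
    lam_indep,
    sample_every,
    seed,
):
    np.random.seed(seed)
    n_steps = int(t_total / dt)
    n_samp = n_steps // sample_every
    v = v_init.copy()
    w = w_init.copy()
    pulse_left = np.zeros(2)
    s = 0.0
    vg = 0.0
    lam = lam_min
    last_spk = np.full(2, -1e18)

    t_samp = np.empty(n_samp)
    v_samp = np.empty((n_samp, 2))
    lam_samp = np.empty(n_samp)
    g_spikes = np.empty(int(t_total) + 16)
    n_gspk = 0

    s_decay = math.exp(-dt / tau_s)
    lam_decay = math.exp(-dt / tau_lam)
    sq = sigma * math.sqrt(dt)
    t = 0.0
    j = 0
    for step in range(n_steps):
        t += dt
        # kick events → brief square inhibitory current pulses
        if np.random.random() < lam * dt:
            pulse_left[0] = pulse_dur
            pulse_left[1] = pulse_dur
        for i in range(2):
            if np.random.random() < lam_indep * dt:
                pulse_left[i] = pulse_dur
        s *= s_decay
        for i in range(2):
            i_ext = i_app
            if pulse_left[i] > 0.0:
                i_ext -= pulse_amp
                pulse_left[i] -= dt
            vp = v[i]
            v[i], w[i] = ml_step_rk4(
                v[i], w[i], i_ext, dt, c, g_l, e_l, g_ca, e_ca, g_k, e_k, v1, v2, v3, v4, phi_w
            )
            if vp < thr <= v[i] and t - last_spk[i] > refrac:
                last_spk[i] = t
                s += g_coupling
        vg += (bias + beta * s - vg) * dt / tau_m + sq * np.random.normal()
        lam = lam_min + (lam - lam_min) * lam_decay
        if vg >= 1.0:
            vg = 0.0
            lam += jump_a
            if n_gspk < g_spikes.shape[0]:
                g_spikes[n_gspk] = t
                n_gspk += 1
        if lam > lam_max:
            lam = lam_max
        if (step + 1) % sample_every == 0 and j < n_samp:
            t_samp[j] = t
            v_samp[j, 0] = v[0]
            v_samp[j, 1] = v[1]
            lam_samp[j] = lam
            j += 1
    return t_samp[:j], v_samp[:j], lam_samp[:j], g_spikes[:n_gspk]
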