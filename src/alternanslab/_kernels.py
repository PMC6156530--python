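"""Numba-compiled numerical core of the reduced calcium-cycling myocyte model.

The model tracks six state variables::

    y = [ca_myo, ca_ss, ca_nsr, ca_jsr, ryr_open, camkii]

free calcium (mM) in the bulk myoplasm, junctional subspace, network SR and
junctional SR, plus the RyR release gate and CaMKII activity (both in [0, 1]).
All fluxes are expressed per millisecond in the *source/receiving compartment's
own volume* and converted with the relative volume ratios, so that total cell
calcium is conserved when the membrane fluxes (trigger influx, NCX-like efflux,
background influx) are switched off.

Everything in this module operates on flat float64 arrays; the user-facing
dataclasses live in :mod:`alternanslab.params` and :mod:`alternanslab.model`.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# Parameter-vector layout. params.ModelParameters.to_vector() follows this
# order; keep the two in sync (tests assert the round trip).
PARAM_ORDER = (
    "g_cal",          # 0  trigger-flux conductance multiplier (dimensionless)
    "i_cal_bar",      # 1  base trigger flux amplitude, mM/ms (SS volume)
    "tau_trig",       # 2  trigger pulse shape time constant, ms
    "k_cdi",          # 3  Ca-dependent inactivation half-sat on ca_ss, mM
    "k_trig",         # 4  RyR activation-drive scale on trigger flux, mM/ms
    "g_rel",          # 5  RyR release conductance, 1/ms
    "tau_act",        # 6  RyR gate activation time constant, ms
    "tau_rel",        # 7  RyR gate inactivation time constant, ms
    "h_rel",          # 8  Hill exponent of the JSR load-release function
    "k_rel",          # 9  load-release half-saturation, mM
    "g_leak_jsr",     # 10 JSR leak conductance, 1/ms
    "tau_tr",         # 11 NSR->JSR diffusion time constant, ms
    "tau_diff",       # 12 subspace->myoplasm diffusion time constant, ms
    "v_up",           # 13 maximal SERCA rate, mM/ms (myoplasm volume)
    "k_up",           # 14 SERCA half-saturation, mM
    "camkii_gain",    # 15 fractional uptake enhancement at full CaMKII activity
    "k_camkii",       # 16 CaMKII half-activation on ca_myo, mM
    "tau_camkii_on",  # 17 CaMKII activation time constant, ms
    "tau_camkii_off", # 18 CaMKII deactivation time constant, ms
    "g_ncx",          # 19 linear membrane extrusion conductance, 1/ms
    "ca_bg",          # 20 background calcium influx, mM/ms (myoplasm volume)
    "v_myo",          # 21 relative compartment volumes (myoplasm = reference)
    "v_ss",           # 22
    "v_nsr",          # 23
    "v_jsr",          # 24
    "beta_myo",       # 25 instantaneous-buffering factors (fraction free)
    "beta_ss",        # 26
    "beta_jsr",       # 27
    "apd_base",       # 28 APD coupling: base APD, ms
    "gamma_ca",       # 29 APD coupling gain, ms per mM of CaT amplitude
    "cat_ref",        # 30 reference CaT amplitude, mM
    "apd_min",        # 31 APD clamp, ms
    "apd_max",        # 32 APD clamp, ms
    "v_rest",         # 33 membrane template resting potential, mV
    "v_peak",         # 34 membrane template peak potential, mV
    "bcl",            # 35 default stimulation period, ms
    "nsr_max",        # 36 SERCA back-pressure: uptake vanishes as ca_nsr
                      #    approaches this luminal concentration, mM
    "n_trig",         # 37 trigger cooperativity: RyR drive scales as
                      #    (J_CaL/k_trig)^n_trig (dimensionless, >= 1)
    "k_tr_stall",     # 38 NSR->JSR refill stalls below this free-JSR level
                      #    (luminal-buffer-limited refilling), mM; 0 disables
    "h_tr_stall",     # 39 Hill exponent of the refill-stall factor
    "k_stall_gate",   # 40 RyR-gate activity at which the release-refractory
                      #    refill block half-engages (dimensionless)
)

NPARAMS = len(PARAM_ORDER)

IG_CAL, II_CAL_BAR, ITAU_TRIG, IK_CDI, IK_TRIG, IG_REL, ITAU_ACT, ITAU_REL, \
    IH_REL, IK_REL, IG_LEAK_JSR, ITAU_TR, ITAU_DIFF, IV_UP, IK_UP, \
    ICAMKII_GAIN, IK_CAMKII, ITAU_CAMKII_ON, ITAU_CAMKII_OFF, IG_NCX, ICA_BG, \
    IV_MYO, IV_SS, IV_NSR, IV_JSR, IBETA_MYO, IBETA_SS, IBETA_JSR, \
    IAPD_BASE, IGAMMA_CA, ICAT_REF, IAPD_MIN, IAPD_MAX, IV_REST, IV_PEAK, \
    IBCL, INSR_MAX, IN_TRIG, IK_TR_STALL, IH_TR_STALL, \
    IK_STALL_GATE = range(NPARAMS)

NSTATE = 6  # ca_myo, ca_ss, ca_nsr, ca_jsr, ryr_open, camkii

# clamp vector: [active flag, duration ms, t_peak ms, total (JSR-vol mM*ms),
#                onset delay ms]
NCLAMP = 5
NO_CLAMP = np.zeros(NCLAMP)

#: free-JSR scale (mM) below which a clamped release waveform tapers to zero
CLAMP_DEPLETION_SCALE = 0.02

# flux-vector layout used by flux recording
FLUX_ORDER = ("j_rel", "j_tr", "j_up", "j_diff", "j_leak_jsr", "j_cal_trigger")
NFLUX = len(FLUX_ORDER)

# per-beat metric columns produced by pace_kernel
METRIC_ORDER = (
    "ca_myo_pre", "ca_myo_max", "ca_myo_min",
    "ca_jsr_start", "ca_jsr_min", "ca_jsr_max",
    "ca_nsr_start", "ca_nsr_min", "ca_nsr_max",
    "camkii_start", "camkii_mean",
    "peak_jrel", "t_peak_jrel", "rel_duration_90",
    "integral_jrel", "integral_jtr", "integral_jup", "integral_jcal",
)
NMETRIC = len(METRIC_ORDER)


@njit(cache=True)
def triangle_flux_scalar(t, duration, t_peak, total, onset_delay):
    """Triangular release waveform, mM/ms in JSR volume; ``t`` is time since
    stimulus. Peak height 2*total/duration at ``onset_delay + t_peak``."""
    s = t - onset_delay
    if s <= 0.0 or s >= duration:
        return 0.0
    peak = 2.0 * total / duration
    if s <= t_peak:
        return peak * s / t_peak
    return peak * (duration - s) / (duration - t_peak)


@njit(cache=True)
def compute_fluxes(t, y, p, clamp, membrane_on, out):
    """Fill ``out`` (length NFLUX) with the instantaneous fluxes."""
    ca_myo = y[0]
    ca_ss = y[1]
    ca_nsr = y[2]
    ca_jsr = y[3]
    ryr = y[4]
    camkii = y[5]

    # trigger influx (I_CaL surrogate): pulse shape peaking at tau_trig with
    # calcium-dependent inactivation sensed on subspace calcium. Beyond
    # ~14 pulse time constants the pulse is below 3e-6 of peak: treated as 0.
    if membrane_on and 0.0 <= t < 14.0 * p[ITAU_TRIG]:
        x = t / p[ITAU_TRIG]
        pulse = x * math.exp(1.0 - x)
        cdi = p[IK_CDI] / (p[IK_CDI] + max(ca_ss, 0.0))
        j_cal = p[IG_CAL] * p[II_CAL_BAR] * pulse * cdi
    else:
        j_cal = 0.0

    if clamp[0] > 0.0:
        # clamped beat: native RyR release and JSR leak overridden; the
        # imposed flux tapers smoothly to zero as the JSR empties so an
        # over-large triangle cannot withdraw calcium that is not there
        j_rel = triangle_flux_scalar(t, clamp[1], clamp[2], clamp[3], clamp[4])
        if ca_jsr < CLAMP_DEPLETION_SCALE:
            j_rel *= max(ca_jsr, 0.0) / CLAMP_DEPLETION_SCALE
        j_leak = 0.0
    else:
        j_rel = p[IG_REL] * ryr * (ca_jsr - ca_ss)
        j_leak = p[IG_LEAK_JSR] * (ca_jsr - ca_myo)

    j_tr = (ca_nsr - ca_jsr) / p[ITAU_TR]
    if p[IK_TR_STALL] > 0.0:
        # release-refractory refilling: while release is active over a
        # depleted JSR, transferred calcium is not retained (it is
        # immediately re-released), so net refill is blocked; once release
        # ends the refill proceeds at full rate -- an emptied JSR always
        # recovers. Under a clamped release the block keys on the imposed
        # waveform instead of the (overridden) native gate.
        cjh_s = max(ca_jsr, 0.0) ** p[IH_TR_STALL]
        avail = cjh_s / (cjh_s + p[IK_TR_STALL] ** p[IH_TR_STALL])
        if clamp[0] > 0.0:
            act = max(j_rel, 0.0)
            gate_open = act / (act + 0.01)
        else:
            g2 = ryr * ryr
            gate_open = g2 / (g2 + p[IK_STALL_GATE] ** 2)
        j_tr *= 1.0 - gate_open * (1.0 - avail)
    j_diff = (ca_ss - ca_myo) / p[ITAU_DIFF]
    cm2 = max(ca_myo, 0.0) ** 2
    # SERCA with CaMKII enhancement and luminal back-pressure (uptake stalls
    # as the NSR approaches nsr_max)
    headroom = max(0.0, 1.0 - ca_nsr / p[INSR_MAX])
    j_up = (p[IV_UP] * (1.0 + p[ICAMKII_GAIN] * camkii) * headroom
            * cm2 / (cm2 + p[IK_UP] ** 2))

    out[0] = j_rel
    out[1] = j_tr
    out[2] = j_up
    out[3] = j_diff
    out[4] = j_leak
    out[5] = j_cal


@njit(cache=True)
def _rhs_buf(t, y, p, clamp, membrane_on, dy, f):
    """Time derivatives of the state vector with caller-provided flux
    scratch buffer ``f``; ``t`` is ms since the stimulus."""
    compute_fluxes(t, y, p, clamp, membrane_on, f)
    j_rel = f[0]
    j_tr = f[1]
    j_up = f[2]
    j_diff = f[3]
    j_leak = f[4]
    j_cal = f[5]

    v_myo = p[IV_MYO]
    v_ss = p[IV_SS]
    v_nsr = p[IV_NSR]
    v_jsr = p[IV_JSR]

    if membrane_on:
        j_mem = p[IG_NCX] * y[0] - p[ICA_BG]  # net efflux from myoplasm
    else:
        j_mem = 0.0

    dy[0] = p[IBETA_MYO] * (j_diff * v_ss / v_myo + j_leak * v_jsr / v_myo
                            - j_up - j_mem)
    dy[1] = p[IBETA_SS] * (j_cal + j_rel * v_jsr / v_ss - j_diff)
    dy[2] = j_up * v_myo / v_nsr - j_tr * v_jsr / v_nsr
    dy[3] = p[IBETA_JSR] * (j_tr - j_rel - j_leak)

    # RyR gate: opened by the trigger flux with luminal (JSR-load)
    # sensitization -- the steep load-release relationship -- and closing
    # with tau_rel
    if f[5] > 0.0:
        trig = (f[5] / p[IK_TRIG]) ** p[IN_TRIG]
        cj = max(y[3], 0.0)
        cjh = cj ** p[IH_REL]
        load = cjh / (cjh + p[IK_REL] ** p[IH_REL])
        drive = trig * load
        dy[4] = drive * (1.0 - y[4]) / p[ITAU_ACT] - y[4] / p[ITAU_REL]
    else:
        dy[4] = -y[4] / p[ITAU_REL]

    # CaMKII: slow activity variable driven by bulk calcium
    cm2 = max(y[0], 0.0) ** 2
    act = cm2 / (cm2 + p[IK_CAMKII] ** 2)
    dy[5] = act * (1.0 - y[5]) / p[ITAU_CAMKII_ON] - y[5] / p[ITAU_CAMKII_OFF]


@njit(cache=True)
def rhs(t, y, p, clamp, membrane_on, dy):
    """Time derivatives of the state vector (allocating convenience entry)."""
    f = np.empty(NFLUX)
    _rhs_buf(t, y, p, clamp, membrane_on, dy, f)


@njit(cache=True)
def _rk4_step(t, y, p, clamp, membrane_on, h, k1, k2, k3, k4, ytmp, f):
    _rhs_buf(t, y, p, clamp, membrane_on, k1, f)
    for i in range(NSTATE):
        ytmp[i] = y[i] + 0.5 * h * k1[i]
    _rhs_buf(t + 0.5 * h, ytmp, p, clamp, membrane_on, k2, f)
    for i in range(NSTATE):
        ytmp[i] = y[i] + 0.5 * h * k2[i]
    _rhs_buf(t + 0.5 * h, ytmp, p, clamp, membrane_on, k3, f)
    for i in range(NSTATE):
        ytmp[i] = y[i] + h * k3[i]
    _rhs_buf(t + h, ytmp, p, clamp, membrane_on, k4, f)
    for i in range(NSTATE):
        y[i] += h / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])


@njit(cache=True)
def integrate_span(y, p, clamp, membrane_on, t0, t1, dt):
    """Advance ``y`` in place from t0 to t1 with fixed RK4 steps (step count
    rounded so the span is hit exactly)."""
    n = max(1, int(round((t1 - t0) / dt)))
    h = (t1 - t0) / n
    k1 = np.empty(NSTATE)
    k2 = np.empty(NSTATE)
    k3 = np.empty(NSTATE)
    k4 = np.empty(NSTATE)
    ytmp = np.empty(NSTATE)
    for s in range(n):
        t = t0 + s * h
        _rk4_step(t, y, p, clamp, membrane_on, h, k1, k2, k3, k4, ytmp, f)


@njit(cache=True)
def pace_kernel(y, p, bcl, n_beats, dt, membrane_on, clamp, metrics):
    """Pace ``n_beats`` stimuli at interval ``bcl``, mutating ``y`` and filling
    ``metrics`` (n_beats x NMETRIC) with per-beat summaries.

    The stimulus of each beat is at beat-local t = 0; the beat spans [0, bcl).
    Flux integrals use the trapezoid rule on the integration grid.
    """
    n = max(1, int(round(bcl / dt)))
    h = bcl / n
    k1 = np.empty(NSTATE)
    k2 = np.empty(NSTATE)
    k3 = np.empty(NSTATE)
    k4 = np.empty(NSTATE)
    ytmp = np.empty(NSTATE)
    f = np.empty(NFLUX)
    jrel_buf = np.empty(n + 1)

    for b in range(n_beats):
        ca_myo_pre = y[0]
        ca_myo_max = y[0]
        ca_myo_min = y[0]
        ca_jsr_start = y[3]
        ca_jsr_min = y[3]
        ca_jsr_max = y[3]
        ca_nsr_start = y[2]
        ca_nsr_min = y[2]
        ca_nsr_max = y[2]
        camkii_start = y[5]
        camkii_sum = 0.0
        int_jrel = 0.0
        int_jtr = 0.0
        int_jup = 0.0
        int_jcal = 0.0
        compute_fluxes(0.0, y, p, clamp, membrane_on, f)
        prev_jrel = f[0]
        prev_jtr = f[1]
        prev_jup = f[2]
        prev_jcal = f[5]
        jrel_buf[0] = prev_jrel

        for s in range(n):
            t = s * h
            # after the step, f holds the stage-4 fluxes, an O(h^2)-accurate
            # stand-in for the end-of-step fluxes -- the same order as the
            # trapezoid rule itself
            _rk4_step(t, y, p, clamp, membrane_on, h, k1, k2, k3, k4, ytmp, f)
            int_jrel += 0.5 * h * (prev_jrel + f[0])
            int_jtr += 0.5 * h * (prev_jtr + f[1])
            int_jup += 0.5 * h * (prev_jup + f[2])
            int_jcal += 0.5 * h * (prev_jcal + f[5])
            prev_jrel = f[0]
            prev_jtr = f[1]
            prev_jup = f[2]
            prev_jcal = f[5]
            jrel_buf[s + 1] = f[0]
            if y[0] > ca_myo_max:
                ca_myo_max = y[0]
            if y[0] < ca_myo_min:
                ca_myo_min = y[0]
            if y[3] < ca_jsr_min:
                ca_jsr_min = y[3]
            if y[3] > ca_jsr_max:
                ca_jsr_max = y[3]
            if y[2] < ca_nsr_min:
                ca_nsr_min = y[2]
            if y[2] > ca_nsr_max:
                ca_nsr_max = y[2]
            camkii_sum += y[5]

        # release-shape features from the per-beat J_rel samples
        ipk = 0
        pk = jrel_buf[0]
        for s in range(n + 1):
            if jrel_buf[s] > pk:
                pk = jrel_buf[s]
                ipk = s
        t_peak = ipk * h
        # onset: first sample reaching 5% of peak; decay end: first sample
        # after the peak below 10% of peak ("90% release recovery")
        t_on = 0.0
        t_off = bcl
        if pk > 0.0:
            for s in range(n + 1):
                if jrel_buf[s] >= 0.05 * pk:
                    t_on = s * h
                    break
            for s in range(ipk, n + 1):
                if jrel_buf[s] < 0.1 * pk:
                    t_off = s * h
                    break
        dur90 = t_off - t_on

        m = metrics[b]
        m[0] = ca_myo_pre
        m[1] = ca_myo_max
        m[2] = ca_myo_min
        m[3] = ca_jsr_start
        m[4] = ca_jsr_min
        m[5] = ca_jsr_max
        m[6] = ca_nsr_start
        m[7] = ca_nsr_min
        m[8] = ca_nsr_max
        m[9] = camkii_start
        m[10] = camkii_sum / n
        m[11] = pk
        m[12] = t_peak
        m[13] = dur90
        m[14] = int_jrel
        m[15] = int_jtr
        m[16] = int_jup
        m[17] = int_jcal


@njit(cache=True)
def trace_kernel(y, p, bcl, n_beats, dt, stride, membrane_on, clamp,
                 times, states, fluxes):
    """Like pace_kernel but records the trajectory every ``stride`` steps.

    Output arrays must have length n_beats*ceil(n/stride) + 1; times are
    absolute (accumulating across beats). Returns the number of samples
    written.
    """
    n = max(1, int(round(bcl / dt)))
    h = bcl / n
    k1 = np.empty(NSTATE)
    k2 = np.empty(NSTATE)
    k3 = np.empty(NSTATE)
    k4 = np.empty(NSTATE)
    ytmp = np.empty(NSTATE)
    f = np.empty(NFLUX)
    idx = 0
    compute_fluxes(0.0, y, p, clamp, membrane_on, f)
    times[0] = 0.0
    for i in range(NSTATE):
        states[0, i] = y[i]
    for i in range(NFLUX):
        fluxes[0, i] = f[i]
    idx = 1
    for b in range(n_beats):
        for s in range(n):
            t = s * h
            _rk4_step(t, y, p, clamp, membrane_on, h, k1, k2, k3, k4, ytmp, f)
            if (s + 1) % stride == 0 or s == n - 1:
                tb = t + h
                compute_fluxes(tb, y, p, clamp, membrane_on, f)
                times[idx] = b * bcl + tb
                for i in range(NSTATE):
                    states[idx, i] = y[i]
                for i in range(NFLUX):
                    fluxes[idx, i] = f[i]
                idx += 1
    return idx


@njit(cache=True)
def clamped_beat_kernel(y, p, clamp, horizon, dt):
    """Single beat with the triangular release clamp (native release and JSR
    leak off). Returns (jsr_initial, jsr_final, refill_integral) where
    refill_integral is the integral of J_tr in JSR-volume mM*ms, accumulated
    with the same RK4 stage weights as the state update so that the JSR
    balance jsr_final - jsr_initial = beta_jsr*(int J_tr - int clamp) holds
    to the discretization itself (not merely to quadrature order).
    """
    n = max(1, int(round(horizon / dt)))
    h = horizon / n
    k1 = np.empty(NSTATE)
    k2 = np.empty(NSTATE)
    k3 = np.empty(NSTATE)
    k4 = np.empty(NSTATE)
    ytmp = np.empty(NSTATE)
    f = np.empty(NFLUX)
    jsr_initial = y[3]
    int_jtr = 0.0
    for s in range(n):
        t = s * h
        _rhs_buf(t, y, p, clamp, True, k1, f)
        j1 = f[1]
        for i in range(NSTATE):
            ytmp[i] = y[i] + 0.5 * h * k1[i]
        _rhs_buf(t + 0.5 * h, ytmp, p, clamp, True, k2, f)
        j2 = f[1]
        for i in range(NSTATE):
            ytmp[i] = y[i] + 0.5 * h * k2[i]
        _rhs_buf(t + 0.5 * h, ytmp, p, clamp, True, k3, f)
        j3 = f[1]
        for i in range(NSTATE):
            ytmp[i] = y[i] + h * k3[i]
        _rhs_buf(t + h, ytmp, p, clamp, True, k4, f)
        j4 = f[1]
        for i in range(NSTATE):
            y[i] += h / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        int_jtr += h / 6.0 * (j1 + 2.0 * j2 + 2.0 * j3 + j4)
    return jsr_initial, y[3], int_jtr
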