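"""Fixed-step integration kernel (numba) shared by all model variants.

One compiled loop integrates the three-compartment system with exponential-
Euler voltage/gating updates and exact two-state propagation of the alpha
conductance kernels, at a fixed time step (0.1 ms by default).  The ``mode``
flag selects the calcium mechanism:

  0  first-order kinetics (g_ca, m, h)
  1  reduced model: threshold-triggered fixed current waveform at the distal
     compartment, with a lockout for the duration of the waveform
  2  passive: no calcium at all

Inputs are pre-rendered onto the grid by Python code: per-step injected
currents, binned alpha-conductance impulse weights, delta-current charges and
delta-conductance integrals.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# parameter-vector layout (must match params.ModelParams field names)
PARAM_NAMES = (
    "C_d", "C_p", "C_s",
    "g_l_d", "g_l_p", "g_l_s",
    "U_l_d", "U_l_p", "U_l_s",
    "g_pd", "g_sp",
    "U_e", "U_i", "tau_e", "tau_i",
    "g_ca", "U_ca", "tau_m", "tau_h",
    "m_slope", "m_half", "h_slope", "h_half",
    "theta_base", "theta_plus", "tau_th", "t_ref", "V_peak", "g_ref",
    "J_ap_p", "J_ap_d", "tau_ap", "bap_delay_p", "bap_delay_d",
)
_IDX = {name: i for i, name in enumerate(PARAM_NAMES)}


def pack_params(params) -> np.ndarray:
    return np.array([getattr(params, name) for name in PARAM_NAMES], dtype=np.float64)


@njit(cache=True)
def _sigmoid(x):
    if x > 40.0:
        x = 40.0
    elif x < -40.0:
        x = -40.0
    return 1.0 / (1.0 + math.exp(x))


@njit(cache=True)
def run_core(dt, n, pv, exc_imp, inh_imp, i_inj, q_jump, g_jump,
             mode, wave, v_theta, spiking_enabled, v0, m0, h0, theta0):
    """Integrate n steps; sample 0 is the initial state.

    Returns (V, ica, ge, gi, theta, spike_steps, n_spikes, trig_steps, n_trig).
    """
    E = math.e
    C_d, C_p, C_s = pv[0], pv[1], pv[2]
    g_l_d, g_l_p, g_l_s = pv[3], pv[4], pv[5]
    U_l_d, U_l_p, U_l_s = pv[6], pv[7], pv[8]
    g_pd, g_sp = pv[9], pv[10]
    U_e, U_i, tau_e, tau_i = pv[11], pv[12], pv[13], pv[14]
    g_ca, U_ca, tau_m, tau_h = pv[15], pv[16], pv[17], pv[18]
    m_slope, m_half, h_slope, h_half = pv[19], pv[20], pv[21], pv[22]
    theta_base, theta_plus, tau_th = pv[23], pv[24], pv[25]
    t_ref, V_peak, g_ref = pv[26], pv[27], pv[28]
    J_ap_p, J_ap_d, tau_ap = pv[29], pv[30], pv[31]
    delay_p_steps = int(round(pv[32] / dt))
    delay_d_steps = int(round(pv[33] / dt))

    dec_e = math.exp(-dt / tau_e)
    dec_i = math.exp(-dt / tau_i)
    dec_ap = math.exp(-dt / tau_ap)
    dec_th = math.exp(-dt / tau_th)
    rel_m = 1.0 - math.exp(-dt / tau_m)
    rel_h = 1.0 - math.exp(-dt / tau_h)
    # step-average weights for the two-state alpha kernels:
    # mean over [0, dt] of (g + s*z)*exp(-s/tau) = ae1*g + ae2*z
    ae1 = tau_e * (1.0 - dec_e) / dt
    ae2 = (tau_e * tau_e * (1.0 - dec_e) - tau_e * dt * dec_e) / dt
    ai1 = tau_i * (1.0 - dec_i) / dt
    ai2 = (tau_i * tau_i * (1.0 - dec_i) - tau_i * dt * dec_i) / dt
    ap1 = tau_ap * (1.0 - dec_ap) / dt
    ap2 = (tau_ap * tau_ap * (1.0 - dec_ap) - tau_ap * dt * dec_ap) / dt

    V = np.empty((3, n))
    ica = np.zeros(n)
    ge_rec = np.empty((3, n))
    gi_rec = np.empty((3, n))
    theta_rec = np.empty(n)

    vd, vp, vs = v0[0], v0[1], v0[2]
    m, h, theta = m0, h0, theta0
    ge = np.zeros(3)
    ze = np.zeros(3)
    gi = np.zeros(3)
    zi = np.zeros(3)
    iap_p = 0.0
    zap_p = 0.0
    iap_d = 0.0
    zap_d = 0.0
    refrac = 0.0
    bap_p = np.zeros(n + delay_p_steps + delay_d_steps + 2)
    bap_d = np.zeros(n + delay_p_steps + delay_d_steps + 2)

    max_spikes = n // max(1, int(t_ref / dt)) + 16
    spike_steps = np.empty(max_spikes, dtype=np.int64)
    n_spikes = 0
    trig_steps = np.empty(max_spikes, dtype=np.int64)
    n_trig = 0
    wave_pos = -1
    n_wave = wave.shape[0]

    V[0, 0], V[1, 0], V[2, 0] = vd, vp, vs
    ge_rec[:, 0] = 0.0
    gi_rec[:, 0] = 0.0
    theta_rec[0] = theta
    if mode == 0:
        ica[0] = g_ca * m * h * (U_ca - vd)

    for k in range(1, n):
        # deliver binned impulses for this step
        for c in range(3):
            if exc_imp[c, k - 1] != 0.0:
                ze[c] += exc_imp[c, k - 1] * E / tau_e
            if inh_imp[c, k - 1] != 0.0:
                zi[c] += inh_imp[c, k - 1] * E / tau_i
        if bap_p[k - 1] != 0.0:
            zap_p += bap_p[k - 1]
        if bap_d[k - 1] != 0.0:
            zap_d += bap_d[k - 1]

        # calcium current sources at start-of-step state
        i_ca_k = 0.0
        g_ca_eff = 0.0
        if mode == 0:
            g_ca_eff = g_ca * m * h
            i_ca_k = g_ca_eff * (U_ca - vd)
        elif mode == 1 and wave_pos >= 0:
            i_ca_k = wave[wave_pos]

        # exponential-Euler voltage update with step-averaged conductances and
        # one corrector pass for the explicit compartment coupling
        ge_b0 = ae1 * ge[0] + ae2 * ze[0]
        ge_b1 = ae1 * ge[1] + ae2 * ze[1]
        ge_b2 = ae1 * ge[2] + ae2 * ze[2]
        gi_b0 = ai1 * gi[0] + ai2 * zi[0]
        gi_b1 = ai1 * gi[1] + ai2 * zi[1]
        gi_b2 = ai1 * gi[2] + ai2 * zi[2]
        iap_p_b = ap1 * iap_p + ap2 * zap_p
        iap_d_b = ap1 * iap_d + ap2 * zap_d

        G_d = g_l_d + ge_b0 + gi_b0 + g_pd + g_ca_eff
        G_p = g_l_p + ge_b1 + gi_b1 + g_pd + g_sp
        gl_s_now = g_ref if refrac > 0.0 else g_l_s
        G_s = gl_s_now + ge_b2 + gi_b2 + g_sp
        c_d = (g_l_d * U_l_d + ge_b0 * U_e + gi_b0 * U_i + g_ca_eff * U_ca
               + iap_d_b + i_inj[0, k - 1] + (i_ca_k if mode == 1 else 0.0))
        c_p = (g_l_p * U_l_p + ge_b1 * U_e + gi_b1 * U_i + iap_p_b + i_inj[1, k - 1])
        c_s = (gl_s_now * U_l_s + ge_b2 * U_e + gi_b2 * U_i + i_inj[2, k - 1])

        ed = math.exp(-G_d * dt / C_d)
        ep = math.exp(-G_p * dt / C_p)
        es = math.exp(-G_s * dt / C_s)

        # predictor: neighbor voltages frozen at step start
        vinf = (c_d + g_pd * (vp - U_l_p + U_l_d)) / G_d
        vd_new = vinf + (vd - vinf) * ed
        vinf = (c_p + g_pd * (vd - U_l_d + U_l_p) + g_sp * (vs - U_l_s + U_l_p)) / G_p
        vp_new = vinf + (vp - vinf) * ep
        vinf = (c_s + g_sp * (vp - U_l_p + U_l_s)) / G_s
        vs_new = vinf + (vs - vinf) * es

        # corrector: neighbors at the step midpoint estimate
        vd_mid = 0.5 * (vd + vd_new)
        vp_mid = 0.5 * (vp + vp_new)
        vs_mid = 0.5 * (vs + vs_new)
        vinf = (c_d + g_pd * (vp_mid - U_l_p + U_l_d)) / G_d
        vd_new = vinf + (vd - vinf) * ed
        vinf = (c_p + g_pd * (vd_mid - U_l_d + U_l_p) + g_sp * (vs_mid - U_l_s + U_l_p)) / G_p
        vp_new = vinf + (vp - vinf) * ep
        vinf = (c_s + g_sp * (vp_mid - U_l_p + U_l_s)) / G_s
        vs_new = vinf + (vs - vinf) * es

        # instantaneous (delta) inputs
        if g_jump[0, k] != 0.0:
            vd_new = U_e + (vd_new - U_e) * math.exp(-g_jump[0, k] / C_d)
        if g_jump[1, k] != 0.0:
            vp_new = U_e + (vp_new - U_e) * math.exp(-g_jump[1, k] / C_p)
        if g_jump[2, k] != 0.0:
            vs_new = U_e + (vs_new - U_e) * math.exp(-g_jump[2, k] / C_s)
        vd_new += q_jump[0, k] / C_d
        vp_new += q_jump[1, k] / C_p
        vs_new += q_jump[2, k] / C_s

        # gating relaxes toward sigmoids of the updated distal voltage
        if mode == 0:
            m += (_sigmoid(m_slope * (vd_new - m_half)) - m) * rel_m
            h += (_sigmoid(h_slope * (vd_new - h_half)) - h) * rel_h

        # adaptive threshold relaxation and refractory countdown
        theta = theta_base + (theta - theta_base) * dec_th
        refrac -= dt

        # exact propagation of alpha kernels
        for c in range(3):
            ge[c] = (ge[c] + dt * ze[c]) * dec_e
            ze[c] *= dec_e
            gi[c] = (gi[c] + dt * zi[c]) * dec_i
            zi[c] *= dec_i
        iap_p = (iap_p + dt * zap_p) * dec_ap
        zap_p *= dec_ap
        iap_d = (iap_d + dt * zap_d) * dec_ap
        zap_d *= dec_ap

        # reduced-model waveform trigger: upward crossing outside a waveform
        if mode == 1:
            if wave_pos >= 0:
                wave_pos += 1
                if wave_pos >= n_wave:
                    wave_pos = -1
            elif vd < v_theta and vd_new >= v_theta:
                wave_pos = 0
                if n_trig < max_spikes:
                    trig_steps[n_trig] = k
                    n_trig += 1

        # somatic spike: end-of-step crossing, ties count
        if spiking_enabled and refrac <= 0.0 and vs_new >= theta:
            vs_new = V_peak
            theta += theta_plus
            refrac = t_ref
            if n_spikes < max_spikes:
                spike_steps[n_spikes] = k
                n_spikes += 1
            kp = k + delay_p_steps  # impulse lands at time t_k + delay (read at index j-1)
            kd = k + delay_d_steps
            if kp < bap_p.shape[0]:
                bap_p[kp] += J_ap_p * E / tau_ap
            if kd < bap_d.shape[0]:
                bap_d[kd] += J_ap_d * E / tau_ap

        vd, vp, vs = vd_new, vp_new, vs_new
        V[0, k], V[1, k], V[2, k] = vd, vp, vs
        ica[k] = i_ca_k
        ge_rec[0, k] = ge[0]
        ge_rec[1, k] = ge[1]
        ge_rec[2, k] = ge[2]
        gi_rec[0, k] = gi[0]
        gi_rec[1, k] = gi[1]
        gi_rec[2, k] = gi[2]
        theta_rec[k] = theta

    return (V, ica, ge_rec, gi_rec, theta_rec,
            spike_steps[:n_spikes], trig_steps[:n_trig])
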