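"""Numba forward-Euler integration kernels.

Two families of kernels:

* ``network_chunk`` advances the full coupled E/I network by a chunk of
  steps (noise draws are pre-generated per chunk by the caller so that all
  randomness flows through seeded numpy Generators).
* ``rsp_batch`` / ``fs_batch`` integrate a batch of independent single
  cells (no background noise) under DC current, an optional shared injected
  current trace, tonic background conductances, and an optional train of
  synaptic conductance events — the workhorses of the virtual single-cell
  protocols and of the calibration bisections.

Synaptic conductances use per-pair-type rise/fall exponential accumulators
(R, F): every arriving spike adds its peak weight to both, each decays with
its own time constant, and the conductance is (F - R)/P with P the
bi-exponential peak normalizer.  This is algebraically identical to
superposing peak-normalized bi-exponential waveforms.

Parameter packing (float64 arrays):

rsp_par: [C, g_l, E_l, Delta_t, V_t, V_reset, V_spike, a_eff, tau_w1,
          b1_eff, tau_w2, b2_eff, exp_clamp]
fs_par:  [C, g_Na, g_Kdr, g_d, g_l, E_Na, E_K, E_l, theta_m, sigma_m,
          theta_h, sigma_h, theta_th, sigma_th, theta_n, sigma_n, theta_a,
          sigma_a, theta_b, sigma_b, tau_a, tau_b, tau_w, b_w, p_Na, p_Kdr,
          p_a, tau_h_base, tau_h_amp, tau_n_c0, tau_n_c1, tau_n_th1,
          tau_n_s1, tau_n_th2, tau_n_s2]
ou_par (per population): [mu_e, mu_i, E_e, E_i, dec_e, dec_i, dif_e, dif_i]
syn_par (per pair type): [dec_r, dec_f, invP, E_syn]
"""

from __future__ import annotations

import numpy as np
from numba import njit

_F = "float64"


@njit(cache=True, inline="always")
def _ipow(x, k):
    r = 1.0
    for _ in range(k):
        r *= x
    return r


@njit(cache=True, inline="always")
def _sig(V, theta, sigma):
    return 1.0 / (1.0 + np.exp(-(V - theta) / sigma))




@njit(cache=True, inline="always")
def _lut(tab, col, V, v_lo, inv_dv, n_tab):
    x = (V - v_lo) * inv_dv
    if x <= 0.0:
        return tab[0, col]
    if x >= n_tab - 1:
        return tab[n_tab - 1, col]
    i = int(x)
    f = x - i
    return tab[i, col] * (1.0 - f) + tab[i + 1, col] * f


@njit(cache=True, inline="always")
def _lut1(tab, V, v_lo, inv_dv, n_tab):
    x = (V - v_lo) * inv_dv
    if x <= 0.0:
        return tab[0]
    if x >= n_tab - 1:
        return tab[n_tab - 1]
    i = int(x)
    f = x - i
    return tab[i] * (1.0 - f) + tab[i + 1] * f


@njit(cache=True, fastmath=True)
def network_chunk(
    n_steps,
    dt,
    step_offset,
    # RSP state
    VE, w1, w2, seE, siE, dcE,
    # FS state
    VI, hI, nI, aI, bI, wI, armedI, seI, siI, dcI,
    # parameters
    rsp_par, fs_par, rsp_exp_tab, fs_tab, v_lo, inv_dv, ouE, ouI,
    # synaptic accumulators, E targets then I targets
    Ree, Fee, Rie, Fie, Rei, Fei, Rii, Fii,
    syn_ee, syn_ie, syn_ei, syn_ii,
    # connectivity CSR (pre -> list of (post, weight))
    ee_ptr, ee_post, ee_w,
    ei_ptr, ei_post, ei_w,
    ie_ptr, ie_post, ie_w,
    ii_ptr, ii_post, ii_w,
    # I->E delay ring buffer: shape (n_buf, N_E); d_ie in steps
    dbuf, d_ie, buf_pos,
    # pre-drawn standard normals: (n_steps, N_E, 2) and (n_steps, N_I, 2)
    zE, zI,
    # spike output
    spike_t, spike_cell, spike_pop, spike_count,
    # trace recording
    rec_decim, selE, selI, recV_E, recV_I, rec_gE, rec_meanVE,
):
    N_E = VE.shape[0]
    N_I = VI.shape[0]
    n_buf = dbuf.shape[0]

    C_E, gl_E, El_E, Dt_E, Vt_E, Vre_E, Vsp_E = (
        rsp_par[0], rsp_par[1], rsp_par[2], rsp_par[3], rsp_par[4], rsp_par[5], rsp_par[6],
    )
    a_E, tw1, b1_E, tw2, b2_E, clamp_E = (
        rsp_par[7], rsp_par[8], rsp_par[9], rsp_par[10], rsp_par[11], rsp_par[12],
    )
    invC_E = 1.0 / C_E
    inv_tw1 = 1.0 / tw1
    inv_tw2 = 1.0 / tw2
    invDt_E = 1.0 / Dt_E
    glDt_E = gl_E * Dt_E

    C_I, gNa, gKdr, gd, gl_I, ENa, EK, El_I = (
        fs_par[0], fs_par[1], fs_par[2], fs_par[3], fs_par[4], fs_par[5], fs_par[6], fs_par[7],
    )
    th_m, s_m, th_h, s_h, th_th, s_th, th_n, s_n = (
        fs_par[8], fs_par[9], fs_par[10], fs_par[11], fs_par[12], fs_par[13], fs_par[14], fs_par[15],
    )
    th_a, s_a, th_b, s_b, tau_a, tau_b, tau_wI, b_wI = (
        fs_par[16], fs_par[17], fs_par[18], fs_par[19], fs_par[20], fs_par[21], fs_par[22], fs_par[23],
    )
    p_Na = int(fs_par[24]); p_Kdr = int(fs_par[25]); p_a = int(fs_par[26])
    tauh_base, tauh_amp = fs_par[27], fs_par[28]
    tn_c0, tn_c1, tn_th1, tn_s1, tn_th2, tn_s2 = (
        fs_par[29], fs_par[30], fs_par[31], fs_par[32], fs_par[33], fs_par[34],
    )
    invC_I = 1.0 / C_I
    inv_tau_a = 1.0 / tau_a
    inv_tau_b = 1.0 / tau_b
    inv_tau_wI = 1.0 / tau_wI

    dec_r_ee, dec_f_ee, invP_ee, Es_ee = syn_ee[0], syn_ee[1], syn_ee[2], syn_ee[3]
    dec_r_ie, dec_f_ie, invP_ie, Es_ie = syn_ie[0], syn_ie[1], syn_ie[2], syn_ie[3]
    dec_r_ei, dec_f_ei, invP_ei, Es_ei = syn_ei[0], syn_ei[1], syn_ei[2], syn_ei[3]
    dec_r_ii, dec_f_ii, invP_ii, Es_ii = syn_ii[0], syn_ii[1], syn_ii[2], syn_ii[3]

    cap = spike_t.shape[0]
    count = spike_count[0]
    pos = buf_pos
    n_tab = fs_tab.shape[0]
    n_tab_r = rsp_exp_tab.shape[0]

    for i in range(n_steps):
        gstep = step_offset + i
        t_next = (gstep + 1) * dt

        # flush delayed I->E arrivals scheduled for this step
        for j in range(N_E):
            pend = dbuf[pos, j]
            if pend != 0.0:
                Rie[j] += pend
                Fie[j] += pend
                dbuf[pos, j] = 0.0

        # --- RSP update
        for j in range(N_E):
            V = VE[j]
            g_ee = (Fee[j] - Ree[j]) * invP_ee
            g_ie = (Fie[j] - Rie[j]) * invP_ie
            I = -g_ee * (V - Es_ee) - g_ie * (V - Es_ie)
            I += -seE[j] * (V - ouE[2]) - siE[j] * (V - ouE[3]) + dcE[j]
            Iexp = _lut1(rsp_exp_tab, V, v_lo, inv_dv, n_tab_r)
            dV = (-gl_E * (V - El_E) + Iexp - w1[j] - w2[j] + I) * invC_E
            dw1 = (a_E * (V - El_E) - w1[j]) * inv_tw1
            w1[j] += dt * dw1
            w2[j] -= dt * w2[j] * inv_tw2
            Vn = V + dt * dV
            if Vn < -120.0:
                Vn = -120.0
            VE[j] = Vn

        # --- FS update
        for j in range(N_I):
            V = VI[j]
            g_ei = (Fei[j] - Rei[j]) * invP_ei
            g_ii = (Fii[j] - Rii[j]) * invP_ii
            I = -g_ei * (V - Es_ei) - g_ii * (V - Es_ii)
            I += -seI[j] * (V - ouI[2]) - siI[j] * (V - ouI[3]) + dcI[j]
            INa = gNa * _lut(fs_tab, 0, V, v_lo, inv_dv, n_tab) * hI[j] * (V - ENa)
            IK = gKdr * _ipow(nI[j], p_Kdr) * (V - EK)
            ID = gd * _ipow(aI[j], p_a) * bI[j] * (V - EK)
            Il = gl_I * (V - El_I)
            dV = (-INa - IK - ID - Il - wI[j] + I) * invC_I
            hI[j] += dt * (_lut(fs_tab, 1, V, v_lo, inv_dv, n_tab) - hI[j]) \
                * _lut(fs_tab, 2, V, v_lo, inv_dv, n_tab)
            nI[j] += dt * (_lut(fs_tab, 3, V, v_lo, inv_dv, n_tab) - nI[j]) \
                * _lut(fs_tab, 4, V, v_lo, inv_dv, n_tab)
            aI[j] += dt * (_lut(fs_tab, 5, V, v_lo, inv_dv, n_tab) - aI[j]) * inv_tau_a
            bI[j] += dt * (_lut(fs_tab, 6, V, v_lo, inv_dv, n_tab) - bI[j]) * inv_tau_b
            wI[j] -= dt * wI[j] * inv_tau_wI
            Vn = V + dt * dV
            if Vn < -120.0:
                Vn = -120.0
            elif Vn > 80.0:
                Vn = 80.0
            VI[j] = Vn

        # --- OU updates (exact discretization, pre-drawn normals)
        for j in range(N_E):
            seE[j] = ouE[0] + (seE[j] - ouE[0]) * ouE[4] + ouE[6] * zE[i, j, 0]
            siE[j] = ouE[1] + (siE[j] - ouE[1]) * ouE[5] + ouE[7] * zE[i, j, 1]
        for j in range(N_I):
            seI[j] = ouI[0] + (seI[j] - ouI[0]) * ouI[4] + ouI[6] * zI[i, j, 0]
            siI[j] = ouI[1] + (siI[j] - ouI[1]) * ouI[5] + ouI[7] * zI[i, j, 1]

        # --- RSP spikes: reset + propagate
        for j in range(N_E):
            if VE[j] > Vsp_E:
                VE[j] = Vre_E
                w1[j] += b1_E
                w2[j] += b2_E
                if count < cap:
                    spike_t[count] = t_next
                    spike_cell[count] = j
                    spike_pop[count] = 0
                    count += 1
                for k in range(ee_ptr[j], ee_ptr[j + 1]):
                    tgt = ee_post[k]
                    Ree[tgt] += ee_w[k]
                    Fee[tgt] += ee_w[k]
                for k in range(ei_ptr[j], ei_ptr[j + 1]):
                    tgt = ei_post[k]
                    Rei[tgt] += ei_w[k]
                    Fei[tgt] += ei_w[k]

        # --- FS spikes: upward zero-crossing with hysteresis
        for j in range(N_I):
            V = VI[j]
            if armedI[j] and V >= 0.0:
                armedI[j] = False
                if count < cap:
                    spike_t[count] = t_next
                    spike_cell[count] = j
                    spike_pop[count] = 1
                    count += 1
                wI[j] += b_wI
                slot = (pos + d_ie) % n_buf
                for k in range(ie_ptr[j], ie_ptr[j + 1]):
                    dbuf[slot, ie_post[k]] += ie_w[k]
                for k in range(ii_ptr[j], ii_ptr[j + 1]):
                    tgt = ii_post[k]
                    Rii[tgt] += ii_w[k]
                    Fii[tgt] += ii_w[k]
            elif V < 0.0:
                armedI[j] = True

        # --- decay synaptic accumulators to the next step
        for j in range(N_E):
            Ree[j] *= dec_r_ee
            Fee[j] *= dec_f_ee
            Rie[j] *= dec_r_ie
            Fie[j] *= dec_f_ie
        for j in range(N_I):
            Rei[j] *= dec_r_ei
            Fei[j] *= dec_f_ei
            Rii[j] *= dec_r_ii
            Fii[j] *= dec_f_ii

        # --- recording
        if (gstep + 1) % rec_decim == 0:
            r = (gstep + 1) // rec_decim - 1
            if 0 <= r < recV_E.shape[0]:
                for k in range(selE.shape[0]):
                    recV_E[r, k] = VE[selE[k]]
                for k in range(selI.shape[0]):
                    recV_I[r, k] = VI[selI[k]]
                sge = 0.0
                sgi = 0.0
                sv = 0.0
                for j in range(N_E):
                    sge += (Fee[j] - Ree[j]) * invP_ee
                    sgi += (Fie[j] - Rie[j]) * invP_ie
                    sv += VE[j]
                rec_gE[r, 0] = sge / N_E
                rec_gE[r, 1] = sgi / N_E
                rec_meanVE[r] = sv / N_E

        pos = (pos + 1) % n_buf

    spike_count[0] = count
    return pos


@njit(cache=True, fastmath=True)
def rsp_batch(
    n_steps, dt,
    V, w1, w2, dc,
    Istim, istim_scale,
    ge0, gi0, E_e, E_i,
    ev_steps, ev_gpeak,
    syn_dec_r, syn_dec_f, syn_invP, syn_Esyn,
    rsp_par, rsp_exp_tab, v_lo, inv_dv,
    rec_decim, recV,
    spike_t, spike_cell, spike_count,
):
    """Batch of independent RSP cells.  ``Istim`` is a shared per-step
    current trace (may be length 0), scaled per cell by ``istim_scale``;
    ``ev_steps``/``ev_gpeak`` schedule synaptic conductance events (shared
    step indices, per-cell peaks) on one bi-exponential synapse."""
    n = V.shape[0]
    C, gl, El, Dt, Vt, Vre, Vsp = (
        rsp_par[0], rsp_par[1], rsp_par[2], rsp_par[3], rsp_par[4], rsp_par[5], rsp_par[6],
    )
    a_, tw1, b1, tw2, b2, clamp = (
        rsp_par[7], rsp_par[8], rsp_par[9], rsp_par[10], rsp_par[11], rsp_par[12],
    )
    invC = 1.0 / C
    n_tab_r = rsp_exp_tab.shape[0]
    R = np.zeros(n)
    F = np.zeros(n)
    has_stim = Istim.shape[0] > 0
    n_ev = ev_steps.shape[0]
    ev_ptr = 0
    cap = spike_t.shape[0]
    count = 0
    for i in range(n_steps):
        while ev_ptr < n_ev and ev_steps[ev_ptr] == i:
            for j in range(n):
                R[j] += ev_gpeak[j]
                F[j] += ev_gpeak[j]
            ev_ptr += 1
        stim = Istim[i] if has_stim else 0.0
        for j in range(n):
            Vj = V[j]
            g_syn = (F[j] - R[j]) * syn_invP
            I = -g_syn * (Vj - syn_Esyn) - ge0[j] * (Vj - E_e) - gi0[j] * (Vj - E_i)
            I += dc[j] + stim * istim_scale[j]
            Iexp = _lut1(rsp_exp_tab, Vj, v_lo, inv_dv, n_tab_r)
            dV = (-gl * (Vj - El) + Iexp - w1[j] - w2[j] + I) * invC
            w1[j] += dt * (a_ * (Vj - El) - w1[j]) / tw1
            w2[j] -= dt * w2[j] / tw2
            V[j] = Vj + dt * dV
            if V[j] > Vsp:
                V[j] = Vre
                w1[j] += b1
                w2[j] += b2
                if count < cap:
                    spike_t[count] = (i + 1) * dt
                    spike_cell[count] = j
                    count += 1
        for j in range(n):
            R[j] *= syn_dec_r
            F[j] *= syn_dec_f
        if rec_decim > 0:
            if (i + 1) % rec_decim == 0:
                r = (i + 1) // rec_decim - 1
                if r < recV.shape[1]:
                    for j in range(n):
                        recV[j, r] = V[j]
    spike_count[0] = count


@njit(cache=True, fastmath=True)
def fs_batch(
    n_steps, dt,
    V, h, nn, aa, bb, w, armed, dc,
    Istim, istim_scale,
    ge0, gi0, E_e, E_i,
    ev_steps, ev_gpeak,
    syn_dec_r, syn_dec_f, syn_invP, syn_Esyn,
    fs_par, fs_tab, v_lo, inv_dv,
    rec_decim, recV,
    spike_t, spike_cell, spike_count,
):
    """Batch of independent FS cells (same conventions as rsp_batch)."""
    n = V.shape[0]
    C, gNa, gKdr, gd, gl, ENa, EK, El = (
        fs_par[0], fs_par[1], fs_par[2], fs_par[3], fs_par[4], fs_par[5], fs_par[6], fs_par[7],
    )
    th_m, s_m, th_h, s_h, th_th, s_th, th_n, s_n = (
        fs_par[8], fs_par[9], fs_par[10], fs_par[11], fs_par[12], fs_par[13], fs_par[14], fs_par[15],
    )
    th_a, s_a, th_b, s_b, tau_a, tau_b, tau_w, b_w = (
        fs_par[16], fs_par[17], fs_par[18], fs_par[19], fs_par[20], fs_par[21], fs_par[22], fs_par[23],
    )
    p_Na = int(fs_par[24]); p_Kdr = int(fs_par[25]); p_a = int(fs_par[26])
    tauh_base, tauh_amp = fs_par[27], fs_par[28]
    tn_c0, tn_c1, tn_th1, tn_s1, tn_th2, tn_s2 = (
        fs_par[29], fs_par[30], fs_par[31], fs_par[32], fs_par[33], fs_par[34],
    )
    invC = 1.0 / C
    n_tab = fs_tab.shape[0]
    R = np.zeros(n)
    F = np.zeros(n)
    has_stim = Istim.shape[0] > 0
    n_ev = ev_steps.shape[0]
    ev_ptr = 0
    cap = spike_t.shape[0]
    count = 0
    for i in range(n_steps):
        while ev_ptr < n_ev and ev_steps[ev_ptr] == i:
            for j in range(n):
                R[j] += ev_gpeak[j]
                F[j] += ev_gpeak[j]
            ev_ptr += 1
        stim = Istim[i] if has_stim else 0.0
        for j in range(n):
            Vj = V[j]
            g_syn = (F[j] - R[j]) * syn_invP
            I = -g_syn * (Vj - syn_Esyn) - ge0[j] * (Vj - E_e) - gi0[j] * (Vj - E_i)
            I += dc[j] + stim * istim_scale[j]
            INa = gNa * _lut(fs_tab, 0, Vj, v_lo, inv_dv, n_tab) * h[j] * (Vj - ENa)
            IK = gKdr * _ipow(nn[j], p_Kdr) * (Vj - EK)
            ID = gd * _ipow(aa[j], p_a) * bb[j] * (Vj - EK)
            dV = (-INa - IK - ID - gl * (Vj - El) - w[j] + I) * invC
            h[j] += dt * (_lut(fs_tab, 1, Vj, v_lo, inv_dv, n_tab) - h[j]) \
                * _lut(fs_tab, 2, Vj, v_lo, inv_dv, n_tab)
            nn[j] += dt * (_lut(fs_tab, 3, Vj, v_lo, inv_dv, n_tab) - nn[j]) \
                * _lut(fs_tab, 4, Vj, v_lo, inv_dv, n_tab)
            aa[j] += dt * (_lut(fs_tab, 5, Vj, v_lo, inv_dv, n_tab) - aa[j]) / tau_a
            bb[j] += dt * (_lut(fs_tab, 6, Vj, v_lo, inv_dv, n_tab) - bb[j]) / tau_b
            w[j] -= dt * w[j] / tau_w
            V[j] = Vj + dt * dV
            if armed[j] and V[j] >= 0.0:
                armed[j] = False
                w[j] += b_w
                if count < cap:
                    spike_t[count] = (i + 1) * dt
                    spike_cell[count] = j
                    count += 1
            elif V[j] < 0.0:
                armed[j] = True
        for j in range(n):
            R[j] *= syn_dec_r
            F[j] *= syn_dec_f
        if rec_decim > 0:
            if (i + 1) % rec_decim == 0:
                r = (i + 1) // rec_decim - 1
                if r < recV.shape[1]:
                    for j in range(n):
                        recV[j, r] = V[j]
    spike_count[0] = count
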