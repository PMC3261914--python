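"""Batched single-cell simulations (wrappers over the numba kernels).

These drive the virtual single-cell experiments (f-I, impedance, recovery
after inhibition, spike latency) and the noise-free calibration bisections
(spike threshold, per-cell DC).  Cells in a batch are independent: each has
its own DC current, tonic background conductances, and synaptic-event
amplitude, but shares the time grid, injected-current trace, event times
and synapse kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .config import E_E, E_I, FSParams, RSPParams, SynapseKinetics
from .neurons import boltzmann, fs_steady_gates, fs_tau_h, fs_tau_n
from .synapses import biexp_norm

# voltage grid of the gating/exponential lookup tables used by the kernels
V_LO, V_HI, DV = -130.0, 80.0, 0.02


def rsp_exp_table(p: RSPParams) -> np.ndarray:
    """Tabulated exponential spike-initiation current g_l*Delta_t*exp(...)
    (pA) on the kernel voltage grid, with the overflow clamp applied."""
    V = np.arange(V_LO, V_HI + DV / 2, DV)
    arg = np.minimum((V - p.V_t) / p.Delta_t, p.exp_clamp)
    return p.g_l * p.Delta_t * np.exp(arg)


def fs_gate_tables(p: FSParams) -> np.ndarray:
    """Tabulated FS gating functions on the kernel voltage grid, columns:
    m_inf^p_Na, h_inf, 1/tau_h, n_inf, 1/tau_n, a_inf, b_inf."""
    V = np.arange(V_LO, V_HI + DV / 2, DV)
    h_inf, n_inf, a_inf, b_inf = fs_steady_gates(V, p)
    tab = np.column_stack(
        [
            boltzmann(V, p.theta_m, p.sigma_m) ** p.p_Na,
            h_inf,
            1.0 / fs_tau_h(V, p),
            n_inf,
            1.0 / fs_tau_n(V, p),
            a_inf,
            b_inf,
        ]
    )
    return np.ascontiguousarray(tab)


def pack_rsp(p: RSPParams) -> np.ndarray:
    return np.array(
        [p.C_pF, p.g_l, p.E_l, p.Delta_t, p.V_t, p.V_reset, p.V_spike,
         p.a_eff, p.tau_w1, p.b1_eff, p.tau_w2, p.b2_eff, p.exp_clamp],
        dtype=np.float64,
    )


def pack_fs(p: FSParams) -> np.ndarray:
    return np.array(
        [p.C_pF, p.g_Na, p.g_Kdr, p.g_d, p.g_l, p.E_Na, p.E_K, p.E_l,
         p.theta_m, p.sigma_m, p.theta_h, p.sigma_h, p.theta_th, p.sigma_th,
         p.theta_n, p.sigma_n, p.theta_a, p.sigma_a, p.theta_b, p.sigma_b,
         p.tau_a, p.tau_b, p.tau_w, p.b_w, p.p_Na, p.p_Kdr, p.p_a,
         p.tau_h_base, p.tau_h_amp, p.tau_n_c0, p.tau_n_c1,
         p.tau_n_theta1, p.tau_n_sigma1, p.tau_n_theta2, p.tau_n_sigma2],
        dtype=np.float64,
    )


@dataclass
class CellBatchResult:
    """Spike times per cell plus (optionally) decimated voltage traces."""

    spikes: list[np.ndarray]        # per-cell sorted spike times, ms
    V: np.ndarray | None            # (n_cells, n_rec) or None
    t: np.ndarray | None            # recording time grid, ms
    V_final: np.ndarray             # state at the end of the run

    def rates(self, duration: float) -> np.ndarray:
        """Mean firing rate per cell, spikes/s."""
        return np.array([len(s) for s in self.spikes]) / (duration * 1e-3)


def simulate_cells(
    model: str,
    params: RSPParams | FSParams,
    dt: float,
    duration: float,
    dc: np.ndarray,
    istim: np.ndarray | None = None,
    istim_scale: np.ndarray | None = None,
    ge0: np.ndarray | float = 0.0,
    gi0: np.ndarray | float = 0.0,
    V0: np.ndarray | float | None = None,
    event_times: np.ndarray | None = None,
    event_gpeak: np.ndarray | float | None = None,
    event_kinetics: SynapseKinetics | None = None,
    record_decim: int = 0,
    max_spikes_per_cell: int = 4000,
) -> CellBatchResult:
    """Integrate a batch of independent cells for ``duration`` ms.

    ``dc`` (pA) fixes the batch size.  ``istim`` is a shared current trace
    sampled at dt (scaled per cell by ``istim_scale``); ``event_times``
    (ms) schedules conductance events of per-cell peak ``event_gpeak`` (nS)
    on one synapse with ``event_kinetics``.  ``ge0``/``gi0`` are tonic
    background conductances (nS) with the background reversals (0 / -75 mV).
    """
    dc = np.atleast_1d(np.asarray(dc, dtype=np.float64))
    n = dc.shape[0]
    n_steps = int(round(duration / dt))

    def bcast(x, default=0.0):
        if x is None:
            x = default
        return np.broadcast_to(np.asarray(x, dtype=np.float64), (n,)).copy()

    ge0 = bcast(ge0)
    gi0 = bcast(gi0)
    istim_scale = bcast(istim_scale, 1.0)
    istim_arr = (
        np.asarray(istim, dtype=np.float64) if istim is not None else np.empty(0)
    )
    if istim is not None and istim_arr.shape[0] != n_steps:
        raise ValueError("istim must have one sample per time step")

    if event_times is not None:
        ev_steps = np.asarray(np.round(np.asarray(event_times) / dt), dtype=np.int64)
        ev_gpeak = bcast(event_gpeak)
        kin = event_kinetics
        if kin is None:
            raise ValueError("event_kinetics required with event_times")
        syn_dec_r = np.exp(-dt / kin.tau_rise)
        syn_dec_f = np.exp(-dt / kin.tau_fall)
        syn_invP = 1.0 / biexp_norm(kin)
        syn_Esyn = kin.E_syn
    else:
        ev_steps = np.empty(0, dtype=np.int64)
        ev_gpeak = np.zeros(n)
        syn_dec_r = syn_dec_f = 0.0
        syn_invP = 0.0
        syn_Esyn = 0.0

    if record_decim > 0:
        n_rec = n_steps // record_decim
        recV = np.empty((n, n_rec), dtype=np.float64)
        t_rec = (np.arange(1, n_rec + 1) * record_decim) * dt
    else:
        recV = np.empty((n, 0), dtype=np.float64)
        t_rec = None

    cap = max_spikes_per_cell * n
    spike_t = np.empty(cap, dtype=np.float64)
    spike_cell = np.empty(cap, dtype=np.int64)
    spike_count = np.zeros(1, dtype=np.int64)

    if model == "rsp":
        assert isinstance(params, RSPParams)
        V = bcast(V0, params.E_l)
        w1 = params.a_eff * (V - params.E_l)
        w2 = np.zeros(n)
        _kernels.rsp_batch(
            n_steps, dt, V, w1, w2, dc,
            istim_arr, istim_scale, ge0, gi0, E_E, E_I,
            ev_steps, ev_gpeak, syn_dec_r, syn_dec_f, syn_invP, syn_Esyn,
            pack_rsp(params), rsp_exp_table(params), V_LO, 1.0 / DV,
            record_decim, recV, spike_t, spike_cell, spike_count,
        )
    elif model == "fs":
        assert isinstance(params, FSParams)
        V = bcast(V0, params.E_l)
        h, nn, aa, bb = (np.asarray(g, dtype=np.float64).copy()
                         for g in fs_steady_gates(V, params))
        w = np.zeros(n)
        armed = V < 0.0
        _kernels.fs_batch(
            n_steps, dt, V, h, nn, aa, bb, w, armed, dc,
            istim_arr, istim_scale, ge0, gi0, E_E, E_I,
            ev_steps, ev_gpeak, syn_dec_r, syn_dec_f, syn_invP, syn_Esyn,
            pack_fs(params), fs_gate_tables(params), V_LO, 1.0 / DV,
            record_decim, recV, spike_t, spike_cell, spike_count,
        )
    else:
        raise ValueError("model must be 'rsp' or 'fs'")

    m = int(spike_count[0])
    spikes = [np.sort(spike_t[:m][spike_cell[:m] == j]) for j in range(n)]
    return CellBatchResult(
        spikes=spikes,
        V=recV if record_decim > 0 else None,
        t=t_rec,
        V_final=V,
    )
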