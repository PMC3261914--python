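"""Single-neuron dynamics.

Two cell models:

* ``RSP`` — regular-spiking pyramidal neuron, an adaptive exponential
  integrate-and-fire model with two adaptation currents: ``w1`` (fast,
  voltage-coupled and spike-triggered, tau ~20 ms) and ``w2`` (slow, purely
  spike-triggered, tau ~550 ms).  A spike is the crossing of the numerical
  cutoff ``V_spike`` (+20 mV), after which V resets and the adaptation
  currents are incremented.

* ``FS`` — fast-spiking interneuron, a single-compartment conductance-based
  model with instantaneous Na activation (m = m_inf(V)), Na inactivation h,
  delayed-rectifier activation n, a D-type K current with activation a and
  inactivation b, a linear leak, and a slow adaptation current w.  Spikes
  are upward zero-crossings of the membrane potential with hysteresis
  (re-arming requires V to return below 0 mV).

All functions are pure and operate elementwise on scalars or numpy arrays,
in the repo-wide unit convention (mV, ms, nS, pA, nF).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import FSParams, RSPParams


def boltzmann(V, theta: float, sigma: float):
    """Boltzmann steady-state activation 1 / (1 + exp(-(V - theta)/sigma)).

    Monotone increasing in V for sigma > 0, decreasing for sigma < 0.
    Raises ``ValueError`` for sigma = 0.
    """
    if sigma == 0:
        raise ValueError("boltzmann: sigma must be nonzero")
    x = -(np.asarray(V, dtype=float) - theta) / sigma
    out = 1.0 / (1.0 + np.exp(np.clip(x, -500.0, 500.0)))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# RSP model


@dataclass
class RSPState:
    """Dynamical variables of one (or a vector of) RSP neuron(s)."""

    V: np.ndarray | float
    w1: np.ndarray | float = 0.0
    w2: np.ndarray | float = 0.0


def rsp_derivative(state: RSPState, params: RSPParams, I_total):
    """Time derivatives (dV/dt, dw1/dt, dw2/dt) of the RSP model.

    ``I_total`` is the net non-leak current in pA, inward-positive (i.e. it
    enters dV/dt with a plus sign); the leak, the exponential
    spike-initiation term and the two adaptation currents are supplied by
    the model itself.  The exponential argument is clamped to avoid
    overflow between threshold crossing and reset.
    """
    V = np.asarray(state.V, dtype=float)
    w1 = np.asarray(state.w1, dtype=float)
    w2 = np.asarray(state.w2, dtype=float)
    arg = np.minimum((V - params.V_t) / params.Delta_t, params.exp_clamp)
    I_exp = params.g_l * params.Delta_t * np.exp(arg)
    # currents in pA, C in pF -> dV/dt in mV/ms
    dV = (-params.g_l * (V - params.E_l) + I_exp - w1 - w2 + I_total) / params.C_pF
    dw1 = (params.a_eff * (V - params.E_l) - w1) / params.tau_w1
    dw2 = -w2 / params.tau_w2
    return dV, dw1, dw2


def rsp_apply_reset(state: RSPState, params: RSPParams):
    """Post-step reset rule: where V exceeds the +20 mV cutoff, V -> V_reset
    and the adaptation currents are incremented by b1/b2.  Returns the new
    state and a boolean spike flag (elementwise)."""
    V = np.asarray(state.V, dtype=float)
    spike = V > params.V_spike
    V_new = np.where(spike, params.V_reset, V)
    w1_new = np.asarray(state.w1, dtype=float) + np.where(spike, params.b1_eff, 0.0)
    w2_new = np.asarray(state.w2, dtype=float) + np.where(spike, params.b2_eff, 0.0)
    if V_new.ndim == 0:
        return RSPState(float(V_new), float(w1_new), float(w2_new)), bool(spike)
    return RSPState(V_new, w1_new, w2_new), spike


# ---------------------------------------------------------------------------
# FS model


@dataclass
class FSState:
    """Dynamical variables of one (or a vector of) FS interneuron(s).

    ``spike_armed`` is the hysteresis flag of the zero-crossing spike
    detector; the instantaneous Na activation m is never stored.
    """

    V: np.ndarray | float
    h: np.ndarray | float = 0.0
    n: np.ndarray | float = 0.0
    a_gate: np.ndarray | float = 0.0
    b_gate: np.ndarray | float = 0.0
    w: np.ndarray | float = 0.0
    spike_armed: np.ndarray | bool = True


def fs_tau_h(V, p: FSParams):
    """Voltage-dependent Na inactivation time constant, ms."""
    return p.tau_h_base + p.tau_h_amp * boltzmann(V, p.theta_th, p.sigma_th)


def fs_tau_n(V, p: FSParams):
    """Voltage-dependent delayed-rectifier time constant, ms (product of two
    sigmoids)."""
    f1 = p.tau_n_c0 + p.tau_n_c1 * boltzmann(V, p.tau_n_theta1, p.tau_n_sigma1)
    f2 = p.tau_n_c0 + p.tau_n_c1 * boltzmann(V, p.tau_n_theta2, p.tau_n_sigma2)
    return f1 * f2


def fs_steady_gates(V, p: FSParams):
    """Steady-state values (h, n, a, b) at voltage V."""
    return (
        boltzmann(V, p.theta_h, p.sigma_h),
        boltzmann(V, p.theta_n, p.sigma_n),
        boltzmann(V, p.theta_a, p.sigma_a),
        boltzmann(V, p.theta_b, p.sigma_b),
    )


def fs_membrane_currents(state: FSState, p: FSParams):
    """Ionic currents (I_Na, I_Kdr, I_d, I_leak) in pA, outward-positive."""
    V = np.asarray(state.V, dtype=float)
    m_inf = boltzmann(V, p.theta_m, p.sigma_m)
    I_Na = p.g_Na * m_inf**p.p_Na * state.h * (V - p.E_Na)
    I_Kdr = p.g_Kdr * np.asarray(state.n) ** p.p_Kdr * (V - p.E_K)
    I_d = p.g_d * np.asarray(state.a_gate) ** p.p_a * state.b_gate * (V - p.E_K)
    I_leak = p.g_l * (V - p.E_l)
    return I_Na, I_Kdr, I_d, I_leak


def fs_derivative(state: FSState, params: FSParams, I_total, gate_tol: float = 1e-9):
    """Time derivatives (dV/dt, dh/dt, dn/dt, da/dt, db/dt, dw/dt) of the FS
    model.  ``I_total`` is the net external current in pA, inward-positive.

    Raises ``FloatingPointError`` if any gating variable has left [0, 1] by
    more than ``gate_tol`` (a symptom of integration instability)."""
    for name in ("h", "n", "a_gate", "b_gate"):
        g = np.asarray(getattr(state, name), dtype=float)
        if np.any(g < -gate_tol) or np.any(g > 1.0 + gate_tol):
            raise FloatingPointError(
                f"FS gating variable {name} outside [0, 1] beyond tolerance: "
                f"range [{g.min():.3e}, {g.max():.3e}]"
            )
    V = np.asarray(state.V, dtype=float)
    I_Na, I_Kdr, I_d, I_leak = fs_membrane_currents(state, params)
    dV = (-I_Na - I_Kdr - I_d - I_leak - state.w + I_total) / params.C_pF
    h_inf, n_inf, a_inf, b_inf = fs_steady_gates(V, params)
    dh = (h_inf - state.h) / fs_tau_h(V, params)
    dn = (n_inf - state.n) / fs_tau_n(V, params)
    da = (a_inf - state.a_gate) / params.tau_a
    db = (b_inf - state.b_gate) / params.tau_b
    dw = -np.asarray(state.w, dtype=float) / params.tau_w
    return dV, dh, dn, da, db, dw


def fs_detect_spike(state: FSState):
    """Upward zero-crossing spike detector with hysteresis.

    A spike is flagged when V >= 0 while the detector is armed; the
    detector re-arms only once V has returned below 0 mV.  Returns the
    updated state and the (elementwise) spike flag."""
    V = np.asarray(state.V, dtype=float)
    armed = np.asarray(state.spike_armed, dtype=bool)
    spike = armed & (V >= 0.0)
    new_armed = np.where(V < 0.0, True, armed & ~spike)
    state.spike_armed = bool(new_armed) if new_armed.ndim == 0 else new_armed
    if V.ndim == 0:
        return state, bool(spike)
    return state, spike


def fs_init_state(V0, params: FSParams) -> FSState:
    """FS state with all gates at their steady-state values for V0."""
    h, n, a, b = fs_steady_gates(V0, params)
    V0 = np.asarray(V0, dtype=float)
    armed = V0 < 0.0
    return FSState(
        V=V0 if V0.ndim else float(V0),
        h=h, n=n, a_gate=a, b_gate=b,
        w=np.zeros_like(V0) if V0.ndim else 0.0,
        spike_armed=armed if V0.ndim else bool(armed),
    )
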