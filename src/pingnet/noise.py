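"""Ornstein-Uhlenbeck background conductance processes.

Each cell receives an independent excitatory and inhibitory conductance
process.  The mean conductances set the 'low' (quiescent-slice-like) or
'high' (in-vivo-like) conductance state; the fluctuation magnitude D sets
the membrane noise level.  The update is the *exact* discretization of the
OU stochastic differential equation,

    s(t + dt) = g_avg + (s(t) - g_avg) e^{-dt/tau}
                + noise_scale * sigma_stat * sqrt(1 - e^{-2 dt/tau}) * r,

with stationary SD sigma_stat = sqrt(D tau / 2) and r a standard normal
draw, so all stationary moments are independent of dt.  Conductances are
not rectified at zero; in the high state negative excursions are
negligible, and in the low state the mean is itself near zero so
rectification would distort the noise statistics.
"""

from __future__ import annotations

import math

import numpy as np

from .config import OUParams, conductance_state  # noqa: F401  (re-export)


def ou_coefficients(params: OUParams, dt: float) -> tuple[float, float]:
    """(decay, diffusion) pair of the exact OU update for step dt:
    s' = g_avg + (s - g_avg)*decay + diffusion*r."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    decay = math.exp(-dt / params.tau)
    diffusion = params.noise_scale * params.sigma_stat * math.sqrt(1.0 - decay**2)
    return decay, diffusion


def ou_step(s, params: OUParams, dt: float, r_norm):
    """Advance the OU conductance by one step of length dt using the
    standard-normal draw(s) ``r_norm``.  Exact for any dt."""
    decay, diffusion = ou_coefficients(params, dt)
    return params.g_avg + (np.asarray(s, dtype=float) - params.g_avg) * decay \
        + diffusion * np.asarray(r_norm, dtype=float)


def ou_current(s_e, s_i, V, params_e: OUParams, params_i: OUParams):
    """Net background-conductance current in pA, inward-positive:
    -s_e (V - E_e) - s_i (V - E_i)."""
    V = np.asarray(V, dtype=float)
    return -np.asarray(s_e) * (V - params_e.E_rev) - np.asarray(s_i) * (V - params_i.E_rev)


def stationary_moments(params: OUParams) -> tuple[float, float]:
    """Closed-form stationary (mean, SD) of the scaled process."""
    return params.g_avg, params.noise_scale * params.sigma_stat


def sample_stationary(params: OUParams, size, rng: np.random.Generator):
    """Draw from the stationary distribution (used for initial conditions)."""
    mean, sd = stationary_moments(params)
    return mean + sd * rng.standard_normal(size)


def simulate_ou(
    params: OUParams,
    dt: float,
    n_steps: int,
    rng: np.random.Generator,
    s0: float | None = None,
) -> np.ndarray:
    """Simulate one OU trajectory of ``n_steps`` steps (vectorized over the
    pre-drawn noise).  Starts from the stationary distribution unless
    ``s0`` is given."""
    decay, diffusion = ou_coefficients(params, dt)
    z = rng.standard_normal(n_steps)
    out = np.empty(n_steps + 1)
    out[0] = s0 if s0 is not None else sample_stationary(params, (), rng)
    # Scan: numpy has no stateful scan; the loop is cheap relative to use.
    s = out[0] - params.g_avg
    for k in range(n_steps):
        s = s * decay + diffusion * z[k]
        out[k + 1] = s + params.g_avg
    return out


def negative_fraction(trajectory: np.ndarray) -> float:
    """Fraction of samples below zero (diagnostic for the no-rectification
    choice; ~0 in the high state, ~1/2 in the low state by construction)."""
    return float(np.mean(np.asarray(trajectory) < 0.0))
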