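# pingnet

Spiking-network simulator for beta/gamma oscillations that arise from
feedback inhibition in the fluctuation-driven regime, together with the
single-cell "virtual dynamic clamp" protocols and population-oscillation
statistics needed to dissect the mechanism.

## The scientific problem

Cortical networks produce prominent 15–80 Hz population rhythms even
though individual pyramidal cells fire sparsely (a few spikes per second)
and irregularly. In the *stochastic synchrony* picture, noisy excitatory
cells recruit coherent feedback inhibition from fast-spiking (FS)
interneurons; the silent period after each inhibitory volley sets the
network period. The frequency of such a rhythm then depends not only on
inhibitory synapse kinetics but on the *membrane* of the participating
cells: tonic background conductance (the in-vivo-like "high-conductance
state") shortens the pyramidal membrane time constant — and therefore the
recovery time after inhibition — and shortens FS spike latency, tightening
the temporal balance between excitation and inhibition. `pingnet` is built
to study exactly these dependencies.

The model network is 400 regular-spiking pyramidal (RSP) neurons — an
adaptive exponential integrate-and-fire model with two adaptation
currents —

```
C dV/dt = -g_l(V-E_l) + g_l Δ_T e^{(V-V_T)/Δ_T} - w₁ - w₂
          - s_e(V-E_e) - s_i(V-E_i) + I_syn + I_DC
```

and 100 conductance-based FS interneurons (Na, delayed-rectifier K, D-type
K, leak, slow adaptation), wired randomly (p_EE = 0.2, others 0.4) with
peak-normalized bi-exponential conductance synapses. Each cell receives
independent excitatory and inhibitory Ornstein–Uhlenbeck background
conductances s_e, s_i whose means set the low/high conductance state and
whose fluctuations drive all firing. Per-cell DC currents place noise-free
resting potentials uniformly 0–15 mV below spike threshold, and the noise
amplitude is calibrated so the subthreshold membrane-potential SD of RSP
cells is 2.56 mV. Integration is forward Euler at dt = 0.01 ms in numba
kernels; everything is reproducible from three named seed streams
(connectivity / DC / noise).

See `docs/methods.md` for the full model description, the calibration
pipeline, numerical choices, and known limitations (including an honest
account of which published operating-point statistics this reconstruction
does and does not reproduce).

## Worked example

```python
import numpy as np
from pingnet import NetworkConfig, build_network, calibrate_noise_scale, run_simulation
from pingnet import analysis

cfg = NetworkConfig()                      # control: both populations low-conductance
inst = build_network(cfg, seed=42)         # wire + calibrate thresholds and DC
scale = calibrate_noise_scale(inst, noise_seed=100)   # match 2.56 mV RSP V_m SD
res = run_simulation(inst, noise_seed=7, duration=10_000.0, noise_scale=scale)

n_steps = int(res.duration / res.dt)
fp = analysis.field_potential(res.spike_t, res.dt, n_steps, res.burn_in)
print(f"f_net = {fp.f_net:.1f} Hz")
print(f"RSP rate = {res.rates(0, cfg.N_E).mean():.2f} spk/s, "
      f"FS rate = {res.rates(1, cfg.N_I).mean():.2f} spk/s")
print(f"cycle period = {fp.cycle_periods.mean():.1f} ± {fp.cycle_periods.std():.1f} ms")
```

prints (seed-dependent within a few percent):

```
f_net = 22.5 Hz
RSP rate = 0.55 spk/s, FS rate = 9.26 spk/s
cycle period = 38.8 ± 10.3 ms
```

— a beta-band population rhythm with FS cells firing on roughly every
other cycle and sparse, loosely phase-locked pyramidal firing (RSP vector
strength ≈ 0.6). Switching a population to the high-conductance state
(`rsp_state="high"` / `fs_state="high"`) raises the network frequency; the
experiment drivers in `pingnet.protocols` automate those sweeps
(conductance states, extra I→E delay, noise magnitude, stability over
recurrent excitation × delay, and subpopulation gain), and
`pingnet.protocols.fi_protocol` / `impedance_protocol` /
`recovery_protocol` / `latency_protocol` run the single-cell
characterizations.

A CLI wraps the same functions:

```bash
pingnet simulate --seed 1 --duration 5000 --out out/       # raster.csv, traces.h5, ...
pingnet protocol fi --cell rsp --out fi.csv
pingnet reproduce states --seed 1 --noise-scale 24.4 --out states.csv
```

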