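# Methods

`pingnet` simulates a cortical network of 400 regular-spiking pyramidal
(RSP) neurons and 100 fast-spiking (FS) interneurons in the
fluctuation-driven regime, in which a coherent beta/gamma-band population
rhythm emerges from feedback inhibition while individual neurons fire
sparsely and irregularly ("stochastic synchrony"). This note documents the
model equations, the calibration pipeline, the numerical choices, and the
places where the package had to make a decision the source material left
open.

## Cell models

**RSP neurons** are adaptive exponential integrate-and-fire (AdEx) cells
with two adaptation currents:

    C dV/dt = -g_l (V - E_l) + g_l Δ_T exp((V - V_T)/Δ_T)
              - w1 - w2 + I_syn + I_noise + I_DC
    τ_w1 dw1/dt = a (V - E_l) - w1
    τ_w2 dw2/dt = -w2

When V crosses the +20 mV numerical cutoff: V → V_reset (-53 mV),
w1 → w1 + b1, w2 → w2 + b2. The fast current w1 (τ = 20 ms) limits
instantaneous firing rates; the slow, purely spike-triggered current w2
(τ = 550 ms) produces the gradual ISI lengthening seen in layer II/III
pyramidal cells over hundreds of milliseconds. Defaults: C = 0.15 nF,
g_l = 4.5 nS, E_l = -65 mV, Δ_T = 0.8 mV, V_T = -52 mV. With these values
the model is an integrator (saddle-node onset): its f-I curve is continuous
from zero.

*Adaptation magnitudes.* The source parameter table prints a = -5e-5,
b1 = 0.05, b2 = 0.0015 in nS-family units. Read literally, these produce
steady-state adaptation currents below 1 pA at realistic rates — no
adaptation at all — which contradicts the clearly adapting f-I behaviour
the model is supposed to reproduce. We treat this as a unit misprint
(nS-family printed for a μS/nA-family quantity) and expose per-variable
scale factors `a_scale`, `b1_scale`, `b2_scale`, default 1000, giving
a = -0.05 nS, b1 = 50 pA, b2 = 1.5 pA — ordinary published AdEx magnitudes
that yield a visible adapted/unadapted f-I separation and cap instantaneous
rates after the reset (V_reset sits only 1 mV below V_T).

**FS interneurons** are single-compartment conductance-based cells
(isopotential sphere, radius 18 μm, so specific parameters convert to
whole-cell values through the membrane area; C ≈ 40.7 pF):

    C dV/dt = -g_Na m∞(V)^3 h (V - E_Na) - g_Kdr n^4 (V - E_K)
              - g_d a^3 b (V - E_K) - g_l (V - E_l) - w + I

with instantaneous Na activation m∞, Na inactivation h, delayed-rectifier
activation n, and a D-type K current with activation a (τ_a = 2 ms) and
slow inactivation b (τ_b = 150 ms). All steady states are Boltzmann
functions x∞(V) = 1/(1 + exp(-(V - θ)/σ)); τ_h(V) = 0.5 + 14·Γ(V; -60, -12)
and τ_n(V) is the two-sigmoid product of the published FS-interneuron model
this cell is based on. Every exponent and τ-form coefficient is a config
field. The model shows the FS phenotype: a discontinuous f-I onset
(> 10 spikes/s at rheobase, Hopf-like), thin spikes, and short latency to
spike after excitatory input. A slow adaptation current w (τ_w = 500 ms,
increment `b_w`, default 2 pA; the source prints no value) mirrors the RSP
w2. FS spikes are detected as upward zero-crossings of V with hysteresis
(re-arming requires V < 0 mV); RSP spikes are reset events.

Two printed FS gate parameters are dynamically impossible as printed and
were corrected to the cited model family's values, both config-overridable:
θ_n = -1.24, σ_n = -9.8 would hold the 27 μS delayed rectifier ~fully open
at rest (input resistance ~0.04 MΩ, the cell could never spike); we use
θ_n = -12.4, σ_n = +9.8. σ_b = +6 would turn the D-current "inactivation"
gate into a second activation gate; we use σ_b = -6.

## Background conductance noise

Each cell receives independent excitatory (τ_e = 2 ms, reversal 0 mV) and
inhibitory (τ_i = 8 ms, reversal -75 mV) Ornstein-Uhlenbeck conductances.
The update is the exact discretization (stationary SD √(Dτ/2)), so all
stationary moments are dt-independent; conductances are not rectified at
zero (in the low state the means are ≈ 0 nS by construction, so the noise
is effectively current-like; in the high state negative excursions are
negligible). The mean conductances define the conductance *state*:
low (quiescent-slice-like, ≈ 0 nS) or high (in-vivo-like: 10.8/2.7 nS e/i
for RSP, 12.0/3.0 nS for FS), which lowers input resistance and membrane
time constant by g_l/(g_l + Σg).

The printed fluctuation magnitudes (D_e = 5e-4, D_i = 2e-3 nS²/ms) produce
sub-0.1 mV membrane fluctuations — far too small to drive any firing in a
network whose excitatory cells are strictly subthreshold at rest. A single
scalar `noise_scale` multiplying the fluctuation SD of both populations is
therefore *calibrated*: it is searched so that the population-mean
subthreshold membrane-potential SD of RSP cells in the control network
(spike-adjacent ±5 ms excised, post burn-in) equals the 2.56 mV operating
point. The calibrated value is ≈ 23 (equivalently D values ~500× larger
than printed, i.e. one more nS↔μS-family slip). All experiments hold the
calibrated value fixed; the noise-sweep experiment scales the RSP
population's fluctuations explicitly while keeping FS noise at the
calibrated value.

## Synapses and wiring

Connection probabilities p_EE = 0.2, p_EI = p_IE = p_II = 0.4 (pre→post
notation), Bernoulli per ordered pair, no self-connections. A presynaptic
spike initiates a peak-normalized bi-exponential conductance
g(t) = g_peak (e^{-t/τ_fall} - e^{-t/τ_rise})/P in every target; waveforms
superpose linearly. Kinetics: E synapses 0.5/2.5 ms, I synapses 1.0/5.0 ms;
reversals E→E 0, E→I 0, I→E -65, I→I -55 mV. Peak conductances follow the
two-level uniform scheme: per postsynaptic cell and pair type a total
budget Ḡ·U(1-k1, 1+k1); per synapse (budget/n̄)·U(1-k2, 1+k2) with
n̄ = p·N_pre and k1 = k2 = 0.25. Budgets (nS/cell): E→E 37.5, E→I 100,
I→E 46.25, I→I 25 — the four printed totals mapped in E_syn-row order
(the row labels are unreadable in the source; the mapping is
config-overridable). When a decay constant is changed (the τ_fall,I
sweeps), sampled peaks are rescaled so the time-integrated conductance per
event is conserved.

The engine does not store waveform lists: each postsynaptic cell keeps one
rise and one fall exponential accumulator per afferent pair type, which is
algebraically identical to superposed bi-exponentials because kinetics are
shared within a pair type (the list-based reference implementation is kept
as the oracle path and cross-checked in the tests against an adaptive ODE
solver). Baseline delay is 0 ms ("immediately following a zero-crossing");
an extra artificial I→E delay is a config parameter implemented with a ring
buffer.

In high-conductance conditions, synaptic peaks onto the high-state
population are rescaled so that the single-event PSP deflection of a
quiescent postsynaptic cell (held 7.5 mV below threshold, the midpoint of
the rest rule) matches the low-state deflection to 1%. Note that for
synapses briefer than the membrane time constant the factor is well below
the steady-state conductance ratio (the PSP is partly charge-dominated):
≈ 1.4 for E→E kinetics onto a high-state RSP cell, not (g_l + Σg)/g_l ≈ 4.

## Calibration pipeline

1. **Spike threshold** (per cell type and conductance state): the highest
   noise-free steady-state voltage attainable without firing, by bisection
   on DC current. Runs that have not settled (the slow passage through the
   saddle-node ghost just above rheobase) are classified with the firing
   side of the bracket. For the RSP model the result is within 0.3 mV of
   V_T.
2. **Per-cell DC**: for each cell an offset u ~ U(0, 15) mV is drawn and
   the DC current giving a noise-free rest at threshold - u is found by
   vectorized bisection (tolerance 0.05 mV; tonic background means
   included for high states). FS cells thereby rest largely below
   threshold and fire only on excitatory input or noise.
3. **PSP rescaling** for high-state targets (above).
4. **noise_scale** against the 2.56 mV RSP V_m SD (above).
5. **Rate matching** across conditions: a uniform DC shift on the RSP
   population found by secant iteration on the population-mean rate.

## Integration and numerics

Forward Euler at dt = 0.01 ms (convergence of the network frequency is
checked against dt = 0.005 ms). Per step: flush delayed arrivals, update
membrane/gating states, advance the OU conductances (pre-drawn normals from
seeded numpy Generators; independent streams for connectivity / DC /
noise), detect spikes, propagate increments, decay accumulators. The
numba kernels tabulate the FS gating functions and the RSP exponential term
on a 0.02 mV voltage grid (linear interpolation; clamped outside
[-130, 80] mV); the RSP exponential argument is clamped at +30 to prevent
overflow between cutoff crossing and reset. Runs are bit-reproducible for
fixed seeds. Initial conditions: V at calibrated rest, gates at steady
state, OU states at their means; the first 500 ms are discarded from all
statistics.

## Analysis

The field-potential approximation is the per-step summed spike count,
low-pass filtered with a zero-phase (forward-reverse) 4th-order Butterworth
at 2·f_net. The dominant frequency f_net is the in-band (5-100 Hz) peak of
the Welch PSD (2-s Hamming segments, 95% overlap) for records ≥ 4 s; the
raw-periodogram argmax (lightly smoothed) is used for shorter records —
the unsmoothed periodogram argmax is an inconsistent estimator and made
f_net jump by tens of percent between record lengths of the same network.
Cycles are segmented by local extrema with prominence ≥ 10% of the trace
SD, a minimum separation of half the dominant period, and enforced
peak/trough alternation (without the latter two, filter ripple creates
spurious short cycles). Spike phases interpolate linearly between
successive peaks (0 to 2π); vector strength is the resultant length; ISI
CV requires ≥ 3 spikes. Synaptic currents are reported inward-positive
(the dV/dt convention), so a net-inhibitory integral is negative; E/I
balance is measured on cycle-averaged population-mean E and I currents
onto RSP cells in simulated voltage clamp at -52 mV (holding at the spike
threshold keeps both driving forces representative of the firing decision
point; free-running conductances are recorded, so any holding potential
can be recomputed). "Recovery time after inhibition" is the time for a
hyperpolarizing deflection to decay by 1 - 1/e = 63.2% (the source prints
both 63.7% and 63.2% for "one time constant"; we use the exact 1 - 1/e).

## Virtual protocols

f-I (2-s steps; unadapted = median of the first five inverse ISIs, adapted
= last five), impedance (10-s flat-spectrum 0-200 Hz current noise at
-60 mV, amplitude auto-scaled to 5 mV peak-to-peak, 5 repetitions),
recovery after inhibition (1-ms-rise IPSGs at -75 mV every 500 ms to a
quiescent cell over a τ_fall × magnitude × tonic-conductance grid, with the
DC re-normalized per tonic level so the baseline sits 7.5 mV below
threshold, and the tonic conductance split 80/20 between the e/i reversals
— the high-state proportion), and spike latency (EPSGs 1/5 ms at 0 mV,
amplitudes 0.5-3.0 × the threshold conductance G_th found by bisection;
the model is deterministic, so one presentation per amplitude suffices).

Network experiments: the four conductance-state combinations (each a
freshly calibrated network, RSP rates DC-matched to control), f_net versus
an extra I→E delay, the RSP noise sweep at matched rates, a stability map
over (recurrent-excitation × delay) classifying hypersynchrony (a 5-ms
window containing spikes from > 50% of RSP cells, at least once per
second — thresholds in config; the source describes but does not quantify
the bursts), and the gain experiment (driven RSP subpopulations of 1-100%,
gain = least-squares slope of subpopulation mean rate vs bias current over
the responsive part of the curve, with common random numbers across
recurrent-excitation levels).

## What the defaults reproduce, and what they do not

With every printed parameter honored and the two prescribed calibrations
applied, the control network oscillates at ~17-23 Hz (beta band, as
reported for quiescent-slice parameters), FS interneurons fire ≈ 9 spk/s
with ISI CV ≈ 0.7-0.8, RSP vector strength is ≈ 0.6, and the cycle period
is broadly distributed (SD ≈ 10-12 ms) with a positive magnitude→period
correlation; the high-conductance manipulations raise the frequency into
the gamma range by the documented mechanisms (shorter recovery time in RSP
cells; tighter temporal E/I balance via shorter FS latency).

The package does *not* reproduce the reported control-network RSP
operating point (3.46 ± 0.33 spk/s, ISI CV 0.44): our reconstruction
settles at ≈ 0.5-1 RSP spk/s with CV ≈ 0.8. The reported ±0.33 across-cell
spread implies near-homogeneous RSP rates despite resting potentials
spread over 15 mV, which requires per-cycle recurrent-excitation volleys
large enough to dominate single-cell rest offsets; with the printed
conductance budgets and the calibrated noise, that high-recruitment state
is not a stable fixed point of our network (igniting it by initialization
collapses within one cycle). The FS equations are the least-constrained
part of the reconstruction (their rendered forms are unavailable), and FS
recruitment gain is exactly the quantity that separates the two operating
points. All downstream comparisons that are *ratios or orderings between
conditions* (frequency orderings, delay/integral reductions, recovery-time
predictions, stability and gain structure) are insensitive to this
operating-point difference; absolute RSP rate and CV are not.

## Problem sizes

Default experiment sizes used by the test-suite and the reproduction
script: one 10-s control realization for the headline statistics; 5-s
realizations for condition comparisons; 2.5-s realizations for the
recovery-surrogate network points; 2-s runs for the 5×5 stability grid;
1-s runs for the gain experiment (8 subpopulation draws at 1%, 3 at larger
fractions). These are the package's desk-scale defaults; durations,
replicate counts and grids are arguments throughout.

## Known limitations

No gap junctions (a presynaptic-coupling hook exists in the population
interface), no short-term plasticity or conductance saturation, no
multi-compartment morphology, no biophysical LFP (the field potential is a
spike-count proxy), and the operating-point caveat above.
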