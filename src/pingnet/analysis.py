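"""Population-oscillation and single-cell analysis metrics.

The field-potential approximation is the per-step summed spike count of the
network, low-pass filtered (zero-phase 4th-order Butterworth at twice the
dominant frequency).  All metrics are pure functions of their inputs.
Sign convention for synaptic currents: inward-positive (depolarizing > 0),
the same convention in which they enter dV/dt; a 'net inhibitory' portion
of the oscillation cycle is therefore net *negative* current.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats as spst

from .config import SynapseKinetics


class AnalysisError(ValueError):
    """Input does not admit the requested metric."""


# ---------------------------------------------------------------------------
# Field potential approximation


@dataclass
class FieldPotentialTrace:
    """Smoothed population-activity signal with cycle segmentation."""

    t: np.ndarray           # ms
    raw: np.ndarray         # spikes per time step
    filtered: np.ndarray
    f_net: float            # Hz, FFT-peak frequency of the raw signal
    peak_idx: np.ndarray
    trough_idx: np.ndarray
    dt: float               # ms

    @property
    def peak_times(self) -> np.ndarray:
        return self.t[self.peak_idx]

    @property
    def cycle_periods(self) -> np.ndarray:
        """Successive peak-to-peak intervals, ms."""
        return np.diff(self.peak_times)

    def cycle_magnitudes(self) -> np.ndarray:
        """Per-cycle magnitude: peak height minus the preceding trough, for
        peaks that have a preceding trough."""
        mags = []
        for p in self.peak_idx:
            prior = self.trough_idx[self.trough_idx < p]
            if prior.size:
                mags.append(self.filtered[p] - self.filtered[prior[-1]])
            else:
                mags.append(np.nan)
        return np.asarray(mags)


def bin_spikes(spike_t: np.ndarray, dt: float, n_steps: int) -> np.ndarray:
    """Total spikes of the network on each time step."""
    idx = np.asarray(np.round(np.asarray(spike_t) / dt), dtype=np.int64) - 1
    idx = np.clip(idx, 0, n_steps - 1)
    return np.bincount(idx, minlength=n_steps).astype(float)


def dominant_frequency(
    x: np.ndarray, dt: float, band: tuple[float, float] = (5.0, 100.0)
) -> float:
    """Dominant frequency (Hz) of ``x`` restricted to ``band``; warns when
    the peak sits at a band edge or does not rise above the noise floor
    (3x the median in-band power).

    For signals of >= 4 s the peak is taken from the Welch PSD (2-s Hamming
    segments, 95% overlap) — the raw-periodogram argmax is an inconsistent
    estimator whose bin-to-bin variance does not shrink with record length;
    shorter signals fall back to the periodogram."""
    fs = 1000.0 / dt
    x = np.asarray(x, dtype=float)
    if x.size * dt >= 4000.0:
        freqs, spec = welch_spectrum(x - x.mean(), fs)
    else:
        spec = np.abs(np.fft.rfft(x - x.mean())) ** 2
        # a short moving average tames the chi-squared bin noise of the
        # raw periodogram (variance independent of record length)
        spec = np.convolve(spec, np.ones(9) / 9.0, mode="same")
        freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(in_band):
        raise AnalysisError("frequency band empty for this signal length")
    sub = spec[in_band]
    fsub = freqs[in_band]
    k = int(np.argmax(sub))
    if sub[k] < 3.0 * np.median(sub):
        warnings.warn("no dominant spectral peak above 3x median in-band power")
    f_net = float(fsub[k])
    df = fsub[1] - fsub[0] if fsub.size > 1 else 0.0
    if k == 0 or k == sub.size - 1 or f_net <= band[0] + df or f_net >= band[1] - df:
        warnings.warn(f"dominant frequency {f_net:.1f} Hz is at the search-band edge")
    return f_net


def field_potential(
    spike_t: np.ndarray,
    dt: float,
    n_steps: int,
    burn_in: float = 0.0,
    band: tuple[float, float] = (5.0, 100.0),
    prominence_frac: float = 0.1,
) -> FieldPotentialTrace:
    """Field-potential approximation of a raster: bin all spikes per step,
    find the dominant frequency f_net, smooth with a zero-phase 4th-order
    Butterworth low-pass at 2*f_net, and segment cycles by local extrema
    with prominence >= ``prominence_frac`` of the trace SD."""
    spike_t = np.asarray(spike_t, dtype=float)
    if spike_t.size == 0:
        raise AnalysisError("cannot compute field potential of an empty raster")
    raw_full = bin_spikes(spike_t, dt, n_steps)
    i0 = int(round(burn_in / dt))
    raw = raw_full[i0:]
    t = (np.arange(i0, n_steps) + 1) * dt
    f_net = dominant_frequency(raw, dt, band)
    fs = 1000.0 / dt
    sos = sps.butter(4, 2.0 * f_net, btype="low", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, raw - raw.mean()) + raw.mean()
    prom = prominence_frac * np.std(filt)
    # cycles shorter than half the dominant period cannot survive the
    # 2*f_net low-pass; a minimum peak separation rejects filter ripple
    min_dist = max(int(round(0.5 * (1000.0 / f_net) / dt)), 1)
    peaks, _ = sps.find_peaks(filt, prominence=prom, distance=min_dist)
    troughs, _ = sps.find_peaks(-filt, prominence=prom, distance=min_dist)
    peaks, troughs = _enforce_alternation(filt, peaks, troughs)
    return FieldPotentialTrace(
        t=t, raw=raw, filtered=filt, f_net=f_net,
        peak_idx=peaks, trough_idx=troughs, dt=dt,
    )


def _enforce_alternation(
    x: np.ndarray, peaks: np.ndarray, troughs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Cycle-segmentation hygiene: between consecutive troughs keep only
    the highest peak, and between consecutive peaks only the lowest trough,
    so extrema strictly alternate."""
    if peaks.size == 0 or troughs.size == 0:
        return peaks, troughs
    events = np.concatenate([peaks, troughs])
    kinds = np.concatenate([np.ones(peaks.size, int), -np.ones(troughs.size, int)])
    order = np.argsort(events)
    events, kinds = events[order], kinds[order]
    kept: list[int] = [0]
    for i in range(1, events.size):
        if kinds[i] != kinds[kept[-1]]:
            kept.append(i)
            continue
        prev = events[kept[-1]]
        cur = events[i]
        better = (x[cur] > x[prev]) if kinds[i] == 1 else (x[cur] < x[prev])
        if better:
            kept[-1] = i
    kept = np.asarray(kept)
    return events[kept[kinds[kept] == 1]], events[kept[kinds[kept] == -1]]


def welch_spectrum(
    x: np.ndarray, fs: float, segment_s: float = 2.0, overlap: float = 0.95
) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density with Hamming segments of ``segment_s``
    seconds and fractional ``overlap``.  ``fs`` in Hz."""
    nperseg = int(round(segment_s * fs))
    if np.asarray(x).size < nperseg:
        raise AnalysisError("signal shorter than one Welch segment")
    return sps.welch(
        np.asarray(x, dtype=float), fs=fs, window="hamming",
        nperseg=nperseg, noverlap=int(round(overlap * nperseg)),
    )


def average_spectra(spectra: list[np.ndarray]) -> np.ndarray:
    """Average spectra of individual realizations (computed first, then
    averaged)."""
    return np.mean(np.stack(spectra), axis=0)


# ---------------------------------------------------------------------------
# Spike-train statistics


def isi_cv(spike_train: np.ndarray) -> float:
    """Coefficient of variation of interspike intervals: SD(ISI)/mean(ISI).
    Undefined (NaN) for trains with fewer than 3 spikes."""
    st = np.sort(np.asarray(spike_train, dtype=float))
    if st.size < 3:
        return float("nan")
    isi = np.diff(st)
    return float(np.std(isi) / np.mean(isi))


def spike_phases(spike_train: np.ndarray, fp: FieldPotentialTrace) -> np.ndarray:
    """Phase of each spike relative to the field potential: 0 at the
    preceding FP peak, 2*pi at the next peak, linear in between.  Spikes
    outside any complete peak-to-peak interval are dropped."""
    pk = fp.peak_times
    if pk.size < 2:
        return np.empty(0)
    st = np.asarray(spike_train, dtype=float)
    st = st[(st >= pk[0]) & (st < pk[-1])]
    if st.size == 0:
        return np.empty(0)
    k = np.searchsorted(pk, st, side="right") - 1
    frac = (st - pk[k]) / (pk[k + 1] - pk[k])
    return 2.0 * np.pi * frac


def vector_strength(spike_train: np.ndarray, fp: FieldPotentialTrace) -> float:
    """Resultant length of the spike phases: |sum exp(i*phi)| / K.
    NaN when no spike falls inside a complete cycle."""
    phi = spike_phases(spike_train, fp)
    if phi.size == 0:
        return float("nan")
    return float(np.abs(np.mean(np.exp(1j * phi))))


def population_mean(values: np.ndarray) -> float:
    """Mean over cells, skipping undefined (NaN) entries."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    return float(np.mean(v)) if v.size else float("nan")


# ---------------------------------------------------------------------------
# Cycle statistics


@dataclass
class CycleStats:
    magnitude: np.ndarray    # per-cycle FP magnitude (peak - preceding trough)
    period: np.ndarray       # subsequent peak-to-peak period, ms
    r: float                 # Pearson correlation
    p: float


def cycle_correlation(fp: FieldPotentialTrace, min_cycles: int = 10) -> CycleStats:
    """Association between the magnitude of one FP cycle and the length of
    the subsequent network period (Pearson r)."""
    mags = fp.cycle_magnitudes()[:-1]
    periods = fp.cycle_periods
    n = min(mags.size, periods.size)
    mags, periods = mags[:n], periods[:n]
    ok = np.isfinite(mags)
    mags, periods = mags[ok], periods[ok]
    if mags.size < min_cycles:
        raise AnalysisError(f"need >= {min_cycles} cycles, got {mags.size}")
    if np.std(mags) == 0 or np.std(periods) == 0:
        raise AnalysisError("degenerate (constant) cycle series")
    r, p = spst.pearsonr(mags, periods)
    return CycleStats(magnitude=mags, period=periods, r=float(r), p=float(p))


# ---------------------------------------------------------------------------
# E/I balance


@dataclass
class EIBalance:
    delay: float             # ms between E-current peak and I-current peak
    net_integral: float      # nA*ms over the contiguous net-inhibitory portion
    t: np.ndarray            # cycle-relative time, ms
    I_e: np.ndarray          # cycle-averaged E current, pA (inward-positive)
    I_i: np.ndarray


def cycle_average(
    x: np.ndarray, t: np.ndarray, peak_times: np.ndarray, window: float,
    lead_frac: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Average ``x`` over windows of length ``window`` ms aligned on FP
    peaks (each window starts ``lead_frac * window`` before its peak)."""
    dt = t[1] - t[0]
    n_win = int(round(window / dt))
    lead = int(round(lead_frac * window / dt))
    segs = []
    for pt in peak_times:
        i = int(np.searchsorted(t, pt)) - lead
        if i >= 0 and i + n_win <= x.size:
            segs.append(x[i:i + n_win])
    if not segs:
        raise AnalysisError("no complete cycles to average")
    avg = np.mean(np.stack(segs), axis=0)
    t_rel = (np.arange(n_win) - lead) * dt
    return t_rel, avg


def ei_balance(I_e: np.ndarray, I_i: np.ndarray, t: np.ndarray) -> EIBalance:
    """Peak E->I delay and net-inhibitory time integral from cycle-averaged
    excitatory and inhibitory current waveforms (pA, inward-positive).

    The delay is the time between the largest-magnitude E and I peaks; the
    integral covers the contiguous portion of the cycle around the net
    current minimum where the net current is hyperpolarizing (< 0),
    reported in nA*ms."""
    I_e = np.asarray(I_e, dtype=float)
    I_i = np.asarray(I_i, dtype=float)
    t = np.asarray(t, dtype=float)
    dt = t[1] - t[0]
    delay = float(t[np.argmax(np.abs(I_i))] - t[np.argmax(np.abs(I_e))])
    net = I_e + I_i
    k = int(np.argmin(net))
    if net[k] >= 0:
        integral = 0.0
    else:
        lo = k
        while lo > 0 and net[lo - 1] < 0:
            lo -= 1
        hi = k
        while hi < net.size - 1 and net[hi + 1] < 0:
            hi += 1
        integral = float(np.sum(net[lo:hi + 1]) * dt * 1e-3)  # pA*ms -> nA*ms
    return EIBalance(delay=delay, net_integral=integral, t=t, I_e=I_e, I_i=I_i)


def ei_balance_network(
    result,
    fp: FieldPotentialTrace | None = None,
    V_hold: float = -52.0,
    kin_e: SynapseKinetics | None = None,
    kin_i: SynapseKinetics | None = None,
) -> EIBalance:
    """E/I balance of the recorded population-mean synaptic conductances
    onto RSP cells, in simulated voltage clamp at ``V_hold``.

    ``result`` is a SimulationResult with the (g_e, g_i) trace; currents
    are I = -g (V_hold - E_syn) per source, cycle-averaged on FP peaks."""
    from .config import default_kinetics

    kins = default_kinetics()
    E_e = (kin_e or kins["EE"]).E_syn
    E_i = (kin_i or kins["IE"]).E_syn
    if fp is None:
        n_steps = int(round(result.duration / result.dt))
        fp = field_potential(result.spike_t, result.dt, n_steps, result.burn_in)
    keep = result.t_rec >= result.burn_in
    t = result.t_rec[keep]
    I_e = -result.g_E[keep, 0] * (V_hold - E_e)
    I_i = -result.g_E[keep, 1] * (V_hold - E_i)
    window = float(np.median(fp.cycle_periods)) if fp.cycle_periods.size else 50.0
    t_rel, Ie_avg = cycle_average(I_e, t, fp.peak_times, window)
    _, Ii_avg = cycle_average(I_i, t, fp.peak_times, window)
    return ei_balance(Ie_avg, Ii_avg, t_rel)


# ---------------------------------------------------------------------------
# Recovery after inhibition


def _trough_and_deflection(V: np.ndarray, baseline: float):
    V = np.asarray(V, dtype=float)
    k = int(np.argmin(V))
    defl = baseline - V[k]
    if defl <= 0:
        raise AnalysisError("trace contains no hyperpolarizing trough below baseline")
    return k, defl


def recovery_time(V: np.ndarray, t: np.ndarray, baseline: float,
                  frac: float = 1.0 - 1.0 / np.e) -> float:
    """Time (ms) from the hyperpolarization trough until the deflection has
    decayed by ``frac`` (default 1 - 1/e = 63.2%, one time constant)."""
    t = np.asarray(t, dtype=float)
    k, defl = _trough_and_deflection(V, baseline)
    thresh = baseline - (1.0 - frac) * defl
    after = np.asarray(V)[k:]
    hits = np.nonzero(after >= thresh)[0]
    if hits.size == 0:
        raise AnalysisError("membrane does not recover within the trace")
    return float(t[k + hits[0]] - t[k])


def recovery_derivative(V: np.ndarray, t: np.ndarray, baseline: float) -> float:
    """Mean dV/dt (mV/ms) between the points where the negative deflection
    has decayed by 10% and by 90%."""
    t = np.asarray(t, dtype=float)
    V = np.asarray(V, dtype=float)
    k, defl = _trough_and_deflection(V, baseline)
    after = V[k:]
    t_after = t[k:]
    out = []
    for p in (0.10, 0.90):
        thr = baseline - (1.0 - p) * defl
        hits = np.nonzero(after >= thr)[0]
        if hits.size == 0:
            raise AnalysisError("membrane does not recover within the trace")
        out.append(hits[0])
    i10, i90 = out
    if i90 == i10:
        raise AnalysisError("10% and 90% recovery points coincide (trace too coarse)")
    return float((after[i90] - after[i10]) / (t_after[i90] - t_after[i10]))
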