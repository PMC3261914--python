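"""Field-potential approximation, spectra, spike-train statistics, E/I
balance, and recovery-time metrics — on constructed inputs with known
answers."""

import numpy as np
import pytest

from pingnet import analysis


DT = 0.05  # ms; analysis metrics are dt-agnostic


def rhythmic_raster(f_hz=25.0, duration=4000.0, n_cells=400, p_fire=0.3, seed=0,
                    jitter=4.0):
    """Population clock at f_hz; each cell fires Bernoulli(p_fire) per
    cycle with Gaussian jitter."""
    rng = np.random.default_rng(seed)
    cycle_times = np.arange(50.0, duration - 50.0, 1000.0 / f_hz)
    spikes = []
    for t0 in cycle_times:
        k = rng.random(n_cells) < p_fire
        spikes.append(t0 + rng.normal(0, jitter, k.sum()))
    return np.sort(np.concatenate(spikes))


class TestFieldPotential:
    def test_recovers_constructed_frequency(self):
        st = rhythmic_raster(f_hz=25.0)
        n_steps = int(4000.0 / DT)
        fp = analysis.field_potential(st, DT, n_steps)
        assert fp.f_net == pytest.approx(25.0, abs=1.0)

    def test_periods_match_dominant_frequency(self):
        st = rhythmic_raster(f_hz=25.0)
        n_steps = int(4000.0 / DT)
        fp = analysis.field_potential(st, DT, n_steps)
        assert fp.cycle_periods.mean() == pytest.approx(1000.0 / fp.f_net, rel=0.05)

    def test_zero_phase_filtering(self):
        """Forward-reverse filtering preserves phase: the filtered and raw
        signals have their peak cross-correlation at (or next to) zero lag."""
        st = rhythmic_raster(f_hz=20.0, seed=3)
        n_steps = int(4000.0 / DT)
        fp = analysis.field_potential(st, DT, n_steps)
        a = fp.raw - fp.raw.mean()
        b = fp.filtered - fp.filtered.mean()
        lags = np.arange(-400, 401)
        xc = [np.dot(a[max(0, k):len(a) + min(0, k)],
                     b[max(0, -k):len(b) + min(0, -k)]) for k in lags]
        assert abs(lags[int(np.argmax(xc))]) <= 20  # within 1 ms at dt=0.05

    def test_empty_raster_rejected(self):
        with pytest.raises(analysis.AnalysisError):
            analysis.field_potential(np.array([]), DT, 1000)

    def test_poisson_raster_warns_no_dominant_peak(self):
        rng = np.random.default_rng(5)
        st = np.sort(rng.uniform(0, 3000.0, 4000))
        with pytest.warns(UserWarning):
            analysis.field_potential(st, DT, int(3000.0 / DT))


class TestWelch:
    def test_sinusoid_peak(self):
        fs = 1000.0
        t = np.arange(0, 8.0, 1 / fs)
        x = np.sin(2 * np.pi * 30.0 * t)
        f, p = analysis.welch_spectrum(x, fs)
        assert f[np.argmax(p)] == pytest.approx(30.0, abs=0.5)

    def test_parseval(self):
        rng = np.random.default_rng(6)
        fs = 1000.0
        x = rng.standard_normal(16_000)
        f, p = analysis.welch_spectrum(x, fs)
        assert np.trapezoid(p, f) == pytest.approx(np.var(x), rel=0.05)

    def test_short_signal_rejected(self):
        with pytest.raises(analysis.AnalysisError):
            analysis.welch_spectrum(np.zeros(100), fs=1000.0)

    def test_average_spectra_is_mean_of_realizations(self):
        a = np.ones(10)
        b = 3 * np.ones(10)
        assert np.allclose(analysis.average_spectra([a, b]), 2.0)


class TestISICV:
    def test_periodic_train_is_zero(self):
        assert analysis.isi_cv(np.arange(0, 1000, 25.0)) == pytest.approx(0.0)

    def test_alternating_intervals(self):
        # ISIs {10, 20} balanced: CV = 5/15 = 1/3
        t = np.concatenate([[0.0], np.cumsum(np.tile([10.0, 20.0], 50))])
        assert analysis.isi_cv(t) == pytest.approx(1.0 / 3.0, rel=1e-6)

    def test_poisson_train_cv_near_one(self):
        rng = np.random.default_rng(7)
        isi = rng.exponential(10.0, 10_000)
        cv = analysis.isi_cv(np.cumsum(isi))
        assert cv == pytest.approx(1.0, abs=3.0 / np.sqrt(10_000) * 2)

    def test_undefined_below_three_spikes(self):
        assert np.isnan(analysis.isi_cv(np.array([1.0, 2.0])))


class TestVectorStrength:
    @pytest.fixture(scope="class")
    def fp(self):
        st = rhythmic_raster(f_hz=20.0, seed=8)
        return analysis.field_potential(st, DT, int(4000.0 / DT))

    def test_spikes_at_peaks_give_unity(self, fp):
        vs = analysis.vector_strength(fp.peak_times[1:-1] + 1e-9, fp)
        assert vs == pytest.approx(1.0, abs=1e-6)

    def test_uniform_phases_give_near_zero(self, fp):
        rng = np.random.default_rng(9)
        k = 10_000
        st = rng.uniform(fp.peak_times[0], fp.peak_times[-1], k)
        assert analysis.vector_strength(st, fp) <= 3.0 / np.sqrt(k)

    def test_antipodal_pair_cancels(self, fp):
        t0, t1 = fp.peak_times[2], fp.peak_times[3]
        st = np.array([t0, (t0 + t1) / 2.0])  # phases 0 and pi
        assert analysis.vector_strength(st, fp) == pytest.approx(0.0, abs=1e-9)

    def test_spikes_outside_cycles_dropped(self, fp):
        st = np.array([fp.peak_times[0] - 50.0])
        assert np.isnan(analysis.vector_strength(st, fp))


class TestCycleCorrelation:
    def test_constructed_positive_association(self):
        """Cycles whose magnitude is proportional to the following period
        give r near 1."""
        rng = np.random.default_rng(10)
        periods = rng.uniform(35, 65, 60)
        t = 300.0  # away from filtfilt edge transients
        spikes = []
        for per in periods:
            n = int(per * 20)  # magnitude proportional to next period
            spikes.append(t + rng.normal(0, 5.0, n))
            t += per
        st = np.sort(np.concatenate(spikes))
        fp = analysis.field_potential(st, DT, int((t + 300) / DT))
        cs = analysis.cycle_correlation(fp)
        assert cs.r > 0.5

    def test_too_few_cycles_rejected(self):
        st = rhythmic_raster(f_hz=20.0, duration=300.0)
        fp = analysis.field_potential(st, DT, int(300.0 / DT), band=(5, 100))
        with pytest.raises(analysis.AnalysisError):
            analysis.cycle_correlation(fp)


class TestEIBalance:
    def _pulse(self, t, t0, width):
        return np.exp(-0.5 * ((t - t0) / width) ** 2)

    def test_identical_opposed_waveforms(self):
        t = np.arange(0, 50, 0.1)
        e = 100 * self._pulse(t, 20, 3)
        out = analysis.ei_balance(e, -e, t)
        assert out.delay == 0.0
        assert out.net_integral == 0.0

    def test_shifted_inhibition_delay(self):
        t = np.arange(0, 60, 0.1)
        e = 100 * self._pulse(t, 20, 3)
        i = -80 * self._pulse(t, 25, 3)
        out = analysis.ei_balance(e, i, t)
        assert out.delay == pytest.approx(5.0, abs=0.2)

    def test_halving_inhibition_halves_integral(self):
        t = np.arange(0, 80, 0.1)
        e = 100 * self._pulse(t, 20, 2)
        i = -60 * self._pulse(t, 50, 2)  # non-overlapping
        full = analysis.ei_balance(e, i, t).net_integral
        half = analysis.ei_balance(e, 0.5 * i, t).net_integral
        assert half == pytest.approx(0.5 * full, rel=1e-6)
        assert full < 0  # hyperpolarizing = negative in dV/dt convention


class TestRecovery:
    def test_exponential_recovery_time_is_tau(self):
        tau = 12.0
        t = np.arange(0, 200, 0.05)
        V = -60.0 - 8.0 * np.exp(-t / tau)
        assert analysis.recovery_time(V, t, -60.0) == pytest.approx(tau, abs=0.1)

    def test_no_trough_rejected(self):
        t = np.arange(0, 50, 0.1)
        with pytest.raises(analysis.AnalysisError):
            analysis.recovery_time(np.full_like(t, -55.0), t, -60.0)

    def test_no_recovery_rejected(self):
        t = np.arange(0, 5, 0.1)  # far too short to recover
        V = -60.0 - 8.0 * np.exp(-t / 100.0)
        with pytest.raises(analysis.AnalysisError):
            analysis.recovery_time(V, t, -60.0)

    def test_derivative_matches_analytic_slope(self):
        tau, A = 15.0, 10.0
        t = np.arange(0, 300, 0.01)
        V = -60.0 - A * np.exp(-t / tau)
        expected = 0.8 * A / (tau * np.log(9.0))
        got = analysis.recovery_derivative(V, t, -60.0)
        assert got == pytest.approx(expected, rel=0.01)

    def test_derivative_linear_in_amplitude_and_monotone_in_tau(self):
        t = np.arange(0, 300, 0.01)

        def d(A, tau):
            return analysis.recovery_derivative(-60 - A * np.exp(-t / tau), t, -60.0)

        assert d(8.0, 15.0) == pytest.approx(2 * d(4.0, 15.0), rel=0.01)
        taus = [5.0, 10.0, 20.0, 40.0]
        vals = [d(8.0, x) for x in taus]
        assert np.all(np.diff(vals) < 0)
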