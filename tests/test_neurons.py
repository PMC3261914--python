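"""Single-neuron dynamics: Boltzmann gates, AdEx pyramidal model, and the
conductance-based fast-spiking model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pingnet import cells, config, network, protocols
from pingnet.neurons import (
    FSState,
    RSPState,
    boltzmann,
    fs_derivative,
    fs_detect_spike,
    fs_init_state,
    rsp_apply_reset,
    rsp_derivative,
)


class TestBoltzmann:
    def test_midpoint_and_saturation(self):
        assert boltzmann(-24.0, -24.0, 11.5) == pytest.approx(0.5)
        assert boltzmann(1e4, -24.0, 11.5) == pytest.approx(1.0)
        assert boltzmann(-1e4, -24.0, 11.5) == pytest.approx(0.0)

    def test_analytic_inversion(self):
        # x_inf = 0.75  <=>  V = theta + sigma*ln(3)
        V = -58.3 + (-6.7) * math.log(3.0)
        assert boltzmann(V, -58.3, -6.7) == pytest.approx(0.75, rel=1e-12)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            boltzmann(0.0, -24.0, 0.0)

    @settings(deadline=None, max_examples=50)
    @given(
        v1=st.floats(-60, 10),
        dv=st.floats(1e-3, 20),
        sigma=st.floats(2.0, 30),
    )
    def test_monotone_in_v_with_sign_of_sigma(self, v1, dv, sigma):
        # away from floating-point saturation the ordering is strict
        assert boltzmann(v1 + dv, -24.0, sigma) > boltzmann(v1, -24.0, sigma)
        assert boltzmann(v1 + dv, -24.0, -sigma) < boltzmann(v1, -24.0, -sigma)


class TestRSPModel:
    def test_derivative_near_zero_at_leak_reversal(self, rsp_params):
        dV, dw1, dw2 = rsp_derivative(RSPState(V=rsp_params.E_l), rsp_params, 0.0)
        # residual is the exponential term, exp(-16.25)-small
        assert abs(dV) < 1e-6
        assert dw1 == 0.0 and dw2 == 0.0

    def test_membrane_time_constant_matches_C_over_gl(self, rsp_params):
        """Exponential fit to the full model's small hyperpolarizing step
        response recovers tau_m = C/g_l within 5%."""
        from scipy.optimize import curve_fit

        res = cells.simulate_cells(
            "rsp", rsp_params, 0.01, 300.0, np.array([-10.0]), record_decim=10
        )
        t, V = res.t, res.V[0]
        V_inf = V[-1]

        def f(t, A, tau):
            return V_inf + A * np.exp(-t / tau)

        (A, tau), _ = curve_fit(f, t, V, p0=(5.0, 30.0))
        tau_expected = rsp_params.C_pF / rsp_params.g_l
        assert tau == pytest.approx(tau_expected, rel=0.05)

    def test_lif_limit_is_exact_rc_charging(self):
        """With the exponential term pushed away and adaptation off, the
        step response is analytic RC charging."""
        p = config.RSPParams(V_t=1e6, a=0.0, b1=0.0, b2=0.0)
        I = 30.0
        res = cells.simulate_cells("rsp", p, 0.01, 200.0, np.array([I]), record_decim=1)
        tau = p.C_pF / p.g_l
        V_pred = p.E_l + (I / p.g_l) * (1.0 - np.exp(-res.t / tau))
        assert np.allclose(res.V[0], V_pred, atol=5e-3)

    def test_reset_rule(self, rsp_params):
        st_, spike = rsp_apply_reset(RSPState(V=25.0, w1=1.0, w2=2.0), rsp_params)
        assert spike and st_.V == rsp_params.V_reset
        assert st_.w1 == pytest.approx(1.0 + rsp_params.b1_eff)
        assert st_.w2 == pytest.approx(2.0 + rsp_params.b2_eff)
        st_, spike = rsp_apply_reset(RSPState(V=-60.0), rsp_params)
        assert not spike and st_.V == -60.0

    def test_consecutive_superthreshold_steps_both_spike(self, rsp_params):
        st_ = RSPState(V=30.0)
        st_, s1 = rsp_apply_reset(st_, rsp_params)
        st_.V = 30.0  # driven straight back over the cutoff
        st_, s2 = rsp_apply_reset(st_, rsp_params)
        assert s1 and s2

    def test_fi_curve_continuous_from_zero(self, rsp_params):
        """Integrator (saddle-node) regime: arbitrarily low rates exist
        near rheobase, so the lowest nonzero rate on a fine grid is small."""
        amps = np.arange(50.0, 70.0, 1.0)
        df = protocols.fi_protocol("rsp", rsp_params, amps)
        nz = df[df.n_spikes > 0]
        assert len(nz) > 0
        first = nz.iloc[0]
        assert first.n_spikes / 2.0 < 5.0  # < 5 spk/s at onset

    def test_adaptation_off_collapses_fi_curves(self):
        p = config.RSPParams(a=0.0, b1=0.0, b2=0.0)
        df = protocols.fi_protocol("rsp", p, np.array([80.0, 150.0, 300.0]))
        assert np.allclose(df.rate_unadapted, df.rate_adapted)

    @pytest.mark.parametrize("amp", [100.0, 250.0])
    def test_dt_halving_changes_counts_by_at_most_one(self, rsp_params, amp):
        n1 = len(cells.simulate_cells("rsp", rsp_params, 0.01, 2000.0,
                                      np.array([amp])).spikes[0])
        n2 = len(cells.simulate_cells("rsp", rsp_params, 0.005, 2000.0,
                                      np.array([amp])).spikes[0])
        assert abs(n1 - n2) <= 1


class TestFSModel:
    def test_whole_cell_capacitance_from_sphere(self, fs_params):
        r_cm = 18e-4
        C_pF_expected = 1.0 * 4 * math.pi * r_cm**2 * 1e6  # uF/cm^2 * cm^2 -> pF
        assert fs_params.C_pF == pytest.approx(C_pF_expected)
        assert fs_params.C_pF == pytest.approx(40.715, abs=0.01)

    def test_leak_only_relaxes_to_El(self):
        p = config.FSParams(gbar_Na=0.0, gbar_Kdr=0.0, gbar_d=0.0)
        res = cells.simulate_cells("fs", p, 0.01, 400.0, np.array([0.0]), V0=-50.0)
        assert res.V_final[0] == pytest.approx(p.E_l, abs=0.01)

    def test_rheobase_brackets_quiescence_and_tonic_spiking(self):
        """Bisection on DC finds a finite rheobase: below it a subthreshold
        equilibrium, above it periodic firing with a nonzero onset rate
        (subcritical Hopf-like transition).  The slow adaptation current is
        disabled so the onset reflects the spike-generating dynamics."""
        fs_params = config.FSParams(b_w=0.0)

        def steady_rate(amp):
            st = cells.simulate_cells("fs", fs_params, 0.01, 3000.0,
                                      np.array([amp])).spikes[0]
            return len(st[st > 1000.0]) / 2.0, st

        lo, hi = 0.0, 400.0
        for _ in range(12):
            mid = 0.5 * (lo + hi)
            if steady_rate(mid)[0] > 1.0:  # sustained firing
                hi = mid
            else:
                lo = mid
        rate_below, _ = steady_rate(lo)
        assert rate_below <= 1.0  # subthreshold equilibrium below rheobase
        # a steep onset: 2 pA above rheobase the cell already fires fast
        rate_above, st_above = steady_rate(hi + 2.0)
        assert rate_above > 10.0
        isi = np.diff(st_above[st_above > 1000.0])
        assert np.std(isi) / np.mean(isi) < 0.1  # periodic firing

    def test_gating_variables_stay_in_unit_interval(self, fs_params):
        """Forward-Euler at dt = 0.01 ms keeps all gates in [0, 1] during
        sustained spiking (reference implementation, 1-s run)."""
        st_ = fs_init_state(fs_params.E_l, fs_params)
        dt = 0.01
        for k in range(100_000):
            dV, dh, dn, da, db, dw = fs_derivative(st_, fs_params, 150.0)
            st_ = FSState(
                V=st_.V + dt * dV, h=st_.h + dt * dh, n=st_.n + dt * dn,
                a_gate=st_.a_gate + dt * da, b_gate=st_.b_gate + dt * db,
                w=st_.w + dt * dw, spike_armed=st_.spike_armed,
            )
            if k % 5000 == 0:
                for g in (st_.h, st_.n, st_.a_gate, st_.b_gate):
                    assert -1e-9 <= g <= 1 + 1e-9

    def test_spike_detector_hysteresis(self):
        st_ = FSState(V=-5.0, spike_armed=True)
        st_, s = fs_detect_spike(st_)
        assert not s
        st_.V = 3.0
        st_, s = fs_detect_spike(st_)
        assert s
        st_.V = 8.0
        st_, s = fs_detect_spike(st_)
        assert not s  # no re-arming above zero
        st_.V = -2.0
        st_, s = fs_detect_spike(st_)
        assert not s
        st_.V = 1.0
        st_, s = fs_detect_spike(st_)
        assert s

    def test_sinusoid_counts_upward_zero_crossings(self):
        t = np.arange(0.0, 100.0, 0.01)
        # starts below zero; 10 upward crossings at t = 1, 11, ..., 91
        V = 20.0 * np.sin(2 * np.pi * (t - 1.0) / 10.0)
        st_ = FSState(V=V[0], spike_armed=V[0] < 0)
        n = 0
        for v in V:
            st_.V = v
            st_, s = fs_detect_spike(st_)
            n += bool(s)
        assert n == 10

    @pytest.mark.parametrize("amp,check", [(10.0, "trace"), (120.0, "spikes")])
    def test_kernel_matches_reference_euler(self, fs_params, amp, check):
        """The LUT-based numba kernel reproduces the reference numpy Euler
        integration of the FS equations: subthreshold trajectories agree
        pointwise, spiking runs agree in spike count."""
        dt = 0.01
        st_ = fs_init_state(-65.0, fs_params)
        n_ref_spikes = 0
        for _ in range(20_000):  # 200 ms
            dV, dh, dn, da, db, dw = fs_derivative(st_, fs_params, amp)
            st_ = FSState(
                V=st_.V + dt * dV, h=st_.h + dt * dh, n=st_.n + dt * dn,
                a_gate=st_.a_gate + dt * da, b_gate=st_.b_gate + dt * db,
                w=st_.w + dt * dw, spike_armed=st_.spike_armed,
            )
            st_, s = fs_detect_spike(st_)
            if s:
                st_.w += fs_params.b_w
                n_ref_spikes += 1
        res = cells.simulate_cells("fs", fs_params, dt, 200.0, np.array([amp]),
                                   V0=-65.0)
        if check == "trace":
            assert res.V_final[0] == pytest.approx(st_.V, abs=1e-3)
        else:
            assert abs(len(res.spikes[0]) - n_ref_spikes) <= 1


class TestSpikeThreshold:
    def test_rsp_threshold_close_to_Vt(self, rsp_params):
        thr = network.find_spike_threshold("rsp", rsp_params)
        assert abs(thr - rsp_params.V_t) < 1.0

    def test_threshold_independent_of_capacitance(self, rsp_params):
        p2 = config.RSPParams(C=2 * rsp_params.C)
        t1 = network.find_spike_threshold("rsp", rsp_params)
        t2 = network.find_spike_threshold("rsp", p2)
        # numerical estimate near the saddle-node: agreement within 1 mV
        assert t1 == pytest.approx(t2, abs=1.0)

    def test_passive_cell_has_no_finite_threshold(self):
        p = config.RSPParams(V_t=1e5)  # exponential term pushed to infinity
        with pytest.raises(network.CalibrationError):
            network.find_spike_threshold("rsp", p)
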