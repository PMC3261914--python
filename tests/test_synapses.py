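"""Bi-exponential synapses, weight sampling, and network wiring."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad, solve_ivp

from pingnet import cells, config, synapses
from pingnet.config import SynapseKinetics
from pingnet.network import rescale_for_high_state, psp_peak


KIN = SynapseKinetics(tau_rise=1.0, tau_fall=5.0, E_syn=-75.0)


class TestBiexpWaveform:
    def test_zero_at_onset(self):
        assert synapses.biexp_conductance(0.0, KIN, 3.0) == pytest.approx(0.0)

    def test_peak_location_and_value(self):
        t_star = synapses.biexp_peak_time(KIN)
        assert t_star == pytest.approx(1.25 * math.log(5.0), rel=1e-12)
        t = np.linspace(0, 60, 200_001)
        g = synapses.biexp_conductance(t, KIN, 2.5)
        assert g.max() == pytest.approx(2.5, rel=1e-6)
        assert t[np.argmax(g)] == pytest.approx(t_star, abs=1e-3)

    def test_integral_matches_quadrature(self):
        analytic = synapses.biexp_integral(KIN, 2.0)
        numeric, _ = quad(lambda t: synapses.biexp_conductance(t, KIN, 2.0), 0, 500)
        assert analytic == pytest.approx(numeric, rel=1e-9)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            synapses.biexp_conductance(-1.0, KIN, 1.0)

    def test_degenerate_kinetics_rejected(self):
        with pytest.raises(Exception):
            SynapseKinetics(tau_rise=2.0, tau_fall=2.0, E_syn=0.0)

    @settings(deadline=None, max_examples=30)
    @given(tau_f=st.floats(1.5, 20.0), g=st.floats(0.1, 50.0))
    def test_peak_normalization_property(self, tau_f, g):
        kin = SynapseKinetics(tau_rise=1.0, tau_fall=tau_f, E_syn=0.0)
        t = np.linspace(0, 30 * tau_f, 40_000)
        assert synapses.biexp_conductance(t, kin, g).max() == pytest.approx(
            g, rel=1e-4
        )


class TestKineticsNormalization:
    def test_identity_at_reference(self):
        assert synapses.kinetics_normalization(5.0, 5.0, KIN) == pytest.approx(1.0)

    @pytest.mark.parametrize("tau_new", [2.0, 5.0, 8.0, 12.0])
    def test_scaled_integral_equals_reference(self, tau_new):
        scale = synapses.kinetics_normalization(tau_new, KIN.tau_fall, KIN)
        kin_new = SynapseKinetics(KIN.tau_rise, tau_new, KIN.E_syn)
        ref, _ = quad(lambda t: synapses.biexp_conductance(t, KIN, 1.0), 0, 1000)
        new, _ = quad(
            lambda t: synapses.biexp_conductance(t, kin_new, scale), 0, 1000
        )
        assert new == pytest.approx(ref, rel=1e-9)

    def test_monotone_decreasing_in_tau_fall(self):
        taus = np.linspace(2.0, 15.0, 12)
        scales = [synapses.kinetics_normalization(t, 5.0, KIN) for t in taus]
        assert np.all(np.diff(scales) < 0)


class TestConnectivitySampling:
    @pytest.fixture(scope="class")
    def conn(self):
        rng = np.random.default_rng(7)
        return synapses.sample_connectivity(rng)

    def test_expected_in_degree(self, conn):
        deg = conn.blocks["EE"].in_degree()
        # binomial(399, 0.2): 3-SE band around p*N = 80 for the mean of 400 cells
        se = math.sqrt(80 * 0.8 / 400)
        assert abs(deg.mean() - 0.2 * 400) < 3 * se + 0.2  # self-exclusion offset

    def test_total_conductance_budget(self, conn):
        for pt, gbar in config.DEFAULT_GBAR_TOT.items():
            tot = conn.blocks[pt].total_onto_post()
            se = tot.std() / math.sqrt(tot.size)
            assert abs(tot.mean() - gbar) < 3 * se + 0.02 * gbar

    def test_no_self_connections(self, conn):
        for pt in ("EE", "II"):
            blk = conn.blocks[pt]
            pre = np.repeat(np.arange(blk.n_pre), np.diff(blk.indptr))
            assert not np.any(pre == blk.post)

    def test_vanishing_dispersion_gives_identical_magnitudes(self):
        rng = np.random.default_rng(8)
        conn = synapses.sample_connectivity(rng, k1=1e-9, k2=1e-9)
        for pt, gbar in config.DEFAULT_GBAR_TOT.items():
            blk = conn.blocks[pt]
            n_bar = config.DEFAULT_P[pt] * blk.n_pre
            assert np.allclose(blk.g_peak, gbar / n_bar, rtol=1e-6)

    def test_all_weights_positive(self, conn):
        for blk in conn.blocks.values():
            assert np.all(blk.g_peak > 0)

    def test_invalid_dispersion_rejected(self):
        rng = np.random.default_rng(9)
        with pytest.raises(ValueError):
            synapses.sample_connectivity(rng, k1=1.5)


class TestSynapticDrive:
    def test_no_events_is_zero(self):
        assert synapses.synaptic_drive([], 10.0, -60.0) == 0.0

    def test_zero_at_reversal(self):
        events = [(0.0, 2.0, KIN)]
        for t in (1.0, 5.0, 20.0):
            assert synapses.synaptic_drive(events, t, -75.0) == 0.0

    def test_linear_superposition(self):
        e1 = [(0.0, 2.0, KIN)]
        e2 = [(1.0, 3.0, KIN)]
        both = e1 + e2
        for t in (0.5, 2.0, 7.0, 15.0):
            assert synapses.synaptic_drive(both, t, -60.0) == pytest.approx(
                synapses.synaptic_drive(e1, t, -60.0)
                + synapses.synaptic_drive(e2, t, -60.0),
                abs=1e-12,
            )

    def test_waveform_returns_below_truncation_bound(self):
        # after tau_fall * ln(1e7) the envelope is well under 1e-6 * g_peak
        t = KIN.tau_fall * math.log(1e7)
        g = synapses.biexp_conductance(t, KIN, 1.0)
        assert 0 <= g < 1e-6


class TestKernelSynapseEquivalence:
    def test_accumulator_scheme_matches_ode_oracle(self):
        """The engine's rise/fall accumulator synapses reproduce the passive
        membrane response to superposed bi-exponential waveforms computed
        with an adaptive ODE solver on the reference event-based drive."""
        p = config.RSPParams(V_t=1e6, a=0.0, b1=0.0, b2=0.0)  # passive limit
        kin = SynapseKinetics(tau_rise=0.5, tau_fall=2.5, E_syn=0.0)
        events = [(20.0, 1.5, kin), (21.0, 1.5, kin)]

        def rhs(t, y):
            I = synapses.synaptic_drive(events, t, y[0], truncate_rel=0.0)
            return [(-p.g_l * (y[0] - p.E_l) + I) / p.C_pF]

        sol = solve_ivp(rhs, (0, 120), [p.E_l], rtol=1e-9, atol=1e-10,
                        dense_output=True)
        res = cells.simulate_cells(
            "rsp", p, 0.01, 120.0, np.array([0.0]),
            event_times=np.array([20.0, 21.0]), event_gpeak=1.5,
            event_kinetics=kin, record_decim=1,
        )
        V_ref = sol.sol(res.t)[0]
        assert np.max(np.abs(res.V[0] - V_ref)) < 0.02  # mV, Euler dt error


class TestHighStateRescale:
    def test_factor_within_passive_bracket_and_psp_matched(self, rsp_params):
        """The PSP-matching factor for a synapse onto a high-conductance
        RSP cell lies in the passive-membrane bracket: above 1 (attenuation
        exists) and below the slow-synapse limit (g_l + g_tonic)/g_l — a
        synapse briefer than the membrane time constant is partly
        charge-dominated, so its peak attenuates less than the steady-state
        ratio.  The rescaled PSP matches the low-state PSP to 1%."""
        kin = config.default_kinetics()["EE"]
        g_ref = 37.5 / 80.0
        f = rescale_for_high_state("rsp", rsp_params, kin, g_ref, 10.8, 2.7)
        slow_limit = (rsp_params.g_l + 10.8 + 2.7) / rsp_params.g_l
        assert 1.0 < f < slow_limit
        low = psp_peak("rsp", rsp_params, kin, g_ref)
        high = psp_peak("rsp", rsp_params, kin, g_ref * f, 10.8, 2.7)
        assert high == pytest.approx(low, rel=0.02)
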