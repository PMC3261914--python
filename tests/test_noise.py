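"""Ornstein-Uhlenbeck background conductance processes."""

import numpy as np
import pytest

from pingnet import noise
from pingnet.config import OUParams, conductance_state
from pingnet.network import steady_state


@pytest.fixture(scope="module")
def ou_e():
    return OUParams(g_avg=0.0, tau=2.0, D=5e-4, E_rev=0.0)


class TestOUStep:
    def test_deterministic_relaxation_is_exact(self):
        p = OUParams(g_avg=3.0, tau=8.0, D=0.0, E_rev=-75.0)
        s = 10.0
        dt = 0.37
        for k in range(1, 40):
            s = noise.ou_step(s, p, dt, 0.0)
            expected = 3.0 + 7.0 * np.exp(-k * dt / 8.0)
            assert s == pytest.approx(expected, rel=1e-12)

    def test_stationary_moments_match_closed_form(self, ou_e):
        rng = np.random.default_rng(11)
        traj = noise.simulate_ou(ou_e, dt=0.01, n_steps=400_000, rng=rng)
        sd_expected = np.sqrt(ou_e.D * ou_e.tau / 2.0)
        # effective number of independent samples ~ N*dt/(2*tau)
        n_eff = 400_000 * 0.01 / (2 * ou_e.tau)
        se_sd = sd_expected / np.sqrt(2 * n_eff)
        assert np.std(traj) == pytest.approx(sd_expected, abs=3 * se_sd)
        se_mean = sd_expected / np.sqrt(n_eff)
        assert np.mean(traj) == pytest.approx(ou_e.g_avg, abs=3 * se_mean)

    def test_autocorrelation_decays_with_tau(self, ou_e):
        rng = np.random.default_rng(12)
        dt = 0.05
        traj = noise.simulate_ou(ou_e, dt=dt, n_steps=300_000, rng=rng)
        x = traj - traj.mean()
        for lag_ms in (1.0, 2.0, 4.0):
            k = int(lag_ms / dt)
            rho = np.dot(x[:-k], x[k:]) / np.dot(x, x)
            assert rho == pytest.approx(np.exp(-lag_ms / ou_e.tau), abs=0.03)

    def test_update_composes_exactly_across_dt(self, ou_e):
        """Exactness of the discretization: two dt-steps have the same
        first two moments as one 2dt-step, for any dt."""
        for dt in (0.01, 0.1, 1.0, 7.3):
            dec1, dif1 = noise.ou_coefficients(ou_e, dt)
            dec2, dif2 = noise.ou_coefficients(ou_e, 2 * dt)
            assert dec1**2 == pytest.approx(dec2, rel=1e-12)
            assert dif1**2 * (1 + dec1**2) == pytest.approx(dif2**2, rel=1e-12)

    def test_bad_dt_rejected(self, ou_e):
        with pytest.raises(ValueError):
            noise.ou_step(0.0, ou_e, 0.0, 0.0)


class TestOUCurrent:
    def test_zero_at_reversal_and_zero_conductance(self):
        pe, pi = conductance_state("rsp", "high")
        assert noise.ou_current(10.8, 0.0, pe.E_rev, pe, pi) == 0.0
        assert noise.ou_current(0.0, 0.0, -60.0, pe, pi) == 0.0

    def test_high_state_driving_current(self):
        pe, pi = conductance_state("rsp", "high")
        I = noise.ou_current(10.8, 0.0, -65.0, pe, pi)
        assert I == pytest.approx(10.8 * 65.0)  # 702 pA, inward-positive


class TestConductanceStates:
    @pytest.mark.parametrize(
        "pop,label,expected",
        [
            ("rsp", "high", (10.8, 2.7)),
            ("fs", "high", (12.0, 3.0)),
            ("rsp", "low", (5e-4, 2e-3)),
            ("fs", "low", (5e-4, 2e-3)),
        ],
    )
    def test_table_means(self, pop, label, expected):
        pe, pi = conductance_state(pop, label)
        assert (pe.g_avg, pi.g_avg) == expected
        assert (pe.tau, pi.tau) == (2.0, 8.0)
        assert (pe.D, pi.D) == (5e-4, 2e-3)

    def test_unknown_label_rejected(self):
        with pytest.raises(Exception):
            conductance_state("rsp", "medium")

    def test_high_state_negative_fraction_negligible(self):
        pe, _ = conductance_state("rsp", "high", noise_scale=20.0)
        rng = np.random.default_rng(3)
        traj = noise.simulate_ou(pe, dt=0.01, n_steps=100_000, rng=rng)
        assert noise.negative_fraction(traj) < 0.01


class TestInputResistanceReduction:
    def test_reduction_follows_conductance_ratio(self, rsp_params):
        """Adding the high-state tonic means reduces the small-signal input
        resistance by ~g_l/(g_l + g_e + g_i) (the model's own closed form)."""
        ge, gi = 10.8, 2.7

        def rin(ge0, gi0, I0):
            V1, _, _ = steady_state("rsp", rsp_params, I0 - 5.0, ge0, gi0)
            V2, _, _ = steady_state("rsp", rsp_params, I0 + 5.0, ge0, gi0)
            return (V2[0] - V1[0]) / 10.0  # GOhm in mV/pA

        r_low = rin(0.0, 0.0, -20.0)
        # hold the high-state cell well below threshold (away from the
        # exponential term's negative conductance) with negative DC
        r_high = rin(ge, gi, -520.0)
        expected = rsp_params.g_l / (rsp_params.g_l + ge + gi)
        assert r_high / r_low == pytest.approx(expected, rel=0.10)
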