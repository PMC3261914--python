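"""Model parameters, network configuration, and YAML config I/O.

Unit convention used across the whole package: voltages in mV, times in ms,
conductances in nS, currents in pA, capacitances in nF.  The fast-spiking
interneuron model is specified with specific (per-area) quantities
(uF/cm^2, mS/cm^2) which are converted to whole-cell values through the
surface area of an isopotential sphere at load time.

The default values are the fitted constants of the two cell models (a
regular-spiking pyramidal AdEx variant with two adaptation time scales, and
a conductance-based fast-spiking interneuron with Na, delayed-rectifier K,
D-type K and leak conductances), of the Ornstein-Uhlenbeck background
conductance processes, and of the bi-exponential synapses and the random
network wiring.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

PAIR_TYPES = ("EE", "EI", "IE", "II")  # pre->post: E->E, E->I, I->E, I->I


class ConfigError(ValueError):
    """A configuration value failed validation."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass
class RSPParams:
    """Regular-spiking pyramidal neuron: adaptive exponential I&F with a fast
    (partly voltage-coupled) and a slow (purely spike-triggered) adaptation
    current.

    ``a``, ``b1``, ``b2`` are stored as printed in the source parameter
    table; the per-variable ``*_scale`` factors convert them to the
    effective values used by the dynamics (see docs/methods.md for why the
    printed magnitudes are rescaled).
    """

    C: float = 0.15          # nF
    g_l: float = 4.5         # nS
    E_l: float = -65.0       # mV
    Delta_t: float = 0.8     # mV, spike sharpness
    V_t: float = -52.0       # mV, exponential threshold
    V_reset: float = -53.0   # mV
    V_spike: float = 20.0    # mV, numerical spike cutoff
    a: float = -5e-5         # subthreshold adaptation coupling (printed units)
    tau_w1: float = 20.0     # ms
    b1: float = 0.05         # fast spike-triggered increment (printed units)
    tau_w2: float = 550.0    # ms
    b2: float = 0.0015       # slow spike-triggered increment (printed units)
    a_scale: float = 1000.0
    b1_scale: float = 1000.0
    b2_scale: float = 1000.0
    exp_clamp: float = 30.0  # cap on the exponential-term argument

    def __post_init__(self) -> None:
        _require(self.C > 0, "RSP C must be > 0")
        _require(self.g_l > 0, "RSP g_l must be > 0")
        _require(self.Delta_t > 0, "RSP Delta_t must be > 0")
        _require(self.V_reset < self.V_spike, "RSP V_reset must be < V_spike")
        _require(self.tau_w1 > 0 and self.tau_w2 > 0, "RSP adaptation taus must be > 0")

    @property
    def C_pF(self) -> float:
        """Capacitance in pF (pA / (mV/ms) in the repo unit system)."""
        return self.C * 1e3

    @property
    def a_eff(self) -> float:
        """Effective subthreshold coupling, nS."""
        return self.a * self.a_scale

    @property
    def b1_eff(self) -> float:
        """Effective fast spike-triggered increment, pA."""
        return self.b1 * self.b1_scale

    @property
    def b2_eff(self) -> float:
        """Effective slow spike-triggered increment, pA."""
        return self.b2 * self.b2_scale


@dataclass
class FSParams:
    """Fast-spiking interneuron: single-compartment conductance-based model
    (isopotential sphere) with instantaneous Na activation, Na inactivation
    ``h``, delayed-rectifier activation ``n``, D-type K activation and
    inactivation ``a``/``b``, a linear leak, and a slow spike-triggered
    adaptation current ``w``.

    Steady states of all gates are Boltzmann functions of voltage;
    ``theta_th``/``sigma_th`` parameterize the voltage dependence of the Na
    inactivation time constant.  Gate exponents and the tau-form
    coefficients are exposed so the kinetics can be matched to variant
    parameterizations of the same model family.
    """

    C_spec: float = 1.0        # uF/cm^2
    radius_um: float = 18.0    # sphere radius
    gbar_Na: float = 135.0     # mS/cm^2
    gbar_Kdr: float = 675.0    # mS/cm^2
    gbar_d: float = 0.3        # mS/cm^2
    g_l: float = 7.0           # nS (whole-cell)
    E_Na: float = 50.0         # mV
    E_K: float = -70.0         # mV
    E_l: float = -65.0         # mV
    theta_m: float = -24.0
    sigma_m: float = 11.5
    theta_h: float = -58.3
    sigma_h: float = -6.7
    theta_th: float = -60.0
    sigma_th: float = -12.0
    theta_n: float = -12.4
    sigma_n: float = 9.8
    theta_a: float = -50.0
    sigma_a: float = 20.0
    theta_b: float = -70.0
    sigma_b: float = -6.0
    tau_a: float = 2.0         # ms
    tau_b: float = 150.0       # ms
    tau_w: float = 500.0       # ms
    b_w: float = 2.0           # pA, spike-triggered adaptation increment
    p_Na: int = 3              # exponent on m_inf
    p_Kdr: int = 4             # exponent on n
    p_a: int = 3               # exponent on the D-current activation gate
    # tau_h(V) = tau_h_base + tau_h_amp * G(V; theta_th, sigma_th)
    tau_h_base: float = 0.5
    tau_h_amp: float = 14.0
    # tau_n(V) = (c0 + c1*G(V; th1, s1)) * (c0 + c1*G(V; th2, s2))
    tau_n_c0: float = 0.087
    tau_n_c1: float = 11.4
    tau_n_theta1: float = -14.6
    tau_n_sigma1: float = -8.6
    tau_n_theta2: float = 1.3
    tau_n_sigma2: float = 18.7

    def __post_init__(self) -> None:
        _require(self.radius_um > 0, "FS radius must be > 0")
        _require(
            min(self.gbar_Na, self.gbar_Kdr, self.gbar_d) >= 0,
            "FS maximal conductances must be >= 0",
        )
        _require(self.g_l > 0, "FS g_l must be > 0")
        for name in ("sigma_m", "sigma_h", "sigma_n", "sigma_a", "sigma_b", "sigma_th"):
            _require(getattr(self, name) != 0, f"FS {name} must be nonzero")

    @property
    def area_cm2(self) -> float:
        """Membrane area of the isopotential sphere, cm^2."""
        r_cm = self.radius_um * 1e-4
        return 4.0 * math.pi * r_cm**2

    @property
    def C(self) -> float:
        """Whole-cell capacitance, nF (uF/cm^2 * cm^2 * 1e3 nF/uF)."""
        return self.C_spec * self.area_cm2 * 1e3

    @property
    def C_pF(self) -> float:
        """Whole-cell capacitance in pF."""
        return self.C * 1e3

    @property
    def g_Na(self) -> float:
        """Whole-cell maximal Na conductance, nS."""
        return self.gbar_Na * self.area_cm2 * 1e6

    @property
    def g_Kdr(self) -> float:
        """Whole-cell maximal delayed-rectifier conductance, nS."""
        return self.gbar_Kdr * self.area_cm2 * 1e6

    @property
    def g_d(self) -> float:
        """Whole-cell maximal D-type K conductance, nS."""
        return self.gbar_d * self.area_cm2 * 1e6


@dataclass
class OUParams:
    """One Ornstein-Uhlenbeck conductance process (excitatory or inhibitory
    background input to one cell).  The stationary SD is
    sqrt(D * tau / 2) before the ``noise_scale`` multiplier."""

    g_avg: float             # nS, stationary mean
    tau: float               # ms, correlation time
    D: float                 # nS^2/ms, fluctuation magnitude
    E_rev: float             # mV
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        _require(self.tau > 0, "OU tau must be > 0")
        _require(self.D >= 0, "OU D must be >= 0")
        _require(self.noise_scale >= 0, "OU noise_scale must be >= 0")

    @property
    def sigma_stat(self) -> float:
        """Unscaled stationary standard deviation, nS."""
        return math.sqrt(self.D * self.tau / 2.0)


# Mean background conductances (nS) per population and conductance state.
_G_AVG = {
    ("rsp", "low"): (5e-4, 2e-3),
    ("rsp", "high"): (10.8, 2.7),
    ("fs", "low"): (5e-4, 2e-3),
    ("fs", "high"): (12.0, 3.0),
}
TAU_E, TAU_I = 2.0, 8.0          # ms
D_E, D_I = 5e-4, 2e-3            # nS^2/ms
E_E, E_I = 0.0, -75.0            # mV


def conductance_state(
    population: str, state_label: str, noise_scale: float = 1.0
) -> tuple[OUParams, OUParams]:
    """Return the (excitatory, inhibitory) OU parameter pair for one
    population ('rsp' | 'fs') in one conductance state ('low' | 'high').

    Only the mean conductances differ between states; the correlation times
    and fluctuation magnitudes are state-independent.
    """
    key = (population.lower(), state_label.lower())
    if key not in _G_AVG:
        raise ConfigError(
            f"unknown population/state {population!r}/{state_label!r}; "
            "expected population in {'rsp','fs'} and state in {'low','high'}"
        )
    g_e, g_i = _G_AVG[key]
    return (
        OUParams(g_avg=g_e, tau=TAU_E, D=D_E, E_rev=E_E, noise_scale=noise_scale),
        OUParams(g_avg=g_i, tau=TAU_I, D=D_I, E_rev=E_I, noise_scale=noise_scale),
    )


@dataclass
class SynapseKinetics:
    """Bi-exponential conductance kinetics for one pair type."""

    tau_rise: float  # ms
    tau_fall: float  # ms
    E_syn: float     # mV
    delay: float = 0.0  # ms, axonal/synaptic delay

    def __post_init__(self) -> None:
        _require(self.tau_rise > 0, "tau_rise must be > 0")
        _require(
            self.tau_rise < self.tau_fall,
            "tau_rise must be < tau_fall (degenerate alpha kinetics unsupported)",
        )
        _require(self.delay >= 0, "delay must be >= 0")


def default_kinetics() -> dict[str, SynapseKinetics]:
    """Table defaults: E synapses 0.5/2.5 ms, I synapses 1.0/5.0 ms;
    reversals EE 0, EI 0, IE -65, II -55 mV; no baseline delay."""
    return {
        "EE": SynapseKinetics(0.5, 2.5, 0.0),
        "EI": SynapseKinetics(0.5, 2.5, 0.0),
        "IE": SynapseKinetics(1.0, 5.0, -65.0),
        "II": SynapseKinetics(1.0, 5.0, -55.0),
    }


# Per-pair connection probabilities and total postsynaptic conductance
# budgets (nS per postsynaptic cell) in the low-conductance state.
DEFAULT_P = {"EE": 0.2, "EI": 0.4, "IE": 0.4, "II": 0.4}
DEFAULT_GBAR_TOT = {"EE": 37.5, "EI": 100.0, "IE": 46.25, "II": 25.0}
DEFAULT_K1 = 0.25
DEFAULT_K2 = 0.25


@dataclass
class NetworkConfig:
    """Everything needed to assemble and run one network simulation."""

    N_E: int = 400
    N_I: int = 100
    dt: float = 0.01            # ms
    duration: float = 10_000.0  # ms
    burn_in: float = 500.0      # ms discarded from all statistics
    rsp_state: str = "low"      # background conductance state of RSP cells
    fs_state: str = "low"
    noise_scale: float = 1.0    # global multiplier on OU fluctuation SD
    rest_offset_lo: float = 0.0   # mV below threshold, rest-rule band
    rest_offset_hi: float = 15.0
    extra_ie_delay: float = 0.0   # ms, added artificial I->E delay
    p: dict = field(default_factory=lambda: dict(DEFAULT_P))
    gbar_tot: dict = field(default_factory=lambda: dict(DEFAULT_GBAR_TOT))
    k1: float = DEFAULT_K1
    k2: float = DEFAULT_K2
    realized_count_mode: bool = False  # per-synapse scale from realized in-degree
    record_decim: int = 10      # trace decimation in steps (0.1 ms at dt=0.01)
    n_record_ve: int = 25       # number of RSP voltage traces kept
    n_record_vi: int = 10
    rsp: RSPParams = field(default_factory=RSPParams)
    fs: FSParams = field(default_factory=FSParams)
    kinetics: dict = field(default_factory=default_kinetics)

    def __post_init__(self) -> None:
        _require(self.dt > 0, "dt must be > 0")
        _require(self.duration > 0, "duration must be > 0")
        _require(self.N_E > 0 and self.N_I > 0, "population sizes must be > 0")
        _require(self.burn_in >= 0, "burn_in must be >= 0")
        _require(self.rsp_state in ("low", "high"), "rsp_state must be low|high")
        _require(self.fs_state in ("low", "high"), "fs_state must be low|high")
        _require(0 < self.k1 < 1 and 0 < self.k2 < 1, "k1, k2 must be in (0, 1)")
        for pt in PAIR_TYPES:
            _require(pt in self.p, f"missing connection probability for {pt}")
            _require(0 < self.p[pt] <= 1, f"p[{pt}] must be in (0, 1]")
            _require(pt in self.gbar_tot, f"missing gbar_tot for {pt}")
        _require(self.extra_ie_delay >= 0, "extra_ie_delay must be >= 0")
        _require(self.record_decim >= 1, "record_decim must be >= 1")

    def noise_params(self, population: str) -> tuple[OUParams, OUParams]:
        state = self.rsp_state if population == "rsp" else self.fs_state
        return conductance_state(population, state, self.noise_scale)


# ---------------------------------------------------------------------------
# YAML round trip


def _to_dict(cfg: NetworkConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["kinetics"] = {
        pt: dataclasses.asdict(k) if not isinstance(k, dict) else k
        for pt, k in (
            (pt, cfg.kinetics[pt]) for pt in PAIR_TYPES
        )
    }
    return d


def save_config(cfg: NetworkConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_dict(cfg), fh, sort_keys=False)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> NetworkConfig:
    """Build a NetworkConfig from defaults plus a YAML override file and/or
    an override mapping.  An empty/absent file yields the exact table
    defaults.  Validation failures raise :class:`ConfigError` naming the
    offending field."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded:
            if not isinstance(loaded, dict):
                raise ConfigError(f"config file {path} must contain a mapping")
            data.update(loaded)
    if overrides:
        data.update(overrides)

    def build(cls, section):
        if section is None:
            return cls()
        if dataclasses.is_dataclass(section):
            return section
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(section) - known
        if bad:
            raise ConfigError(f"unknown field(s) for {cls.__name__}: {sorted(bad)}")
        try:
            return cls(**section)
        except TypeError as exc:  # pragma: no cover - defensive
            raise ConfigError(str(exc)) from exc

    rsp = build(RSPParams, data.pop("rsp", None))
    fs = build(FSParams, data.pop("fs", None))
    kin_raw = data.pop("kinetics", None)
    kinetics = default_kinetics()
    if kin_raw:
        for pt, spec_ in kin_raw.items():
            if pt not in PAIR_TYPES:
                raise ConfigError(f"unknown pair type {pt!r} in kinetics")
            kinetics[pt] = build(SynapseKinetics, spec_)
    known = {f.name for f in dataclasses.fields(NetworkConfig)}
    bad = set(data) - known
    if bad:
        raise ConfigError(f"unknown NetworkConfig field(s): {sorted(bad)}")
    return NetworkConfig(rsp=rsp, fs=fs, kinetics=kinetics, **data)
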