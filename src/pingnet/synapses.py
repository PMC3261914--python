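"""Bi-exponential conductance synapses and random network wiring.

A presynaptic spike initiates a peak-normalized bi-exponential conductance
waveform in each connected postsynaptic cell,

    g(t) = g_peak * (exp(-t/tau_fall) - exp(-t/tau_rise)) / P,

where P is the maximum of the bracketed difference, so that ``g_peak`` is
the waveform peak.  Successive waveforms superpose linearly.

Wiring is random (Bernoulli per ordered pair, no self-connections) with a
two-level uniform sampling scheme for conductance magnitudes: the total
conductance budget of each postsynaptic cell for a given pair type is drawn
from U(Gbar*(1-k1), Gbar*(1+k1)); individual synapse peaks are then drawn
from U((G_tot/n)(1-k2), (G_tot/n)(1+k2)) where n is the expected afferent
count p * N_pre (a config flag switches to the realized count).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PAIR_TYPES, SynapseKinetics


def biexp_peak_time(kinetics: SynapseKinetics) -> float:
    """Time of the waveform maximum: tau_f*tau_r/(tau_f - tau_r) * ln(tau_f/tau_r)."""
    tr, tf = kinetics.tau_rise, kinetics.tau_fall
    return tf * tr / (tf - tr) * math.log(tf / tr)


def biexp_norm(kinetics: SynapseKinetics) -> float:
    """Peak P of exp(-t/tau_fall) - exp(-t/tau_rise) (the normalizer)."""
    t_star = biexp_peak_time(kinetics)
    return math.exp(-t_star / kinetics.tau_fall) - math.exp(-t_star / kinetics.tau_rise)


def biexp_conductance(t_since_event, kinetics: SynapseKinetics, g_peak: float):
    """Conductance (nS) at time(s) ``t_since_event`` (ms, >= 0) after
    initiation; g(0) = 0 and max_t g(t) = g_peak."""
    t = np.asarray(t_since_event, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_since_event must be >= 0")
    g = g_peak * (np.exp(-t / kinetics.tau_fall) - np.exp(-t / kinetics.tau_rise)) \
        / biexp_norm(kinetics)
    return g if g.ndim else float(g)


def biexp_integral(kinetics: SynapseKinetics, g_peak: float = 1.0) -> float:
    """Analytic time integral of the waveform: g_peak*(tau_fall - tau_rise)/P."""
    return g_peak * (kinetics.tau_fall - kinetics.tau_rise) / biexp_norm(kinetics)


def kinetics_normalization(
    tau_fall_new: float, tau_fall_ref: float, kinetics: SynapseKinetics
) -> float:
    """Scale factor on g_peak that keeps the time-integrated conductance
    equal to the reference-kinetics integral when the decay time constant is
    changed from ``tau_fall_ref`` to ``tau_fall_new`` (rise time unchanged).
    """
    kin_ref = SynapseKinetics(kinetics.tau_rise, tau_fall_ref, kinetics.E_syn)
    kin_new = SynapseKinetics(kinetics.tau_rise, tau_fall_new, kinetics.E_syn)
    return biexp_integral(kin_ref) / biexp_integral(kin_new)


# ---------------------------------------------------------------------------
# Connectivity


@dataclass
class PairBlock:
    """Synapses of one pair type in presynaptic CSR layout.

    ``indptr[i]:indptr[i+1]`` indexes the outgoing synapses of presynaptic
    cell i; ``post`` and ``g_peak`` hold target indices and peak
    conductances (nS)."""

    indptr: np.ndarray
    post: np.ndarray
    g_peak: np.ndarray
    n_pre: int
    n_post: int

    @property
    def n_syn(self) -> int:
        return int(self.post.size)

    def in_degree(self) -> np.ndarray:
        return np.bincount(self.post, minlength=self.n_post)

    def total_onto_post(self) -> np.ndarray:
        return np.bincount(self.post, weights=self.g_peak, minlength=self.n_post)


@dataclass
class Connectivity:
    """Directed synapse table for the full network, one block per pair type."""

    blocks: dict[str, PairBlock]
    p: dict[str, float]
    gbar_tot: dict[str, float]
    k1: float
    k2: float
    seed_info: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pt, blk in self.blocks.items():
            pre = np.repeat(np.arange(blk.n_pre), np.diff(blk.indptr))
            rows.append(
                pd.DataFrame(
                    {
                        "pre_id": pre,
                        "post_id": blk.post,
                        "pair_type": pt,
                        "g_peak_nS": blk.g_peak,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _sample_pair(
    rng: np.random.Generator,
    n_pre: int,
    n_post: int,
    p: float,
    gbar: float,
    k1: float,
    k2: float,
    same_population: bool,
    realized_count_mode: bool,
) -> PairBlock:
    adj = rng.random((n_pre, n_post)) < p
    if same_population:
        np.fill_diagonal(adj, False)
    g_tot = gbar * rng.uniform(1.0 - k1, 1.0 + k1, size=n_post)
    in_deg = adj.sum(axis=0)
    n_bar = in_deg.astype(float) if realized_count_mode else np.full(n_post, p * n_pre)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_syn = np.where(n_bar > 0, g_tot / np.maximum(n_bar, 1e-300), 0.0)
    pre_idx, post_idx = np.nonzero(adj)
    scale = per_syn[post_idx]
    w = scale * rng.uniform(1.0 - k2, 1.0 + k2, size=post_idx.size)
    indptr = np.zeros(n_pre + 1, dtype=np.int64)
    np.add.at(indptr, pre_idx + 1, 1)
    indptr = np.cumsum(indptr)
    # np.nonzero returns row-major order, already grouped by pre_idx.
    return PairBlock(
        indptr=indptr,
        post=post_idx.astype(np.int64),
        g_peak=w.astype(np.float64),
        n_pre=n_pre,
        n_post=n_post,
    )


def sample_connectivity(
    rng: np.random.Generator,
    N_E: int = 400,
    N_I: int = 100,
    p: dict[str, float] | None = None,
    gbar_tot: dict[str, float] | None = None,
    k1: float = 0.25,
    k2: float = 0.25,
    realized_count_mode: bool = False,
) -> Connectivity:
    """Draw one random network realization.

    Pair types are pre->post: EE (E->E), EI (E->I), IE (I->E), II (I->I).
    """
    from .config import DEFAULT_GBAR_TOT, DEFAULT_P

    p = dict(DEFAULT_P if p is None else p)
    gbar_tot = dict(DEFAULT_GBAR_TOT if gbar_tot is None else gbar_tot)
    if not (0 < k1 < 1 and 0 < k2 < 1):
        raise ValueError("k1, k2 must be in (0, 1)")
    for pt in PAIR_TYPES:
        if not 0 < p[pt] <= 1:
            raise ValueError(f"p[{pt}] must be in (0, 1]")
    sizes = {"EE": (N_E, N_E), "EI": (N_E, N_I), "IE": (N_I, N_E), "II": (N_I, N_I)}
    blocks = {
        pt: _sample_pair(
            rng,
            *sizes[pt],
            p[pt],
            gbar_tot[pt],
            k1,
            k2,
            same_population=pt in ("EE", "II"),
            realized_count_mode=realized_count_mode,
        )
        for pt in PAIR_TYPES
    }
    return Connectivity(blocks=blocks, p=p, gbar_tot=gbar_tot, k1=k1, k2=k2)


def scale_pair(conn: Connectivity, pair_type: str, factor: float) -> None:
    """Multiply all peak conductances of one pair type in place."""
    conn.blocks[pair_type].g_peak *= factor


def rescale_for_high_state(*args, **kwargs):
    """PSP-matched rescaling of synapses onto high-conductance-state cells
    (lazy re-export; the implementation lives with the single-cell
    calibration machinery in :mod:`pingnet.network`)."""
    from .network import rescale_for_high_state as _impl

    return _impl(*args, **kwargs)


# ---------------------------------------------------------------------------
# Reference event-based synaptic drive (oracle path; the engine uses
# mathematically-identical two-state exponential accumulators)


def synaptic_drive(
    events: list[tuple[float, float, SynapseKinetics]],
    t: float,
    V_post: float,
    truncate_rel: float = 1e-6,
) -> float:
    """Total synaptic current (pA, inward-positive) at time t from a list of
    (arrival_time_ms, g_peak_nS, kinetics) events, superposing waveforms
    linearly.  Contributions whose conductance envelope has decayed below
    ``truncate_rel * g_peak`` are dropped."""
    I = 0.0
    for t_arr, g_peak, kin in events:
        dt = t - t_arr
        if dt < 0:
            continue
        if truncate_rel > 0 and dt > 0:
            # envelope bound: exp(-dt/tau_fall) >= waveform / g_peak * P
            if math.exp(-dt / kin.tau_fall) < truncate_rel * biexp_norm(kin):
                continue
        g = biexp_conductance(dt, kin, g_peak)
        I += -g * (V_post - kin.E_syn)
    return I


# ---------------------------------------------------------------------------
# Edge-list export / import


def write_connectivity(conn: Connectivity, path: str | Path, delays: dict | None = None) -> None:
    """Write the synapse table as CSV with a JSON comment header recording
    the sampling parameters."""
    path = Path(path)
    header = {
        "p": conn.p,
        "gbar_tot": conn.gbar_tot,
        "k1": conn.k1,
        "k2": conn.k2,
        "seed_info": conn.seed_info,
        "delays_ms": delays or {},
    }
    df = conn.to_frame()
    df["delay_ms"] = [header["delays_ms"].get(pt, 0.0) for pt in df["pair_type"]]
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        df.to_csv(fh, index=False)


def read_connectivity(path: str | Path) -> tuple[pd.DataFrame, dict]:
    with open(path) as fh:
        first = fh.readline()
        header = json.loads(first.lstrip("# ").strip()) if first.startswith("#") else {}
        df = pd.read_csv(fh)
    return df, header
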