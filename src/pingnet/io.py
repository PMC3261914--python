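"""File writers/readers and run manifests.

Tabular outputs are plain CSV; voltage/conductance traces go to one HDF5
container; the manifest (resolved config, seeds, calibration outputs) is
YAML, sufficient to reproduce any output bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .network import NetworkInstance, SimulationResult


class RasterFormatError(ValueError):
    """Malformed raster file."""


def write_raster(result_or_frame, path: str | Path) -> None:
    """Write a spike raster as CSV with columns (cell_id, t_ms, pop);
    times at 0.01 ms precision; pop is 'rsp' or 'fs'."""
    if isinstance(result_or_frame, SimulationResult):
        r = result_or_frame
        df = pd.DataFrame(
            {
                "cell_id": r.spike_cell,
                "t_ms": np.round(r.spike_t, 2),
                "pop": np.where(r.spike_pop == 0, "rsp", "fs"),
            }
        )
    else:
        df = result_or_frame
    df.to_csv(path, index=False, float_format="%.2f")


def read_raster(path: str | Path) -> pd.DataFrame:
    """Read a raster CSV back, validating per-cell time monotonicity."""
    df = pd.read_csv(path)
    expected = ["cell_id", "t_ms", "pop"]
    if list(df.columns) != expected:
        raise RasterFormatError(f"expected columns {expected}, got {list(df.columns)}")
    for (pop, cell), grp in df.groupby(["pop", "cell_id"], sort=False):
        t = grp["t_ms"].to_numpy()
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            row = grp.index[bad[0] + 1] + 2  # header + 1-based
            raise RasterFormatError(
                f"non-monotone spike times for {pop} cell {cell} at line {row}"
            )
    return df


def save_traces(result: SimulationResult, path: str | Path) -> None:
    """Store the decimated traces of one run in an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("t_ms", data=result.t_rec)
        f.create_dataset("V_E", data=result.V_E)
        f.create_dataset("V_I", data=result.V_I)
        f.create_dataset("g_E", data=result.g_E)
        f.create_dataset("mean_V_E", data=result.mean_V_E)
        f.create_dataset("sel_E", data=result.sel_E)
        f.create_dataset("sel_I", data=result.sel_I)
        f.attrs["dt_ms"] = result.dt
        f.attrs["duration_ms"] = result.duration
        f.attrs["burn_in_ms"] = result.burn_in
        f.attrs["seeds"] = json.dumps(result.seeds)
        f.attrs["config"] = json.dumps(result.config, default=str)


def load_traces(path: str | Path) -> dict:
    with h5py.File(path, "r") as f:
        out = {k: f[k][...] for k in f.keys()}
        out.update({k: f.attrs[k] for k in f.attrs})
    return out


@dataclass
class RunManifest:
    """Everything required to re-create a run's outputs bit-exactly."""

    config: dict
    seeds: dict
    version: str
    calibration: dict = field(default_factory=dict)
    notes: dict = field(default_factory=dict)

    @classmethod
    def from_instance(cls, inst: NetworkInstance, noise_scale: float | None = None):
        from . import __version__

        return cls(
            config=dataclasses.asdict(inst.cfg),
            seeds=dict(inst.seeds),
            version=__version__,
            calibration={
                "threshold_E_mV": inst.threshold_E,
                "threshold_I_mV": inst.threshold_I,
                "dc_E_pA": inst.dc_E.tolist(),
                "dc_I_pA": inst.dc_I.tolist(),
                "rescale_factors": inst.rescale_factors,
                "noise_scale": noise_scale,
            },
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def write_summary(summary: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
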