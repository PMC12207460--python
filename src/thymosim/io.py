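"""Readers and writers for simulation artifacts.

Field snapshots go to HDF5 (one group per snapshot, one dataset per field,
coordinate vectors and unit strings as attributes, full parameter set and
seed in the file attributes); scalar metrics and dispersion curves go to
CSV; run manifests to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .fields import FieldState
from .grid import Grid
from .params import ModelParams
from .solver import Trajectory

FIELD_UNITS = {
    "rho_T": "um^-3", "rho_Tstar": "um^-3", "rho_M": "um^-3",
    "rho_C": "nM", "rho_T0": "um^-3",
}


def write_snapshots(path: str | Path, traj: Trajectory,
                    rng_seed: int | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["code_version"] = __version__
        f.attrs["params"] = json.dumps(traj.params.to_dict())
        f.attrs["ndim"] = traj.grid.ndim
        f.attrs["n"] = traj.grid.n
        f.attrs["L_um"] = traj.grid.L
        if rng_seed is not None:
            f.attrs["rng_seed"] = int(rng_seed)
        x = traj.grid.coords()[0]
        dset = f.create_dataset("coords/x", data=x)
        dset.attrs["units"] = "um"
        for i, state in enumerate(traj.snapshots):
            g = f.create_group(f"snapshots/{i:04d}")
            g.attrs["t"] = state.t
            g.attrs["t_units"] = "h"
            for name, arr in state.items():
                d = g.create_dataset(name, data=arr)
                d.attrs["units"] = FIELD_UNITS[name]


def read_snapshots(path: str | Path) -> tuple[list[FieldState], ModelParams, Grid]:
    with h5py.File(path, "r") as f:
        raw = json.loads(f.attrs["params"])
        # p_T0 is serialized resolved; keep it explicit on reload
        params = ModelParams(**raw)
        grid = Grid(int(f.attrs["ndim"]), int(f.attrs["n"]), float(f.attrs["L_um"]))
        states = []
        for key in sorted(f["snapshots"]):
            g = f[f"snapshots/{key}"]
            states.append(FieldState(
                t=float(g.attrs["t"]),
                rho_T=g["rho_T"][...],
                rho_Tstar=g["rho_Tstar"][...],
                rho_M=g["rho_M"][...],
                rho_C=g["rho_C"][...],
                rho_T0=g["rho_T0"][...] if "rho_T0" in g else None,
            ))
    return states, params, grid


def write_metrics_csv(path: str | Path, metrics: pd.DataFrame) -> None:
    metrics.to_csv(path, index=False, float_format="%.12g")


def write_manifest(path: str | Path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
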