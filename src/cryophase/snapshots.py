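"""HDF5 field snapshots and CSV diagnostics output."""

from __future__ import annotations

import hashlib
import json
from importlib.metadata import PackageNotFoundError, version

import h5py
import numpy as np
import pandas as pd

from .solver import Diagnostics, FieldState

__all__ = ["save_snapshot", "load_snapshot", "diagnostics_to_frame", "config_hash"]

_DATASETS = ("phi_sl", "phi_c", "T_tilde", "vx", "vy", "p", "vsx", "vsy")


def _version() -> str:
    try:
        return version("cryophase")
    except PackageNotFoundError:
        return "unknown"


def config_hash(cfg_dict: dict) -> str:
    """Stable short hash of a configuration dictionary."""
    blob = json.dumps(cfg_dict, sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def save_snapshot(state: FieldState, path, cfg_dict: dict | None = None) -> None:
    """Write a field state to HDF5 (datasets + t_tilde/config-hash attrs)."""
    with h5py.File(path, "w") as f:
        arrays = (state.phi_sl, state.phi_c, state.T_tilde, state.vx,
                  state.vy, state.p_tilde, state.vsx, state.vsy)
        for name, arr in zip(_DATASETS, arrays):
            f.create_dataset(name, data=arr)
        f.attrs["t_tilde"] = state.t_tilde
        f.attrs["code_version"] = _version()
        if cfg_dict is not None:
            f.attrs["config_hash"] = config_hash(cfg_dict)
            f.attrs["config_json"] = json.dumps(cfg_dict, default=float)


def load_snapshot(path) -> FieldState:
    """Read a field state back from HDF5 (for resume or rendering)."""
    with h5py.File(path, "r") as f:
        arrs = [np.asarray(f[name]) for name in _DATASETS]
        t = float(f.attrs["t_tilde"])
    return FieldState(arrs[0], arrs[1], arrs[2], arrs[3], arrs[4], arrs[5],
                      t, arrs[6], arrs[7])


def diagnostics_to_frame(diags: list[Diagnostics]) -> pd.DataFrame:
    """One row per output interval."""
    return pd.DataFrame([d.__dict__ for d in diags])
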