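"""HDF5 / CSV persistence for sessions, model parameters and metrics.

Sessions store activity, latents and discrete states as HDF5 datasets
(``activity [N x T]``, ``latents [D x T]``, ``states [T]``); bouts and cell
positions travel as CSV tables with headers ``(start_s, stop_s, label)`` and
``(cell_id, x_um, y_um, dim_label)``.  Model parameters are written one named
dataset per parameter.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .decoders import BoutTable
from .rslds import LatentTrajectory, ObservedActivity, RSLDSParams

__all__ = [
    "save_session",
    "load_session",
    "save_params",
    "load_params",
    "save_bouts_csv",
    "load_bouts_csv",
    "save_positions_csv",
]


def save_session(session, path) -> None:
    """Write a synthetic session's arrays to HDF5 and its tables to CSV
    siblings (``<stem>_bouts.csv``, ``<stem>_positions.csv``)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("activity", data=session.activity.y)
        f.create_dataset("latents", data=session.latents.x)
        f.create_dataset("states", data=session.latents.z)
        f.create_dataset("input_schedule", data=session.input_schedule)
        f.attrs["frame_rate"] = session.activity.frame_rate
        f.attrs["seed"] = session.seed
        _write_params_group(f.create_group("ground_truth"), session.ground_truth)
    save_bouts_csv(session.bouts, path.with_name(path.stem + "_bouts.csv"))
    save_positions_csv(session.positions,
                       path.with_name(path.stem + "_positions.csv"))


def load_session(path):
    """Read back the arrays written by :func:`save_session`.

    Returns ``(activity, latents, ground_truth, input_schedule, seed)``; the
    CSV tables are loaded separately with :func:`load_bouts_csv`.
    """
    with h5py.File(path, "r") as f:
        act = ObservedActivity(y=f["activity"][()],
                               frame_rate=float(f.attrs["frame_rate"]))
        lat = LatentTrajectory(x=f["latents"][()], z=f["states"][()])
        params = _read_params_group(f["ground_truth"])
        u = f["input_schedule"][()]
        seed = int(f.attrs["seed"])
    return act, lat, params, u, seed


def _write_params_group(g, params: RSLDSParams) -> None:
    for name in ("As", "bs", "Qs", "Rs", "rs", "C", "d", "S"):
        g.create_dataset(name, data=getattr(params, name))
    if params.Bs is not None:
        g.create_dataset("Bs", data=params.Bs)


def _read_params_group(g) -> RSLDSParams:
    kw = {name: g[name][()] for name in ("As", "bs", "Qs", "Rs", "rs",
                                         "C", "d", "S")}
    if "Bs" in g:
        kw["Bs"] = g["Bs"][()]
    return RSLDSParams(**kw)


def save_params(params: RSLDSParams, path) -> None:
    with h5py.File(path, "w") as f:
        _write_params_group(f, params)


def load_params(path) -> RSLDSParams:
    with h5py.File(path, "r") as f:
        return _read_params_group(f)


def save_bouts_csv(bouts: BoutTable, path) -> None:
    bouts.table.to_csv(path, index=False, columns=["start_s", "stop_s", "label"])


def load_bouts_csv(path, merge_gap_s: float = 5.0) -> BoutTable:
    return BoutTable(pd.read_csv(path), merge_gap_s=merge_gap_s)


def save_positions_csv(positions, path) -> None:
    positions.table.to_csv(
        path, index=False, columns=["cell_id", "x_um", "y_um", "dim_label"])
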