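"""Trajectory file formats, TrackMate import, and config handling.

The trajectory CSV schema is ``track_id,frame,time_s,x_um,y_um`` (header
required, UTF-8, '.' decimal).  Floats are written with 17 significant
digits so that a write/read round trip is bit-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .trajstats import Trajectory

__all__ = [
    "TRAJECTORY_COLUMNS",
    "write_trajectories",
    "read_trajectories",
    "from_trackmate",
    "load_config",
    "save_config",
    "provenance",
]

TRAJECTORY_COLUMNS = ("track_id", "frame", "time_s", "x_um", "y_um")


class TrajectoryParseError(ValueError):
    """Raised for malformed trajectory CSVs, with the offending line number."""


def write_trajectories(trajs, path) -> None:
    """Write trajectories to the trajectory CSV schema."""
    frames = []
    for t in trajs:
        frames.append(pd.DataFrame({
            "track_id": t.track_id,
            "frame": np.arange(t.n_frames),
            "time_s": t.times,
            "x_um": t.xs,
            "y_um": t.ys,
        }))
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=list(TRAJECTORY_COLUMNS))
    df.to_csv(path, index=False, float_format="%.17g")


def read_trajectories(path, source: str = "experiment") -> list:
    """Read a trajectory CSV into :class:`Trajectory` objects.

    Raises :class:`TrajectoryParseError` with a line number for malformed
    input (missing columns, non-numeric fields, empty file).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise TrajectoryParseError(f"{path}: empty file (line 1)") from exc
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryParseError(f"{path}: header (line 1) lacks columns {missing}")
    for col in ("frame", "time_s", "x_um", "y_um"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
            raise TrajectoryParseError(
                f"{path}: non-numeric value in column '{col}' at line {line}")
        df[col] = coerced
    trajs = []
    for tid, g in df.groupby("track_id", sort=False):
        g = g.sort_values("frame")
        trajs.append(Trajectory(
            track_id=str(tid),
            times=g["time_s"].to_numpy(float),
            xs=g["x_um"].to_numpy(float),
            ys=g["y_um"].to_numpy(float),
            source=source,
        ))
    return trajs


def from_trackmate(path, frame_interval: float = 0.05) -> list:
    """Convert a TrackMate spots export (CSV) into trajectories.

    Expects the standard spots table with ``TRACK_ID``, ``FRAME``,
    ``POSITION_X`` and ``POSITION_Y`` columns; the up-to-three auxiliary
    header rows TrackMate inserts below the column names are skipped.
    Times are rebuilt as ``FRAME * frame_interval`` so that tracks are
    uniformly sampled even when ``POSITION_T`` is absent or rounded.
    """
    df = pd.read_csv(path)
    required = ["TRACK_ID", "FRAME", "POSITION_X", "POSITION_Y"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TrajectoryParseError(f"{path}: not a TrackMate spots table; lacks {missing}")
    # drop TrackMate's extra non-numeric header rows
    keep = pd.to_numeric(df["FRAME"], errors="coerce").notna()
    df = df.loc[keep].copy()
    for col in required:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df = df.dropna(subset=required)
    trajs = []
    for tid, g in df.groupby("TRACK_ID", sort=False):
        g = g.sort_values("FRAME")
        frames = g["FRAME"].to_numpy(int)
        # keep only the leading contiguous stretch; gaps break uniform sampling
        contiguous = np.flatnonzero(np.diff(frames) != 1)
        stop = contiguous[0] + 1 if contiguous.size else frames.size
        g = g.iloc[:stop]
        trajs.append(Trajectory(
            track_id=f"tm-{int(tid)}",
            times=g["FRAME"].to_numpy(float) * frame_interval,
            xs=g["POSITION_X"].to_numpy(float),
            ys=g["POSITION_Y"].to_numpy(float),
            source="experiment",
        ))
    return trajs


def load_config(path) -> dict:
    """Load a YAML config mapping flag names to values."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping of option names to values")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def provenance(params: dict, seed=None) -> dict:
    """Provenance block embedded in every workflow output."""
    from . import __version__

    return {"package": "lanetaxis", "version": __version__, "seed": seed,
            "parameters": params}


def write_provenance_json(path, payload: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
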