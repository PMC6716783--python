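"""Tabular IO for every stage: trajectory tables, localization tables,
plate-reader spectra and traces, tidy result CSVs and JSON run manifests.

Conventions: CSV is comma-separated UTF-8 with a header row and '.'
decimal; trajectory coordinates are stored in micrometres, localization
coordinates in nanometres; frames are 0-based and the time of frame i is
i * dt. Trajectory readers accept a user-supplied column map so
externally deposited tables with arbitrary headers (e.g. public
single-particle-tracking datasets) can be adapted without editing code.
Readers never silently drop rows: malformed input raises, and any
filtering is logged with counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .motion import Trajectory
from .point_pattern import PointPattern

logger = logging.getLogger(__name__)

__all__ = [
    "read_trajectories",
    "write_trajectories",
    "read_localizations",
    "write_localizations",
    "read_spectra",
    "write_spectra",
    "read_traces",
    "write_traces",
    "write_results",
]

_UNIT_TO_UM = {"um": 1.0, "nm": 1e-3}

DEFAULT_TRAJECTORY_COLUMNS = {"id": "track_id", "frame": "frame", "x": "x", "y": "y"}


def read_trajectories(
    path: str | Path,
    dt: float,
    column_map: dict[str, str] | None = None,
    unit: str = "um",
    pixel_size_um: float | None = None,
) -> list[Trajectory]:
    """Read a trajectory table into per-track :class:`Trajectory` objects.

    ``column_map`` maps the roles ``id``, ``frame``, ``x``, ``y`` to the
    file's actual headers. ``unit`` is one of ``um``, ``nm``, ``pixel``
    (``pixel`` requires ``pixel_size_um``); coordinates are converted to
    micrometres. Tracks are sorted by frame; duplicate (track, frame)
    pairs are a hard error naming the offending rows.
    """
    path = Path(path)
    cols = dict(DEFAULT_TRAJECTORY_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing columns {missing}; available: {list(df.columns)}"
        )
    if unit == "pixel":
        if pixel_size_um is None:
            raise ValueError("pixel units require pixel_size_um")
        scale = float(pixel_size_um)
    else:
        try:
            scale = _UNIT_TO_UM[unit]
        except KeyError:
            raise ValueError(f"unknown unit {unit!r}; use um, nm or pixel") from None

    dup = df.duplicated(subset=[cols["id"], cols["frame"]], keep=False)
    if dup.any():
        rows = df.index[dup].tolist()[:10]
        raise ValueError(f"{path}: duplicate (track, frame) pairs at rows {rows}")

    trajectories: list[Trajectory] = []
    n_single = 0
    for track_id, g in df.groupby(cols["id"], sort=True):
        g = g.sort_values(cols["frame"])
        if len(g) < 2:
            n_single += 1
            continue
        traj = Trajectory(
            frames=g[cols["frame"]].to_numpy(np.int64),
            xy=g[[cols["x"], cols["y"]]].to_numpy(float) * scale,
            dt=dt,
            track_id=track_id,
        )
        if traj.is_gapped:
            logger.info("track %s has frame gaps (%d/%d frames observed)",
                        track_id, traj.n_observed, traj.span)
        trajectories.append(traj)
    if n_single:
        logger.warning("%s: dropped %d single-point tracks", path, n_single)
    return trajectories


def write_trajectories(
    trajectories: list[Trajectory], path: str | Path
) -> None:
    """Write trajectories as a tidy CSV (track_id, frame, x, y in um)."""
    rows = []
    for i, traj in enumerate(trajectories):
        track_id = traj.track_id if traj.track_id != "" else i
        rows.append(
            pd.DataFrame(
                {
                    "track_id": track_id,
                    "frame": traj.frames,
                    "x": traj.xy[:, 0],
                    "y": traj.xy[:, 1],
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_localizations(
    path: str | Path, window: tuple[float, float, float, float] | None = None
) -> PointPattern:
    """Read a 2D localization table (x, y in nm) into a PointPattern.

    Without an explicit window, the bounding box of the points is used.
    """
    df = pd.read_csv(path)
    for c in ("x", "y"):
        if c not in df.columns:
            raise ValueError(f"{path}: need columns x,y; got {list(df.columns)}")
    pts = df[["x", "y"]].to_numpy(float)
    if window is None:
        window = (
            float(pts[:, 0].min()), float(pts[:, 1].min()),
            float(pts[:, 0].max()), float(pts[:, 1].max()),
        )
    return PointPattern(points=pts, window=window)


def write_localizations(pattern: PointPattern, path: str | Path) -> None:
    pd.DataFrame({"x": pattern.points[:, 0], "y": pattern.points[:, 1]}).to_csv(
        path, index=False
    )


def read_spectra(path: str | Path) -> pd.DataFrame:
    """Read a spectra table (well, wavelength_nm, intensity[, is_blank]).

    Enforces a shared wavelength grid across wells.
    """
    df = pd.read_csv(path)
    required = {"well", "wavelength_nm", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    if "is_blank" not in df.columns:
        df["is_blank"] = False
    grids = df.groupby("well")["wavelength_nm"].apply(tuple)
    if grids.nunique() > 1:
        raise ValueError(f"{path}: wells do not share a wavelength grid")
    return df


def write_spectra(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_traces(path: str | Path) -> pd.DataFrame:
    """Read a kinetic-trace table (well, time_s, channel_nm, intensity).

    Times must be non-decreasing within each (well, channel) series.
    """
    df = pd.read_csv(path)
    required = {"well", "time_s", "channel_nm", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    for (well, ch), g in df.groupby(["well", "channel_nm"]):
        if np.any(np.diff(g["time_s"].to_numpy(float)) < 0):
            raise ValueError(f"{path}: non-monotone times in well {well}, "
                             f"channel {ch:g} nm")
    return df


def write_traces(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_results(
    df: pd.DataFrame,
    path: str | Path,
    manifest: dict | None = None,
    manifest_path: str | Path | None = None,
) -> None:
    """Write a tidy result CSV plus a JSON run manifest.

    The manifest records whatever the caller passes (inputs, config,
    seed) plus the package version, so a run can be reproduced exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    if manifest is not None:
        from . import __version__

        manifest = dict(manifest)
        manifest.setdefault("version", __version__)
        manifest.setdefault("output", str(path))
        mpath = Path(manifest_path) if manifest_path else path.with_suffix(".manifest.json")
        mpath.write_text(json.dumps(_jsonable(manifest), indent=2, sort_keys=True))
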