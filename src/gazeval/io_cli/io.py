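"""File I/O for gaze exports, schedules, target tracks, frames, and results.

Gaze exports are delimited tables with a configurable column map (defaults:
``Timestamp``, ``Gaze Point X``, ``Gaze Point Y``, ``Pupil Diameter``).  The
canonical frame format is a numbered PNG sequence (``frame_%06d.png``); MP4 is
decoded opportunistically when a codec is available.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterator

import imageio.v3 as iio
import numpy as np
import pandas as pd

from ..camera_geometry import CameraModel
from ..core import (
    DataError,
    FormatError,
    GazeRecording,
    InstructionSchedule,
    LabelTrack,
    TargetTrack,
)
from ..quality_metrics import Heatmap

__all__ = [
    "DEFAULT_COLUMNS",
    "read_gaze_export",
    "write_gaze_export",
    "read_schedule",
    "write_schedule",
    "read_track",
    "write_track",
    "read_frames",
    "write_heatmap",
    "read_heatmap",
]

log = logging.getLogger(__name__)

DEFAULT_COLUMNS = {
    "t": "Timestamp",
    "x": "Gaze Point X",
    "y": "Gaze Point Y",
    "pupil": "Pupil Diameter",
}

_TIME_SCALE = {"s": 1.0, "ms": 1e-3, "us": 1e-6}


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_gaze_export(
    path: str | Path,
    device: str = "tobii2",
    columns: dict[str, str] | None = None,
    time_unit: str = "s",
    rate_hz: float | None = None,
    camera: CameraModel | None = None,
) -> GazeRecording:
    """Read a delimited gaze export into a :class:`GazeRecording`.

    Rows with empty or NaN gaze coordinates are retained as invalid samples.
    Timestamps are normalised to seconds from ``time_unit`` (s / ms / us).
    """
    path = Path(path)
    colmap = {**DEFAULT_COLUMNS, **(columns or {})}
    if time_unit not in _TIME_SCALE:
        raise FormatError(f"unknown time unit {time_unit!r}")
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    for key in ("t", "x", "y"):
        if colmap[key] not in df.columns:
            raise FormatError(f"missing required column {colmap[key]!r} in {path.name}")
    t = df[colmap["t"]].to_numpy(dtype=float) * _TIME_SCALE[time_unit]
    x = pd.to_numeric(df[colmap["x"]], errors="coerce").to_numpy(dtype=float)
    y = pd.to_numeric(df[colmap["y"]], errors="coerce").to_numpy(dtype=float)
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise DataError(f"timestamps in {path.name} are not strictly increasing")
    valid = np.isfinite(x) & np.isfinite(y)
    pupil = None
    if colmap["pupil"] in df.columns:
        pupil = pd.to_numeric(df[colmap["pupil"]], errors="coerce").to_numpy(dtype=float)
    return GazeRecording(
        t=t,
        x=x,
        y=y,
        valid=valid,
        device=device,
        rate_hz=rate_hz,
        pupil_mm=pupil,
        camera=camera or CameraModel(),
    )


def write_gaze_export(
    rec: GazeRecording,
    path: str | Path,
    columns: dict[str, str] | None = None,
) -> None:
    """Write a recording as a delimited table (invalid samples become empty cells)."""
    path = Path(path)
    colmap = {**DEFAULT_COLUMNS, **(columns or {})}
    data = {
        colmap["t"]: rec.t,
        colmap["x"]: rec.x,
        colmap["y"]: rec.y,
    }
    if rec.pupil_mm is not None:
        data[colmap["pupil"]] = rec.pupil_mm
    # %.17g round-trips doubles exactly
    pd.DataFrame(data).to_csv(path, sep=_sep_for(path), index=False, float_format="%.17g")


def read_schedule(path: str | Path) -> InstructionSchedule:
    """Read an ``onset_s,label`` CSV schedule."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("onset_s", "label"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path.name}")
    return InstructionSchedule(
        onsets_s=tuple(df["onset_s"].astype(float)),
        labels=tuple(df["label"].astype(str)),
    )


def write_schedule(schedule: InstructionSchedule, path: str | Path) -> None:
    pd.DataFrame({"onset_s": schedule.onsets_s, "label": schedule.labels}).to_csv(
        path, index=False
    )


def read_track(path: str | Path, frame_rate_hz: float = 25.0) -> TargetTrack:
    """Read a long-format target track CSV: ``frame,label,x,y,detected[,visible]``."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("frame", "label", "x", "y", "detected"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path.name}")
    tracks: dict[str, LabelTrack] = {}
    visible = None
    for label, grp in df.groupby("label", sort=False):
        grp = grp.sort_values("frame")
        tracks[str(label)] = LabelTrack(
            frame_index=grp["frame"].to_numpy(dtype=int),
            x=grp["x"].to_numpy(dtype=float),
            y=grp["y"].to_numpy(dtype=float),
            detected=grp["detected"].to_numpy(dtype=bool),
        )
    if "visible" in df.columns:
        vis = df.drop_duplicates("frame").sort_values("frame")
        visible = vis["visible"].to_numpy(dtype=bool)
    return TargetTrack(tracks=tracks, frame_rate_hz=frame_rate_hz, visible=visible)


def write_track(track: TargetTrack, path: str | Path) -> None:
    rows = []
    for label in track.labels():
        lt = track[label]
        for i in range(len(lt)):
            row = {
                "frame": int(lt.frame_index[i]),
                "label": label,
                "x": lt.x[i],
                "y": lt.y[i],
                "detected": bool(lt.detected[i]),
            }
            if track.visible is not None:
                row["visible"] = bool(track.visible[i])
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


_FRAME_RE = re.compile(r"frame_(\d+)\.(png|bmp|jpg|jpeg|tif|tiff)$", re.IGNORECASE)


def read_frames(
    path: str | Path,
    frame_rate_hz: float = 25.0,
    expected_shape: tuple[int, int] | None = None,
) -> Iterator[tuple[int, np.ndarray, float]]:
    """Yield ``(index, image, t)`` from a numbered image directory or a video file.

    Directory frames are ordered by their embedded number; unreadable frames
    are skipped with a warning, leaving a gap in the indices.  Mixed
    resolutions raise a data error.
    """
    path = Path(path)
    shape: tuple[int, int] | None = expected_shape
    if path.is_dir():
        entries = []
        for p in sorted(path.iterdir()):
            m = _FRAME_RE.search(p.name)
            if m:
                entries.append((int(m.group(1)), p))
        entries.sort()
        for index, p in entries:
            try:
                img = iio.imread(p)
            except Exception as exc:  # unreadable frame: gap, not fatal
                log.warning("skipping unreadable frame %s: %s", p.name, exc)
                continue
            if shape is None:
                shape = img.shape[:2]
            elif img.shape[:2] != tuple(shape):
                raise DataError(
                    f"frame {p.name} has resolution {img.shape[:2]}, expected {shape}"
                )
            yield index, img, index / frame_rate_hz
    else:
        for index, img in enumerate(iio.imiter(path)):
            if shape is None:
                shape = img.shape[:2]
            elif img.shape[:2] != tuple(shape):
                raise DataError(f"frame {index} has mixed resolution")
            yield index, img, index / frame_rate_hz


def write_heatmap(hm: Heatmap, path: str | Path) -> None:
    """Write the heatmap grid as a plain CSV matrix (rows = image rows)."""
    np.savetxt(path, hm.grid, delimiter=",", fmt="%.17g")


def read_heatmap(path: str | Path, cell_px: int = 20) -> Heatmap:
    return Heatmap(np.loadtxt(path, delimiter=","), cell_px)
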