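"""Per-interval data-quality metrics and their across-participant summaries.

Accuracy is the mean (and, as a robust variant, the median) per-frame angular
distance between gaze and target.  Bias is the angular size of the mean
gaze-minus-target displacement and can be far below accuracy when errors are
symmetric.  Precision is reported both as RMS of successive-sample angular
distances (target-independent) and as the SD of the per-frame angular
deviations.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .camera_geometry import CameraModel, angular_distance
from .core import AccuracyResult, DomainError, FrameGazeSeries, Interval, TargetTrack

__all__ = [
    "interval_accuracy",
    "interval_bias",
    "interval_precision",
    "target_speed",
    "heatmap",
    "Heatmap",
    "condition_summary",
]

log = logging.getLogger(__name__)

HEATMAP_CELL_PX = 20
HEATMAP_TOTAL = 1000.0


def _interval_arrays(
    frames: FrameGazeSeries,
    track: TargetTrack,
    interval: Interval,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Gaze and target positions over the interval's frames (NaN where unusable)."""
    fps = frames.frame_rate_hz
    f = interval.frames(fps)
    gx = np.full(f.shape, np.nan)
    gy = np.full(f.shape, np.nan)
    in_span = (f >= frames.frame_index[0]) & (f <= frames.frame_index[-1]) if len(frames) else np.zeros(f.shape, bool)
    pos = f - (frames.frame_index[0] if len(frames) else 0)
    gx[in_span] = frames.x[pos[in_span]]
    gy[in_span] = frames.y[pos[in_span]]
    if interval.label not in track:
        raise DomainError(f"track has no label {interval.label!r}")
    tx, ty = track[interval.label].at_frames(f)
    return f, gx, gy, tx, ty


def _theta_series(gx, gy, tx, ty, cam: CameraModel) -> np.ndarray:
    usable = np.isfinite(gx) & np.isfinite(gy) & np.isfinite(tx) & np.isfinite(ty)
    theta = np.full(gx.shape, np.nan)
    if np.any(usable):
        theta[usable] = angular_distance(
            np.stack([gx[usable], gy[usable]], axis=-1),
            np.stack([tx[usable], ty[usable]], axis=-1),
            cam,
        )
    return theta


def interval_accuracy(
    frames: FrameGazeSeries,
    track: TargetTrack,
    cam: CameraModel,
    interval: Interval,
) -> AccuracyResult:
    """All per-interval quality metrics for one analysis window.

    Frames lacking either a valid gaze estimate or a detected target are
    excluded from the angular-distance series (an undetected target is not
    counted as missing gaze data).
    """
    f, gx, gy, tx, ty = _interval_arrays(frames, track, interval)
    theta = _theta_series(gx, gy, tx, ty, cam)
    usable = np.isfinite(theta)
    n_valid = int(np.count_nonzero(usable))
    gaze_missing = ~(np.isfinite(gx) & np.isfinite(gy))
    missing_pct = 100.0 * float(np.count_nonzero(gaze_missing)) / f.size
    if n_valid == 0:
        return AccuracyResult(
            interval=interval,
            accuracy_deg=np.nan,
            accuracy_median_deg=np.nan,
            bias_deg=np.nan,
            precision_rms_s2s_deg=np.nan,
            precision_sd_deg=np.nan,
            n_frames_valid=0,
            missing_pct=missing_pct,
            valid=False,
        )
    accuracy = float(np.mean(theta[usable]))
    accuracy_median = float(np.median(theta[usable]))
    bias = _bias_from_arrays(gx, gy, tx, ty, cam)
    rms_s2s, sd = _precision_from_arrays(gx, gy, theta, cam)
    return AccuracyResult(
        interval=interval,
        accuracy_deg=accuracy,
        accuracy_median_deg=accuracy_median,
        bias_deg=bias,
        precision_rms_s2s_deg=rms_s2s,
        precision_sd_deg=sd,
        n_frames_valid=n_valid,
        missing_pct=missing_pct,
        valid=True,
    )


def _bias_from_arrays(gx, gy, tx, ty, cam: CameraModel) -> float:
    usable = np.isfinite(gx) & np.isfinite(gy) & np.isfinite(tx) & np.isfinite(ty)
    if not np.any(usable):
        return float("nan")
    dx = float(np.mean(gx[usable] - tx[usable]))
    dy = float(np.mean(gy[usable] - ty[usable]))
    cx, cy = cam.center
    return float(angular_distance((cx + dx, cy + dy), (cx, cy), cam))


def interval_bias(
    frames: FrameGazeSeries,
    track: TargetTrack,
    cam: CameraModel,
    interval: Interval,
) -> float:
    """Angular size of the mean per-frame gaze-target displacement vector.

    The mean displacement is applied at the image centre before conversion, so
    a constant pixel offset yields bias equal to accuracy while symmetric
    errors cancel.
    """
    _, gx, gy, tx, ty = _interval_arrays(frames, track, interval)
    return _bias_from_arrays(gx, gy, tx, ty, cam)


def _precision_from_arrays(gx, gy, theta, cam: CameraModel) -> tuple[float, float]:
    valid_gaze = np.isfinite(gx) & np.isfinite(gy)
    pair = valid_gaze[:-1] & valid_gaze[1:]
    if np.any(pair):
        steps = angular_distance(
            np.stack([gx[:-1][pair], gy[:-1][pair]], axis=-1),
            np.stack([gx[1:][pair], gy[1:][pair]], axis=-1),
            cam,
        )
        rms = float(np.sqrt(np.mean(np.square(steps))))
    else:
        rms = float("nan")
    usable = np.isfinite(theta)
    sd = float(np.std(theta[usable], ddof=1)) if np.count_nonzero(usable) >= 2 else float("nan")
    return rms, sd


def interval_precision(
    frames: FrameGazeSeries,
    track: TargetTrack,
    cam: CameraModel,
    interval: Interval,
) -> tuple[float, float]:
    """(RMS sample-to-sample, SD of angular deviations) over the interval.

    Requires at least two usable frames; otherwise both values are NaN.
    """
    _, gx, gy, tx, ty = _interval_arrays(frames, track, interval)
    theta = _theta_series(gx, gy, tx, ty, cam)
    return _precision_from_arrays(gx, gy, theta, cam)


def target_speed(
    track: TargetTrack,
    cam: CameraModel,
    interval: Interval,
) -> float:
    """Mean angular speed (deg/s) of the interval's target across frame steps."""
    fps = track.frame_rate_hz
    f = interval.frames(fps)
    if interval.label not in track:
        raise DomainError(f"track has no label {interval.label!r}")
    tx, ty = track[interval.label].at_frames(f)
    det = np.isfinite(tx) & np.isfinite(ty)
    pair = det[:-1] & det[1:]
    if np.count_nonzero(det) < 2 or not np.any(pair):
        return float("nan")
    steps = angular_distance(
        np.stack([tx[:-1][pair], ty[:-1][pair]], axis=-1),
        np.stack([tx[1:][pair], ty[1:][pair]], axis=-1),
        cam,
    )
    return float(np.mean(steps) * fps)


class Heatmap:
    """Spatial density of points over the camera image in 20-px cells.

    The grid is ``(height/20) x (width/20)`` (54 x 96 at 1920x1080) and is
    normalised so that all cells sum to ``HEATMAP_TOTAL`` (1000).
    """

    def __init__(self, grid: np.ndarray, cell_px: int = HEATMAP_CELL_PX):
        self.grid = np.asarray(grid, dtype=float)
        self.cell_px = cell_px

    @property
    def total(self) -> float:
        return float(self.grid.sum())


def heatmap(
    x: np.ndarray,
    y: np.ndarray,
    cam: CameraModel | None = None,
    cell_px: int = HEATMAP_CELL_PX,
) -> Heatmap:
    """Bin points into ``cell_px`` squares, normalised to a total of 1000.

    Out-of-frame or non-finite points are dropped (with a logged count); having
    zero in-bounds points is a domain error.
    """
    cam = cam or CameraModel()
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    ok = np.isfinite(x) & np.isfinite(y)
    ok &= (x >= 0) & (x < cam.width_px) & (y >= 0) & (y < cam.height_px)
    dropped = x.size - int(np.count_nonzero(ok))
    if dropped:
        log.info("heatmap: dropped %d out-of-bounds points", dropped)
    if not np.any(ok):
        raise DomainError("heatmap requires at least one in-bounds point")
    nx = cam.width_px // cell_px
    ny = cam.height_px // cell_px
    grid, _, _ = np.histogram2d(
        y[ok], x[ok], bins=[ny, nx], range=[[0, ny * cell_px], [0, nx * cell_px]]
    )
    grid *= HEATMAP_TOTAL / grid.sum()
    return Heatmap(grid, cell_px)


def condition_summary(
    results: pd.DataFrame,
    value: str = "accuracy_deg",
    by: tuple[str, ...] = ("device", "condition"),
    participant: str = "participant",
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Across-participant mean / SD / median of per-participant mean metrics.

    ``results`` holds one row per interval.  Values are first averaged within
    participant (over that participant's intervals in the group), then
    summarised across participants.  ``labels`` optionally restricts to a
    subset of target labels (e.g. the central dot only).
    """
    df = results
    if labels is not None:
        df = df[df["label"].isin(labels)]
    if df.empty:
        raise DomainError("no rows to summarise")
    per_participant = (
        df.groupby([*by, participant], sort=False)[value].mean().reset_index()
    )
    rows = []
    for key, grp in per_participant.groupby(list(by), sort=False):
        vals = grp[value].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            log.warning("condition_summary: empty group %s omitted", key)
            continue
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        rows.append(
            dict(
                zip(by, key if isinstance(key, tuple) else (key,)),
                mean=float(np.mean(vals)),
                sd=sd,
                median=float(np.median(vals)),
                n=int(vals.size),
                sd_defined=vals.size > 1,
            )
        )
    return pd.DataFrame(rows)
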