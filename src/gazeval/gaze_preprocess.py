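"""Raw-gaze conditioning: missing-omitting moving median, per-frame averaging,
and missing-data accounting.

The median filter runs over a centred window of fixed *time* width; any window
that contains missing samples takes the median of its non-missing elements
only, so short blink gaps are bridged while step edges (saccades) survive.
Windows at the recording edges shrink rather than pad.
"""

from __future__ import annotations

import warnings

import numpy as np

from .camera_geometry import CameraModel
from .core import DomainError, FrameGazeSeries, GazeRecording

__all__ = [
    "median_filter_series",
    "median_filter_recording",
    "frame_average",
    "missing_fraction",
]


def _window_samples(window_s: float, rate_hz: float) -> int:
    n = int(round(window_s * rate_hz))
    return max(n, 1)


def _nan_sliding_median(values: np.ndarray, n: int) -> np.ndarray:
    """Centred n-sample sliding median ignoring NaNs; edges use truncated windows.

    For even n the window extends one sample further after than before the
    centre; an even count of in-window values yields the mean of the middle two.
    """
    before = (n - 1) // 2
    after = n // 2
    padded = np.concatenate(
        [np.full(before, np.nan), np.asarray(values, dtype=float), np.full(after, np.nan)]
    )
    windows = np.lib.stride_tricks.sliding_window_view(padded, n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)  # all-NaN windows
        return np.nanmedian(windows, axis=1)


def median_filter_series(
    values: np.ndarray,
    window_s: float = 0.30,
    rate_hz: float = 50.0,
    t: np.ndarray | None = None,
) -> np.ndarray:
    """Missing-omitting moving median over one gaze coordinate series.

    Parameters
    ----------
    values : array of floats, NaN marking missing samples.
    window_s : total window width in seconds (0.30 s -> 15 samples at 50 Hz,
        30 samples at 100 Hz).
    rate_hz : nominal sampling rate; if ``t`` is given and ``rate_hz`` is None
        the rate is inferred from the median timestamp spacing.
    """
    if window_s <= 0:
        raise DomainError(f"window_s must be positive, got {window_s}")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return values.copy()
    if rate_hz is None:
        if t is None or len(t) < 2:
            raise DomainError("rate_hz or timestamps required to size the window")
        rate_hz = 1.0 / float(np.median(np.diff(t)))
    return _nan_sliding_median(values, _window_samples(window_s, rate_hz))


def median_filter_recording(rec: GazeRecording, window_s: float = 0.30) -> GazeRecording:
    """Apply the moving median independently to the x and y series of a recording."""
    rate = rec.rate_hz
    x = median_filter_series(rec.x, window_s, rate, t=rec.t)
    y = median_filter_series(rec.y, window_s, rate, t=rec.t)
    valid = np.isfinite(x) & np.isfinite(y)
    return GazeRecording(
        t=rec.t.copy(),
        x=x,
        y=y,
        valid=valid,
        device=rec.device,
        rate_hz=rec.rate_hz,
        pupil_mm=None if rec.pupil_mm is None else rec.pupil_mm.copy(),
        camera=rec.camera,
    )


def frame_average(rec: GazeRecording, cam: CameraModel | None = None) -> FrameGazeSeries:
    """Mean gaze per scene-camera frame.

    Frame ``f`` collects the samples with ``t`` in ``[f/fps, (f+1)/fps)``;
    invalid samples are excluded from the mean, and a frame with no valid
    samples is marked missing.  Frames are emitted contiguously from 0 through
    the frame of the last sample.
    """
    cam = cam or rec.camera
    fps = cam.frame_rate_hz
    if len(rec) == 0:
        return FrameGazeSeries(
            frame_index=np.array([], dtype=int),
            t=np.array([]),
            x=np.array([]),
            y=np.array([]),
            missing=np.array([], dtype=bool),
            frame_rate_hz=fps,
        )
    # small epsilon guards binary-representation error at exact frame boundaries
    idx = np.floor(rec.t * fps + 1e-9).astype(int)
    if np.any(idx < 0):
        raise DomainError("negative sample times cannot be mapped to frames")
    n_frames = int(idx.max()) + 1
    ok = rec.valid & np.isfinite(rec.x) & np.isfinite(rec.y)
    counts = np.bincount(idx[ok], minlength=n_frames)
    sx = np.bincount(idx[ok], weights=rec.x[ok], minlength=n_frames)
    sy = np.bincount(idx[ok], weights=rec.y[ok], minlength=n_frames)
    missing = counts == 0
    with np.errstate(invalid="ignore"):
        x = np.where(missing, np.nan, sx / np.maximum(counts, 1))
        y = np.where(missing, np.nan, sy / np.maximum(counts, 1))
    frames = np.arange(n_frames)
    return FrameGazeSeries(
        frame_index=frames,
        t=frames / fps,
        x=x,
        y=y,
        missing=missing,
        frame_rate_hz=fps,
    )


def missing_fraction(
    frames: FrameGazeSeries, span: tuple[float, float] | None = None
) -> float:
    """Percentage of frames with no valid gaze, optionally restricted to a time span."""
    missing = frames.missing
    if span is not None:
        sel = (frames.t >= span[0]) & (frames.t < span[1])
        missing = missing[sel]
    if missing.size == 0:
        raise DomainError("missing_fraction over an empty span")
    return 100.0 * float(np.count_nonzero(missing)) / missing.size
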