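"""Shared domain types and errors.

Coordinate convention: gaze and target positions are expressed in scene-camera
pixels with (1, 1) at the top-left corner, x increasing rightward and y
increasing downward.  Missing positions are stored as NaN with ``valid=False``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

from .camera_geometry import CameraModel

__all__ = [
    "GazeValError",
    "FormatError",
    "DataError",
    "ConfigError",
    "DomainError",
    "NoIntersectionError",
    "DEVICE_RATES",
    "DOT_LABELS",
    "TARGET_LABELS",
    "GazeSample",
    "GazeRecording",
    "InstructionSchedule",
    "FrameGazeSeries",
    "TargetObservation",
    "LabelTrack",
    "TargetTrack",
    "Interval",
    "AccuracyResult",
]


class GazeValError(Exception):
    """Base class for all package errors."""


class FormatError(GazeValError):
    """Malformed input file (missing columns, wrong structure)."""


class DataError(GazeValError):
    """Structurally valid input with inconsistent content."""


class ConfigError(GazeValError):
    """Invalid pipeline / scenario configuration."""


class DomainError(GazeValError, ValueError):
    """Argument outside the mathematical domain of an operation."""


class NoIntersectionError(GazeValError):
    """Fitted lines are parallel within tolerance."""


#: nominal sampling rate per device label
DEVICE_RATES: Mapping[str, float] = {"tobii2": 50.0, "tobii3": 100.0}

#: the nine seated-pattern dot labels, centre first
DOT_LABELS: tuple[str, ...] = (
    "center",
    "top",
    "top-right",
    "right",
    "bottom-right",
    "bottom",
    "bottom-left",
    "left",
    "top-left",
)

TARGET_LABELS: tuple[str, ...] = DOT_LABELS + ("bullseye",)


@dataclass(frozen=True)
class GazeSample:
    t: float
    x_px: float
    y_px: float
    valid: bool = True
    pupil_mm: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.t):
            raise DataError(f"sample timestamp must be finite, got {self.t}")
        if self.pupil_mm is not None and not self.pupil_mm > 0:
            raise DataError(f"pupil_mm must be positive, got {self.pupil_mm}")


@dataclass
class GazeRecording:
    """Column-oriented gaze stream.  ``x``/``y`` are NaN where ``valid`` is False."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    device: str = "tobii2"
    rate_hz: float | None = None
    pupil_mm: np.ndarray | None = None
    camera: CameraModel = field(default_factory=CameraModel)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.t.size
        if not (self.x.size == self.y.size == self.valid.size == n):
            raise DataError("gaze columns must have equal length")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise DataError("gaze timestamps must be strictly increasing")
        self.x = np.where(self.valid, self.x, np.nan)
        self.y = np.where(self.valid, self.y, np.nan)
        if self.rate_hz is None:
            self.rate_hz = DEVICE_RATES.get(self.device)

    def __len__(self) -> int:
        return int(self.t.size)

    def __iter__(self) -> Iterator[GazeSample]:
        pupil = self.pupil_mm
        for i in range(len(self)):
            yield GazeSample(
                t=float(self.t[i]),
                x_px=float(self.x[i]),
                y_px=float(self.y[i]),
                valid=bool(self.valid[i]),
                pupil_mm=None if pupil is None or not np.isfinite(pupil[i]) else float(pupil[i]),
            )

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) else 0.0


@dataclass(frozen=True)
class InstructionSchedule:
    """Ordered (onset, label) gaze instructions."""

    onsets_s: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.onsets_s) != len(self.labels):
            raise DataError("schedule onsets and labels must have equal length")
        onsets = np.asarray(self.onsets_s, dtype=float)
        if onsets.size > 1 and not np.all(np.diff(onsets) > 0):
            raise DataError("schedule onsets must be strictly increasing")
        for lab in self.labels:
            if lab not in TARGET_LABELS:
                raise DataError(f"unknown target label {lab!r}")

    def __len__(self) -> int:
        return len(self.onsets_s)

    def __iter__(self):
        return iter(zip(self.onsets_s, self.labels))


@dataclass
class FrameGazeSeries:
    """Per-video-frame mean gaze.  Frame indices are contiguous from 0."""

    frame_index: np.ndarray
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    missing: np.ndarray
    frame_rate_hz: float = 25.0

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.frame_index.size and np.any(np.diff(self.frame_index) != 1):
            raise DataError("frame indices must be contiguous")

    def __len__(self) -> int:
        return int(self.frame_index.size)


@dataclass(frozen=True)
class TargetObservation:
    frame_index: int
    label: str
    x_px: float
    y_px: float
    detected: bool = True
    radius_px: float | None = None


@dataclass
class LabelTrack:
    """Per-frame positions of a single labelled target; NaN where undetected."""

    frame_index: np.ndarray
    x: np.ndarray
    y: np.ndarray
    detected: np.ndarray
    radius: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.detected = np.asarray(self.detected, dtype=bool)
        self.x = np.where(self.detected, self.x, np.nan)
        self.y = np.where(self.detected, self.y, np.nan)

    def __len__(self) -> int:
        return int(self.frame_index.size)

    def at_frames(self, frames: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Positions at the requested frame indices (NaN outside span / undetected)."""
        frames = np.asarray(frames, dtype=int)
        x = np.full(frames.shape, np.nan)
        y = np.full(frames.shape, np.nan)
        if len(self) == 0:
            return x, y
        f0 = int(self.frame_index[0])
        pos = frames - f0
        ok = (pos >= 0) & (pos < len(self))
        x[ok] = self.x[pos[ok]]
        y[ok] = self.y[pos[ok]]
        return x, y


@dataclass
class TargetTrack:
    """Labelled target tracks plus an optional scene-visibility flag per frame."""

    tracks: dict[str, LabelTrack]
    frame_rate_hz: float = 25.0
    visible: np.ndarray | None = None  # carpet/scene visibility, walking trials

    def labels(self) -> list[str]:
        return list(self.tracks)

    def __getitem__(self, label: str) -> LabelTrack:
        return self.tracks[label]

    def __contains__(self, label: str) -> bool:
        return label in self.tracks

    @property
    def n_frames(self) -> int:
        return max((len(tr) for tr in self.tracks.values()), default=0)


@dataclass(frozen=True)
class Interval:
    """A single analysis window."""

    start_t: float
    end_t: float
    label: str
    kind: str = "seated"  # {"seated", "walking"}

    def __post_init__(self) -> None:
        if self.end_t <= self.start_t:
            raise DomainError("interval must have positive duration")

    @property
    def duration_s(self) -> float:
        return self.end_t - self.start_t

    def frame_range(self, frame_rate_hz: float = 25.0) -> tuple[int, int]:
        """Inclusive (first, last) frame indices covered by this window.

        A full 10-s window at 25 fps spans exactly 250 frames.
        """
        f0 = int(round(self.start_t * frame_rate_hz))
        n = int(round(self.duration_s * frame_rate_hz))
        return f0, f0 + n - 1

    def frames(self, frame_rate_hz: float = 25.0) -> np.ndarray:
        f0, f1 = self.frame_range(frame_rate_hz)
        return np.arange(f0, f1 + 1)


@dataclass
class AccuracyResult:
    interval: Interval
    accuracy_deg: float
    accuracy_median_deg: float
    bias_deg: float
    precision_rms_s2s_deg: float
    precision_sd_deg: float
    n_frames_valid: int
    missing_pct: float
    valid: bool = True

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        iv = d.pop("interval")
        d.update(
            start_t=iv["start_t"], end_t=iv["end_t"], label=iv["label"], kind=iv["kind"]
        )
        return d
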