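"""Scene-camera angular geometry.

Angles between image points are computed through a pinhole-style model: a pixel
position ``(x, y)`` is lifted to the 3-D ray ``(x - cx, y - cy, VD)`` where
``(cx, cy)`` is the image centre and ``VD`` the *virtual viewing distance* —
the physical camera-to-wall distance expressed in pixel units, i.e. the
magnification of the scene camera.  The angle between two rays is the angular
distance between the two image points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CameraModel",
    "CalibrationMeasurement",
    "angular_distance",
    "mm_to_deg",
    "estimate_vd",
    "fov_from_edges",
    "pixel_offset_for_angle",
]


@dataclass(frozen=True)
class CameraModel:
    """Scene-camera intrinsics used for pixel→degree conversion."""

    width_px: int = 1920
    height_px: int = 1080
    vd_px: float = 1132.4
    frame_rate_hz: float = 25.0
    pitch_deg: float | None = None  # recorded metadata; not used in computation

    def __post_init__(self) -> None:
        if self.vd_px <= 0:
            raise ValueError(f"vd_px must be positive, got {self.vd_px}")
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")

    @property
    def center(self) -> tuple[float, float]:
        return self.width_px / 2.0, self.height_px / 2.0


#: default camera models for the two supported devices
DEVICE_CAMERAS = {
    "tobii2": CameraModel(vd_px=1132.4, pitch_deg=12.0),
    "tobii3": CameraModel(vd_px=912.8, pitch_deg=1.0),
}


@dataclass(frozen=True)
class CalibrationMeasurement:
    """Physical measurements used to estimate the virtual viewing distance.

    ``offsets`` holds ``((x_px, y_px), d_mm)`` pairs: image points at a common
    nominal pixel eccentricity and their measured physical distance from the
    image-centre point on the wall.
    """

    camera_wall_distance_mm: float
    offsets: tuple[tuple[tuple[float, float], float], ...]
    eccentricity_px: float = 400.0

    def __post_init__(self) -> None:
        if self.camera_wall_distance_mm <= 0:
            raise ValueError("camera-wall distance must be positive")
        if not self.offsets:
            raise ValueError("at least one offset measurement is required")
        if any(d <= 0 for _, d in self.offsets):
            raise ValueError("all offset distances must be positive")
        if self.eccentricity_px <= 0:
            raise ValueError("eccentricity must be positive")

    @property
    def distances_mm(self) -> np.ndarray:
        return np.asarray([d for _, d in self.offsets], dtype=float)


def _rays(x, y, cam: CameraModel) -> np.ndarray:
    cx, cy = cam.center
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.stack(
        [x - cx, y - cy, np.full(np.broadcast(x, y).shape, cam.vd_px)], axis=-1
    )


def angular_distance(gaze, target, cam: CameraModel):
    """Angular distance in degrees between two image points.

    ``gaze`` and ``target`` are ``(x, y)`` pairs or ``(..., 2)`` arrays of pixel
    coordinates.  Non-finite coordinates propagate to NaN output.  The angle is
    evaluated as ``atan2(|u x v|, u . v)`` of the two centre-referred rays,
    which is algebraically the arccos of the normalised dot product but
    numerically stable for near-parallel rays.
    """
    gaze = np.asarray(gaze, dtype=float)
    target = np.asarray(target, dtype=float)
    u = _rays(gaze[..., 0], gaze[..., 1], cam)
    v = _rays(target[..., 0], target[..., 1], cam)
    dot = np.sum(u * v, axis=-1)
    cross = np.cross(u, v)
    theta = np.degrees(np.arctan2(np.linalg.norm(cross, axis=-1), dot))
    if theta.ndim == 0:
        return float(theta)
    return theta


def mm_to_deg(d, D: float):
    """Convert a physical offset ``d`` (mm) on a wall at distance ``D`` (mm) to degrees."""
    if D <= 0:
        raise ValueError(f"wall distance D must be positive, got {D}")
    return np.degrees(np.arctan(np.asarray(d, dtype=float) / D))


def estimate_vd(cal: CalibrationMeasurement) -> float:
    """Estimate the virtual viewing distance (px) from calibration offsets.

    ``VD = eccentricity_px * D / mean(d)``: the pixel eccentricity divided by
    the tangent of the mean measured angle.
    """
    mean_d = float(np.mean(cal.distances_mm))
    if mean_d == 0:
        raise ValueError("mean offset distance is zero")
    return cal.eccentricity_px * cal.camera_wall_distance_mm / mean_d


def fov_from_edges(left_mm: float, right_mm: float, D: float, rounding: int = 1) -> float:
    """Field of view (degrees) from the two edge-to-centre wall distances.

    Each edge distance is converted with :func:`mm_to_deg`, rounded to
    ``rounding`` decimals, and the two half-angles are summed.  The per-edge
    rounding mirrors how such half-angles are tabulated before summation.
    """
    if left_mm <= 0 or right_mm <= 0:
        raise ValueError("edge distances must be positive")
    half = [round(float(mm_to_deg(d, D)), rounding) for d in (left_mm, right_mm)]
    return float(sum(half))


def pixel_offset_for_angle(angle_deg: float, cam: CameraModel) -> float:
    """Pixel offset from the image centre subtending ``angle_deg`` at the centre."""
    return cam.vd_px * float(np.tan(np.radians(angle_deg)))
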