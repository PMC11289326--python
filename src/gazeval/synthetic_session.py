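"""Synthetic gaze sessions with exact ground truth.

A scenario fixes the condition (seated with chinrest, seated free-head, or
walking), the device profile, and the gaze-error model.  Gaze error is injected
*in angle space*: the ray through the current target pixel is rotated by the
bias angle plus isotropic Gaussian angular noise and projected back to the
image plane, so the angular distance between simulated gaze and target equals
the injected offset exactly (the noise-only angular error is Rayleigh with
mean ``sigma * sqrt(pi / 2)``).

Frames can optionally be rendered (nine green disks on white; a red-carpet
corridor with a concentric-ring bullseye) to exercise the vision stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import disk, polygon

from .camera_geometry import CameraModel, DEVICE_CAMERAS, pixel_offset_for_angle
from .core import (
    DEVICE_RATES,
    DOT_LABELS,
    ConfigError,
    GazeRecording,
    InstructionSchedule,
    LabelTrack,
    TargetTrack,
)

__all__ = [
    "SyntheticScenario",
    "SessionData",
    "make_protocol",
    "simulate_target_track",
    "simulate_gaze",
    "simulate_session",
    "render_frame",
    "render_dots_image",
    "render_corridor_image",
    "dot_layout",
]

CONDITIONS = ("seated_chinrest", "seated_free", "walking")

#: physical stimulus geometry: 536-mm dot ring and 20-mm dots viewed from 1 m,
#: 480-mm bullseye
RING_RADIUS_MM = 268.0
DOT_DIAMETER_MM = 20.0
WALL_DISTANCE_MM = 1000.0
BULLSEYE_RADIUS_MM = 240.0


@dataclass(frozen=True)
class SyntheticScenario:
    """Ground-truth parameters of one simulated trial."""

    condition: str = "seated_chinrest"
    device: str = "tobii2"
    rate_hz: float | None = None
    camera: CameraModel | None = None
    bias_deg: float = 0.0
    bias_direction_deg: float = 0.0
    noise_sd_deg: float = 0.0
    blink_rate_hz: float = 0.0
    blink_duration_median_s: float = 0.15
    blink_duration_sigma: float = 0.4
    tremor_sd_px: float = 0.0
    head_recenter: float = 0.85  # seated_free: fraction of eccentricity absorbed
    recenter_tau_s: float = 0.6
    gait_amplitude_px: tuple[float, float] = (30.0, 15.0)
    step_frequency_hz: float = 1.6
    approach_radius_px: tuple[float, float] = (12.0, 60.0)
    walk_duration_s: float = 20.0
    turn_gap_s: float = 8.0
    instruction_spacing_s: float = 12.0
    pitch_offset_deg: float = 0.0
    reaction_lag_s: tuple[float, float] = (0.3, 0.5)
    session_duration_s: float | None = None  # override the protocol-implied length
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ConfigError(f"unknown condition {self.condition!r}")
        if self.device not in DEVICE_RATES:
            raise ConfigError(f"unknown device {self.device!r}")
        if not 0.0 <= self.head_recenter <= 1.0:
            raise ConfigError("head_recenter must be in [0, 1]")
        for name in ("bias_deg", "noise_sd_deg", "blink_rate_hz", "tremor_sd_px"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")

    @property
    def cam(self) -> CameraModel:
        return self.camera if self.camera is not None else DEVICE_CAMERAS[self.device]

    @property
    def sampling_rate_hz(self) -> float:
        return self.rate_hz if self.rate_hz is not None else DEVICE_RATES[self.device]

    @property
    def duration_s(self) -> float:
        if self.session_duration_s is not None:
            return self.session_duration_s
        if self.condition == "walking":
            return 2 * self.walk_duration_s + self.turn_gap_s + 2.0
        return 19 * self.instruction_spacing_s

    def with_(self, **kwargs) -> "SyntheticScenario":
        return replace(self, **kwargs)


@dataclass
class SessionData:
    """Everything a simulated trial produces, plus the injected ground truth."""

    scenario: SyntheticScenario
    schedule: InstructionSchedule
    track: TargetTrack
    recording: GazeRecording
    truth: dict = field(default_factory=dict)


def make_protocol(
    condition: str,
    seed: int = 0,
    spacing_s: float = 12.0,
    walk_duration_s: float = 20.0,
    turn_gap_s: float = 8.0,
) -> InstructionSchedule:
    """Instruction schedule for a trial.

    Seated: 19 instructions at fixed spacing; the centre dot at the first,
    middle, and last slot, every other dot twice in random order.  Walking: one
    entry per walk epoch.
    """
    if condition not in CONDITIONS:
        raise ConfigError(f"unknown condition {condition!r}")
    if condition == "walking":
        onsets = (0.0, walk_duration_s + turn_gap_s)
        return InstructionSchedule(onsets_s=onsets, labels=("bullseye", "bullseye"))
    rng = np.random.default_rng(seed)
    peripheral = [lab for lab in DOT_LABELS if lab != "center"] * 2
    order = rng.permutation(len(peripheral))
    labels: list[str] = ["center"] * 19
    slots = [k for k in range(19) if k not in (0, 9, 18)]
    for slot, idx in zip(slots, order):
        labels[slot] = peripheral[idx]
    onsets = tuple(k * spacing_s for k in range(19))
    return InstructionSchedule(onsets_s=onsets, labels=tuple(labels))


def dot_layout(cam: CameraModel, pitch_offset_deg: float = 0.0) -> dict[str, np.ndarray]:
    """Static pixel positions of the nine-dot pattern.

    The ring radius is the 268-mm physical radius at 1 m projected through the
    camera's virtual viewing distance; a scene-camera pitch shifts the whole
    pattern vertically (downward camera pitch puts targets above the centre).
    """
    cx, cy = cam.center
    ring_px = cam.vd_px * RING_RADIUS_MM / WALL_DISTANCE_MM
    dy_pitch = pixel_offset_for_angle(pitch_offset_deg, cam)
    layout = {"center": np.array([cx, cy - dy_pitch])}
    compass = {
        "right": 0.0,
        "top-right": 45.0,
        "top": 90.0,
        "top-left": 135.0,
        "left": 180.0,
        "bottom-left": 225.0,
        "bottom": 270.0,
        "bottom-right": 315.0,
    }
    for label, ang in compass.items():
        a = np.radians(ang)
        layout[label] = np.array(
            [cx + ring_px * np.cos(a), cy - dy_pitch - ring_px * np.sin(a)]
        )
    return layout


def _recenter_offset(
    schedule: InstructionSchedule,
    layout: dict[str, np.ndarray],
    cam: CameraModel,
    head_recenter: float,
    tau_s: float,
    t: np.ndarray,
) -> np.ndarray:
    """Pattern translation over time for the free-head condition.

    After each instruction the head turns so the instructed dot moves toward
    the image centre by ``head_recenter`` of its eccentricity, with an
    exponential transition of time constant ``tau_s``.
    """
    cx, cy = cam.center
    center = np.array([cx, cy])
    offset = np.zeros((t.size, 2))
    current = np.zeros(2)
    onsets = list(schedule.onsets_s) + [np.inf]
    for k, (onset, label) in enumerate(schedule):
        goal = -head_recenter * (layout[label] - center)
        seg = (t >= onset) & (t < onsets[k + 1])
        if not np.any(seg):
            current = goal
            continue
        frac = 1.0 - np.exp(-(t[seg] - onset) / tau_s)
        offset[seg] = current + (goal - current) * frac[:, None]
        current = current + (goal - current) * (
            1.0 - np.exp(-(onsets[k + 1] - onset) / tau_s) if np.isfinite(onsets[k + 1]) else 1.0
        )
    return offset


def simulate_target_track(
    scenario: SyntheticScenario,
    schedule: InstructionSchedule,
) -> TargetTrack:
    """Per-frame target positions (and, for walking, scene visibility flags)."""
    cam = scenario.cam
    fps = cam.frame_rate_hz
    n_frames = int(round(scenario.duration_s * fps))
    frames = np.arange(n_frames)
    t = frames / fps
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 101]))
    if scenario.condition == "walking":
        if schedule.labels and any(lab != "bullseye" for lab in schedule.labels):
            raise ConfigError("walking scenario requires a bullseye schedule")
        return _walking_track(scenario, schedule, cam, t, frames, rng)
    if any(lab == "bullseye" for lab in schedule.labels):
        raise ConfigError("seated scenario cannot use a bullseye schedule")
    layout = dot_layout(cam, scenario.pitch_offset_deg)
    if scenario.condition == "seated_free":
        offset = _recenter_offset(
            schedule, layout, cam, scenario.head_recenter, scenario.recenter_tau_s, t
        )
    else:
        offset = np.zeros((n_frames, 2))
    if scenario.tremor_sd_px > 0:
        offset = offset + rng.normal(0.0, scenario.tremor_sd_px, size=(n_frames, 2))
    tracks: dict[str, LabelTrack] = {}
    w, h = cam.width_px, cam.height_px
    for label, base in layout.items():
        x = base[0] + offset[:, 0]
        y = base[1] + offset[:, 1]
        in_frame = (x >= 0) & (x < w) & (y >= 0) & (y < h)
        tracks[label] = LabelTrack(frame_index=frames, x=x, y=y, detected=in_frame)
    return TargetTrack(tracks=tracks, frame_rate_hz=fps)


def _walking_track(scenario, schedule, cam, t, frames, rng) -> TargetTrack:
    cx, cy = cam.center
    dy_pitch = pixel_offset_for_angle(scenario.pitch_offset_deg, cam)
    ax, ay = scenario.gait_amplitude_px
    f = scenario.step_frequency_hz
    phase = rng.uniform(0, 2 * np.pi, size=2)
    # vertical bob at step frequency, lateral sway at half of it
    x = cx + ax * np.sin(2 * np.pi * (f / 2.0) * t + phase[0])
    y = cy - dy_pitch + ay * np.sin(2 * np.pi * f * t + phase[1])
    r0, r1 = scenario.approach_radius_px
    radius = np.full(t.shape, r0)
    visible = np.zeros(t.shape, dtype=bool)
    for onset in schedule.onsets_s:
        walk = (t >= onset) & (t < onset + scenario.walk_duration_s)
        visible |= walk
        prog = (t[walk] - onset) / scenario.walk_duration_s
        radius[walk] = r0 + (r1 - r0) * prog
    track = LabelTrack(
        frame_index=frames, x=x, y=y, detected=visible, radius=radius
    )
    return TargetTrack(
        tracks={"bullseye": track}, frame_rate_hz=cam.frame_rate_hz, visible=visible
    )


def _tangent_basis(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal tangent basis at unit rays v (aligned with image x then y)."""
    ex = np.array([1.0, 0.0, 0.0])
    e1 = ex - v * v[..., :1]
    e1 /= np.linalg.norm(e1, axis=-1, keepdims=True)
    e2 = np.cross(v, e1)
    return e1, e2


def _apply_angular_error(
    x: np.ndarray,
    y: np.ndarray,
    cam: CameraModel,
    tangent_angles_rad: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Rotate the rays through (x, y) by the given 2-component tangent angles.

    The rotation magnitude (in radians) equals the resulting angular distance
    from the original point exactly.
    """
    cx, cyc = cam.center
    v = np.stack([x - cx, y - cyc, np.full(x.shape, cam.vd_px)], axis=-1)
    v /= np.linalg.norm(v, axis=-1, keepdims=True)
    e1, e2 = _tangent_basis(v)
    w = tangent_angles_rad[..., :1] * e1 + tangent_angles_rad[..., 1:] * e2
    alpha = np.linalg.norm(tangent_angles_rad, axis=-1, keepdims=True)
    small = alpha[..., 0] < 1e-15
    with np.errstate(invalid="ignore", divide="ignore"):
        w_hat = np.where(small[..., None], 0.0, w / np.where(alpha == 0, 1.0, alpha))
    v_new = np.cos(alpha) * v + np.sin(alpha) * w_hat
    scale = cam.vd_px / v_new[..., 2]
    return cx + v_new[..., 0] * scale, cyc + v_new[..., 1] * scale


def simulate_gaze(
    scenario: SyntheticScenario,
    track: TargetTrack,
    schedule: InstructionSchedule,
) -> tuple[GazeRecording, dict]:
    """Simulate the gaze stream for a trial.

    Gaze follows the instructed target (with a uniform reaction lag and an
    instantaneous saccadic jump after each onset), displaced by the scenario's
    bias and angular noise; blinks arrive as a Poisson process and invalidate
    the overlapped samples.  Returns the recording and a ground-truth log.
    """
    cam = scenario.cam
    rate = scenario.sampling_rate_hz
    n = int(round(scenario.duration_s * rate))
    t = np.arange(n) / rate
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 202]))

    lags = rng.uniform(*scenario.reaction_lag_s, size=len(schedule))
    switch_times = np.asarray(schedule.onsets_s) + lags
    # index of the currently fixated instruction per sample (first label before lag elapses)
    idx = np.clip(np.searchsorted(switch_times, t, side="right") - 1, 0, None).astype(int)

    frame_t = np.arange(track.n_frames) / track.frame_rate_hz
    tx = np.empty(n)
    ty = np.empty(n)
    label_per_sample = np.asarray(schedule.labels, dtype=object)[idx]
    for label in set(schedule.labels):
        sel = label_per_sample == label
        if not np.any(sel):
            continue
        lt = track[label]
        # forward-fill undetected spans so gaze stays put while the target is unseen
        x_ff = _ffill(lt.x)
        y_ff = _ffill(lt.y)
        tx[sel] = np.interp(t[sel], frame_t, x_ff)
        ty[sel] = np.interp(t[sel], frame_t, y_ff)

    bias_rad = np.radians(scenario.bias_deg)
    dir_rad = np.radians(scenario.bias_direction_deg)
    tangent = np.tile(
        [bias_rad * np.cos(dir_rad), bias_rad * np.sin(dir_rad)], (n, 1)
    )
    if scenario.noise_sd_deg > 0:
        tangent = tangent + rng.normal(
            0.0, np.radians(scenario.noise_sd_deg), size=(n, 2)
        )
    gx, gy = _apply_angular_error(tx, ty, cam, tangent)

    valid = np.ones(n, dtype=bool)
    blinks: list[tuple[float, float]] = []
    if scenario.blink_rate_hz > 0:
        t_blink = rng.exponential(1.0 / scenario.blink_rate_hz)
        while t_blink < scenario.duration_s:
            dur = float(
                np.exp(
                    rng.normal(
                        np.log(scenario.blink_duration_median_s),
                        scenario.blink_duration_sigma,
                    )
                )
            )
            blinks.append((t_blink, dur))
            valid &= ~((t >= t_blink) & (t < t_blink + dur))
            t_blink += dur + rng.exponential(1.0 / scenario.blink_rate_hz)

    recording = GazeRecording(
        t=t,
        x=np.where(valid, gx, np.nan),
        y=np.where(valid, gy, np.nan),
        valid=valid,
        device=scenario.device,
        rate_hz=rate,
        camera=cam,
    )
    truth = {
        "bias_deg": scenario.bias_deg,
        "bias_direction_deg": scenario.bias_direction_deg,
        "noise_sd_deg": scenario.noise_sd_deg,
        "reaction_lags_s": lags,
        "switch_times_s": switch_times,
        "blinks": blinks,
        "blink_sample_fraction": 1.0 - float(np.count_nonzero(valid)) / max(n, 1),
    }
    return recording, truth


def _ffill(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    if not np.any(ok):
        return np.zeros_like(values)
    idx = np.maximum.accumulate(np.where(ok, np.arange(values.size), 0))
    first = np.argmax(ok)
    out = values[idx]
    out[: first] = values[first]
    return out


def simulate_session(scenario: SyntheticScenario) -> SessionData:
    """Full trial: protocol, target track, and gaze recording with ground truth."""
    schedule = make_protocol(
        scenario.condition,
        seed=scenario.seed,
        spacing_s=scenario.instruction_spacing_s,
        walk_duration_s=scenario.walk_duration_s,
        turn_gap_s=scenario.turn_gap_s,
    )
    track = simulate_target_track(scenario, schedule)
    recording, truth = simulate_gaze(scenario, track, schedule)
    return SessionData(
        scenario=scenario, schedule=schedule, track=track, recording=recording, truth=truth
    )


# ---------------------------------------------------------------------------
# rendering


def render_dots_image(
    positions: dict[str, tuple[float, float]] | list[tuple[float, float]],
    radius_px: float = 11.0,
    cam: CameraModel | None = None,
) -> np.ndarray:
    """White frame with a pure-green disk at each position (out-of-frame parts clipped)."""
    cam = cam or CameraModel()
    img = np.full((cam.height_px, cam.width_px, 3), 255, dtype=np.uint8)
    pts = positions.values() if isinstance(positions, dict) else positions
    for x, y in pts:
        if not (np.isfinite(x) and np.isfinite(y)):
            continue
        rr, cc = disk((y, x), radius_px, shape=img.shape[:2])
        img[rr, cc] = (0, 200, 0)
    return img


def render_corridor_image(
    bullseye: tuple[float, float],
    radius_px: float,
    vanishing_point: tuple[float, float],
    cam: CameraModel | None = None,
    carpet_halfwidth_bottom_px: float = 700.0,
    carpet_top_frac: float = 0.8,
    occlude_bullseye: bool = False,
) -> np.ndarray:
    """Corridor frame: red carpet trapezoid whose long edges meet at the
    vanishing point, plus a concentric-ring green bullseye.

    ``carpet_top_frac`` sets where the carpet's far end is cut, as a fraction
    of the distance from the bottom corners to the vanishing point.
    """
    cam = cam or CameraModel()
    h, w = cam.height_px, cam.width_px
    img = np.full((h, w, 3), 235, dtype=np.uint8)
    vx, vy = vanishing_point
    bl = np.array([vx - carpet_halfwidth_bottom_px, h - 1.0])
    br = np.array([vx + carpet_halfwidth_bottom_px, h - 1.0])
    vp = np.array([vx, vy])
    tl = bl + carpet_top_frac * (vp - bl)
    tr = br + carpet_top_frac * (vp - br)
    poly = np.array([bl, br, tr, tl])
    rr, cc = polygon(poly[:, 1], poly[:, 0], shape=(h, w))
    img[rr, cc] = (190, 30, 30)
    if not occlude_bullseye:
        bx, by = bullseye
        for frac, color in ((1.0, (0, 200, 0)), (2 / 3, (255, 255, 255)), (1 / 3, (0, 200, 0))):
            rr, cc = disk((by, bx), max(radius_px * frac, 1.0), shape=(h, w))
            img[rr, cc] = color
    return img


def render_frame(
    scenario: SyntheticScenario,
    track: TargetTrack,
    frame_index: int,
) -> np.ndarray:
    """Render one scene-camera frame of a simulated trial."""
    cam = scenario.cam
    if scenario.condition == "walking":
        lt = track["bullseye"]
        if not lt.detected[frame_index]:
            vx = cam.center[0]
            vy = cam.center[1] - pixel_offset_for_angle(scenario.pitch_offset_deg, cam)
            return render_corridor_image(
                (vx, vy), 1.0, (vx, vy), cam, occlude_bullseye=True
            )
        x, y = float(lt.x[frame_index]), float(lt.y[frame_index])
        r = float(lt.radius[frame_index]) if lt.radius is not None else 30.0
        return render_corridor_image((x, y), r, (x, y), cam)
    positions = {}
    for label in track.labels():
        lt = track[label]
        positions[label] = (float(lt.x[frame_index]), float(lt.y[frame_index]))
    dot_radius = cam.vd_px * (DOT_DIAMETER_MM / 2.0) / WALL_DISTANCE_MM
    return render_dots_image(positions, dot_radius, cam)
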