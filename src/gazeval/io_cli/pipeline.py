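"""Pipeline orchestration: preprocess -> (detect|load track) -> segment ->
metrics, driven by a YAML config.

Config keys::

    device: tobii2 | tobii3
    condition: seated_chinrest | seated_free | walking
    participant: free-form id               (default "p01")
    seed: int                               (default 0)
    out_dir: directory for results          (optional; no files if absent)
    scenario: {...}                         simulate a synthetic session, or
    inputs:                                 load recorded data
      gaze: gaze export CSV/TSV
      schedule: onset_s,label CSV
      track: target-track CSV
      time_unit: s | ms | us
    camera: {vd_px: ..., pitch_deg: ...}    optional camera override
    filter_window_s: 0.30
    track_smooth_frames: 5
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ..camera_geometry import CameraModel, DEVICE_CAMERAS
from ..core import ConfigError, DEVICE_RATES, GazeRecording, TargetTrack
from ..gaze_preprocess import frame_average, median_filter_recording, missing_fraction
from ..quality_metrics import heatmap, interval_accuracy, target_speed
from ..scene_vision import smooth_track
from ..segmentation import seated_intervals, walking_intervals
from ..synthetic_session import CONDITIONS, SyntheticScenario, simulate_session
from .io import read_gaze_export, read_schedule, read_track, write_heatmap

__all__ = ["load_config", "run_pipeline"]

log = logging.getLogger(__name__)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML mapping")
    return cfg


def _camera_from(cfg: dict, device: str) -> CameraModel:
    base = DEVICE_CAMERAS[device]
    overrides = cfg.get("camera") or {}
    if overrides:
        return dataclasses.replace(base, **overrides)
    return base


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise type(exc)(f"[stage {name}] {exc}") from exc


def run_pipeline(config: str | Path | dict) -> tuple[pd.DataFrame, dict]:
    """Run the full evaluation for one trial.

    Returns the results table (one row per analysis interval plus one
    aggregate row) and a dict of in-memory artifacts (frame gaze, track,
    intervals, heatmap).  With ``out_dir`` set, ``results.csv`` and
    ``heatmap.csv`` are written there.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = config
    device = cfg.get("device", "tobii2")
    condition = cfg.get("condition", "seated_chinrest")
    if device not in DEVICE_RATES:
        raise ConfigError(f"unknown device {device!r}")
    if condition not in CONDITIONS:
        raise ConfigError(f"unknown condition {condition!r}")
    participant = cfg.get("participant", "p01")
    seed = int(cfg.get("seed", 0))
    cam = _camera_from(cfg, device)

    if "scenario" in cfg and "inputs" in cfg:
        raise ConfigError("config must name either 'scenario' or 'inputs', not both")
    if "scenario" in cfg:
        scenario = SyntheticScenario(
            condition=condition,
            device=device,
            camera=cam,
            seed=seed,
            **(cfg.get("scenario") or {}),
        )
        session = _stage("simulate", simulate_session, scenario)
        recording, track, schedule = session.recording, session.track, session.schedule
        log.info("simulate: %d samples, %d frames", len(recording), track.n_frames)
    elif "inputs" in cfg:
        inputs = cfg["inputs"]
        if "gaze" not in inputs or "schedule" not in inputs:
            raise ConfigError("'inputs' requires 'gaze' and 'schedule'")
        recording = _stage(
            "read_gaze",
            read_gaze_export,
            inputs["gaze"],
            device=device,
            time_unit=inputs.get("time_unit", "s"),
            camera=cam,
        )
        schedule = _stage("read_schedule", read_schedule, inputs["schedule"])
        if "track" not in inputs:
            raise ConfigError("'inputs' requires a 'track' CSV (run `gazeval detect` first)")
        track = _stage("read_track", read_track, inputs["track"], cam.frame_rate_hz)
        log.info("load: %d samples, %d frames of track", len(recording), track.n_frames)
    else:
        raise ConfigError("config must provide 'scenario' or 'inputs'")

    window_s = float(cfg.get("filter_window_s", 0.30))
    raw_frames = _stage("frame_average_raw", frame_average, recording, cam)
    filtered = _stage("median_filter", median_filter_recording, recording, window_s)
    frames = _stage("frame_average", frame_average, filtered, cam)
    log.info(
        "preprocess: missing %.2f%% before / %.2f%% after filtering",
        missing_fraction(raw_frames),
        missing_fraction(frames),
    )

    smooth_n = int(cfg.get("track_smooth_frames", 5))
    track = _stage("smooth_track", smooth_track, track, smooth_n)

    if condition == "walking":
        intervals = _stage("segment", walking_intervals, track)
    else:
        intervals = _stage("segment", seated_intervals, schedule)
    log.info("segment: %d analysis intervals", len(intervals))

    rows = []
    target_points_x: list[np.ndarray] = []
    target_points_y: list[np.ndarray] = []
    for k, interval in enumerate(intervals):
        res = _stage("metrics", interval_accuracy, frames, track, cam, interval)
        speed = _stage("metrics", target_speed, track, cam, interval)
        row = res.as_dict()
        row.update(
            participant=participant,
            device=device,
            condition=condition,
            interval=k,
            target_speed_deg_s=speed,
        )
        rows.append(row)
        tx, ty = track[interval.label].at_frames(interval.frames(cam.frame_rate_hz))
        target_points_x.append(tx)
        target_points_y.append(ty)
    results = pd.DataFrame(rows)

    agg = {
        "participant": participant,
        "device": device,
        "condition": condition,
        "interval": "aggregate",
        "label": "all",
        "kind": intervals[0].kind if intervals else "",
        "accuracy_deg": results["accuracy_deg"].mean(),
        "accuracy_median_deg": results["accuracy_median_deg"].mean(),
        "bias_deg": results["bias_deg"].mean(),
        "precision_rms_s2s_deg": results["precision_rms_s2s_deg"].mean(),
        "precision_sd_deg": results["precision_sd_deg"].mean(),
        "n_frames_valid": results["n_frames_valid"].sum(),
        "missing_pct": results["missing_pct"].mean(),
        "target_speed_deg_s": results["target_speed_deg_s"].mean(),
        "valid": bool(results["valid"].all()),
    }
    results = pd.concat([results, pd.DataFrame([agg])], ignore_index=True)

    hm = None
    all_tx = np.concatenate(target_points_x) if target_points_x else np.array([])
    all_ty = np.concatenate(target_points_y) if target_points_y else np.array([])
    if np.any(np.isfinite(all_tx)):
        hm = _stage("heatmap", heatmap, all_tx, all_ty, cam)

    artifacts = {
        "frames": frames,
        "raw_frames": raw_frames,
        "track": track,
        "intervals": intervals,
        "heatmap": hm,
        "recording": recording,
        "schedule": schedule,
    }
    out_dir = cfg.get("out_dir")
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.to_csv(out / "results.csv", index=False)
        if hm is not None:
            write_heatmap(hm, out / "heatmap.csv")
        log.info("wrote results to %s", out)
    return results, artifacts
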