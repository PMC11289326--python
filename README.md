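# gazeval

Data-quality evaluation of head-mounted (wearable) eye-trackers. The package
implements an end-to-end pipeline for assessing gaze accuracy against targets
localised in the scene-camera video, together with a ground-truthed synthetic
session simulator used to validate every stage:

- **camera_geometry** — the angular model: angular distance between two image
  points via centre-referred 3-D rays and the *virtual viewing distance* (VD),
  mm↔degree conversion (`atan(d/D)`), VD estimation from calibration
  measurements, and field-of-view computation.
- **gaze_preprocess** — a missing-omitting 0.30-s moving median filter (bridges
  blinks, preserves saccade edges), per-video-frame averaging of gaze samples,
  and missing-data accounting.
- **scene_vision** — target localisation: colour segmentation, circular-Hough
  dot detection with compass-sector labelling of the nine-dot pattern,
  carpet-edge line fitting with vanishing-point estimation as a bullseye prior,
  and 5-frame median track smoothing.
- **segmentation** — the 10-second analysis windows: instruction-driven for
  seated trials (2-s skip after each onset → 250 frames at 25 fps) and
  visibility-driven for walking trials (window ends when the carpet leaves the
  camera view).
- **quality_metrics** — per-interval accuracy (mean and median angular
  distance), bias (angular size of the mean gaze−target displacement),
  precision (RMS sample-to-sample and SD variants), target speed, 20-px
  heatmaps normalised to a total of 1000, and across-participant summaries.
- **study_stats** — paired t-tests, 2×3 repeated-measures ANOVA with partial
  η², Pearson / point-biserial correlations, 21-tick workload-scale scoring,
  and z-scored overall accuracy.
- **synthetic_session** — scenario-driven simulation of complete trials
  (chinrest / free-head / walking) with exact angular ground truth for bias,
  noise, blinks, head re-centering, and gait oscillation, plus a frame
  renderer for exercising the vision stage.
- **io_cli** — CSV/TSV gaze exports with configurable column maps, schedule /
  track / heatmap files, PNG-sequence (or MP4) frame reading, YAML-configured
  pipeline orchestration, and the CLI.

## CLI

```sh
# generate a synthetic session (gaze export, schedule, target track, optional frames)
gazeval simulate --config cfg.yaml --out session/ --seed 1 [--render]

# extract a target track from scene-camera frames
gazeval detect --frames session/frames --out track.csv --condition seated_chinrest

# run preprocess -> segment -> metrics; writes results.csv and heatmap.csv
gazeval evaluate --config cfg.yaml --out out/

# across-participant summary of one or more results tables
gazeval report --results out/results.csv --out summary.csv
```

A minimal config:

```yaml
device: tobii2            # tobii2 (50 Hz) or tobii3 (100 Hz)
condition: seated_chinrest  # seated_chinrest | seated_free | walking
seed: 1
scenario:                 # simulate a synthetic session...
  bias_deg: 2.0
  noise_sd_deg: 0.5
  blink_rate_hz: 0.2
# inputs:                 # ...or evaluate recorded data instead
#   gaze: gaze.csv
#   schedule: schedule.csv
#   track: track.csv
```

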