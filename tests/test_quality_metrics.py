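import numpy as np
import pandas as pd
import pytest

from gazeval.camera_geometry import angular_distance
from gazeval.core import DomainError, FrameGazeSeries, Interval, LabelTrack, TargetTrack
from gazeval.quality_metrics import (
    condition_summary,
    heatmap,
    interval_accuracy,
    interval_bias,
    interval_precision,
    target_speed,
)


def _frames(x, y, fps=25.0):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    return FrameGazeSeries(
        frame_index=np.arange(n),
        t=np.arange(n) / fps,
        x=x,
        y=y,
        missing=~(np.isfinite(x) & np.isfinite(y)),
        frame_rate_hz=fps,
    )


def _static_track(label, x, y, n, fps=25.0):
    return TargetTrack(
        tracks={
            label: LabelTrack(
                frame_index=np.arange(n),
                x=np.full(n, float(x)),
                y=np.full(n, float(y)),
                detected=np.ones(n, dtype=bool),
            )
        },
        frame_rate_hz=fps,
    )


IV = Interval(start_t=0.0, end_t=10.0, label="center", kind="seated")


class TestIntervalAccuracy:
    def test_gaze_on_target_zero(self, cam_t2):
        frames = _frames(np.full(250, 960.0), np.full(250, 540.0))
        track = _static_track("center", 960, 540, 250)
        res = interval_accuracy(frames, track, cam_t2, IV)
        assert res.accuracy_deg == 0.0 and res.accuracy_median_deg == 0.0
        assert res.n_frames_valid == 250 and res.valid

    def test_constant_offset_closed_form(self, cam_t2):
        frames = _frames(np.full(250, 1360.0), np.full(250, 540.0))
        track = _static_track("center", 960, 540, 250)
        res = interval_accuracy(frames, track, cam_t2, IV)
        expected = np.degrees(np.arctan(400.0 / 1132.4))
        assert res.accuracy_deg == pytest.approx(expected, abs=1e-12)
        assert res.bias_deg == pytest.approx(expected, abs=1e-12)

    def test_rayleigh_mean_of_isotropic_noise(self, cam_t2, rng):
        # sigma = 1 deg of isotropic angular noise around a central target:
        # E[theta] = sigma * sqrt(pi/2); check against a Monte-Carlo oracle CI
        sigma_px = cam_t2.vd_px * np.tan(np.radians(1.0))
        n = 2500
        gx = 960.0 + rng.normal(0, sigma_px, n)
        gy = 540.0 + rng.normal(0, sigma_px, n)
        frames = _frames(gx, gy)
        track = _static_track("center", 960, 540, n)
        iv = Interval(0.0, n / 25.0, "center")
        res = interval_accuracy(frames, track, cam_t2, iv)
        expected = np.sqrt(np.pi / 2)
        se = np.sqrt((2 - np.pi / 2)) / np.sqrt(n)  # SD of Rayleigh / sqrt(n)
        assert abs(res.accuracy_deg - expected) < 3 * se + 0.01

    def test_median_below_mean_with_outliers(self, cam_t2):
        gx = np.full(250, 1000.0)
        gx[::25] = 1900.0  # injected large deviations right-skew the series
        frames = _frames(gx, np.full(250, 540.0))
        track = _static_track("center", 960, 540, 250)
        res = interval_accuracy(frames, track, cam_t2, IV)
        assert res.accuracy_median_deg < res.accuracy_deg

    def test_zero_usable_frames_flagged(self, cam_t2):
        frames = _frames(np.full(250, np.nan), np.full(250, np.nan))
        track = _static_track("center", 960, 540, 250)
        res = interval_accuracy(frames, track, cam_t2, IV)
        assert not res.valid and np.isnan(res.accuracy_deg)
        assert res.missing_pct == 100.0

    def test_undetected_target_not_missing_gaze(self, cam_t2):
        frames = _frames(np.full(250, 960.0), np.full(250, 540.0))
        track = _static_track("center", 960, 540, 250)
        track["center"].detected[:50] = False
        track["center"].x[:50] = np.nan
        track["center"].y[:50] = np.nan
        res = interval_accuracy(frames, track, cam_t2, IV)
        assert res.n_frames_valid == 200
        assert res.missing_pct == 0.0  # gaze itself was never missing


class TestIntervalBias:
    def test_alternating_offsets_cancel(self, cam_t2):
        gx = np.full(250, 960.0)
        gx[::2] = 560.0
        gx[1::2] = 1360.0
        frames = _frames(gx, np.full(250, 540.0))
        track = _static_track("center", 960, 540, 250)
        bias = interval_bias(frames, track, cam_t2, IV)
        acc = interval_accuracy(frames, track, cam_t2, IV).accuracy_deg
        assert bias == pytest.approx(0.0, abs=1e-12)
        assert acc > 19.0

    def test_constant_offset_equals_accuracy(self, cam_t2):
        frames = _frames(np.full(250, 1360.0), np.full(250, 940.0))
        track = _static_track("center", 960, 540, 250)
        res = interval_accuracy(frames, track, cam_t2, IV)
        assert res.bias_deg == pytest.approx(res.accuracy_deg, abs=1e-12)

    def test_bias_with_noise_recovers_truth(self, cam_t2, rng):
        delta_px = cam_t2.vd_px * np.tan(np.radians(2.0))
        sigma_px = cam_t2.vd_px * np.tan(np.radians(1.0))
        n = 2500
        gx = 960.0 + delta_px + rng.normal(0, sigma_px, n)
        gy = 540.0 + rng.normal(0, sigma_px, n)
        frames = _frames(gx, gy)
        track = _static_track("center", 960, 540, n)
        bias = interval_bias(frames, track, cam_t2, Interval(0, n / 25.0, "center"))
        se = 1.0 / np.sqrt(n)
        assert abs(bias - 2.0) < 3 * se + 0.01


class TestIntervalPrecision:
    def test_constant_gaze(self, cam_t2):
        frames = _frames(np.full(250, 1000.0), np.full(250, 500.0))
        track = _static_track("center", 960, 540, 250)
        rms, sd = interval_precision(frames, track, cam_t2, IV)
        assert rms == 0.0 and sd == 0.0

    def test_alternating_two_points(self, cam_t2):
        a, b = (900.0, 500.0), (1020.0, 580.0)
        gx = np.where(np.arange(250) % 2 == 0, a[0], b[0])
        gy = np.where(np.arange(250) % 2 == 0, a[1], b[1])
        frames = _frames(gx, gy)
        track = _static_track("center", 960, 540, 250)
        rms, _ = interval_precision(frames, track, cam_t2, IV)
        assert rms == pytest.approx(angular_distance(a, b, cam_t2), abs=1e-12)

    def test_rms_s2s_of_gaussian_noise(self, cam_t2, rng):
        # independent isotropic noise sigma: successive differences are
        # N(0, 2 sigma^2 I); RMS of their norm is 2 sigma (Monte-Carlo oracle)
        sigma = 1.0
        sigma_px = cam_t2.vd_px * np.tan(np.radians(sigma))
        n = 5000
        gx = 960.0 + rng.normal(0, sigma_px, n)
        gy = 540.0 + rng.normal(0, sigma_px, n)
        frames = _frames(gx, gy)
        track = _static_track("center", 960, 540, n)
        rms, _ = interval_precision(frames, track, cam_t2, Interval(0, n / 25.0, "center"))
        oracle = rng.normal(0, sigma, (20000, 2)) - rng.normal(0, sigma, (20000, 2))
        oracle_rms = np.sqrt(np.mean(np.sum(oracle**2, axis=1)))
        assert rms == pytest.approx(oracle_rms, rel=0.05)
        assert rms == pytest.approx(2 * sigma, rel=0.05)

    def test_too_few_frames(self, cam_t2):
        x = np.full(250, np.nan)
        x[0] = 960.0
        frames = _frames(x, x.copy())
        track = _static_track("center", 960, 540, 250)
        rms, sd = interval_precision(frames, track, cam_t2, IV)
        assert np.isnan(rms) and np.isnan(sd)


class TestTargetSpeed:
    def test_static_target(self, cam_t2):
        track = _static_track("center", 960, 540, 250)
        assert target_speed(track, cam_t2, IV) == 0.0

    def test_stepping_target_closed_form(self, cam_t2):
        # target alternates between the centre and 40 px right of it: every
        # frame step subtends atan(40/VD) from the centre
        n = 250
        x = np.where(np.arange(n) % 2 == 0, 960.0, 1000.0)
        track = TargetTrack(
            tracks={
                "center": LabelTrack(
                    frame_index=np.arange(n),
                    x=x,
                    y=np.full(n, 540.0),
                    detected=np.ones(n, dtype=bool),
                )
            }
        )
        expected = 25.0 * np.degrees(np.arctan(40.0 / 1132.4))
        assert target_speed(track, cam_t2, IV) == pytest.approx(expected, abs=1e-9)

    def test_sinusoid_matches_dense_oracle(self, cam_t2):
        # gait-like oscillation, amplitude/frequency chosen freely
        amp, freq, fps, dur = 30.0, 1.6, 25.0, 10.0
        t25 = np.arange(int(dur * fps)) / fps
        x = 960.0 + amp * np.sin(2 * np.pi * freq * t25)
        track = TargetTrack(
            tracks={
                "center": LabelTrack(
                    frame_index=np.arange(t25.size),
                    x=x,
                    y=np.full(t25.size, 540.0),
                    detected=np.ones(t25.size, dtype=bool),
                )
            }
        )
        speed = target_speed(track, cam_t2, IV)
        # dense numeric-integration oracle of the mean angular speed
        td = np.arange(0, dur, 1e-4)
        xd = 960.0 + amp * np.sin(2 * np.pi * freq * td)
        ang = np.degrees(np.arctan((xd - 960.0) / cam_t2.vd_px))
        oracle = np.sum(np.abs(np.diff(ang))) / dur
        assert speed == pytest.approx(oracle, rel=0.05)

    def test_undetected_invalid(self, cam_t2):
        track = _static_track("center", 960, 540, 250)
        track["center"].detected[:] = False
        track["center"].x[:] = np.nan
        track["center"].y[:] = np.nan
        assert np.isnan(target_speed(track, cam_t2, IV))


class TestHeatmap:
    def test_single_cell(self):
        hm = heatmap(np.full(50, 10.0), np.full(50, 10.0))
        assert hm.grid[0, 0] == 1000.0
        assert hm.total == pytest.approx(1000.0, abs=1e-6)

    def test_two_cells_split(self):
        x = np.array([10.0] * 5 + [30.0] * 5)
        y = np.full(10, 10.0)
        hm = heatmap(x, y)
        assert hm.grid[0, 0] == 500.0 and hm.grid[0, 1] == 500.0

    def test_matches_direct_binning_oracle(self, rng):
        x = rng.uniform(0, 1920, 5000)
        y = rng.uniform(0, 1080, 5000)
        hm = heatmap(x, y)
        counts = np.zeros((54, 96))
        for xi, yi in zip(x, y):
            counts[int(yi // 20), int(xi // 20)] += 1
        assert np.allclose(hm.grid, counts * 1000.0 / counts.sum())
        assert hm.total == pytest.approx(1000.0, abs=1e-6)

    def test_out_of_bounds_dropped(self):
        x = np.array([10.0, -5.0, 5000.0])
        y = np.array([10.0, 10.0, 10.0])
        hm = heatmap(x, y)
        assert hm.grid[0, 0] == 1000.0

    def test_no_inbounds_points(self):
        with pytest.raises(DomainError):
            heatmap(np.array([-1.0]), np.array([-1.0]))


class TestConditionSummary:
    @staticmethod
    def _results_df(rng, n_participants=6, n_intervals=19):
        rows = []
        for p in range(n_participants):
            for k in range(n_intervals):
                rows.append(
                    dict(
                        participant=f"p{p:02d}",
                        device="tobii2",
                        condition="seated_chinrest",
                        label="center" if k in (0, 9, 18) else "top",
                        accuracy_deg=float(rng.gamma(4.0, 0.5)),
                    )
                )
        return pd.DataFrame(rows)

    def test_single_value(self):
        df = pd.DataFrame(
            [dict(participant="p0", device="d", condition="c", label="center", accuracy_deg=1.5)]
        )
        out = condition_summary(df)
        assert out.loc[0, "mean"] == 1.5 and out.loc[0, "sd"] == 0.0
        assert not out.loc[0, "sd_defined"]

    def test_matches_direct_computation(self, rng):
        df = self._results_df(rng)
        out = condition_summary(df)
        per_p = df.groupby("participant")["accuracy_deg"].mean()
        assert out.loc[0, "mean"] == pytest.approx(per_p.mean())
        assert out.loc[0, "sd"] == pytest.approx(per_p.std(ddof=1))
        assert out.loc[0, "median"] == pytest.approx(per_p.median())

    def test_central_dot_filter(self, rng):
        df = self._results_df(rng)
        out = condition_summary(df, labels=["center"])
        sel = df[df["label"] == "center"]
        assert len(sel) == 3 * 6  # three central intervals per participant
        per_p = sel.groupby("participant")["accuracy_deg"].mean()
        assert out.loc[0, "mean"] == pytest.approx(per_p.mean())

    def test_empty_raises(self):
        with pytest.raises(DomainError):
            condition_summary(pd.DataFrame(columns=["participant", "device", "condition", "label", "accuracy_deg"]))
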