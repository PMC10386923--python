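"""Movement-end detection, frame synchronisation, acceleration estimation,
spatial calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import savgol_filter

from conftest import make_trial
from reachrc import (
    SessionConfig,
    annotate_session,
    calibrate_affine,
    find_movement_end,
    frame_indices_from_end,
    savgol_acceleration,
    savgol_acceleration_batch,
)


def ramp_trial(y_end, t_end=0.7, dt=0.002, path_y=200.0):
    """Finger moving straight ahead from y=0 to y_end over t_end seconds."""
    times = np.arange(0, t_end + dt / 2, dt)
    y = y_end * times / t_end
    x = np.zeros_like(times)
    return make_trial(times, x, y)


class TestMovementEnd:
    def test_crossing_is_linearly_interpolated(self, cfg):
        """Finger y passing 195 -> 205 mm across the 200 mm path between
        samples at 0.548 and 0.550 s ends the movement at 0.549 s."""
        times = np.arange(0, 0.7001, 0.002)
        y = 195.0 + (times - 0.548) * 5000.0  # 195 at 0.548, 205 at 0.550
        trial = make_trial(times, np.zeros_like(times), y)
        end = find_movement_end(trial, cfg)
        assert end.end_kind == "crossed_path"
        assert end.end_time == pytest.approx(0.549, abs=1e-12)

    def test_peak_15mm_short_uses_max_distance(self, cfg):
        """Stopping 15 mm short of the path (< 20 mm threshold) anchors the
        end at the maximal distance from the start."""
        times = np.arange(0, 0.8001, 0.002)
        y = 185.0 * np.sin(np.pi * times / 0.8)  # peak 185 at t = 0.4
        trial = make_trial(times, np.zeros_like(times), y)
        end = find_movement_end(trial, cfg)
        assert end.end_kind == "max_distance"
        assert end.end_time == pytest.approx(0.4, abs=0.002)
        assert not trial.excluded

    def test_peak_50mm_short_is_excluded(self, cfg):
        times = np.arange(0, 0.8001, 0.002)
        y = 150.0 * np.sin(np.pi * times / 0.8)
        trial = make_trial(times, np.zeros_like(times), y)
        assert find_movement_end(trial, cfg) is None
        assert trial.excluded

    def test_every_trial_annotated_or_excluded(self, cfg, model, small_session):
        kept, excluded = annotate_session(list(small_session), cfg)
        assert len(kept) + len(excluded) == len(small_session)
        assert all(t.movement_end is not None for t in kept)
        assert all(t.excluded for t in excluded)

    def test_too_few_samples_rejected(self, cfg):
        trial = ramp_trial(300.0)
        trial.times, trial.x, trial.y = trial.times[:1], trial.x[:1], trial.y[:1]
        with pytest.raises(ValueError):
            find_movement_end(trial, cfg)


class TestFrameSync:
    def test_last_frame_before_end_is_k0(self, cfg):
        """End at 0.580 s on a 60 Hz grid: the last frame at or before the
        end is at 34/60 = 0.5667 s, 13.3 ms before the end."""
        trial = ramp_trial(200.0 * 0.7 / 0.580)  # crosses the path at 0.580 s
        end = find_movement_end(trial, cfg)
        assert end.end_time == pytest.approx(0.580, abs=1e-9)
        assert end.last_sync_frame == 34
        mapping = frame_indices_from_end(trial, end)
        assert mapping[0] == 34
        assert mapping[-1] == 0
        np.testing.assert_array_equal(mapping, np.arange(34, -1, -1))

    def test_end_exactly_on_a_frame_makes_that_frame_k0(self, cfg):
        t_end = 30 / 60.0  # crossing exactly on frame 30
        trial = ramp_trial(200.0 * 0.7 / t_end)
        end = find_movement_end(trial, cfg)
        assert end.end_time == pytest.approx(t_end, abs=1e-9)
        assert end.last_sync_frame == 30
        assert (end.end_time - end.last_sync_frame / 60.0) < 1 / 60.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.35, max_value=0.69))
    def test_sync_offset_always_within_one_frame(self, cfg, t_end):
        """For any end time the k=0 frame lies 0-17 ms before the end."""
        trial = ramp_trial(200.0 * 0.7 / t_end)
        end = find_movement_end(trial, cfg)
        offset = end.end_time - trial.frame_times[end.last_sync_frame]
        assert 0.0 <= offset < 1 / 60.0 + 1e-9


class TestSavgolAcceleration:
    def test_exact_on_quadratic(self, cfg):
        times = np.arange(0, 1.0, cfg.sample_dt)
        positions = 250_000.0 * times**2
        for center in (0.1, 0.25, 0.5003, 0.9):
            acc = savgol_acceleration(positions, times, center, cfg)
            assert acc == pytest.approx(500_000.0, rel=1e-9)

    def test_zero_on_linear_ramp(self, cfg):
        times = np.arange(0, 1.0, cfg.sample_dt)
        positions = -123.0 + 456.0 * times
        acc = savgol_acceleration(positions, times, 0.5, cfg)
        assert acc == pytest.approx(0.0, abs=1e-6)

    def test_linearity_in_the_input(self, cfg):
        rng = np.random.default_rng(0)
        times = np.arange(0, 0.5, cfg.sample_dt)
        a, b = rng.normal(size=len(times)), rng.normal(size=len(times))
        f = lambda p: savgol_acceleration(p, times, 0.25, cfg)
        assert f(2.0 * a + 3.0 * b) == pytest.approx(2.0 * f(a) + 3.0 * f(b), rel=1e-9)

    def test_matches_brute_force_quadratic_fit(self, cfg):
        """On a noisy sinusoid the windowed estimate equals an independent
        normal-equations quadratic fit over the same samples."""
        rng = np.random.default_rng(1)
        times = np.arange(0, 1.0, cfg.sample_dt)
        positions = 50.0 * np.sin(2 * np.pi * 3.0 * times) + rng.normal(0, 0.5, len(times))
        for center in (0.2, 0.4711, 0.83):
            half = cfg.savgol_window / 2
            sel = (times >= center - half - 1e-9) & (times <= center + half + 1e-9)
            design = np.vander(times[sel] - center, 3, increasing=True)
            coef = np.linalg.solve(design.T @ design, design.T @ positions[sel])
            assert savgol_acceleration(positions, times, center, cfg) == pytest.approx(
                2.0 * coef[2], rel=1e-9
            )

    def test_equals_scipy_savgol_filter_on_grid(self, cfg):
        """Centred on a sample, the estimator is the classic 21-point
        Savitzky-Golay second-derivative output."""
        rng = np.random.default_rng(2)
        times = np.arange(0, 1.0, cfg.sample_dt)
        positions = np.cumsum(rng.normal(size=len(times)))
        ref = savgol_filter(
            positions,
            window_length=cfg.savgol_window_samples,
            polyorder=cfg.savgol_polyorder,
            deriv=2,
            delta=cfg.sample_dt,
        )
        for i in (30, 100, 250, 480):
            assert savgol_acceleration(positions, times, times[i], cfg) == pytest.approx(
                ref[i], rel=1e-9
            )

    def test_incomplete_window_yields_no_value(self, cfg):
        times = np.arange(0, 0.1, cfg.sample_dt)
        positions = np.ones_like(times)
        assert savgol_acceleration(positions, times, 0.005, cfg) is None  # too close to start
        assert savgol_acceleration(positions, times, 0.097, cfg) is None  # too close to end
        assert savgol_acceleration(positions, times, 0.05, cfg) is not None

    def test_batch_agrees_with_scalar(self, cfg):
        rng = np.random.default_rng(3)
        times = np.arange(0, 0.6, cfg.sample_dt)
        positions = rng.normal(size=len(times))
        centers = np.array([0.01, 0.1, 0.2345, 0.3, 0.595])
        batch = savgol_acceleration_batch(positions, times, centers, cfg)
        for c, b in zip(centers, batch):
            scalar = savgol_acceleration(positions, times, c, cfg)
            if scalar is None:
                assert np.isnan(b)
            else:
                assert b == pytest.approx(scalar, rel=1e-12)


class TestCalibration:
    def test_pure_translation_recovered(self):
        pts = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0], [100.0, 100.0]])
        tf = calibrate_affine(pts, pts + [5.0, -3.0])
        np.testing.assert_allclose(tf.linear, np.eye(2), atol=1e-10)
        np.testing.assert_allclose(tf.translation, [5.0, -3.0], atol=1e-10)

    def test_rotation_and_scale_recovered(self):
        pts = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0], [100.0, 100.0]])
        rot = 2.0 * np.array([[0.0, -1.0], [1.0, 0.0]])  # 90 deg + scale 2
        tf = calibrate_affine(pts, pts @ rot.T)
        np.testing.assert_allclose(tf.linear, rot, atol=1e-10)
        np.testing.assert_allclose(tf.apply(pts), pts @ rot.T, atol=1e-9)

    def test_noisy_fit_matches_normal_equations(self):
        rng = np.random.default_rng(4)
        measured = rng.uniform(-100, 100, (4, 2))
        screen = measured @ [[1.1, 0.05], [-0.03, 0.97]] + [4.0, -2.0] + rng.normal(0, 1.0, (4, 2))
        tf = calibrate_affine(measured, screen)
        design = np.column_stack([measured, np.ones(4)])
        sol = np.linalg.solve(design.T @ design, design.T @ screen)
        np.testing.assert_allclose(tf.linear, sol[:2].T, rtol=1e-9)
        np.testing.assert_allclose(tf.translation, sol[2], rtol=1e-9)
        residual = np.sum((tf.apply(measured) - screen) ** 2)
        oracle_residual = np.sum((design @ sol - screen) ** 2)
        assert residual == pytest.approx(oracle_residual, rel=1e-9)

    def test_collinear_points_rejected(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        with pytest.raises(ValueError, match="collinear"):
            calibrate_affine(pts, pts)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            calibrate_affine(np.zeros((2, 2)), np.zeros((2, 2)))
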