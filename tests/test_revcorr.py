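"""Step-triggered averaging: validity filter, splitting, curves, kernel matrix."""

import numpy as np
import pytest

from conftest import make_trial
from reachrc import (
    FeedbackModel,
    kernel_matrix,
    response_at_lag,
    response_curve,
    simulate_session,
    split_by_step_direction,
    valid_step_frames,
)
from reachrc.preprocess import annotate_session, savgol_acceleration
from reachrc.revcorr import _step_time


def crossing_trial(t_end, step_dirs=None, perturb_type="target", trial_id=0, rng=None):
    """Straight reach crossing the target path at exactly ``t_end``; lateral
    position is small noise so accelerations are well defined everywhere."""
    times = np.arange(0, 0.84, 0.002)
    y = 200.0 * times / t_end
    x = np.zeros_like(times)
    if rng is not None:
        x = rng.normal(0, 0.01, len(times))
    return make_trial(times, x, y, step_dirs=step_dirs, perturb_type=perturb_type, trial_id=trial_id)


class TestValidStepFrames:
    @pytest.mark.parametrize(
        "offset_ms,expected_valid",
        [(90.0, False), (100.0, False), (116.0, True)],
        ids=["90ms-too-late", "100ms-boundary-strict", "116ms-valid"],
    )
    def test_latency_floor_on_actual_times(self, cfg, offset_ms, expected_valid):
        """A step is analysable only if strictly more than 100 ms before the
        end of the movement."""
        # choose an end time so that some frame falls exactly offset_ms before it
        frame = 20
        t_end = frame / 60.0 + offset_ms / 1000.0
        trial = crossing_trial(t_end)
        annotate_session([trial], cfg)
        end = trial.movement_end
        assert end.end_time == pytest.approx(t_end, abs=1e-9)
        k = end.last_sync_frame - frame
        valid = valid_step_frames(trial, cfg)
        assert (k in valid) == expected_valid

    def test_validity_decided_on_times_not_k(self, cfg, model):
        """k = 6 lies 100-117 ms before the end depending on the 0-17 ms
        synchronisation offset; its validity must follow the actual time."""
        rng = np.random.default_rng(0)
        n_checked = 0
        for seed in range(300):
            t_end = rng.uniform(0.45, 0.7)
            trial = crossing_trial(t_end)
            annotate_session([trial], cfg)
            end = trial.movement_end
            valid = valid_step_frames(trial, cfg)
            t_k6 = end.end_time - trial.frame_times[end.last_sync_frame - 6]
            assert (6 in valid) == (t_k6 > 0.100)
            n_checked += 1
        assert n_checked == 300


class TestSplit:
    def _session(self, cfg, dirs_at_k, k=10, t_end=0.58):
        trials = []
        for i, d in enumerate(dirs_at_k):
            trial = crossing_trial(t_end, trial_id=i)
            annotate_session([trial], cfg)
            frame = trial.movement_end.last_sync_frame - k
            trial.step_dirs[frame] = d
            trials.append(trial)
        return trials

    def test_partition_counts(self, cfg):
        dirs = [-1, -1, -1, 1, 1, 1, 1, -1, 1, -1]
        trials = self._session(cfg, dirs)
        left, right = split_by_step_direction(trials, 10, "target", cfg)
        assert len(left) == 5 and len(right) == 5
        assert {t.trial_id for t in left} == {0, 1, 2, 7, 9}

    def test_one_sided_split_gives_undefined_curve(self, cfg):
        trials = self._session(cfg, [1, 1, 1, 1])
        left, right = split_by_step_direction(trials, 10, "target", cfg)
        assert left == [] and len(right) == 4
        assert response_curve(trials, 10, "target", cfg) is None

    def test_trials_with_invalid_k_are_omitted(self, cfg):
        trials = self._session(cfg, [1, -1, 1, -1], t_end=0.58)
        short = crossing_trial(0.15, trial_id=99)  # movement too short to contain frame k=10
        annotate_session([short], cfg)
        left, right = split_by_step_direction(trials + [short], 10, "target", cfg)
        assert 99 not in {t.trial_id for t in left + right}

    def test_conditioning_leaves_other_frames_balanced(self, cfg):
        """Within the left group at frame k, directions at every other frame
        are balanced to within binomial sampling error."""
        rng = np.random.default_rng(7)
        trials = []
        for i in range(10_000):
            dirs = rng.integers(0, 2, 51) * 2 - 1
            trial = crossing_trial(0.58, step_dirs=dirs, trial_id=i)
            trial.movement_end = None
            trials.append(trial)
        annotate_session(trials, cfg)
        k = 10
        left, _right = split_by_step_direction(trials, k, "target", cfg)
        frame_k = left[0].movement_end.last_sync_frame - k
        dirs = np.vstack([t.step_dirs for t in left])
        assert np.all(dirs[:, frame_k] == -1)
        others = np.delete(np.arange(51), frame_k)
        means = dirs[:, others].mean(axis=0)
        se = 1.0 / np.sqrt(len(left))
        assert np.all(np.abs(means) < 4.5 * se)


class TestResponseCurve:
    def test_matches_brute_force_group_means(self, cfg, model):
        """On a small session the curve equals an explicit re-implementation
        that loops over trials, lags and groups, to machine precision."""
        trials = simulate_session(cfg, model, 16, seed=3)
        annotate_session(trials, cfg)
        for ptype in ("target", "cursor"):
            for k in (8, 12, 20):
                curve = response_curve(trials, k, ptype, cfg)
                if curve is None:
                    continue
                sign = 1.0 if ptype == "target" else -1.0
                for i, lag_ms in enumerate(curve.lags_ms[::25]):
                    lag_idx = i * 25
                    groups = {-1: [], 1: []}
                    for t in trials:
                        if t.perturb_type != ptype or t.movement_end is None or t.excluded:
                            continue
                        end = t.movement_end
                        if k > end.last_sync_frame:
                            continue
                        step_t = t.frame_times[end.last_sync_frame - k]
                        if end.end_time - step_t <= cfg.latency_floor:
                            continue
                        center = step_t + lag_ms / 1000.0
                        if center > end.end_time + 1e-9:
                            continue
                        acc = savgol_acceleration(t.x, t.times, center, cfg)
                        if acc is None:
                            continue
                        groups[int(t.step_dirs[end.last_sync_frame - k])].append(acc)
                    expected = (
                        sign * (np.mean(groups[1]) - np.mean(groups[-1]))
                        if groups[1] and groups[-1]
                        else None
                    )
                    got = curve.values[lag_idx] if lag_idx < len(curve.values) else None
                    if expected is None:
                        assert got is None or np.isnan(got)
                    else:
                        assert got == pytest.approx(expected, rel=1e-9, abs=1e-9)

    def test_zero_gain_curves_are_null(self, cfg):
        """With an open-loop simulator every kernel value stays within a few
        standard errors of zero (nothing to recover). Small-n smoke version."""
        from reachrc import zero_gain

        model = FeedbackModel(target_gain=zero_gain(), cursor_weight=0.0)
        trials = simulate_session(cfg, model, 60, seed=11)
        annotate_session(trials, cfg)
        curves = kernel_matrix(trials, cfg)
        assert curves
        z_max = 0.0
        for c in curves.values():
            # SEs are only meaningful with enough trials per direction group
            ok = (c.n_left_by_lag >= 10) & (c.n_right_by_lag >= 10) & (c.se > 0)
            if np.any(ok):
                z_max = max(z_max, np.nanmax(np.abs(c.values[ok] / c.se[ok])))
        assert z_max < 6.0  # loose: just catches gross systematic leakage

    def test_curve_never_extends_past_movement_end(self, cfg, model, small_session):
        curves = kernel_matrix(list(small_session), cfg)
        for (ptype, k), curve in curves.items():
            # the latest lag with any contribution must fit inside some
            # contributing trial's movement
            max_possible = max(
                t.movement_end.end_time
                - t.frame_times[t.movement_end.last_sync_frame - k]
                for t in small_session
                if t.perturb_type == ptype
                and not t.excluded
                and t.movement_end is not None
                and k <= t.movement_end.last_sync_frame
            )
            assert curve.lags_ms[-1] / 1000.0 <= max_possible + 1e-9

    def test_order_invariance(self, cfg, model):
        trials = simulate_session(cfg, model, 12, seed=5)
        annotate_session(trials, cfg)
        a = response_curve(trials, 10, "target", cfg)
        b = response_curve(trials[::-1], 10, "target", cfg)
        assert a is not None and b is not None
        np.testing.assert_array_equal(a.values, b.values)

    def test_single_trial_session_has_no_curves(self, cfg, model):
        trial = simulate_session(cfg, model, 2, seed=1)[0]
        annotate_session([trial], cfg)
        assert kernel_matrix([trial], cfg) == {}

    def test_compensatory_sign_positive_for_both_channels(self, cfg):
        """A known strongly-responding simulation yields positive kernel peaks
        for target steps and for cursor steps (despite the raw cursor
        response being opposite in direction)."""
        model = FeedbackModel(cursor_weight=1.0, motor_noise_sd=200.0, duration_sd=0.02)
        trials = simulate_session(cfg, model, 300, seed=21)
        annotate_session(trials, cfg)
        curves = kernel_matrix(trials, cfg)
        for ptype in ("target", "cursor"):
            peak_zone = []
            for k in (11, 13, 15, 17):
                curve = curves.get((ptype, k))
                if curve is None:
                    continue
                v = response_at_lag(curve, 200.0)
                if v is not None:
                    peak_zone.append(v)
            assert peak_zone, f"no curves for {ptype}"
            assert np.mean(peak_zone) > 0


def test_step_time_helper_consistency(cfg, model, small_session):
    for t in small_session:
        if t.movement_end is None:
            continue
        assert _step_time(t, 0) == pytest.approx(
            t.frame_times[t.movement_end.last_sync_frame]
        )
        assert _step_time(t, t.movement_end.last_sync_frame + 1) is None
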