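"""Reverse correlation: step-triggered averaging of lateral acceleration.

The perturbation at each display frame is an independent fair coin, so the
response to the step at one selected frame can be isolated by splitting
trials on that step's direction and differencing the group-mean lateral
accelerations: all other steps are equally often left and right in both
groups and average out.  Frames are selected backwards from the movement end
(frame-from-end index k), and only steps more than the visuomotor latency
floor (100 ms by default) before the end are analysed — later steps cannot
have evoked any response.

The difference is signed so that compensation is positive for both channels:
acceleration in the direction of a target step, or opposite to a cursor step,
counts as positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SessionConfig
from .preprocess import savgol_acceleration_batch
from .simulate import Trial

__all__ = [
    "ResponseCurve",
    "valid_step_frames",
    "split_by_step_direction",
    "response_curve",
    "kernel_matrix",
    "average_kernels",
    "kernels_to_frame",
]


@dataclass(frozen=True)
class ResponseCurve:
    """Acceleration-difference trace for one step time and perturbation type.

    ``values[i]`` is the compensatory-positive difference between the mean
    lateral accelerations of the right- and left-step groups at
    ``lags_ms[i]`` milliseconds after the selected step.  ``se`` is the
    Monte-Carlo standard error of that difference (from the within-group
    sample variances).  ``n_left_by_lag``/``n_right_by_lag`` track how many
    trials still contribute at each lag: trials drop out of late lags when
    the lag would reach past their own end of movement or past their sampled
    record (the curve is truncated, never padded).
    """

    perturb_type: str
    k: int  # frame-from-end index of the selected step
    step_time_before_end_ms: float  # mean over contributing trials
    lags_ms: np.ndarray
    values: np.ndarray  # mm/s^2, compensatory-positive
    se: np.ndarray  # mm/s^2
    n_left: int
    n_right: int
    n_left_by_lag: np.ndarray
    n_right_by_lag: np.ndarray


def valid_step_frames(trial: Trial, cfg: SessionConfig) -> np.ndarray:
    """Frame-from-end indices k whose step is strictly more than the latency
    floor before the end of the movement, evaluated on actual times.

    The synchronisation offset (the end falls 0 to one frame interval after
    the last synchronised frame) shifts frame times relative to the end, so
    validity is decided on times, not on k itself.
    """
    end = trial.movement_end
    if end is None:
        raise ValueError(f"trial {trial.trial_id}: movement end not annotated")
    frame_idx = np.arange(end.last_sync_frame, -1, -1)
    time_before_end = end.end_time - trial.frame_times[frame_idx]
    # strictly more than the floor; the epsilon keeps an exactly-at-floor
    # step invalid in the face of float rounding
    return np.nonzero(time_before_end > cfg.latency_floor + 1e-9)[0]


def _step_time(trial: Trial, k: int) -> float | None:
    """Absolute time of the step k frames before the last synchronised frame."""
    end = trial.movement_end
    if end is None or k < 0 or k > end.last_sync_frame:
        return None
    return float(trial.frame_times[end.last_sync_frame - k])


def split_by_step_direction(
    trials: list[Trial], k: int, perturb_type: str, cfg: SessionConfig
) -> tuple[list[Trial], list[Trial]]:
    """Partition the analysable trials of one perturbation type by the
    direction of the step at frame-from-end index k.

    Trials for which k is not a valid step frame (too close to the end, or
    before target appearance) are omitted from both groups.
    """
    left, right = [], []
    for trial in trials:
        if trial.perturb_type != perturb_type or trial.excluded or trial.movement_end is None:
            continue
        step_time = _step_time(trial, k)
        # same criterion as valid_step_frames: strictly more than the latency
        # floor before the end, on actual times
        if step_time is None or trial.movement_end.end_time - step_time <= cfg.latency_floor + 1e-9:
            continue
        direction = trial.step_dirs[trial.movement_end.last_sync_frame - k]
        (right if direction > 0 else left).append(trial)
    return left, right


def _lag_grid_ms(cfg: SessionConfig) -> np.ndarray:
    n_lags = int(np.floor(cfg.response_window / cfg.sample_dt + 1e-9)) + 1
    return np.arange(n_lags) * cfg.sample_dt * 1000.0


def _trial_lag_accelerations(trial: Trial, k: int, cfg: SessionConfig) -> np.ndarray:
    """Lateral acceleration of one trial at step-time-plus-lag for all lags.

    NaN where the lag reaches beyond the trial's end of movement or where no
    full estimation window exists.  Cached per trial: the per-frame
    acceleration matrix is reused across every k that selects the same trial.
    """
    cache_key = ("lag_accel", id(cfg))
    per_frame = trial._cache.get(cache_key)
    end = trial.movement_end
    if per_frame is None:
        lags = _lag_grid_ms(cfg) / 1000.0
        frame_idx = np.arange(end.last_sync_frame + 1)
        centers = trial.frame_times[frame_idx][:, None] + lags[None, :]
        accel = savgol_acceleration_batch(trial.x, trial.times, centers.ravel(), cfg)
        accel = accel.reshape(centers.shape)
        accel[centers > end.end_time + 1e-9] = np.nan  # never beyond the movement end
        per_frame = accel
        trial._cache[cache_key] = per_frame
    return per_frame[end.last_sync_frame - k]


def response_curve(
    trials: list[Trial], k: int, perturb_type: str, cfg: SessionConfig
) -> ResponseCurve | None:
    """The difference-of-conditional-means acceleration trace for one step.

    For every trial in which frame k (from the end) is a valid step, the
    lateral acceleration is estimated at the step time plus each lag on the
    sample-interval grid from 0 up to the response window.  The curve value
    is ``sign * (mean over right-step trials - mean over left-step trials)``
    with ``sign`` +1 for target and -1 for cursor perturbations.  Group means
    are unweighted; a trial drops out of any lag its own record cannot
    support.  Returns None when either direction group is empty (the curve is
    undefined, not zero).
    """
    left, right = split_by_step_direction(trials, k, perturb_type, cfg)
    if not left or not right:
        return None
    # canonical summation order: permuting the input trials leaves the curve
    # bit-identical
    left = sorted(left, key=lambda t: t.trial_id)
    right = sorted(right, key=lambda t: t.trial_id)

    lags_ms = _lag_grid_ms(cfg)
    acc_left = np.vstack([_trial_lag_accelerations(t, k, cfg) for t in left])
    acc_right = np.vstack([_trial_lag_accelerations(t, k, cfg) for t in right])

    n_l = np.sum(~np.isnan(acc_left), axis=0)
    n_r = np.sum(~np.isnan(acc_right), axis=0)
    defined = (n_l > 0) & (n_r > 0)
    if not np.any(defined):
        return None
    # truncate the tail where trials run out; lags undefined for other reasons
    # (e.g. no full estimation window around the very first frames) stay NaN
    n_keep = int(np.nonzero(defined)[0][-1]) + 1
    sl = slice(0, n_keep)

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_l = np.nansum(acc_left[:, sl], axis=0) / n_l[sl]
        mean_r = np.nansum(acc_right[:, sl], axis=0) / n_r[sl]
        var_l = _nanvar_ddof1(acc_left[:, sl])
        var_r = _nanvar_ddof1(acc_right[:, sl])
        se = np.sqrt(var_l / n_l[sl] + var_r / n_r[sl])
    sign = 1.0 if perturb_type == "target" else -1.0
    values = sign * (mean_r - mean_l)
    values[~defined[sl]] = np.nan
    se[~defined[sl]] = np.nan

    step_times_before_end = [
        t.movement_end.end_time - _step_time(t, k) for t in left + right
    ]
    return ResponseCurve(
        perturb_type=perturb_type,
        k=k,
        step_time_before_end_ms=float(np.mean(step_times_before_end) * 1000.0),
        lags_ms=lags_ms[sl],
        values=values,
        se=se,
        n_left=len(left),
        n_right=len(right),
        n_left_by_lag=n_l[sl],
        n_right_by_lag=n_r[sl],
    )


def _nanvar_ddof1(arr: np.ndarray) -> np.ndarray:
    """Column-wise sample variance ignoring NaN, 0 where fewer than 2 values."""
    n = np.sum(~np.isnan(arr), axis=0)
    out = np.zeros(arr.shape[1])
    ok = n >= 2
    if np.any(ok):
        out[ok] = np.nanvar(arr[:, ok], axis=0, ddof=1)
    return out


def kernel_matrix(
    trials: list[Trial], cfg: SessionConfig
) -> dict[tuple[str, int], ResponseCurve]:
    """All defined response curves of a session, both types, every valid k.

    The same trials are reused across every selected step frame; the result
    maps (perturb_type, k) to the curve, omitting undefined combinations.
    """
    curves: dict[tuple[str, int], ResponseCurve] = {}
    analysable = [t for t in trials if not t.excluded and t.movement_end is not None]
    if not analysable:
        return curves
    for ptype in ("target", "cursor"):
        subset = [t for t in analysable if t.perturb_type == ptype]
        if not subset:
            continue
        k_max = max(int(valid_step_frames(t, cfg).max(initial=-1)) for t in subset)
        for k in range(k_max + 1):
            curve = response_curve(subset, k, ptype, cfg)
            if curve is not None:
                curves[(ptype, k)] = curve
    return curves


def average_kernels(
    kernel_dicts: list[dict[tuple[str, int], ResponseCurve]]
) -> dict[tuple[str, int], ResponseCurve]:
    """Unweighted mean of response curves across sessions.

    For each (perturb_type, k) present in any session, curves are averaged
    lag-wise over the sessions where they are defined; the combined standard
    error treats sessions as independent.  A single session passes through
    unchanged.
    """
    if not kernel_dicts:
        return {}
    if len(kernel_dicts) == 1:
        return dict(kernel_dicts[0])
    keys = sorted({key for d in kernel_dicts for key in d}, key=lambda kk: (kk[0], kk[1]))
    out: dict[tuple[str, int], ResponseCurve] = {}
    for key in keys:
        curves = [d[key] for d in kernel_dicts if key in d]
        n_lags = max(len(c.values) for c in curves)

        def _pad(arr, fill=np.nan):
            padded = np.full(n_lags, fill)
            padded[: len(arr)] = arr
            return padded

        vals = np.vstack([_pad(c.values) for c in curves])
        ses = np.vstack([_pad(c.se) for c in curves])
        n_sessions = np.sum(~np.isnan(vals), axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_vals = np.where(
                n_sessions > 0, np.nansum(vals, axis=0) / np.maximum(n_sessions, 1), np.nan
            )
            comb_se = np.where(
                n_sessions > 0,
                np.sqrt(np.nansum(ses**2, axis=0)) / np.maximum(n_sessions, 1),
                np.nan,
            )
        lags = max((c.lags_ms for c in curves), key=len)
        out[key] = ResponseCurve(
            perturb_type=key[0],
            k=key[1],
            step_time_before_end_ms=float(np.mean([c.step_time_before_end_ms for c in curves])),
            lags_ms=lags,
            values=mean_vals,
            se=comb_se,
            n_left=int(np.sum([c.n_left for c in curves])),
            n_right=int(np.sum([c.n_right for c in curves])),
            n_left_by_lag=np.sum(
                np.vstack([_pad(c.n_left_by_lag, 0) for c in curves]), axis=0
            ).astype(int),
            n_right_by_lag=np.sum(
                np.vstack([_pad(c.n_right_by_lag, 0) for c in curves]), axis=0
            ).astype(int),
        )
    return out


def kernels_to_frame(curves: dict[tuple[str, int], ResponseCurve]):
    """Tidy long-format table of all curves (one row per perturbation type,
    step frame and lag)."""
    import pandas as pd

    rows = []
    for (ptype, k), curve in sorted(curves.items()):
        for i, lag in enumerate(curve.lags_ms):
            rows.append(
                {
                    "perturb_type": ptype,
                    "k": k,
                    "step_time_before_end_ms": curve.step_time_before_end_ms,
                    "lag_ms": lag,
                    "value": curve.values[i],
                    "se": curve.se[i],
                    "n_left": curve.n_left_by_lag[i],
                    "n_right": curve.n_right_by_lag[i],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "perturb_type",
            "k",
            "step_time_before_end_ms",
            "lag_ms",
            "value",
            "se",
            "n_left",
            "n_right",
        ],
    )
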