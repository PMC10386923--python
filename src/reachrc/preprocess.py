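"""Trial annotation and kinematic estimation.

The analysis needs each trial anchored to an *end of movement* that reflects
the time still available for corrections: the interpolated moment the finger
crosses the target's path, or — if it stops short by less than
``near_path_threshold`` — the moment of maximal distance from the start.
Trials whose finger never comes that close to the path are excluded
explicitly.  Display frames are then indexed backwards from the last frame at
or before the end, so that trials with different durations line up on the
frame grid (the last synchronised frame lies 0 to one frame interval before
the end).

Lateral acceleration is estimated by fitting a second-order polynomial to the
finger positions inside a short centred window (simultaneous smoothing and
double differentiation; on the regular sample grid this is exactly the
Savitzky-Golay second-derivative filter).  Incomplete windows near the edges
of the record yield no value rather than a padded estimate, because padding
would bias accelerations exactly where responses matter most.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SessionConfig
from .simulate import Trial

__all__ = [
    "MovementEnd",
    "CalibrationTransform",
    "find_movement_end",
    "annotate_session",
    "frame_indices_from_end",
    "savgol_acceleration",
    "savgol_acceleration_batch",
    "calibrate_affine",
]


@dataclass(frozen=True)
class MovementEnd:
    """End-of-movement annotation for one trial.

    ``end_time`` is in seconds from target appearance; ``end_kind`` records
    whether the finger crossed the target's path (``crossed_path``) or merely
    came close enough and the time of maximal distance from the start was
    used (``max_distance``); ``last_sync_frame`` is the index of the last
    display frame at or before ``end_time``.
    """

    end_time: float
    end_kind: str  # "crossed_path" | "max_distance"
    last_sync_frame: int


def find_movement_end(trial: Trial, cfg: SessionConfig) -> MovementEnd | None:
    """Annotate (and return) the trial's end of movement, or None if excluded.

    The first crossing of the target-path y by the finger defines the end,
    linearly interpolated between the two straddling samples.  If the finger
    never reaches the path but its closest approach is within
    ``cfg.near_path_threshold``, the time of its maximal Euclidean distance
    from the starting point is used instead.  Otherwise the trial is marked
    ``excluded`` and None is returned.
    """
    if len(trial.times) < 2:
        raise ValueError(f"trial {trial.trial_id}: need at least 2 finger samples")

    y = trial.y
    path_y = float(np.interp(trial.times[0], trial.frame_times, trial.target_y))

    reached = np.nonzero(y >= path_y)[0]
    if len(reached) > 0 and reached[0] > 0:
        i = int(reached[0])
        y0, y1 = y[i - 1], y[i]
        t0, t1 = trial.times[i - 1], trial.times[i]
        end_time = float(t0 + (path_y - y0) / (y1 - y0) * (t1 - t0)) if y1 > y0 else float(t1)
    elif len(reached) > 0:
        end_time = float(trial.times[0])  # started on/over the path: degenerate but annotated
    else:
        closest = float(np.min(path_y - y))
        if closest >= cfg.near_path_threshold:
            trial.excluded = True
            trial.movement_end = None
            return None
        start = np.array([trial.x[0], trial.y[0]])
        dist = np.hypot(trial.x - start[0], trial.y - start[1])
        end_time = float(trial.times[int(np.argmax(dist))])

    frame_dt = 1.0 / cfg.frame_rate
    last_sync = int(np.floor(end_time / frame_dt + 1e-9))
    last_sync = min(last_sync, len(trial.frame_times) - 1)
    end = MovementEnd(
        end_time=end_time,
        end_kind="crossed_path" if len(reached) > 0 else "max_distance",
        last_sync_frame=last_sync,
    )
    trial.movement_end = end
    trial.excluded = False
    return end


def annotate_session(trials: list[Trial], cfg: SessionConfig) -> tuple[list[Trial], list[Trial]]:
    """Annotate every trial; return (kept, excluded) lists.  No silent drops."""
    kept, excluded = [], []
    for trial in trials:
        if find_movement_end(trial, cfg) is None:
            excluded.append(trial)
        else:
            kept.append(trial)
    return kept, excluded


def frame_indices_from_end(trial: Trial, end: MovementEnd | None = None) -> np.ndarray:
    """Frame indices ordered by frame-from-end index k.

    Element k of the returned array is the display-frame index that lies k
    frames before the last synchronised frame (k = 0 is ``last_sync_frame``
    itself, 0 to one frame interval before the end of the movement).  Every
    frame from target appearance up to the last synchronised frame is indexed.
    """
    if end is None:
        end = trial.movement_end
    if end is None:
        raise ValueError(f"trial {trial.trial_id}: movement end not annotated")
    if end.end_time < trial.frame_times[0]:
        raise ValueError(
            f"trial {trial.trial_id}: end time {end.end_time:.4f} s precedes the first frame"
        )
    return np.arange(end.last_sync_frame, -1, -1)


# ---------------------------------------------------------------------------
# local-polynomial acceleration


def savgol_acceleration(
    positions: np.ndarray,
    times: np.ndarray,
    center_time: float,
    cfg: SessionConfig,
) -> float | None:
    """Second derivative of a local least-squares polynomial fit.

    Fits a polynomial of order ``cfg.savgol_polyorder`` to all samples within
    ``cfg.savgol_window_ms`` centred on ``center_time`` and returns twice the
    quadratic coefficient (mm/s^2).  On the regular sample grid with the
    window centred on a sample this reproduces the classic Savitzky-Golay
    second-derivative output.  Returns None when the window is not fully
    contained in the sampled record (the time point is dropped, never padded).
    """
    out = savgol_acceleration_batch(positions, times, np.array([center_time]), cfg)
    return None if np.isnan(out[0]) else float(out[0])


def savgol_acceleration_batch(
    positions: np.ndarray,
    times: np.ndarray,
    center_times: np.ndarray,
    cfg: SessionConfig,
) -> np.ndarray:
    """Vectorised :func:`savgol_acceleration` over many centre times.

    Returns an array aligned with ``center_times``; entries whose window is
    incomplete are NaN.  Assumes ``times`` is a uniform grid (the native
    motion-capture sampling), which lets all windows share one gather.
    """
    times = np.asarray(times, dtype=float)
    positions = np.asarray(positions, dtype=float)
    centers = np.atleast_1d(np.asarray(center_times, dtype=float))
    if len(times) != len(positions):
        raise ValueError("positions and times must have equal length")
    half = cfg.savgol_window / 2.0
    out = np.full(len(centers), np.nan)
    if len(times) == 0:
        return out

    eps = 1e-9
    valid = (centers - half >= times[0] - eps) & (centers + half <= times[-1] + eps)
    if not np.any(valid):
        return out
    cv = centers[valid]

    # gather the samples inside [c - half, c + half] for every centre at once
    first = np.searchsorted(times, cv - half - eps, side="left")
    last = np.searchsorted(times, cv + half + eps, side="right")
    counts = last - first
    enough = counts >= cfg.savgol_polyorder + 1
    if not np.any(enough):
        return out
    valid[valid] = enough
    cv, first, last, counts = cv[enough], first[enough], last[enough], counts[enough]
    n_win = int(np.max(counts))
    idx = first[:, None] + np.arange(n_win)[None, :]
    in_window = idx < last[:, None]
    idx = np.minimum(idx, len(times) - 1)

    tau = times[idx] - cv[:, None]
    w = in_window.astype(float)
    order = cfg.savgol_polyorder
    # weighted (0/1) polynomial least squares via batched normal equations
    powers = np.empty(tau.shape + (order + 1,))
    powers[..., 0] = 1.0
    for p in range(1, order + 1):
        powers[..., p] = powers[..., p - 1] * tau
    a_mat = np.einsum("cw,cwi,cwj->cij", w, powers, powers)
    b_vec = np.einsum("cw,cwi,cw->ci", w, powers, positions[idx])
    coef = np.linalg.solve(a_mat, b_vec[..., None])[..., 0]
    if order >= 2:
        out[valid] = 2.0 * coef[:, 2]
    else:
        out[valid] = 0.0
    return out


# ---------------------------------------------------------------------------
# spatial calibration


@dataclass(frozen=True)
class CalibrationTransform:
    """Least-squares 2-D affine map from measured to display coordinates."""

    linear: np.ndarray  # (2, 2)
    translation: np.ndarray  # (2,)

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return points @ self.linear.T + self.translation


def calibrate_affine(measured_points: np.ndarray, screen_points: np.ndarray) -> CalibrationTransform:
    """Fit the affine map taking measured marker positions to screen positions.

    Requires at least three non-collinear correspondences; with four (the
    usual calibration routine: the participant places the finger on four
    known targets) the map is the unique least-squares affine transform,
    which also absorbs the constant offset between the marker on the
    fingernail and the point the participant aligns with the targets.
    """
    measured = np.atleast_2d(np.asarray(measured_points, dtype=float))
    screen = np.atleast_2d(np.asarray(screen_points, dtype=float))
    if measured.shape != screen.shape or measured.shape[1] != 2:
        raise ValueError("measured and screen points must be matching (n, 2) arrays")
    n = measured.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 point correspondences, got {n}")
    design = np.column_stack([measured, np.ones(n)])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("calibration points are collinear; the affine map is underdetermined")
    sol, *_ = np.linalg.lstsq(design, screen, rcond=None)
    return CalibrationTransform(linear=sol[:2].T.copy(), translation=sol[2].copy())
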