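"""Synthetic interception trials with random-walk visual perturbations.

Generates seeded sessions in which a participant-like controller reaches from
a start point through the path of a target that moves rightward at constant
speed.  On every display frame a fixed-amplitude lateral step, randomly left
or right, is added either to the target position or to the cursor offset (the
displacement between the displayed cursor and the true finger position).  The
simulated finger responds to each step after a visuomotor latency with a
smooth, compensatory lateral acceleration whose gain grows as the remaining
movement time shrinks.

The generative law is deliberately simple and linear in the steps, so that
the reverse-correlation analysis downstream has a closed-form ground truth:
conditioning on the direction of the step at one frame should recover
``2 * amplitude * gain * h(lag - latency)`` where ``h`` is the acceleration
impulse response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng
from scipy.optimize import brentq
from scipy.special import gammaln

from .config import SessionConfig

__all__ = [
    "StepSequence",
    "FeedbackModel",
    "Trial",
    "generate_step_sequence",
    "simulate_trial",
    "detect_hit",
    "simulate_session",
    "zero_gain",
    "constant_gain",
    "inverse_time_gain",
    "gamma_impulse_response",
    "minimum_jerk",
]


# ---------------------------------------------------------------------------
# step sequences


@dataclass(frozen=True)
class StepSequence:
    """One random-walk perturbation sequence: one +/-1 step per display frame."""

    directions: np.ndarray  # int, +/-1 per frame
    amplitude: float  # mm
    frame_times: np.ndarray  # s, strictly increasing

    @property
    def cumulative_offset(self) -> np.ndarray:
        """Accumulated lateral offset after each frame's step, mm."""
        return self.amplitude * np.cumsum(self.directions)

    def __len__(self) -> int:
        return len(self.directions)


def generate_step_sequence(
    n_frames: int,
    amplitude: float,
    rng: Generator | int | None = None,
    frame_rate: float = 60.0,
) -> StepSequence:
    """Draw i.i.d. equiprobable +/-1 steps, one per frame, accumulated as a walk.

    Parameters
    ----------
    n_frames:
        Number of display frames (>= 1); one step is applied at each.
    amplitude:
        Step size in mm (>= 0).
    rng:
        ``numpy`` random generator or seed; a fixed seed reproduces the
        sequence exactly.
    frame_rate:
        Display rate in Hz, used only to lay out ``frame_times``.
    """
    if n_frames < 1:
        raise ValueError(f"n_frames must be >= 1, got {n_frames}")
    if amplitude < 0:
        raise ValueError(f"amplitude must be >= 0, got {amplitude}")
    rng = default_rng(rng)
    directions = rng.integers(0, 2, size=n_frames) * 2 - 1
    frame_times = np.arange(n_frames) / frame_rate
    return StepSequence(directions=directions, amplitude=float(amplitude), frame_times=frame_times)


# ---------------------------------------------------------------------------
# feedback model


def zero_gain() -> Callable[[np.ndarray], np.ndarray]:
    """Gain schedule that ignores the jitter entirely (open-loop control)."""

    def gain(t_remaining):
        return np.zeros_like(np.asarray(t_remaining, dtype=float))

    gain.spec = {"kind": "zero"}
    return gain


def constant_gain(value: float) -> Callable[[np.ndarray], np.ndarray]:
    """Time-invariant feedback gain (per-step velocity correction fraction)."""
    if value < 0:
        raise ValueError("gain must be non-negative")

    def gain(t_remaining):
        return np.full_like(np.asarray(t_remaining, dtype=float), float(value))

    gain.spec = {"kind": "constant", "value": float(value)}
    return gain


def inverse_time_gain(scale: float = 0.7, floor: float = 0.1) -> Callable[[np.ndarray], np.ndarray]:
    """Gain inversely proportional to the remaining movement time.

    ``gain(t) = scale / max(t, floor)`` (units 1/s): a step of ``A`` mm evokes
    a corrective velocity change of ``scale * A / t_remaining`` mm/s, i.e. the
    fraction ``scale`` of what full compensation within the remaining time
    would require.  ``floor`` (s) keeps the gain finite near and past the end
    of the movement.
    """
    if scale < 0:
        raise ValueError("scale must be non-negative")
    if floor <= 0:
        raise ValueError("floor must be positive")

    def gain(t_remaining):
        t = np.asarray(t_remaining, dtype=float)
        return scale / np.maximum(t, floor)

    gain.spec = {"kind": "inverse_time", "scale": float(scale), "floor": float(floor)}
    return gain


def gamma_impulse_response(t: np.ndarray, peak: float, sd: float) -> np.ndarray:
    """Gamma-density acceleration impulse response, unit integral (1/s).

    Parameterised by the mode ``peak`` (s) and standard deviation ``sd`` (s);
    zero for t <= 0.
    """
    theta = (-peak + math.sqrt(peak * peak + 4.0 * sd * sd)) / 2.0
    k = 1.0 + peak / theta
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = np.exp((k - 1.0) * np.log(tp) - tp / theta - gammaln(k) - k * math.log(theta))
    return out


@dataclass
class FeedbackModel:
    """Generative law of the simulated controller.

    None of these parameters is an empirical estimate: they are invented
    simulator settings, chosen to produce sessions that look like plausible
    fast interception data and to give the analysis a known ground truth.

    Parameters
    ----------
    latency_ms:
        Delay between a perturbation step and the onset of the corrective
        acceleration, ms.
    irf_peak_ms, irf_duration_ms:
        Shape of the gamma acceleration impulse response: time-to-peak after
        response onset and overall duration (the gamma's standard deviation is
        ``irf_duration_ms / 4``), ms.
    target_gain:
        Maps remaining movement time (s) to the feedback gain (1/s) applied
        to target steps; see :func:`inverse_time_gain`.
    cursor_weight:
        Relative strength of responses to cursor-offset steps, in [0, 1].
        Cursor responses use the same gain schedule and impulse response but
        are sign-flipped (moving the finger opposite to the cursor step is
        what reduces the induced error).
    cursor_gain:
        Optional independent gain schedule for cursor steps (1/s).  None
        (the default) means ``cursor_weight * target_gain``, i.e. both
        channels' vigour grows identically during the movement; supplying a
        schedule that rises faster toward the end simulates the alternative
        hypothesis of late over-reliance on visual hand information.
    motor_noise_sd:
        SD of white acceleration noise per motion-capture sample, mm/s^2,
        added independently on both axes.
    nominal_duration:
        Mean planned time from target appearance to crossing the target's
        path, s.
    duration_sd:
        Trial-to-trial SD of the planned crossing time, s.
    path_overshoot:
        How far beyond the target's path the baseline reach aims, mm, so the
        finger crosses the path at speed instead of stopping on it.
    """

    latency_ms: float = 110.0
    irf_peak_ms: float = 100.0
    irf_duration_ms: float = 200.0
    target_gain: Callable[[np.ndarray], np.ndarray] = field(default_factory=inverse_time_gain)
    cursor_weight: float = 0.6
    cursor_gain: Callable[[np.ndarray], np.ndarray] | None = None
    motor_noise_sd: float = 950.0
    nominal_duration: float = 0.58
    duration_sd: float = 0.045
    path_overshoot: float = 35.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cursor_weight <= 1.0:
            raise ValueError(f"cursor_weight must be in [0, 1], got {self.cursor_weight}")
        if self.latency_ms <= 0:
            raise ValueError("latency_ms must be positive")
        if self.irf_peak_ms <= 0 or self.irf_duration_ms <= 0:
            raise ValueError("impulse-response times must be positive")
        if self.nominal_duration <= 0:
            raise ValueError("nominal_duration must be positive")
        if self.motor_noise_sd < 0 or self.duration_sd < 0:
            raise ValueError("noise magnitudes must be non-negative")
        if self.path_overshoot <= 0:
            raise ValueError("path_overshoot must be positive")

    @property
    def latency(self) -> float:
        return self.latency_ms / 1000.0

    def impulse_response(self, t: np.ndarray) -> np.ndarray:
        return gamma_impulse_response(
            t, peak=self.irf_peak_ms / 1000.0, sd=self.irf_duration_ms / 4000.0
        )


# ---------------------------------------------------------------------------
# trials


@dataclass
class Trial:
    """One interception attempt: finger samples plus per-frame display records."""

    trial_id: int
    perturb_type: str  # "target" or "cursor"
    times: np.ndarray  # s, finger samples
    x: np.ndarray  # mm, lateral finger position
    y: np.ndarray  # mm, forward finger position
    frame_times: np.ndarray  # s
    step_dirs: np.ndarray  # +/-1 per frame
    jitter: np.ndarray  # mm, cumulative random-walk offset per frame
    target_x: np.ndarray  # mm, displayed target centre per frame
    target_y: np.ndarray  # mm
    cursor_offset: np.ndarray  # mm, lateral cursor-minus-finger offset per frame
    hit: bool | None = None
    hit_position: tuple[float, float] | None = None
    session_id: str = "s0"
    movement_end: Any = None  # filled by preprocessing; None = not yet annotated
    excluded: bool = False
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.perturb_type not in ("target", "cursor"):
            raise ValueError(f"perturb_type must be 'target' or 'cursor', got {self.perturb_type!r}")
        if len(self.times) != len(self.x) or len(self.times) != len(self.y):
            raise ValueError("finger sample arrays must have equal length")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError(f"trial {self.trial_id}: finger sample times must be strictly increasing")
        if len(self.frame_times) >= 2 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError(f"trial {self.trial_id}: frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frame_times)


def minimum_jerk(u: np.ndarray) -> np.ndarray:
    """Normalised minimum-jerk position profile on u in [0, 1]."""
    u = np.clip(np.asarray(u, dtype=float), 0.0, 1.0)
    return u**3 * (10.0 - 15.0 * u + 6.0 * u * u)


_crossing_fraction_cache: dict[float, float] = {}


def _crossing_fraction(ratio: float) -> float:
    """Movement-phase u at which the minimum-jerk profile reaches ``ratio`` of its extent."""
    u = _crossing_fraction_cache.get(ratio)
    if u is None:
        u = brentq(lambda v: minimum_jerk(v) - ratio, 0.0, 1.0, xtol=1e-12)
        _crossing_fraction_cache[ratio] = u
    return u


def _positions_from_acceleration(a: np.ndarray, dt: float) -> np.ndarray:
    """Doubly integrate an acceleration series (zero initial state)."""
    v = np.cumsum(a) * dt
    return np.cumsum(v) * dt


def simulate_trial(
    cfg: SessionConfig,
    model: FeedbackModel,
    perturb_type: str,
    rng: Generator | int | None = None,
    trial_id: int = 0,
    session_id: str = "s0",
) -> Trial:
    """Simulate one trial: baseline reach, corrective responses, noise, hit test.

    The baseline is a minimum-jerk reach from the start point to a point
    ``path_overshoot`` mm beyond the target's path, scaled so the finger
    crosses the path at the planned crossing time exactly where the
    unperturbed target will then be.  Each frame's jitter step adds, after
    ``model.latency``, a lateral acceleration ``s * A * gain(t_remaining) *
    h(t - t_step - latency)`` with ``s`` the step direction for target steps
    and ``-cursor_weight`` times the step direction for cursor steps, so the
    net response is compensatory in both cases.
    """
    if perturb_type not in ("target", "cursor"):
        raise ValueError(f"perturb_type must be 'target' or 'cursor', got {perturb_type!r}")
    if model.nominal_duration > cfg.max_trial_duration:
        raise ValueError(
            f"nominal_duration ({model.nominal_duration} s) exceeds "
            f"max_trial_duration ({cfg.max_trial_duration} s)"
        )
    rng = default_rng(rng)

    # planned crossing time and full (follow-through) movement duration
    t_cross = model.nominal_duration + rng.normal(0.0, model.duration_sd)
    t_cross = float(np.clip(t_cross, 0.2, 0.95 * cfg.max_trial_duration))
    y_full = cfg.path_y + model.path_overshoot
    u_star = _crossing_fraction(cfg.path_y / y_full)
    duration = min(t_cross / u_star, cfg.max_trial_duration)

    dt = cfg.sample_dt
    n_samples = int(math.floor(duration / dt)) + 1
    ts = np.arange(n_samples) * dt

    frame_dt = cfg.frame_dt
    n_frames = int(math.floor(ts[-1] / frame_dt)) + 1
    steps = generate_step_sequence(n_frames, cfg.step_amplitude, rng, frame_rate=cfg.frame_rate)
    frame_times = steps.frame_times
    cum_offset = steps.cumulative_offset

    # baseline minimum-jerk reach, aimed at the unperturbed interception point
    x_at_cross = cfg.target_start[0] + cfg.target_speed * t_cross
    x_full = x_at_cross * y_full / cfg.path_y
    profile = minimum_jerk(ts / duration)
    x = x_full * profile
    y = y_full * profile

    # corrective lateral acceleration: linear superposition over steps
    t_remaining = t_cross - frame_times
    if perturb_type == "target":
        gains = np.maximum(model.target_gain(t_remaining), 0.0)
        coef = cfg.step_amplitude * gains * steps.directions
    else:
        if model.cursor_gain is not None:
            gains = np.maximum(model.cursor_gain(t_remaining), 0.0)
        else:
            gains = model.cursor_weight * np.maximum(model.target_gain(t_remaining), 0.0)
        coef = -cfg.step_amplitude * gains * steps.directions
    if np.any(coef != 0.0):
        lag_matrix = ts[None, :] - (frame_times + model.latency)[:, None]
        x = x + _positions_from_acceleration(coef @ model.impulse_response(lag_matrix), dt)

    if model.motor_noise_sd > 0:
        x = x + _positions_from_acceleration(rng.normal(0.0, model.motor_noise_sd, n_samples), dt)
        y = y + _positions_from_acceleration(rng.normal(0.0, model.motor_noise_sd, n_samples), dt)

    target_x = cfg.target_start[0] + cfg.target_speed * frame_times
    if perturb_type == "target":
        target_x = target_x + cum_offset
        cursor_offset = np.zeros(n_frames)
    else:
        cursor_offset = cum_offset.copy()

    trial = Trial(
        trial_id=trial_id,
        perturb_type=perturb_type,
        times=ts,
        x=x,
        y=y,
        frame_times=frame_times,
        step_dirs=steps.directions,
        jitter=cum_offset,
        target_x=target_x,
        target_y=np.full(n_frames, cfg.path_y),
        cursor_offset=cursor_offset,
        session_id=session_id,
    )
    trial.hit, trial.hit_position = detect_hit(trial, cfg)
    return trial


# ---------------------------------------------------------------------------
# hit detection


def detect_hit(trial: Trial, cfg: SessionConfig) -> tuple[bool, tuple[float, float] | None]:
    """Was the interpolated cursor centre ever within the target disc?

    Both the cursor trajectory (finger + interpolated cursor offset) and the
    target trajectory (frame positions interpolated linearly — exact for the
    constant-velocity base motion) are treated as piecewise linear between
    samples; the minimum distance on each segment is found in closed form, so
    a hit that exists only between samples is still detected.  Returns the
    hit flag and the target-centre position at the first moment of the hit.
    """
    if len(trial.times) < 2:
        raise ValueError("detect_hit requires at least two finger samples")
    if len(trial.frame_times) < 1:
        raise ValueError("detect_hit requires at least one frame record")

    ts = trial.times
    offset = np.interp(ts, trial.frame_times, trial.cursor_offset)
    tx = np.interp(ts, trial.frame_times, trial.target_x)
    ty = np.interp(ts, trial.frame_times, trial.target_y)
    rel_x = (trial.x + offset) - tx
    rel_y = trial.y - ty

    p0x, p0y = rel_x[:-1], rel_y[:-1]
    dx, dy = np.diff(rel_x), np.diff(rel_y)
    dd = dx * dx + dy * dy
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(dd > 0, -(p0x * dx + p0y * dy) / np.where(dd > 0, dd, 1.0), 0.0)
    alpha = np.clip(alpha, 0.0, 1.0)
    min_d2 = (p0x + alpha * dx) ** 2 + (p0y + alpha * dy) ** 2

    r = cfg.target_radius
    hits = min_d2 <= r * r
    if not np.any(hits):
        return False, None
    seg = int(np.argmax(hits))

    # earliest alpha in the first hitting segment with |p0 + alpha d| <= r
    a, b = dd[seg], p0x[seg] * dx[seg] + p0y[seg] * dy[seg]
    c = p0x[seg] ** 2 + p0y[seg] ** 2 - r * r
    if c <= 0:
        alpha_hit = 0.0
    elif a > 0:
        disc = max(b * b - a * c, 0.0)
        alpha_hit = float(np.clip((-b - math.sqrt(disc)) / a, 0.0, 1.0))
    else:
        alpha_hit = 0.0
    t_hit = ts[seg] + alpha_hit * (ts[seg + 1] - ts[seg])
    hit_pos = (
        float(np.interp(t_hit, trial.frame_times, trial.target_x)),
        float(np.interp(t_hit, trial.frame_times, trial.target_y)),
    )
    return True, hit_pos


# ---------------------------------------------------------------------------
# sessions


def simulate_session(
    cfg: SessionConfig,
    model: FeedbackModel,
    n_trials: int,
    seed: int | SeedSequence | None = None,
    session_id: str = "s0",
) -> list[Trial]:
    """Simulate a session of interleaved target- and cursor-jitter trials.

    The two perturbation types are balanced to within one trial and presented
    in a seeded random order.  One master seed deterministically derives
    independent per-trial seeds, so identical seeds give identical sessions.
    """
    if n_trials < 2:
        raise ValueError(f"a session needs at least 2 trials, got {n_trials}")
    ss = seed if isinstance(seed, SeedSequence) else SeedSequence(seed)
    order_rng = default_rng(ss.spawn(1)[0])
    types = ["target"] * (n_trials // 2) + ["cursor"] * (n_trials // 2)
    if n_trials % 2:
        types.append("target" if order_rng.integers(0, 2) else "cursor")
    order_rng.shuffle(types)
    trial_seeds = ss.spawn(n_trials)
    return [
        simulate_trial(
            cfg,
            model,
            perturb_type=ptype,
            rng=default_rng(trial_seeds[i]),
            trial_id=i,
            session_id=session_id,
        )
        for i, ptype in enumerate(types)
    ]
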