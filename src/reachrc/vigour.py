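"""Vigour read-outs and the cursor-vs-target origin-line comparison.

The full response kernels are reduced to single "vigour" values: the
acceleration difference at a few fixed lags after the step (160, 170 and
180 ms by default, where responses to both channels are clearly developed).
Plotting the cursor value against the target value across step times tests
whether the two responses grow in the same way as the movement nears its
end: if they do, the points lie on a straight line through the origin whose
slope is the relative cursor weight; if reliance on visual hand information
grows disproportionately late in the movement, the cloud bends upward.  The
bend is quantified here as the quadratic coefficient of a through-origin
fit, with a bootstrap confidence interval over step-time pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.random import default_rng

from .config import SessionConfig
from .revcorr import ResponseCurve
from .simulate import Trial

__all__ = [
    "OriginFit",
    "VigourSummary",
    "response_at_lag",
    "origin_line_fit",
    "vigour_pairs",
    "vigour_summary",
    "session_summary",
]

DEFAULT_LAGS_MS = (160.0, 170.0, 180.0)


def response_at_lag(curve: ResponseCurve, lag_ms: float) -> float | None:
    """Curve value at one lag (ms); linear interpolation off the grid.

    Returns None when the lag lies beyond the curve's truncation point or on
    an undefined stretch of the grid.
    """
    lags = curve.lags_ms
    if len(lags) == 0 or lag_ms < lags[0] - 1e-9 or lag_ms > lags[-1] + 1e-9:
        return None
    i = int(np.searchsorted(lags, lag_ms - 1e-9))
    if i < len(lags) and abs(lags[i] - lag_ms) < 1e-6:
        value = curve.values[i]
        return None if np.isnan(value) else float(value)
    lo, hi = i - 1, i
    if lo < 0 or hi >= len(lags):
        return None
    v0, v1 = curve.values[lo], curve.values[hi]
    if np.isnan(v0) or np.isnan(v1):
        return None
    frac = (lag_ms - lags[lo]) / (lags[hi] - lags[lo])
    return float(v0 + frac * (v1 - v0))


@dataclass(frozen=True)
class OriginFit:
    """Through-origin comparison of cursor vs target responses at one lag.

    ``slope`` is the least-squares slope of cursor-on-target constrained
    through the origin; ``curvature`` is the quadratic coefficient b of the
    through-origin fit cursor = a*t + b*t^2 (positive = the cloud bends
    upward, i.e. cursor responses grow disproportionately late), with a
    percentile bootstrap confidence interval over the step-time pairs.
    """

    slope: float
    curvature: float
    curvature_ci: tuple[float, float]
    n_pairs: int


def _origin_slope(t: np.ndarray, c: np.ndarray) -> float:
    denom = float(np.sum(t * t))
    if denom == 0.0:
        raise ValueError("origin slope undefined: all target responses are zero")
    return float(np.sum(t * c) / denom)


def _origin_quadratic(t: np.ndarray, c: np.ndarray) -> float:
    design = np.column_stack([t, t * t])
    coef, *_ = np.linalg.lstsq(design, c, rcond=None)
    return float(coef[1])


def origin_line_fit(
    pairs: np.ndarray,
    n_boot: int = 2000,
    rng=None,
    ci_level: float = 0.95,
) -> OriginFit:
    """Fit the through-origin line and quadratic to (target, cursor) pairs.

    ``pairs`` is an (n, 2) array of responses at a fixed lag, one row per
    step time.  The bootstrap resamples rows with replacement (seeded via
    ``rng``).
    """
    pairs = np.atleast_2d(np.asarray(pairs, dtype=float))
    if pairs.shape[0] < 3 or pairs.shape[1] != 2:
        raise ValueError(f"need at least 3 (target, cursor) pairs, got shape {pairs.shape}")
    t, c = pairs[:, 0], pairs[:, 1]
    slope = _origin_slope(t, c)
    curvature = _origin_quadratic(t, c)

    rng = default_rng(rng)
    n = len(t)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        tb, cb = t[idx], c[idx]
        if np.sum(tb * tb) == 0.0 or np.linalg.matrix_rank(np.column_stack([tb, tb * tb])) < 2:
            boot[b] = np.nan
            continue
        boot[b] = _origin_quadratic(tb, cb)
    alpha = (1.0 - ci_level) / 2.0
    ci = tuple(np.nanpercentile(boot, [100 * alpha, 100 * (1 - alpha)]))
    return OriginFit(slope=slope, curvature=curvature, curvature_ci=ci, n_pairs=n)


def _support_at_lag(curve: ResponseCurve, lag_ms: float) -> int:
    """Trials contributing to the curve at (the grid point nearest) one lag."""
    if len(curve.lags_ms) == 0 or lag_ms > curve.lags_ms[-1] + 1e-9:
        return 0
    i = int(np.argmin(np.abs(curve.lags_ms - lag_ms)))
    return int(curve.n_left_by_lag[i] + curve.n_right_by_lag[i])


def vigour_pairs(
    curves: dict[tuple[str, int], ResponseCurve],
    lags_ms=DEFAULT_LAGS_MS,
    min_support: float = 0.5,
) -> pd.DataFrame:
    """Per step time and lag, the (target, cursor) response pair.

    Rows exist only for step frames where both perturbation types have a
    defined curve value at that lag; pairs with either side undefined are
    dropped pairwise.  ``min_support`` additionally drops step times whose
    curves draw on fewer than that fraction of the maximally available trials
    at the lag (for steps much earlier than the typical movement duration
    only the few longest trials contribute, and their conditional means are
    statistically worthless; 0 disables the filter).
    """
    ks = sorted({k for (ptype, k) in curves if (("target", k) in curves and ("cursor", k) in curves)})
    rows = []
    for lag in lags_ms:
        supports = {
            k: min(_support_at_lag(curves[("target", k)], lag), _support_at_lag(curves[("cursor", k)], lag))
            for k in ks
        }
        needed = min_support * max(supports.values(), default=0)
        for k in ks:
            if supports[k] < needed or supports[k] == 0:
                continue
            t_curve = curves[("target", k)]
            c_curve = curves[("cursor", k)]
            t_val = response_at_lag(t_curve, lag)
            c_val = response_at_lag(c_curve, lag)
            if t_val is None or c_val is None:
                continue
            rows.append(
                {
                    "lag_ms": lag,
                    "k": k,
                    "step_time_before_end_ms": 0.5
                    * (t_curve.step_time_before_end_ms + c_curve.step_time_before_end_ms),
                    "target_response": t_val,
                    "cursor_response": c_val,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["lag_ms", "k", "step_time_before_end_ms", "target_response", "cursor_response"],
    )


@dataclass
class VigourSummary:
    """Per-lag origin fits plus session-level statistics."""

    lags_ms: tuple[float, ...]
    pairs: pd.DataFrame
    fits: dict[float, OriginFit]
    hit_fraction: dict[str, float] = field(default_factory=dict)
    end_time_mean_ms: dict[str, float] = field(default_factory=dict)
    end_time_sd_ms: dict[str, float] = field(default_factory=dict)
    n_trials: dict[str, int] = field(default_factory=dict)
    n_excluded: dict[str, int] = field(default_factory=dict)


def vigour_summary(
    curves: dict[tuple[str, int], ResponseCurve],
    trials: list[Trial] | None = None,
    lags_ms=DEFAULT_LAGS_MS,
    n_boot: int = 2000,
    rng=None,
    min_support: float = 0.5,
) -> VigourSummary:
    """Reduce a kernel matrix to per-lag origin fits (+ optional session stats)."""
    pairs = vigour_pairs(curves, lags_ms, min_support=min_support)
    rng = default_rng(rng)
    fits: dict[float, OriginFit] = {}
    for lag in lags_ms:
        sub = pairs[pairs["lag_ms"] == lag]
        if len(sub) >= 3:
            fits[lag] = origin_line_fit(
                sub[["target_response", "cursor_response"]].to_numpy(), n_boot=n_boot, rng=rng
            )
    summary = VigourSummary(lags_ms=tuple(lags_ms), pairs=pairs, fits=fits)
    if trials is not None:
        stats = session_summary(trials)
        summary.hit_fraction = stats["hit_fraction"]
        summary.end_time_mean_ms = stats["end_time_mean_ms"]
        summary.end_time_sd_ms = stats["end_time_sd_ms"]
        summary.n_trials = stats["n_trials"]
        summary.n_excluded = stats["n_excluded"]
    return summary


def session_summary(trials: list[Trial]) -> dict:
    """Hit fraction, end-time mean/SD (ms) and counts per perturbation type.

    Computed over annotated, non-excluded trials; excluded trials are only
    counted.  Raises on an empty session.
    """
    if not trials:
        raise ValueError("session_summary: empty session")
    out = {
        "hit_fraction": {},
        "end_time_mean_ms": {},
        "end_time_sd_ms": {},
        "n_trials": {},
        "n_excluded": {},
    }
    for ptype in ("target", "cursor"):
        subset = [t for t in trials if t.perturb_type == ptype]
        kept = [t for t in subset if not t.excluded and t.movement_end is not None]
        out["n_trials"][ptype] = len(kept)
        out["n_excluded"][ptype] = sum(1 for t in subset if t.excluded)
        if kept:
            out["hit_fraction"][ptype] = float(np.mean([bool(t.hit) for t in kept]))
            ends = np.array([t.movement_end.end_time for t in kept]) * 1000.0
            out["end_time_mean_ms"][ptype] = float(np.mean(ends))
            out["end_time_sd_ms"][ptype] = float(np.std(ends, ddof=1)) if len(ends) > 1 else 0.0
    return out
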