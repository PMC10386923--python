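"""Diagnostic figures: frame-synchronised positions, kernel families, lag slices."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .config import SessionConfig
from .revcorr import ResponseCurve
from .vigour import VigourSummary


def _colour(time_before_end_ms: float, span_ms: float = 600.0):
    return plt.cm.viridis(1.0 - min(time_before_end_ms / span_ms, 1.0))


def plot_mean_positions(trials, cfg: SessionConfig, ax=None):
    """Mean finger position at each synchronised frame-from-end, colour-coded
    by time before the end of the movement."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    k_max = max(t.movement_end.last_sync_frame for t in trials)
    for k in range(k_max + 1):
        xs, ys, tbe = [], [], []
        for t in trials:
            idx = t.movement_end.last_sync_frame - k
            if idx < 0:
                continue
            ft = t.frame_times[idx]
            xs.append(np.interp(ft, t.times, t.x))
            ys.append(np.interp(ft, t.times, t.y))
            tbe.append((t.movement_end.end_time - ft) * 1000.0)
        if xs:
            ax.plot(np.mean(xs), np.mean(ys), "o", ms=4, color=_colour(np.mean(tbe)))
    ax.axhline(cfg.path_y, color="0.6", lw=1)
    ax.plot(0, 0, "o", ms=10, mfc="none", mec="green")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_title("mean finger position per frame from end")
    return ax


def plot_kernels(curves: dict[tuple[str, int], ResponseCurve], perturb_type: str, ax=None):
    """Family of response curves for one perturbation type, coloured by the
    selected step's time before the end."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for (ptype, _k), curve in sorted(curves.items()):
        if ptype != perturb_type:
            continue
        ax.plot(
            curve.lags_ms,
            curve.values,
            lw=1,
            color=_colour(curve.step_time_before_end_ms),
        )
    ax.axhline(0, color="0.6", lw=1)
    ax.set_xlabel("time after step (ms)")
    ax.set_ylabel("compensatory acceleration difference (mm/s$^2$)")
    ax.set_title(f"{perturb_type} steps")
    return ax


def plot_lag_slices(summary: VigourSummary, axes=None):
    """Cursor response vs target response per step time, one panel per lag."""
    lags = summary.lags_ms
    if axes is None:
        _, axes = plt.subplots(1, len(lags), figsize=(4 * len(lags), 4), squeeze=False)
        axes = axes[0]
    for ax, lag in zip(axes, lags):
        sub = summary.pairs[summary.pairs["lag_ms"] == lag]
        for _, row in sub.iterrows():
            ax.plot(
                row["target_response"],
                row["cursor_response"],
                "o",
                ms=4,
                color=_colour(row["step_time_before_end_ms"]),
            )
        fit = summary.fits.get(lag)
        if fit is not None and len(sub):
            tmax = float(sub["target_response"].abs().max())
            tt = np.linspace(0, 1.1 * tmax, 50)
            ax.plot(tt, fit.slope * tt, "-", color="0.4", lw=1)
        ax.axhline(0, color="0.8", lw=0.8)
        ax.axvline(0, color="0.8", lw=0.8)
        ax.set_xlabel("target response (mm/s$^2$)")
        ax.set_title(f"{lag:.0f} ms after step")
    axes[0].set_ylabel("cursor response (mm/s$^2$)")
    return axes


def save_diagnostics(trials, curves, summary: VigourSummary, cfg: SessionConfig, out_dir):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ax = plot_mean_positions(trials, cfg)
    ax.figure.savefig(out_dir / "mean_positions.png", dpi=150, bbox_inches="tight")
    plt.close(ax.figure)
    fig, axs = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    plot_kernels(curves, "target", axs[0])
    plot_kernels(curves, "cursor", axs[1])
    fig.savefig(out_dir / "kernels.png", dpi=150, bbox_inches="tight")
    plt.close(fig)
    axes = plot_lag_slices(summary)
    axes[0].figure.savefig(out_dir / "lag_slices.png", dpi=150, bbox_inches="tight")
    plt.close(axes[0].figure)
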