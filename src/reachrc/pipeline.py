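"""End-to-end pipeline: declarative config, simulate and/or analyse, report.

A single YAML (or plain dict) config mirrors :class:`SessionConfig`, the
simulator's :class:`FeedbackModel` and the run options.  The whole pipeline
is deterministic given the seed: the master seed derives per-session
simulation seeds and the bootstrap seed, and the run log echoes the seed and
a hash of the resolved config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml
from numpy.random import SeedSequence, default_rng

from . import io as session_io
from .config import SessionConfig
from .preprocess import annotate_session
from .revcorr import average_kernels, kernel_matrix, kernels_to_frame
from .simulate import FeedbackModel, constant_gain, inverse_time_gain, simulate_session, zero_gain
from .vigour import DEFAULT_LAGS_MS, vigour_summary

logger = logging.getLogger("reachrc")

__all__ = ["RunOptions", "ConfigError", "load_config", "run_pipeline", "analyze_sessions"]


class ConfigError(ValueError):
    """The configuration violates the schema; raised before any computation."""


@dataclass
class RunOptions:
    n_trials: int = 200
    n_sessions: int = 1
    seed: int = 0
    lags_ms: tuple[float, ...] = DEFAULT_LAGS_MS
    n_boot: int = 2000
    write_sessions: bool = True

    def __post_init__(self) -> None:
        if self.n_trials < 2:
            raise ConfigError("run.n_trials must be >= 2")
        if self.n_sessions < 1:
            raise ConfigError("run.n_sessions must be >= 1")
        if self.n_boot < 1:
            raise ConfigError("run.n_boot must be >= 1")
        if not self.lags_ms:
            raise ConfigError("run.lags_ms must not be empty")


_GAIN_BUILDERS = {
    "zero": lambda spec: zero_gain(),
    "constant": lambda spec: constant_gain(spec.get("value", 0.0)),
    "inverse_time": lambda spec: inverse_time_gain(
        scale=spec.get("scale", 0.7), floor=spec.get("floor", 0.1)
    ),
}


def gain_from_spec(spec: dict):
    if not isinstance(spec, dict) or "kind" not in spec:
        raise ConfigError(f"model.gain must be a mapping with a 'kind' key, got {spec!r}")
    kind = spec["kind"]
    if kind not in _GAIN_BUILDERS:
        raise ConfigError(f"unknown gain kind {kind!r}; expected one of {sorted(_GAIN_BUILDERS)}")
    extra = set(spec) - {"kind", "value", "scale", "floor"}
    if extra:
        raise ConfigError(f"unknown keys in model.gain: {sorted(extra)}")
    return _GAIN_BUILDERS[kind](spec)


def _build(cls, section: dict, name: str, special: dict | None = None):
    allowed = {f.name for f in fields(cls)}
    special = special or {}
    unknown = set(section) - allowed - set(special)
    if unknown:
        raise ConfigError(f"unknown keys in '{name}' section: {sorted(unknown)}")
    kwargs = {k: v for k, v in section.items() if k in allowed}
    kwargs.update({dst: fn(section[src]) for src, (dst, fn) in special.items() if src in section})
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid '{name}' section: {exc}") from exc


def load_config(source: str | Path | dict | None) -> tuple[SessionConfig, FeedbackModel, RunOptions]:
    """Resolve a YAML file or dict into the three configuration objects.

    Unknown sections or keys are rejected outright so that typos cannot
    silently fall back to defaults.
    """
    if source is None:
        raw: dict = {}
    elif isinstance(source, dict):
        raw = source
    else:
        with open(source, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - {"session", "model", "run"}
    if unknown:
        raise ConfigError(f"unknown top-level config sections: {sorted(unknown)}")

    session_sec = dict(raw.get("session") or {})
    if "target_start" in session_sec:
        session_sec["target_start"] = tuple(session_sec["target_start"])
    cfg = _build(SessionConfig, session_sec, "session")
    model = _build(
        FeedbackModel,
        dict(raw.get("model") or {}),
        "model",
        special={"gain": ("target_gain", gain_from_spec)},
    )
    run_sec = dict(raw.get("run") or {})
    if "lags_ms" in run_sec:
        run_sec["lags_ms"] = tuple(float(v) for v in run_sec["lags_ms"])
    options = _build(RunOptions, run_sec, "run")
    return cfg, model, options


def _config_hash(cfg: SessionConfig, model: FeedbackModel, options: RunOptions) -> str:
    def _clean(obj):
        if callable(obj):
            return getattr(obj, "spec", str(obj))
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    payload = {
        "session": {f.name: _clean(getattr(cfg, f.name)) for f in fields(cfg)},
        "model": {f.name: _clean(getattr(model, f.name)) for f in fields(model)},
        "run": {f.name: _clean(getattr(options, f.name)) for f in fields(options)},
    }
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16], payload


def _session_dirs(root: Path) -> list[Path]:
    if (root / session_io.SAMPLES_FILE).exists():
        return [root]
    subdirs = sorted(p for p in root.iterdir() if (p / session_io.SAMPLES_FILE).exists())
    if not subdirs:
        raise session_io.SessionFormatError(f"no session tables found under {root}")
    return subdirs


def analyze_sessions(
    sessions: list[list],
    cfg: SessionConfig,
    options: RunOptions,
    boot_rng=None,
):
    """Annotate, exclude, reverse-correlate and summarise a list of sessions.

    Returns (kernels, summary, exclusion counts).  Kernels are computed per
    session and averaged unweighted across sessions.
    """
    all_trials = []
    per_session_kernels = []
    n_excluded = 0
    for trials in sessions:
        kept, excluded = annotate_session(trials, cfg)
        n_excluded += len(excluded)
        all_trials.extend(trials)
        per_session_kernels.append(kernel_matrix(kept, cfg))
    kernels = average_kernels(per_session_kernels)
    summary = vigour_summary(
        kernels, trials=all_trials, lags_ms=options.lags_ms, n_boot=options.n_boot, rng=boot_rng
    )
    return kernels, summary, n_excluded


def run_pipeline(
    config: str | Path | dict | None,
    out_dir: str | Path,
    seed: int | None = None,
    session_dir: str | Path | None = None,
    n_trials: int | None = None,
    make_plots: bool = False,
) -> dict:
    """Run simulate-then-analyse (default) or analyse an existing session dir.

    Writes the kernel table, vigour pairs and fits, session summary, a
    human-readable report and a ``run_info.json`` echoing seed, config hash,
    trial counts and exclusions into ``out_dir``.  Returns the in-memory
    results.
    """
    cfg, model, options = load_config(config)
    if seed is not None:
        options.seed = int(seed)
    if n_trials is not None:
        options.n_trials = int(n_trials)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash, cfg_payload = _config_hash(cfg, model, options)
    logger.info("run: seed=%d config_hash=%s", options.seed, cfg_hash)

    ss = SeedSequence(options.seed)
    boot_seed, *session_seeds = ss.spawn(1 + options.n_sessions)

    if session_dir is not None:
        dirs = _session_dirs(Path(session_dir))
        sessions = [session_io.read_session(d) for d in dirs]
        logger.info("loaded %d session(s) from %s", len(sessions), session_dir)
    else:
        sessions = []
        for i, child in enumerate(session_seeds):
            sid = f"s{i + 1:02d}"
            trials = simulate_session(cfg, model, options.n_trials, seed=child, session_id=sid)
            sessions.append(trials)
            if options.write_sessions:
                session_io.write_session(trials, out_dir / "sessions" / sid)
        logger.info("simulated %d session(s) of %d trials", len(sessions), options.n_trials)

    kernels, summary, n_excluded = analyze_sessions(
        sessions, cfg, options, boot_rng=default_rng(boot_seed)
    )
    logger.info(
        "analysed %d trials (%d excluded); %d response curves",
        sum(len(s) for s in sessions),
        n_excluded,
        len(kernels),
    )

    kernels_df = kernels_to_frame(kernels)
    kernels_df.to_csv(out_dir / "kernels.csv", index=False)
    summary.pairs.to_csv(out_dir / "vigour_pairs.csv", index=False)

    import pandas as pd

    fits_df = pd.DataFrame(
        [
            {
                "lag_ms": lag,
                "origin_slope": fit.slope,
                "curvature_index": fit.curvature,
                "curvature_ci_low": fit.curvature_ci[0],
                "curvature_ci_high": fit.curvature_ci[1],
                "n_pairs": fit.n_pairs,
            }
            for lag, fit in sorted(summary.fits.items())
        ],
        columns=[
            "lag_ms",
            "origin_slope",
            "curvature_index",
            "curvature_ci_low",
            "curvature_ci_high",
            "n_pairs",
        ],
    )
    fits_df.to_csv(out_dir / "vigour_fits.csv", index=False)

    stats_rows = []
    for ptype in ("target", "cursor"):
        if ptype in summary.n_trials:
            stats_rows.append(
                {
                    "perturb_type": ptype,
                    "n_trials": summary.n_trials.get(ptype, 0),
                    "n_excluded": summary.n_excluded.get(ptype, 0),
                    "hit_fraction": summary.hit_fraction.get(ptype, np.nan),
                    "end_time_mean_ms": summary.end_time_mean_ms.get(ptype, np.nan),
                    "end_time_sd_ms": summary.end_time_sd_ms.get(ptype, np.nan),
                }
            )
    stats_df = pd.DataFrame(stats_rows)
    stats_df.to_csv(out_dir / "session_summary.csv", index=False)

    report = _format_report(summary, stats_df, cfg_hash, options)
    (out_dir / "report.txt").write_text(report, encoding="utf-8")

    run_info = {
        "seed": options.seed,
        "config_hash": cfg_hash,
        "config": cfg_payload,
        "n_sessions": len(sessions),
        "n_trials_total": sum(len(s) for s in sessions),
        "n_excluded": n_excluded,
        "n_curves": len(kernels),
    }
    (out_dir / "run_info.json").write_text(json.dumps(run_info, indent=2), encoding="utf-8")

    if make_plots:
        from . import plots

        fig_dir = out_dir / "figures"
        annotated = [t for s in sessions for t in s if not t.excluded and t.movement_end is not None]
        plots.save_diagnostics(annotated, kernels, summary, cfg, fig_dir)
        logger.info("wrote figures to %s", fig_dir)

    return {
        "kernels": kernels,
        "summary": summary,
        "sessions": sessions,
        "run_info": run_info,
        "out_dir": out_dir,
    }


def _format_report(summary, stats_df, cfg_hash: str, options: RunOptions) -> str:
    lines = [
        "Reverse-correlation feedback analysis",
        f"config {cfg_hash}, seed {options.seed}",
        "",
        "Session statistics (annotated trials):",
    ]
    for _, row in stats_df.iterrows():
        lines.append(
            f"  {row['perturb_type']:>6s}: n={int(row['n_trials'])} "
            f"(excluded {int(row['n_excluded'])}), hit fraction {row['hit_fraction']:.2f}, "
            f"end of movement {row['end_time_mean_ms']:.0f} +/- {row['end_time_sd_ms']:.0f} ms"
        )
    lines.append("")
    lines.append("Cursor-vs-target origin-line fits (per lag after the step):")
    for lag, fit in sorted(summary.fits.items()):
        lines.append(
            f"  {lag:.0f} ms: slope {fit.slope:.3f}, curvature {fit.curvature:+.2e} "
            f"(95% CI {fit.curvature_ci[0]:+.2e} .. {fit.curvature_ci[1]:+.2e}, "
            f"{fit.n_pairs} step times)"
        )
    lines.append("")
    return "\n".join(lines)
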