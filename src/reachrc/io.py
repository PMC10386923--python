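"""On-disk trial tables: three comma-separated text files per session.

``samples.csv``  one row per finger sample: trial_id, t_s, finger_x_mm, finger_y_mm
``frames.csv``   one row per display frame: trial_id, frame_idx, t_s, step_dir,
                 jitter_mm, target_x_mm, target_y_mm, cursor_offset_mm
``trials.csv``   one row per trial: trial_id, perturb_type, hit, session_id
                 (plus hit_x_mm / hit_y_mm when the target was hit)

All files are UTF-8 with a header row and '.' decimal separator.  Writing is
deterministic (ordered by trial_id then time) and round-trips numerically:
write -> read -> write reproduces the bytes.  Reading validates the tables
and reports violations with the trial id and row number; no malformed row is
silently ignored.  Movement-end annotations and exclusions are analysis-time
state and are not serialised.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import Trial

__all__ = ["write_session", "read_session", "SessionFormatError"]

SAMPLES_FILE = "samples.csv"
FRAMES_FILE = "frames.csv"
TRIALS_FILE = "trials.csv"

_SAMPLE_COLS = ["trial_id", "t_s", "finger_x_mm", "finger_y_mm"]
_FRAME_COLS = [
    "trial_id",
    "frame_idx",
    "t_s",
    "step_dir",
    "jitter_mm",
    "target_x_mm",
    "target_y_mm",
    "cursor_offset_mm",
]
_TRIAL_COLS = ["trial_id", "perturb_type", "hit", "session_id", "hit_x_mm", "hit_y_mm"]


class SessionFormatError(ValueError):
    """A trial table violates the dialect; the message cites trial/row."""


def write_session(trials: list[Trial], directory: str | Path) -> dict[str, Path]:
    """Write a session's three trial tables into ``directory``.

    Excluded trials are written like any other (exclusion is an analysis-time
    annotation, not a property of the data).  Returns the paths written.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if not trials:
        raise ValueError("write_session: empty session")

    ordered = sorted(trials, key=lambda t: t.trial_id)

    samples = pd.concat(
        [
            pd.DataFrame(
                {
                    "trial_id": t.trial_id,
                    "t_s": t.times,
                    "finger_x_mm": t.x,
                    "finger_y_mm": t.y,
                }
            )
            for t in ordered
        ],
        ignore_index=True,
    )
    frames = pd.concat(
        [
            pd.DataFrame(
                {
                    "trial_id": t.trial_id,
                    "frame_idx": np.arange(t.n_frames),
                    "t_s": t.frame_times,
                    "step_dir": t.step_dirs,
                    "jitter_mm": t.jitter,
                    "target_x_mm": t.target_x,
                    "target_y_mm": t.target_y,
                    "cursor_offset_mm": t.cursor_offset,
                }
            )
            for t in ordered
        ],
        ignore_index=True,
    )
    trials_df = pd.DataFrame(
        {
            "trial_id": [t.trial_id for t in ordered],
            "perturb_type": [t.perturb_type for t in ordered],
            "hit": [bool(t.hit) for t in ordered],
            "session_id": [t.session_id for t in ordered],
            "hit_x_mm": [t.hit_position[0] if t.hit_position else np.nan for t in ordered],
            "hit_y_mm": [t.hit_position[1] if t.hit_position else np.nan for t in ordered],
        }
    )

    paths = {
        SAMPLES_FILE: directory / SAMPLES_FILE,
        FRAMES_FILE: directory / FRAMES_FILE,
        TRIALS_FILE: directory / TRIALS_FILE,
    }
    try:
        samples.to_csv(paths[SAMPLES_FILE], index=False)
        frames.to_csv(paths[FRAMES_FILE], index=False)
        trials_df.to_csv(paths[TRIALS_FILE], index=False)
    except OSError as exc:
        raise OSError(f"cannot write session tables to {directory}: {exc}") from exc
    return paths


def _require_columns(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SessionFormatError(f"{name} is missing required columns: {missing}")


def _check_monotone(times: np.ndarray, trial_id, name: str, rows: np.ndarray) -> None:
    bad = np.nonzero(np.diff(times) <= 0)[0]
    if len(bad):
        row = int(rows[bad[0] + 1])
        raise SessionFormatError(
            f"{name}: trial {trial_id} has non-increasing t_s at file row {row + 2} "
            "(times must be strictly increasing)"
        )


def read_session(directory: str | Path) -> list[Trial]:
    """Read and validate a session written in the trial-table dialect.

    Raises :class:`SessionFormatError` naming the offending trial and row for
    any violation: missing columns, unknown perturbation type, non-monotone
    times, orphan trial ids, or jitter on the wrong channel (nonzero cursor
    offset on a target-jitter trial).
    """
    directory = Path(directory)
    for fname in (SAMPLES_FILE, FRAMES_FILE, TRIALS_FILE):
        if not (directory / fname).exists():
            raise SessionFormatError(f"missing session file: {directory / fname}")

    # round_trip float parsing: write->read->write must be byte-identical
    samples = pd.read_csv(directory / SAMPLES_FILE, float_precision="round_trip")
    frames = pd.read_csv(directory / FRAMES_FILE, float_precision="round_trip")
    trials_df = pd.read_csv(directory / TRIALS_FILE, float_precision="round_trip")

    _require_columns(samples, _SAMPLE_COLS, SAMPLES_FILE)
    _require_columns(frames, _FRAME_COLS, FRAMES_FILE)
    _require_columns(trials_df, ["trial_id", "perturb_type", "hit", "session_id"], TRIALS_FILE)

    if trials_df["trial_id"].duplicated().any():
        dup = trials_df.loc[trials_df["trial_id"].duplicated(), "trial_id"].iloc[0]
        raise SessionFormatError(f"{TRIALS_FILE}: duplicate trial_id {dup}")
    known = set(trials_df["trial_id"])
    for name, df in ((SAMPLES_FILE, samples), (FRAMES_FILE, frames)):
        orphans = sorted(set(df["trial_id"]) - known)
        if orphans:
            raise SessionFormatError(
                f"{name}: trial_id(s) {orphans} do not appear in {TRIALS_FILE}"
            )

    bad_type = ~trials_df["perturb_type"].isin(["target", "cursor"])
    if bad_type.any():
        row = int(trials_df.index[bad_type][0])
        raise SessionFormatError(
            f"{TRIALS_FILE}: unknown perturb_type "
            f"{trials_df.loc[row, 'perturb_type']!r} at file row {row + 2}"
        )

    has_hit_pos = "hit_x_mm" in trials_df.columns and "hit_y_mm" in trials_df.columns
    sample_groups = dict(iter(samples.groupby("trial_id", sort=False)))
    frame_groups = dict(iter(frames.groupby("trial_id", sort=False)))

    trials: list[Trial] = []
    for _, row in trials_df.iterrows():
        tid = row["trial_id"]
        if tid not in sample_groups:
            raise SessionFormatError(f"{SAMPLES_FILE}: no samples for trial {tid}")
        if tid not in frame_groups:
            raise SessionFormatError(f"{FRAMES_FILE}: no frames for trial {tid}")
        sg = sample_groups[tid]
        fg = frame_groups[tid].sort_values("frame_idx")
        _check_monotone(sg["t_s"].to_numpy(), tid, SAMPLES_FILE, sg.index.to_numpy())
        _check_monotone(fg["t_s"].to_numpy(), tid, FRAMES_FILE, fg.index.to_numpy())

        ptype = row["perturb_type"]
        offsets = fg["cursor_offset_mm"].to_numpy()
        if ptype == "target" and np.any(offsets != 0.0):
            bad = int(fg.index[np.nonzero(offsets != 0.0)[0][0]])
            raise SessionFormatError(
                f"{FRAMES_FILE}: trial {tid} is a target-jitter trial but has a nonzero "
                f"cursor_offset_mm at file row {bad + 2}"
            )
        dirs = fg["step_dir"].to_numpy()
        if not np.all(np.isin(dirs, (-1, 1))):
            bad = int(fg.index[np.nonzero(~np.isin(dirs, (-1, 1)))[0][0]])
            raise SessionFormatError(
                f"{FRAMES_FILE}: trial {tid} has step_dir not in {{-1, +1}} at file row {bad + 2}"
            )

        hit = bool(row["hit"])
        hit_position = None
        if hit and has_hit_pos and np.isfinite(row.get("hit_x_mm", np.nan)):
            hit_position = (float(row["hit_x_mm"]), float(row["hit_y_mm"]))
        trials.append(
            Trial(
                trial_id=int(tid),
                perturb_type=str(ptype),
                times=sg["t_s"].to_numpy(dtype=float),
                x=sg["finger_x_mm"].to_numpy(dtype=float),
                y=sg["finger_y_mm"].to_numpy(dtype=float),
                frame_times=fg["t_s"].to_numpy(dtype=float),
                step_dirs=dirs.astype(int),
                jitter=fg["jitter_mm"].to_numpy(dtype=float),
                target_x=fg["target_x_mm"].to_numpy(dtype=float),
                target_y=fg["target_y_mm"].to_numpy(dtype=float),
                cursor_offset=offsets.astype(float),
                hit=hit,
                hit_position=hit_position,
                session_id=str(row["session_id"]),
            )
        )
    return trials
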