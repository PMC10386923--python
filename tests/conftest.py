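import numpy as np
import pytest

from reachrc import FeedbackModel, SessionConfig, Trial, simulate_session
from reachrc.preprocess import annotate_session


@pytest.fixture(scope="session")
def cfg():
    return SessionConfig()


@pytest.fixture(scope="session")
def model():
    return FeedbackModel()


@pytest.fixture(scope="session")
def small_session(cfg, model):
    """A 20-trial annotated session shared (read-only) across tests."""
    trials = simulate_session(cfg, model, 20, seed=42)
    annotate_session(trials, cfg)
    return trials


def make_trial(
    times,
    x,
    y,
    frame_rate=60.0,
    perturb_type="target",
    step_dirs=None,
    cursor_offset=None,
    target_speed=500.0,
    target_start=(-300.0, 200.0),
    trial_id=0,
):
    """Hand-constructed trial with a regular frame grid covering the samples."""
    times = np.asarray(times, dtype=float)
    n_frames = int(np.floor(times[-1] * frame_rate)) + 1
    frame_times = np.arange(n_frames) / frame_rate
    if step_dirs is None:
        step_dirs = np.ones(n_frames, dtype=int)
    step_dirs = np.asarray(step_dirs, dtype=int)
    jitter = 2.5 * np.cumsum(step_dirs)
    target_x = target_start[0] + target_speed * frame_times
    if perturb_type == "target":
        target_x = target_x + jitter
        offsets = np.zeros(n_frames)
    else:
        offsets = jitter.copy() if cursor_offset is None else np.asarray(cursor_offset, float)
    return Trial(
        trial_id=trial_id,
        perturb_type=perturb_type,
        times=times,
        x=np.asarray(x, dtype=float),
        y=np.asarray(y, dtype=float),
        frame_times=frame_times,
        step_dirs=step_dirs,
        jitter=jitter,
        target_x=target_x,
        target_y=np.full(n_frames, target_start[1]),
        cursor_offset=offsets,
    )
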