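#!/usr/bin/env python
"""Simulate synthetic interception sessions and write their trial tables.

Four sessions of 200 trials each (100 target-jitter + 100 cursor-jitter,
randomly interleaved) are generated under the default task geometry — target
appearing 30 cm left / 20 cm beyond the start, moving rightward at 50 cm/s,
with a +/-2.5 mm lateral random-walk step per 60 Hz frame — and the default
(invented) feedback law: 110 ms latency, gamma impulse response, gain
inversely proportional to the remaining movement time, cursor responses at
0.6 of target responses.

Writes results/sessions/s01..s04/{samples,frames,trials}.csv
"""

from pathlib import Path

from numpy.random import SeedSequence

from reachrc import FeedbackModel, SessionConfig, simulate_session
from reachrc.io import write_session

SEED = 1
N_SESSIONS = 4
N_TRIALS = 200

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cfg = SessionConfig()
    model = FeedbackModel()
    out = ROOT / "results" / "sessions"
    for i, child in enumerate(SeedSequence(SEED).spawn(N_SESSIONS)):
        sid = f"s{i + 1:02d}"
        trials = simulate_session(cfg, model, N_TRIALS, seed=child, session_id=sid)
        write_session(trials, out / sid)
        n_hit = sum(bool(t.hit) for t in trials)
        print(f"{sid}: {N_TRIALS} trials written, {n_hit} hits ({n_hit / N_TRIALS:.0%})")
    print(f"\nsessions under {out}")


if __name__ == "__main__":
    main()
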