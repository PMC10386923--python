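#!/usr/bin/env python
"""Extract the reverse-correlation response kernels from the sessions.

For every display frame counted backwards from the movement end (and both
perturbation types), trials are split by the direction of that frame's
jitter step and the group-mean lateral accelerations are differenced,
compensatory-positive, for 250 ms after the step.  Only steps more than
100 ms before the end are analysable.  Kernels are computed per session and
averaged unweighted across sessions.

Reads  results/sessions/
Writes results/kernels.csv (tidy: perturb_type, k, step time, lag, value, se, counts)
"""

from pathlib import Path

from reachrc import SessionConfig, kernel_matrix
from reachrc.io import read_session
from reachrc.preprocess import annotate_session
from reachrc.revcorr import average_kernels, kernels_to_frame

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cfg = SessionConfig()
    kernel_dicts = []
    for sdir in sorted((ROOT / "results" / "sessions").iterdir()):
        trials = read_session(sdir)
        kept, _ = annotate_session(trials, cfg)
        kernel_dicts.append(kernel_matrix(kept, cfg))
        print(f"{sdir.name}: {len(kernel_dicts[-1])} response curves")
    kernels = average_kernels(kernel_dicts)
    df = kernels_to_frame(kernels)
    out = ROOT / "results" / "kernels.csv"
    df.to_csv(out, index=False)

    for ptype in ("target", "cursor"):
        ks = sorted(k for (p, k) in kernels if p == ptype)
        print(
            f"{ptype}: {len(ks)} step times analysed, "
            f"k = {ks[0]}..{ks[-1]} "
            f"({kernels[(ptype, ks[0])].step_time_before_end_ms:.0f}-"
            f"{kernels[(ptype, ks[-1])].step_time_before_end_ms:.0f} ms before the end)"
        )
    print(f"\nwrote {out} ({len(df)} rows)")


if __name__ == "__main__":
    main()
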