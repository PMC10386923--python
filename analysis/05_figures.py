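#!/usr/bin/env python
"""Diagnostic figures: synchronised mean positions, kernel families, lag slices.

Writes PNGs under results/figures/ (generated output, not tracked sources).
"""

from pathlib import Path

from reachrc import SessionConfig
from reachrc.io import read_session
from reachrc.preprocess import annotate_session
from reachrc.revcorr import average_kernels, kernel_matrix
from reachrc.vigour import vigour_summary
from reachrc import plots

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cfg = SessionConfig()
    kernel_dicts, all_kept = [], []
    for sdir in sorted((ROOT / "results" / "sessions").iterdir()):
        trials = read_session(sdir)
        kept, _ = annotate_session(trials, cfg)
        all_kept.extend(kept)
        kernel_dicts.append(kernel_matrix(kept, cfg))
    kernels = average_kernels(kernel_dicts)
    summary = vigour_summary(kernels, trials=all_kept, n_boot=500, rng=1)
    out = ROOT / "results" / "figures"
    plots.save_diagnostics(all_kept, kernels, summary, cfg, out)
    print(f"wrote {sorted(p.name for p in out.iterdir())} to {out}")


if __name__ == "__main__":
    main()
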