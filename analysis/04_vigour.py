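#!/usr/bin/env python
"""Compare the growth of cursor and target response vigour during movement.

Reduces the kernels to responses at fixed lags after the step (160, 170,
180 ms) and plots — numerically — the cursor response against the target
response across step times.  If both channels' vigour grows in the same way
as the movement nears its end, the points lie on a straight line through the
origin whose slope is the relative cursor weight; an upward bend (positive
curvature with an interval excluding 0) would mean the cursor response grows
disproportionately late.

Reads  results/sessions/ (recomputes kernels so the pairs carry full
       trial-count metadata)
Writes results/vigour_pairs.csv, results/vigour_fits.csv
"""

from pathlib import Path

import pandas as pd
from numpy.random import default_rng

from reachrc import SessionConfig
from reachrc.io import read_session
from reachrc.preprocess import annotate_session
from reachrc.revcorr import average_kernels, kernel_matrix
from reachrc.vigour import origin_line_fit, vigour_pairs

SEED = 1
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cfg = SessionConfig()
    kernel_dicts = []
    for sdir in sorted((ROOT / "results" / "sessions").iterdir()):
        trials = read_session(sdir)
        kept, _ = annotate_session(trials, cfg)
        kernel_dicts.append(kernel_matrix(kept, cfg))
    kernels = average_kernels(kernel_dicts)

    pairs = vigour_pairs(kernels)
    pairs.to_csv(ROOT / "results" / "vigour_pairs.csv", index=False)

    rng = default_rng(SEED)
    rows = []
    print("cursor-vs-target origin-line fits (simulated cursor weight: 0.6):")
    for lag in (160.0, 170.0, 180.0):
        sub = pairs[pairs["lag_ms"] == lag]
        fit = origin_line_fit(
            sub[["target_response", "cursor_response"]].to_numpy(), n_boot=2000, rng=rng
        )
        rows.append(
            {
                "lag_ms": lag,
                "origin_slope": fit.slope,
                "curvature_index": fit.curvature,
                "curvature_ci_low": fit.curvature_ci[0],
                "curvature_ci_high": fit.curvature_ci[1],
                "n_pairs": fit.n_pairs,
            }
        )
        covers = fit.curvature_ci[0] <= 0.0 <= fit.curvature_ci[1]
        print(
            f"  {lag:.0f} ms: slope {fit.slope:.3f} over {fit.n_pairs} step times; "
            f"curvature {fit.curvature:+.2e} "
            f"(95% CI {fit.curvature_ci[0]:+.2e}..{fit.curvature_ci[1]:+.2e}; "
            f"{'covers 0: straight line' if covers else 'excludes 0'})"
        )
    out = ROOT / "results" / "vigour_fits.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
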