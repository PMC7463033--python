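"""Coarse grid search over scoring parameters on simulated data.

The numeric defaults of the scoring model (missing-label score c, length
exponent k, step-filter level) are calibrated against simulations where the
correct segment placements are known: a parameter set is good when true
placements score far above the significance cutoff while shuffled decoy
segments stay below it, and end-to-end mean F1 is high. This script documents
and reproduces that procedure; it is exploratory tooling, not part of the
pipeline.

Usage:  python scripts/calibrate_scoring.py [--seed 7] [--n 6]
"""

from __future__ import annotations

import argparse
import itertools

from amprecon.align import ScoringParams
from amprecon.study import run_single_amplicon_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--n", type=int, default=6, help="amplicons per grid point")
    args = ap.parse_args()

    grid_c = [1000.0, 2000.0, 3000.0, 5000.0]
    grid_k = [1.0, 1.05, 1.1, 1.2]
    print("c\tk\tmean_F1")
    best = (None, -1.0)
    for c, k in itertools.product(grid_c, grid_k):
        params = ScoringParams(c=c, k=k)
        r = run_single_amplicon_cohort(args.seed, n_amplicons=args.n, params=params)
        print(f"{c:.0f}\t{k:.2f}\t{r['mean_f1']:.4f}")
        if r["mean_f1"] > best[1]:
            best = ((c, k), r["mean_f1"])
    print(f"best: c={best[0][0]:.0f} k={best[0][1]:.2f} (mean F1 {best[1]:.4f})")


if __name__ == "__main__":
    main()
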