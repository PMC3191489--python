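#!/usr/bin/env python
"""How different must two step durations be to be told apart at N = 200?

Sweeps the true duration ratio (1.0 ... 3.0) at 200 intervals per
replicate and reports, per ratio, the LRT rejection rate of the
equal-duration null, the fraction of replicates whose fitted ratio is
log-closer to the truth than to 1, and the median fitted ratio.

Typical output: the LRT is conservative at the null and nearly powerless
below 2x separation — the unequal-step and best-Erlang densities are
almost identical at these ratios — while the estimate-based detection
fraction climbs steadily with separation (~0.55 near the detectability
threshold to ~0.9 at 3x) and the median fitted ratio tracks the true
ratio from ~25% separation upward. Near equality the fitted-ratio
distribution is bimodal (a point mass of replicates collapsing to exactly
equal durations plus a dispersed component), which is the bias toward
identical inferred durations at small true separations.
"""

import argparse
from pathlib import Path

from initsteps.validation import discriminability_curve


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--reps", type=int, default=100)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    df = discriminability_curve(
        1000.0,
        (1.0, 1.15, 1.25, 1.5, 2.0, 3.0),
        n_intervals=200,
        n_reps=args.reps,
        seed=args.seed,
    )
    df.to_csv(args.outdir / "discriminability.tsv", sep="\t", index=False)
    print(
        df[
            ["ratio", "rejection_fraction", "detected_fraction", "median_fitted_ratio"]
        ].to_string(index=False)
    )
    print(f"wrote {args.outdir}/discriminability.tsv")


if __name__ == "__main__":
    main()
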