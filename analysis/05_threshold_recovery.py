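#!/usr/bin/env python
"""Closed-loop recovery of the positional-information thresholds.

Generates fate-labeled synthetic cell datasets from known (T1, T2, tau_bra,
tau_cdx2) on an exposure field mixing sustained, ramped and pulsed
trajectories, adds 5% label noise, refits by grid search, and reports the
per-parameter recovery errors across seeds.  Writes results/threshold_recovery.csv.
"""

from pathlib import Path

from rdpi.experiments import threshold_recovery


def main():
    out = Path("results/threshold_recovery.csv")
    out.parent.mkdir(parents=True, exist_ok=True)
    df = threshold_recovery(n_seeds=20, label_noise=0.05, seed=0)
    df.to_csv(out, index=False, float_format="%.6g")
    errs = df[["T1_err", "T2_err", "tau_bra_err", "tau_cdx2_err"]]
    print(df.describe().loc[["mean", "std", "min", "max"]].to_string())
    print("\nmax |error| per parameter:", errs.abs().max().to_dict())
    print("grid steps: T 0.05 a.u., tau 4 h")
    print(f"mean agreement with noisy labels: {df.agreement.mean():.3f} "
          "(5% of labels were randomized)")


if __name__ == "__main__":
    main()
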