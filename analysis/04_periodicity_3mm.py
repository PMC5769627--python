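#!/usr/bin/env python
"""Fourier periodicity of 3 mm colonies: dose-gated RD-like patterning.

Simulates 3 mm colonies at the standard and at a 4x BMP4 dose, quantifies
the dominant period along 12 radii of the terminal activator field, compares
the two period distributions (Mann-Whitney U, Kolmogorov-Smirnov), and
reports the detector's own noise-null so the periodic call is calibrated.
Writes period tables under results/periods/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from rdpi.experiments import noise_null_fraction
from rdpi.periodicity import compare_period_sets, field_periods
from rdpi.rd import DEFAULT_PARAMS, BoundaryCondition, Domain, InitialCondition, simulate

OUT = Path("results/periods")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    sets = {}
    rows = []
    for dose in (50.0, 200.0):
        res = simulate(DEFAULT_PARAMS, Domain(3000.0, 20.0), BoundaryCondition(bmpi=dose),
                       InitialCondition(noise_rel=0.05, seed=3), 24.0, 0.02)
        ps = field_periods(res.terminal, source="model", field_id=f"dose_{dose:g}")
        sets[dose] = ps
        for ang, per in zip(ps.angles_deg, ps.periods):
            rows.append({"dose_ng_ml": dose, "angle_deg": ang, "period": per,
                         "classified_periodic": bool(per <= 1.0)})
        print(f"3 mm, {dose:g} ng/ml: fraction of radii periodic "
              f"{np.mean(ps.periods <= 1):.2f}, median period "
              f"{np.median(ps.periods):.3g}")
    pd.DataFrame(rows).to_csv(OUT / "periods_3mm.csv", index=False,
                              float_format="%.6g")

    stats = compare_period_sets(sets[50.0], sets[200.0])
    pd.DataFrame([stats]).to_csv(OUT / "period_comparison.csv", index=False,
                                 float_format="%.6g")
    print(f"low vs high dose period distributions: MWU p={stats['mwu_p']:.3g}, "
          f"KS D={stats['ks_D']:.3g} (p={stats['ks_p']:.3g})")

    null = noise_null_fraction(n_fields=50, source="model", seed=0)
    pd.DataFrame({"aperiodic_fraction": null["per_field"]}).to_csv(
        OUT / "noise_null.csv", index=False)
    print(f"noise-null aperiodic fraction (50 fields): "
          f"{null['mean_aperiodic_fraction']:.2f} - the per-radius period>1 "
          "rule has a high chance rate on unstructured noise, so periodic "
          "calls are made against this simulated null")


if __name__ == "__main__":
    main()
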