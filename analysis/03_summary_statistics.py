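#!/usr/bin/env python
"""Campaign statistics: descriptives, variance split, ANOVA, regressions.

Reads the simulated campaign and its risk report (run 01 and 02 first)
and reproduces the study-style statistical analysis: a per-chemical
descriptive table (AM/median/range/GM/GSD plus max HQ), the
between-/within-salon variance decomposition of exposure, one-way ANOVA
with Bonferroni pairwise comparisons of salon HI means, and OLS
regressions HI ~ TVOC and CO₂ ~ TVOC.

Usage: python analysis/03_summary_statistics.py
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from vocmix import (
    anova_oneway,
    compute_tvoc,
    hazard_index,
    load_table3_registry,
    ols_fit,
    pooled_between_fraction,
    read_climate,
    read_measurements,
    summarize_chemicals,
    variance_components,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    meas = RESULTS / "campaign_measurements.csv"
    if not meas.exists():
        sys.exit("missing results/campaign_measurements.csv — run 01_simulate_campaign.py first")

    registry = load_table3_registry()
    samples = read_measurements(meas)
    table = summarize_chemicals(samples, registry)
    table.to_csv(RESULTS / "chemical_summary.csv", index=False)
    print(f"chemical summary: {len(table)} chemicals -> chemical_summary.csv")

    results = [hazard_index(s, registry) for s in samples]
    hi_by_salon: dict[str, list] = {}
    tvoc_by_salon: dict[str, list] = {}
    for s, r in zip(samples, results):
        hi_by_salon.setdefault(s.salon_id, []).append(r.hi)
        tvoc_by_salon.setdefault(s.salon_id, []).append(compute_tvoc(s))

    vc = variance_components(tvoc_by_salon)
    print(
        f"TVOC variance split: between-salon {vc.between_frac:.0%}, "
        f"within-salon {vc.within_frac:.0%}"
    )
    pooled = pooled_between_fraction(samples)
    print(f"pooled per-chemical log-scale between-salon share: {pooled:.0%}")

    anova = anova_oneway(
        list(hi_by_salon.values()), pairwise=True, labels=list(hi_by_salon)
    )
    print(
        f"one-way ANOVA of HI across salons: F({anova.df[0]}, {anova.df[1]}) = "
        f"{anova.f:.2f}, P = {anova.p_value:.3g}"
    )
    sig = anova.pairwise[anova.pairwise["p_bonferroni"] < 0.05]
    print(f"  Bonferroni pairwise comparisons below 0.05: {len(sig)} of {len(anova.pairwise)}")
    anova.pairwise.to_csv(RESULTS / "anova_pairwise.csv", index=False)

    tvoc = [compute_tvoc(s) for s in samples]
    hi = [r.hi for r in results]
    fit = ols_fit(tvoc, hi)
    print(
        f"OLS HI ~ TVOC: beta = {fit.slope:.4g}, P = {fit.p_value:.3g}, "
        f"R^2 = {fit.r_squared:.2f}"
    )

    climate_path = RESULTS / "campaign_climate.csv"
    if climate_path.exists():
        climate = {r.salon_id: r for r in read_climate(climate_path)}
        x = [climate[s].co2_ppm for s in tvoc_by_salon]
        y = [float(np.mean(v)) for v in tvoc_by_salon.values()]
        fit2 = ols_fit(x, y)
        print(
            f"OLS salon TVOC ~ CO2: beta = {fit2.slope:.3g}, P = {fit2.p_value:.3g}, "
            f"R^2 = {fit2.r_squared:.2f}"
        )

    pd.DataFrame(
        {
            "salon_id": list(hi_by_salon),
            "mean_hi": [float(np.mean(v)) for v in hi_by_salon.values()],
            "mean_tvoc": [float(np.mean(v)) for v in tvoc_by_salon.values()],
        }
    ).to_csv(RESULTS / "salon_means.csv", index=False)
    print("written: chemical_summary.csv, anova_pairwise.csv, salon_means.csv")


if __name__ == "__main__":
    main()
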