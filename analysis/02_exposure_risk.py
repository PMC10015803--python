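#!/usr/bin/env python
"""Exposure-risk assessment of the simulated campaign.

Reads results/campaign_measurements.csv (run 01_simulate_campaign.py
first), resolves every analyte through the packaged limit-value registry,
and computes per-worker and per-salon TVOC, hazard index, maximum hazard
quotient, maximum cumulative ratio, and MCR substance groups. Writes the
full risk report (plus HQ breakdown) under results/ and prints the
campaign headline numbers.

Usage: python analysis/02_exposure_risk.py
"""

import statistics
import sys
from pathlib import Path

from vocmix import (
    RunConfig,
    classify_cohort,
    hazard_index,
    load_table3_registry,
    read_measurements,
    registry_coverage,
    salon_aggregate,
    write_report,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    meas = RESULTS / "campaign_measurements.csv"
    if not meas.exists():
        sys.exit("missing results/campaign_measurements.csv — run 01_simulate_campaign.py first")

    config = RunConfig()
    registry = load_table3_registry()
    samples = read_measurements(meas, config.reporting_limits)
    sample_results = [hazard_index(s, registry, config) for s in samples]

    by_salon: dict[str, list] = {}
    for res in sample_results:
        by_salon.setdefault(res.salon_id, []).append(res)
    salon_results = [salon_aggregate(rs, config) for rs in by_salon.values()]

    write_report(sample_results + salon_results, RESULTS / "risk_report.csv", config)

    his = sorted(r.hi for r in sample_results)
    tvocs = sorted(r.tvoc for r in sample_results)
    print(f"{len(samples)} worker-shifts, {len(salon_results)} salons")
    print(
        f"  TVOC µg/m³: median {statistics.median(tvocs):.0f}, "
        f"range {tvocs[0]:.0f}-{tvocs[-1]:.0f}"
    )
    print(
        f"  HI: median {statistics.median(his):.2f}, range {his[0]:.4f}-{his[-1]:.3g}; "
        f"{sum(r.risk_flag for r in sample_results)} of {len(samples)} workers at HI >= 1"
    )
    cov = registry_coverage(samples, registry)
    print(
        f"  registry coverage: {cov.n_chemicals - cov.n_unresolved} of "
        f"{cov.n_chemicals} detected chemicals resolved; unresolved excluded from HI"
    )

    cohort = classify_cohort(sample_results + salon_results, config)
    for scope in ("sample", "salon"):
        tally = cohort.tally(scope)
        parts = ", ".join(f"{g.value}: {n}" for g, n in sorted(tally.items()))
        print(f"  {scope} substance groups — {parts}")
    concern = {
        c.name
        for _, _, group, chems in cohort.assignments
        for c in chems
        if group.value in ("I", "IIIA", "IIIB")
    }
    if concern:
        print(f"  substances of concern: {', '.join(sorted(concern))}")
    print("  written: risk_report.csv, risk_report_hq.csv")


if __name__ == "__main__":
    main()
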