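#!/usr/bin/env python
"""Paired disease statistics and correlation analysis over the cohort.

Aggregates the per-condition summaries from 03_calibrate_cohort.py,
runs the a-priori one-sided paired t-tests (stiffness, resistances and
mPAP/PVR up; compliance and TAWSS down; phi up), and computes Pearson
correlations of the per-subject relative changes. Writes the cohort
table, test results, and correlation matrix under results/stats/.
"""

import json
from pathlib import Path

from pulmo1d.stats import (
    cohort_table,
    paired_tests,
    relative_change_correlations,
)

ROOT = Path(__file__).resolve().parents[1] / "results"
SUMMARIES = ROOT / "summaries"
OUT = ROOT / "stats"

CORR_COLUMNS = [
    "mpap", "r_prox_total", "r_dist_total", "c_total", "stiffness",
    "tawss_MPA", "tawss_LPA", "tawss_RPA", "tawss_intralobar",
    "osi_LPA", "osi_intralobar", "phi",
]


def main() -> None:
    summaries = []
    for f in sorted(SUMMARIES.glob("S*_*.json")):
        with open(f) as fh:
            s = json.load(fh)
        s.pop("timings", None)
        summaries.append(s)
    cohort = cohort_table(summaries)
    tests = paired_tests(cohort)
    corr, mask = relative_change_correlations(cohort,
                                              columns=CORR_COLUMNS)

    OUT.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(OUT / "cohort.csv")
    tests.to_csv(OUT / "paired_tests.csv")
    corr.round(3).to_csv(OUT / "correlations.csv")
    mask.to_csv(OUT / "correlations_strong.csv")

    print("paired one-sided t-tests (baseline -> CTEPH):")
    print(tests.round(4).to_string())
    strong = [
        (a, b, round(corr.loc[a, b], 2))
        for a in corr.index for b in corr.columns
        if a < b and bool(mask.loc[a, b])
    ]
    print(f"\nstrong correlations of relative changes (|r| > 0.8): "
          f"{strong if strong else 'none'}")
    print(f"-> {OUT}")


if __name__ == "__main__":
    main()
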