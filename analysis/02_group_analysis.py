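#!/usr/bin/env python
"""Group statistics on the extracted cohort tables.

Reads the tables written by 01_simulate_and_extract.py and produces the full
report: questionnaire and behavioural group contrasts (Kruskal-Wallis),
mixed-logistic error models (odds ratios per error type), ERP group
contrasts, the Spearman correlation matrix between CP Go P3 measures and the
questionnaire scales, and both biomarker regression pairs
(BBI-15 / MI ~ P3 amplitude + latency, and ~ P3 amplitude + IPL).

Writes results/analysis/summary.json and prints the headline findings.
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from burnout_erp.group_stats import run_full_analysis
from burnout_erp.reporting import read_table, report_to_json

COHORT = os.path.join(os.path.dirname(__file__), "..", "results", "cohort")
OUT = os.path.join(os.path.dirname(__file__), "..", "results", "analysis")


def main():
    measurements = read_table(os.path.join(COHORT, "measurements.tsv"))
    profiles = read_table(os.path.join(COHORT, "profiles.tsv"))
    outcomes = read_table(os.path.join(COHORT, "outcomes.tsv"))
    behavior = read_table(os.path.join(COHORT, "behavior.tsv"))

    report = run_full_analysis(measurements, profiles, outcomes=outcomes,
                               behavior=behavior)
    os.makedirs(OUT, exist_ok=True)
    report_to_json(report, os.path.join(OUT, "summary.json"))

    print("questionnaire contrasts (Kruskal-Wallis):")
    print(report["questionnaires"].round(3).to_string(index=False))
    print("\nERP group contrasts:")
    print(report["erp_contrasts"].round(3).to_string(index=False))
    amp = report["erp_contrasts"].set_index("measure").loc["CP P3 Go amplitude"]
    direction = ">" if amp["median_burnout"] > amp["median_non_burnout"] else "<="
    print(f"\nCP P3 Go amplitude: burnout median {direction} non-burnout median")
    print("\ncorrelations (rho, CP Go P3 measures x questionnaires):")
    print(report["correlations"].round(3).to_string(index=False))
    print("\nbiomarker regressions:")
    for name, s in report["regressions"].items():
        print(f"  {name}: R2={s.r_squared:.3f} adjR2={s.adj_r_squared:.3f} "
              f"F({s.df1},{s.df2})={s.f_statistic:.2f} p={s.p_value:.4f}")
    if report["flags"]:
        print("\nflags:", report["flags"])
    print(f"\nsummary written to {os.path.abspath(OUT)}/summary.json")


if __name__ == "__main__":
    main()
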