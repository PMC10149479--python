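"""Validation of CMA against viral non-suppression (ROC/AUC).

For each lookback window (1, 3, 6, 12 months) pairs every viral-load
test with the preceding CMA and reports the cluster-bootstrap AUC at
the primary threshold (400 copies/mL), writing results/validation.csv.

Usage: python analysis/04_validate_cma.py [seed]
"""

import sys

sys.path.insert(0, "src")

from hivcma import claims_io, pipeline, validation

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 42

tables = claims_io.read_tables("results/cohort")
elig = claims_io.apply_eligibility(tables)
sup = elig.cohort[elig.cohort["patient_id"].isin(elig.analysis_ids["suppression"])]
daily = pipeline._daily_by_patient(tables, sup, claims_io.load_ddd_table())

table = validation.auc_by_window(daily, sup, tables.labs,
                                 windows=(1, 3, 6, 12), n_boot=500, seed=seed)
table.to_csv("results/validation.csv", index=False)
print(table[["window_months", "auc", "ci_low", "ci_high", "n_tests", "n_patients"]]
      .round(3).to_string(index=False))
best = table.loc[table["auc"].idxmax()]
print(f"\nlongest lookback discriminates best: {int(best.window_months)}-month AUC "
      f"{best.auc:.2f} (95% CI {best.ci_low:.2f}-{best.ci_high:.2f})")
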