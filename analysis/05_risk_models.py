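"""Risk-ratio models: non-adherence, viral non-suppression, mediation,
trajectory-group membership, and marginal predictions.

Builds the person-period and per-test tables, fits the modified Poisson
models (cluster-robust SEs) at increasing adjustment levels, the
CMA-mediation contrast, and the multinomial trajectory-group model;
writes tidy estimate tables to results/.

Usage: python analysis/05_risk_models.py
"""

import sys

sys.path.insert(0, "src")

import pandas as pd

from hivcma import claims_io, models, pipeline

tables = claims_io.read_tables("results/cohort")
elig = claims_io.apply_eligibility(tables)
timeline = claims_io.build_diagnosis_timeline(tables.diagnoses)
cma12 = pd.read_csv("results/cma_12m.csv",
                    parse_dates=["window_start", "window_end"])

adh = elig.cohort[elig.cohort["patient_id"].isin(elig.analysis_ids["adherence"])]
pp = models.build_person_period(adh, cma12, timeline)
fits = []
for tag, adj in [("unadjusted", "none"), ("adj-demographic", "demo"),
                 ("adj-comorbidity", "comorbid")]:
    fit = models.fit_rr_model(pp, models.rr_formula(adj), model_tag=tag)
    fits.append(fit.estimates.assign(model=tag))
rr_na = pd.concat(fits, ignore_index=True)
rr_na.to_csv("results/rr_nonadherence.csv", index=False)
any_mh = models.term_rr(
    models.fit_rr_model(pp, models.rr_formula("demo")), "mh_any")
print(f"non-adherence, any diagnosis (demographics-adjusted): "
      f"RR {any_mh['rr']:.2f} ({any_mh['ci_low']:.2f}-{any_mh['ci_high']:.2f})")

sup = elig.cohort[elig.cohort["patient_id"].isin(elig.analysis_ids["suppression"])]
daily = pipeline._daily_by_patient(tables, sup, claims_io.load_ddd_table())
vns = models.build_vns_table(sup, daily, tables.labs, timeline)
vfit = models.fit_rr_model(vns, models.rr_formula("demo"), model_tag="adj-demographic")
vfit.estimates.assign(model="adj-demographic").to_csv("results/rr_vns.csv", index=False)

med = models.mediation_by_cma(vns)
med.to_csv("results/mediation.csv", index=False)
print("\nmediation of VNS risk by adherence (CMA):")
print(med[["category", "rr_unmediated", "rr_cma_adjusted", "fully_mediated"]]
      .round(2).to_string(index=False))

pred = models.marginal_predictions(vfit, vns, at_period=2)
pred.to_csv("results/vns_predictions_2y.csv", index=False)

assign = pd.read_csv("results/trajectory_assignments.csv", dtype={"patient_id": str})
grp = assign.merge(elig.cohort[["patient_id", "sex", "birth_date", "baseline"]],
                   on="patient_id")
grp["age_group"] = models.age_to_group(
    (grp["baseline"] - grp["birth_date"]).dt.days / 365.25)
flags = claims_io.exposure_flags(timeline, grp["patient_id"], grp["baseline"])
grp["mh_baseline"] = flags["mh_any"].to_numpy().astype(int)
grp = grp.rename(columns={"label": "group"})
rrr, gpred, _ = models.fit_multinomial_groups(grp)
rrr.to_csv("results/trajectory_rrr.csv", index=False)
gpred.to_csv("results/trajectory_group_probabilities.csv", index=False)
mh_row = rrr[(rrr.group == "continuous_non_adherence") & (rrr.term == "mh_baseline")]
if len(mh_row):
    r = mh_row.iloc[0]
    print(f"\nbaseline diagnosis -> continuous non-adherence group: "
          f"RRR {r['rrr']:.2f} ({r['ci_low']:.2f}-{r['ci_high']:.2f})")
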