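"""Person-period construction and modified Poisson / multinomial models."""

import numpy as np
import pandas as pd
import pytest

from hivcma import models, synth
from hivcma.claims_io import build_diagnosis_timeline
from hivcma.models import (
    age_to_group,
    build_person_period,
    cma_decile_category,
    fit_multinomial_groups,
    fit_rr_model,
    marginal_predictions,
    mediation_by_cma,
    rr_formula,
    term_rr,
)


def test_age_groups_are_left_closed():
    got = age_to_group(np.array([15.0, 19.99, 20.0, 24.9, 25.0, 34.99, 44.0, 54.0, 64.0, 65.0, 80.0]))
    assert list(got) == ["15-19", "15-19", "20-24", "20-24", "25-34", "25-34",
                         "35-44", "45-54", "55-64", "65+", "65+"]


def test_cma_decile_categories():
    got = cma_decile_category(np.array([1.0, 0.999, 0.95, 0.80, 0.001, 0.0, 0.55]))
    assert list(got) == ["100", "90-99", "90-99", "80-89", "0-9", "0-9", "50-59"]


def _cohort_frame():
    return pd.DataFrame({
        "patient_id": ["A"],
        "sex": ["female"],
        "birth_date": [pd.Timestamp("1991-02-01")],
        "baseline": [pd.Timestamp("2016-01-01")],
    })


def test_person_period_covariate_timing():
    """A diagnosis arriving mid-period-2 flips the flag only from period 3
    (flags are evaluated at period start); the first window is period 1."""
    cma = pd.DataFrame({
        "patient_id": ["A"] * 3,
        "window_index": [0, 1, 2],
        "window_start": pd.to_datetime(["2016-01-01", "2017-01-01", "2018-01-01"]),
        "window_end": pd.to_datetime(["2017-01-01", "2018-01-01", "2019-01-01"]),
        "cma_value": [0.9, 0.7, 0.85],
    })
    dx = pd.DataFrame({
        "patient_id": ["A"], "diagnosis_date": [pd.Timestamp("2017-06-15")],
        "icd10_code": ["F32"], "setting": ["outpatient"],
    })
    pp = build_person_period(_cohort_frame(), cma, build_diagnosis_timeline(dx))
    pp = pp.sort_values("period_index")
    assert list(pp["period_index"]) == [1, 2, 3]
    assert list(pp["mh_depression"]) == [False, False, True]
    assert list(pp["outcome"]) == [0, 1, 0]  # CMA<0.8 only in period 2
    # aged 24y11m at first period start -> 20-24
    assert pp["age_group"].iloc[0] == "20-24"


def test_rr_reference_levels_absent_from_estimates():
    df = synth.simulate_person_period(800, rr=1.3, seed=0)
    fit = fit_rr_model(df, rr_formula("demo"))
    assert not fit.estimates["term"].str.contains("[T.25-34]", regex=False).any()
    assert not fit.estimates["term"].str.contains("[T.female]", regex=False).any()
    assert (fit.estimates["ci_low"] <= fit.estimates["rr"]).all()
    assert (fit.estimates["rr"] <= fit.estimates["ci_high"]).all()


def test_rr_recovery_and_null_validity():
    df = synth.simulate_person_period(6000, rr=1.5, seed=4)
    r = term_rr(fit_rr_model(df, "outcome ~ mh_any"), "mh_any")
    assert r["rr"] == pytest.approx(1.5, abs=0.12)
    null = synth.simulate_person_period(6000, rr=1.0, seed=5)
    rn = term_rr(fit_rr_model(null, "outcome ~ mh_any"), "mh_any")
    assert rn["ci_low"] <= 1.0 <= rn["ci_high"]


def test_rr_invariant_to_relabelling_and_row_order():
    df = synth.simulate_person_period(1500, rr=1.4, seed=8)
    base = term_rr(fit_rr_model(df, "outcome ~ mh_any"), "mh_any")
    shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
    shuffled["patient_id"] = "X" + shuffled["patient_id"]
    alt = term_rr(fit_rr_model(shuffled, "outcome ~ mh_any"), "mh_any")
    assert base["rr"] == pytest.approx(alt["rr"], rel=1e-9)
    assert base["robust_se"] == pytest.approx(alt["robust_se"], rel=1e-9)


def test_sandwich_variance_exceeds_model_based_under_clustering():
    df = synth.simulate_person_period(3000, rr=1.2, frailty_sd=0.7, periods=4, seed=2)
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    naive = smf.glm("outcome ~ mh_any", df, family=sm.families.Poisson()).fit()
    robust = fit_rr_model(df, "outcome ~ mh_any")
    assert term_rr(robust, "mh_any")["robust_se"] > naive.bse["mh_any"]


def test_rr_ci_coverage_under_null_and_effect():
    hits = {1.0: 0, 1.5: 0}
    n_rep = 40
    for rr0 in hits:
        for i in range(n_rep):
            df = synth.simulate_person_period(800, rr=rr0, seed=1000 + i)
            r = term_rr(fit_rr_model(df, "outcome ~ mh_any"), "mh_any")
            hits[rr0] += r["ci_low"] <= rr0 <= r["ci_high"]
    for rr0, h in hits.items():
        assert h / n_rep >= 0.85, f"coverage for RR={rr0}: {h}/{n_rep}"


def test_too_few_clusters_rejected():
    df = synth.simulate_person_period(50, seed=0)
    df["patient_id"] = "same"
    with pytest.raises(ValueError, match="clusters"):
        fit_rr_model(df, "outcome ~ mh_any")


def test_mediation_indirect_vs_direct():
    ind = mediation_by_cma(synth.simulate_mediation(3000, direct_rr=1.0, seed=3))
    su = ind[ind.category == "substance_use"].iloc[0]
    assert su["rr_unmediated"] > 1.3  # strong crude association via CMA
    assert su["fully_mediated"]
    dirm = mediation_by_cma(synth.simulate_mediation(3000, direct_rr=1.8, seed=3))
    sd = dirm[dirm.category == "substance_use"].iloc[0]
    assert not sd["fully_mediated"]
    assert sd["rr_cma_adjusted"] > 1.2


def test_cma_gradient_monotone_in_planted_data():
    df = synth.simulate_mediation(6000, direct_rr=1.0, seed=9)
    fit = fit_rr_model(df, "outcome ~ C(cma_decile, Treatment('100'))")
    est = fit.estimates.set_index("term")["rr"]
    order = ["90-99", "70-79", "50-59", "30-39", "10-19"]
    vals = [est[[t for t in est.index if f"[T.{lev}]" in t][0]] for lev in order]
    assert all(a < b for a, b in zip(vals, vals[1:]))


def test_marginal_predictions_null_model_equal_marginal_rate():
    df = synth.simulate_person_period(2000, rr=1.0, seed=6)
    fit = fit_rr_model(df, "outcome ~ 1")
    pred = marginal_predictions(fit, df, at_period=2, by=("sex",))
    marginal = df["outcome"].mean()
    assert np.allclose(pred["prediction"], marginal, atol=1e-9)


def test_marginal_predictions_spread_tracks_effect_size():
    strong = synth.simulate_person_period(4000, rr=2.5, seed=7)
    weak = synth.simulate_person_period(4000, rr=1.1, seed=7)
    fs = fit_rr_model(strong, "outcome ~ mh_any")
    fw = fit_rr_model(weak, "outcome ~ mh_any")
    ps = marginal_predictions(fs, strong, by=("mh_any",))["prediction"]
    pw = marginal_predictions(fw, weak, by=("mh_any",))["prediction"]
    assert (ps.max() - ps.min()) > (pw.max() - pw.min())


def _group_data(n=6000, planted=2.0, seed=0):
    rng = np.random.default_rng(seed)
    mh = (rng.random(n) < 0.3).astype(int)
    names = list(synth.CLASS_NAMES)
    base = np.array([0.0, -1.7, -2.4, -2.3])
    z = np.tile(base, (n, 1))
    z[:, 3] += np.log(planted) * mh
    p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
    gidx = (rng.random(n)[:, None] > p.cumsum(axis=1)).sum(axis=1)
    return pd.DataFrame({
        "group": np.asarray(names, dtype=object)[gidx],
        "mh_baseline": mh,
        "age_group": rng.choice(np.asarray(models.AGE_GROUPS, dtype=object), n),
        "sex": rng.choice(["male", "female"], n),
    })


def test_multinomial_recovers_planted_group_effect():
    rrr, pred, _ = fit_multinomial_groups(_group_data(n=10000, planted=2.0))
    row = rrr[(rrr.group == "continuous_non_adherence") & (rrr.term == "mh_baseline")]
    assert row["rrr"].iloc[0] == pytest.approx(2.0, abs=0.3)
    names = list(synth.CLASS_NAMES)
    assert np.allclose(pred[names].sum(axis=1), 1.0)


def test_multinomial_null_model_returns_observed_shares():
    df = _group_data(n=3000, planted=1.0)
    _, pred, _ = fit_multinomial_groups(df, formula_rhs="1")
    shares = df["group"].value_counts(normalize=True)
    for name in synth.CLASS_NAMES:
        assert pred[name].iloc[0] == pytest.approx(shares[name], abs=1e-6)


def test_multinomial_missing_reference_rejected():
    df = _group_data(n=500)
    df = df[df.group != "continuous_high"]
    with pytest.raises(ValueError, match="reference"):
        fit_multinomial_groups(df)
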