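"""Risk-ratio models for non-adherence and viral non-suppression.

The regression substrate is a person-period table: one row per patient
per complete 12-month CMA window (adherence outcome) or per viral-load
test (VNS outcome), with time-varying covariates — mental-health
diagnosis flags, age group, and year since baseline (rounded up to the
next integer and modelled categorically).

Risk ratios come from a modified Poisson fit: a log-link Poisson working
model for the binary outcome with a patient-clustered sandwich variance
("robust" standard errors) and Wald 95% CIs on the log scale.  A
patient-level random-intercept variant (variational Bayes) sits behind a
flag, but the cluster-robust fit governs reported intervals.  Mediation
by adherence is assessed by re-fitting the VNS model with the 11-level
CMA category (100, 90-99, ..., 0-9) and comparing the exposure RRs.
Trajectory-group membership is modelled with multinomial logistic
regression (relative risk ratios against the continuous-high group).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
import statsmodels.formula.api as smf

from hivcma.claims_io import MH_CATEGORIES, exposure_flags
from hivcma.validation import lookback_cma

AGE_GROUPS = ("15-19", "20-24", "25-34", "35-44", "45-54", "55-64", "65+")
AGE_REF = "25-34"
_AGE_EDGES = (15, 20, 25, 35, 45, 55, 65, np.inf)

#: CMA categories of the mediation adjustment, highest first.
CMA_DECILES = ("100", "90-99", "80-89", "70-79", "60-69", "50-59",
               "40-49", "30-39", "20-29", "10-19", "0-9")


def age_to_group(age_years: float | np.ndarray) -> np.ndarray:
    """Map age in years to the seven study age groups."""
    idx = np.digitize(np.asarray(age_years, dtype=float), _AGE_EDGES[1:-1])
    return np.asarray(AGE_GROUPS, dtype=object)[idx]


def cma_decile_category(cma: float | np.ndarray) -> np.ndarray:
    """11-level CMA category: exactly 100%, then 10-point bands down to 0-9."""
    pct = np.asarray(cma, dtype=float) * 100.0
    dec = np.clip(np.floor(pct / 10.0).astype(int), 0, 9)
    out = np.where(pct >= 100.0, "100",
                   np.char.add(np.char.add((dec * 10).astype(str), "-"),
                               (dec * 10 + 9).astype(str)))
    return out.astype(object)


# --------------------------------------------------------------------------
# Person-period construction


def build_person_period(
    cohort: pd.DataFrame,
    cma_12m: pd.DataFrame,
    timeline: pd.DataFrame,
    threshold_pct: int = 80,
) -> pd.DataFrame:
    """One row per complete 12-month CMA window with time-varying covariates.

    Outcome is non-adherence (CMA strictly below the threshold); age
    group and mental-health flags are evaluated at the window (period)
    start; ``period_index`` is the year since baseline (first window = 1).
    """
    df = cma_12m.merge(cohort[["patient_id", "sex", "birth_date", "baseline"]], on="patient_id")
    df["period_index"] = df["window_index"].astype(int) + 1
    age = (df["window_start"] - df["birth_date"]).dt.days / 365.25
    df["age_group"] = age_to_group(age)
    flags = exposure_flags(timeline, df["patient_id"], df["window_start"])
    df = pd.concat([df, flags], axis=1)
    df["outcome"] = (df["cma_value"] < threshold_pct / 100.0).astype(int)
    assert not df.duplicated(["patient_id", "period_index"]).any(), "overlapping periods"
    return df


def build_vns_table(
    cohort: pd.DataFrame,
    daily_by_patient: dict[str, np.ndarray],
    labs: pd.DataFrame,
    timeline: pd.DataFrame,
    vns_threshold: float = 400.0,
    lookback_months: int = 12,
) -> pd.DataFrame:
    """One row per viral-load test: VNS outcome plus covariates at test date.

    ``period_index`` is the year since baseline rounded up to the next
    integer (minimum 1); ``cma_decile`` is the 11-level category of the
    CMA over the 12-month lookback.  Tests without a fully observed
    lookback are dropped.
    """
    vl = labs[labs["test_type"] == "viral_load"].merge(
        cohort[["patient_id", "sex", "birth_date", "baseline", "followup_end"]], on="patient_id"
    )
    vl = vl[(vl["test_date"] >= vl["baseline"]) & (vl["test_date"] <= vl["followup_end"])]
    rows = []
    for r in vl.itertuples(index=False):
        daily = daily_by_patient.get(r.patient_id)
        if daily is None:
            continue
        day = int((r.test_date - r.baseline) / pd.Timedelta(days=1))
        cma = lookback_cma(daily, day, lookback_months)
        if cma is None:
            continue
        rows.append((r.patient_id, r.test_date, day, r.sex, r.birth_date, r.value, cma))
    df = pd.DataFrame(
        rows, columns=["patient_id", "test_date", "day", "sex", "birth_date", "value", "cma_before"]
    )
    if df.empty:
        return df
    df["outcome"] = (df["value"] >= vns_threshold).astype(int)
    df["period_index"] = np.maximum(1, np.ceil(df["day"] / 365.25).astype(int))
    age = (df["test_date"] - df["birth_date"]).dt.days / 365.25
    df["age_group"] = age_to_group(age)
    df["cma_decile"] = cma_decile_category(df["cma_before"].to_numpy())
    flags = exposure_flags(timeline, df["patient_id"], df["test_date"])
    return pd.concat([df, flags], axis=1)


# --------------------------------------------------------------------------
# Modified Poisson risk-ratio fit


@dataclass
class RRFit:
    """Tidy risk-ratio estimates plus the underlying statsmodels result."""

    estimates: pd.DataFrame  # term, rr, ci_low, ci_high, robust_se
    result: object
    model_tag: str = ""


def _demographic_terms() -> str:
    return (
        f"C(age_group, Treatment('{AGE_REF}'))"
        " + C(sex, Treatment('female'))"
        " + C(period_index)"
    )


def rr_formula(adjustment: str = "demo", exposure: str = "mh_any") -> str:
    """Model formula for a named adjustment set.

    ``none``: exposure only.  ``demo``: + age, sex, year since baseline.
    ``comorbid``: all six categories + demographics.  ``cma``: comorbid
    + the 11-level CMA category.
    """
    demo = _demographic_terms()
    comorbid = " + ".join(f"mh_{c}" for c in MH_CATEGORIES)
    if adjustment == "none":
        rhs = exposure
    elif adjustment == "demo":
        rhs = f"{exposure} + {demo}"
    elif adjustment == "comorbid":
        rhs = f"{comorbid} + {demo}"
    elif adjustment == "cma":
        rhs = f"{comorbid} + {demo} + C(cma_decile, Treatment('100'))"
    else:
        raise ValueError(f"unknown adjustment: {adjustment!r}")
    return f"outcome ~ {rhs}"


def fit_rr_model(
    table: pd.DataFrame,
    formula: str,
    cluster_col: str = "patient_id",
    random_intercept: bool = False,
    model_tag: str = "",
) -> RRFit:
    """Modified Poisson regression: log-link working model, sandwich SEs.

    ``random_intercept=True`` additionally fits a patient-level
    random-intercept Poisson model by variational Bayes and stores it as
    ``result_re``; reported CIs always come from the cluster-robust fit.
    """
    if table[cluster_col].nunique() < 2:
        raise ValueError("need at least two clusters for the sandwich variance")
    model = smf.glm(formula, table, family=sm.families.Poisson())
    res = model.fit(cov_type="cluster", cov_kwds={"groups": table[cluster_col]})
    if not getattr(res, "converged", True):
        raise RuntimeError(f"IRLS did not converge: {res.mle_retvals}")
    params, conf = res.params, res.conf_int()
    est = pd.DataFrame(
        {
            "term": params.index,
            "rr": np.exp(params.to_numpy()),
            "ci_low": np.exp(conf[0].to_numpy()),
            "ci_high": np.exp(conf[1].to_numpy()),
            "robust_se": res.bse.to_numpy(),
        }
    )
    fit = RRFit(estimates=est[est["term"] != "Intercept"].reset_index(drop=True),
                result=res, model_tag=model_tag)
    if random_intercept:
        from statsmodels.genmod.bayes_mixed_glm import PoissonBayesMixedGLM

        vc = {"patient": f"0 + C({cluster_col})"}
        re_model = PoissonBayesMixedGLM.from_formula(formula, vc, table)
        fit.result_re = re_model.fit_vb()
    return fit


def term_rr(fit: RRFit, contains: str) -> pd.Series:
    """First estimate row whose term name contains the given fragment."""
    hits = fit.estimates[fit.estimates["term"].str.contains(contains, regex=False)]
    if hits.empty:
        raise KeyError(f"no term containing {contains!r}")
    return hits.iloc[0]


# --------------------------------------------------------------------------
# Mediation by CMA


def mediation_by_cma(
    vns_table: pd.DataFrame,
    categories: tuple[str, ...] = MH_CATEGORIES,
) -> pd.DataFrame:
    """Attenuation of mental-health VNS risk ratios after CMA adjustment.

    Fits the comorbidity-adjusted model with and without the 11-level
    CMA category and reports, per diagnosis category, both RRs, the
    log-RR attenuation ratio, and whether the CMA-adjusted CI includes 1
    ("fully mediated").
    """
    base = fit_rr_model(vns_table, rr_formula("comorbid"), model_tag="adj-comorbidity")
    adj = fit_rr_model(vns_table, rr_formula("cma"), model_tag="adj-cma")
    rows = []
    for c in categories:
        b = term_rr(base, f"mh_{c}")
        a = term_rr(adj, f"mh_{c}")
        lb, la = np.log(b["rr"]), np.log(a["rr"])
        rows.append(
            {
                "category": c,
                "rr_unmediated": b["rr"],
                "ci_low_unmediated": b["ci_low"],
                "ci_high_unmediated": b["ci_high"],
                "rr_cma_adjusted": a["rr"],
                "ci_low_cma_adjusted": a["ci_low"],
                "ci_high_cma_adjusted": a["ci_high"],
                "attenuation": (1.0 - la / lb) if abs(lb) > 1e-12 else np.nan,
                "fully_mediated": bool(a["ci_low"] <= 1.0 <= a["ci_high"]),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Marginal (standardised) predictions


def marginal_predictions(
    fit: RRFit,
    table: pd.DataFrame,
    at_period: int = 2,
    by: tuple[str, ...] = ("age_group", "sex", "mh_any"),
) -> pd.DataFrame:
    """Standardised outcome predictions at a fixed year since baseline.

    Within each stratum of ``by``, every observed row is moved to
    ``period_index = at_period``, predicted under the fitted model, and
    the predictions averaged; CIs use the delta method on the averaged
    mean.  Empty strata are omitted.
    """
    res = fit.result
    design_info = res.model.data.design_info
    cov = np.asarray(res.cov_params())
    beta = res.params.to_numpy()
    rows = []
    for key, grp in table.groupby(list(by), observed=True):
        g = grp.copy()
        g["period_index"] = at_period
        try:
            X = np.asarray(patsy.dmatrix(design_info, g, return_type="matrix"))
        except patsy.PatsyError:
            continue
        if len(X) == 0:
            continue
        p = np.exp(X @ beta)
        pbar = p.mean()
        grad = (p[:, None] * X).mean(axis=0)
        se = float(np.sqrt(grad @ cov @ grad))
        key = key if isinstance(key, tuple) else (key,)
        rows.append(dict(zip(by, key)) | {
            "prediction": float(pbar),
            "ci_low": float(pbar - 1.96 * se),
            "ci_high": float(pbar + 1.96 * se),
            "n": len(g),
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Multinomial trajectory-group model


def fit_multinomial_groups(
    groups: pd.DataFrame,
    reference: str = "continuous_high",
    formula_rhs: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, object]:
    """Multinomial logit of trajectory-group membership on baseline covariates.

    ``groups`` needs columns group (pattern label), age_group, sex and
    mh_baseline (0/1 diagnosis at baseline).  The default linear
    predictor has categorical age, sex, baseline mental-health status
    and an age x sex interaction.  Returns (relative-risk-ratio table,
    predicted group probabilities per sex x age x mh stratum, result).
    """
    df = groups.copy()
    if reference not in set(df["group"]):
        raise ValueError(f"reference group {reference!r} absent")
    order = [reference] + sorted(set(df["group"]) - {reference})
    df["group_code"] = pd.Categorical(df["group"], categories=order).codes
    if formula_rhs is None:
        formula_rhs = (
            f"C(age_group, Treatment('{AGE_REF}')) * C(sex, Treatment('female'))"
            " + mh_baseline"
        )
    model = smf.mnlogit(f"group_code ~ {formula_rhs}", df)
    res = model.fit(method="newton", maxiter=200, disp=False)
    params = res.params  # columns: non-reference outcomes in order[1:]
    rrr_rows = []
    conf = res.conf_int()
    for j, grp_name in enumerate(order[1:]):
        # conf_int index level 0 is the outcome code as a string ("1", "2", ...)
        ci = conf.loc[str(j + 1)] if isinstance(conf.index, pd.MultiIndex) else conf
        for term in params.index:
            if term == "Intercept":
                continue
            rrr_rows.append(
                {
                    "group": grp_name,
                    "term": term,
                    "rrr": float(np.exp(params.loc[term, j])),
                    "ci_low": float(np.exp(ci.loc[term, "lower"])),
                    "ci_high": float(np.exp(ci.loc[term, "upper"])),
                }
            )
    rrr = pd.DataFrame(rrr_rows)

    strata = df[["age_group", "sex", "mh_baseline"]].drop_duplicates().reset_index(drop=True)
    probs = res.predict(strata)
    probs.columns = order
    pred = pd.concat([strata, probs], axis=1)
    return rrr, pred, res
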