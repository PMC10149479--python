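"""Synthetic claims cohorts with planted ground truth.

The generator emulates the statistical structure the analysis assumes:

* demographics with a female majority and adult age distribution;
* four latent adherence-behaviour classes (continuous high, decreasing,
  increasing, continuous non-adherence) whose probabilities depend on
  age group, sex and baseline mental-health status;
* a refill process driven by the class trajectory — refill gaps track
  30-day supply divided by current intended adherence, so early refills
  (stockpiling), growing gaps and interruptions all arise naturally;
* age- and sex-dependent mental-health diagnosis onset per ICD-10
  category, with follow-up diagnosis claims after onset;
* viral-load tests (labs available only from a configurable start date)
  whose non-suppression probability follows a planted log-link model in
  the 12-month lookback adherence decile, age group, sex and direct
  diagnosis effects.

Every cohort ships with its ground truth (behaviour class, intended
quarterly adherence trajectory, planted coefficients).  All randomness
flows from a single seed; identical seeds give byte-identical tables.

Two structural simulators bypass the claims layer for parameter-recovery
testing: :func:`simulate_person_period` plants an exact marginal risk
ratio with patient-level frailty, and :func:`simulate_mediation` plants
an exposure whose effect on viral non-suppression runs partly or wholly
through the adherence decile.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from hivcma.claims_io import ClaimsTables, MH_CATEGORIES
from hivcma.models import AGE_GROUPS, age_to_group, cma_decile_category

_MH_CODES = {
    "organic": ("F03", "F06.7"),
    "substance_use": ("F10.2", "F19.1"),
    "serious": ("F20.0", "F31.9", "F25.1"),
    "depression": ("F32.1", "F33.0", "F34.1"),
    "anxiety": ("F41.1", "F40.0", "F43.2"),
    "other": ("F30.1", "F50.0", "F90.0"),
}

#: Quarterly intended-adherence patterns over 5 years (20 quarters).
CLASS_PATTERNS = {
    "continuous_high": np.full(20, 0.95),
    "decreasing": np.linspace(0.95, 0.25, 20),
    "increasing": np.linspace(0.30, 0.90, 20),
    "continuous_non_adherence": np.full(20, 0.20),
}
CLASS_NAMES = tuple(CLASS_PATTERNS)


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic-cohort generator.

    Defaults encode the study-like scenario: cohort margins (female
    share, age distribution, per-category diagnosis prevalence),
    behaviour-class shares 0.73/0.13/0.06/0.07 with baseline-diagnosis
    and age multipliers, and a viral non-suppression model whose
    adherence-decile gradient runs from 1 (CMA 100%) to 15.89 (CMA
    0-9%).
    """

    n_patients: int = 1000
    seed: int = 0
    start_date: str = "2011-01-01"
    closure_date: str = "2020-06-30"
    lab_start_date: str = "2016-01-01"
    female_prob: float = 0.589
    age_mean: float = 40.1
    age_sd: float = 9.9
    age_min: float = 15.0
    followup_log_median_years: float = 1.2528  # ln(3.5)
    followup_log_sd: float = 0.90
    # mental health: latent ever-diagnosed indicator at the target "any"
    # prevalence; categories drawn with within-diagnosed prevalences so
    # that comorbidity (anxiety+depression co-occurrence) is preserved
    mh_any_prob: float = 0.381
    mh_within_prevalence: dict = field(default_factory=lambda: {
        "anxiety": 0.687, "depression": 0.530, "other": 0.166,
        "serious": 0.060, "organic": 0.024, "substance_use": 0.021,
    })
    mh_sex_multiplier: dict = field(default_factory=lambda: {"female": 1.13, "male": 0.84})
    mh_age_multiplier: dict = field(default_factory=lambda: {
        "15-19": 0.8, "20-24": 0.8, "25-34": 1.0, "35-44": 1.05,
        "45-54": 1.2, "55-64": 0.9, "65+": 0.8,
    })
    mh_visits_per_year: float = 2.0
    # behaviour classes
    # printed rounded shares 73/13/6/7% come from counts 23686/4152/2073/2343 of 32254
    class_shares: tuple = (23686 / 32254, 4152 / 32254, 2073 / 32254, 2343 / 32254)
    class_mh_multiplier: dict = field(default_factory=lambda: {
        "decreasing": 1.41, "increasing": 1.59, "continuous_non_adherence": 2.02,
    })
    class_age_multiplier: dict = field(default_factory=lambda: {
        "decreasing": {"15-19": 1.83, "20-24": 1.51, "35-44": 0.71,
                       "45-54": 0.54, "55-64": 0.55, "65+": 0.26},
        "increasing": {"15-19": 1.80, "20-24": 1.95, "35-44": 0.70,
                       "45-54": 0.49, "55-64": 0.49, "65+": 0.18},
        "continuous_non_adherence": {"15-19": 0.87, "20-24": 2.18, "35-44": 0.41,
                                     "45-54": 0.27, "55-64": 0.25, "65+": 0.28},
    })
    trajectory_noise_sd: float = 0.08
    # refill process
    supply_days: float = 30.0
    art_atc: str = "J05AR10"
    pills_per_claim: int = 30
    gap_noise_sd: float = 0.12  # lognormal sd of refill-gap noise
    # viral load process
    vl_rate_per_year: float = 1.5
    vns_base_prob: float = 0.04  # P(VNS) at CMA 100, female 25-34, no diagnoses
    vns_decile_rr: tuple = (1.0, 1.55, 2.26, 3.00, 3.58, 4.54,
                            5.41, 6.32, 7.24, 9.96, 15.89)
    vns_age_rr: dict = field(default_factory=lambda: {
        "15-19": 2.71, "20-24": 2.29, "25-34": 1.0, "35-44": 0.87,
        "45-54": 0.63, "55-64": 0.50, "65+": 0.41,
    })
    vns_male_rr: float = 1.47
    vns_mh_direct_rr: dict = field(default_factory=lambda: {
        "organic": 1.34, "substance_use": 1.03, "serious": 1.27,
        "depression": 1.11, "anxiety": 1.00, "other": 1.06,
    })
    cd4_rate_per_year: float = 0.8

    def validate(self) -> None:
        if abs(sum(self.class_shares) - 1.0) > 1e-6:
            raise ValueError("class_shares must sum to 1")
        if not 0.0 <= self.female_prob <= 1.0:
            raise ValueError("female_prob must be a probability")
        if len(self.vns_decile_rr) != 11:
            raise ValueError("vns_decile_rr needs 11 entries (100 down to 0-9)")
        for v in self.mh_within_prevalence.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError("mh_within_prevalence entries must be probabilities")


def study_scenario(**overrides) -> GeneratorConfig:
    """The documented study-like default configuration.

    Magnitudes encode the published cohort margins this package's report
    layouts follow: 38.1% any mental-health diagnosis (58.9% female,
    anxiety 26.2%, depression 20.2%), behaviour-class shares
    73/13/6/7%, a baseline-diagnosis multiplier of 2.02 on the
    continuous-non-adherence class, and a VNS adherence-decile gradient
    from 1.00 to 15.89.
    """
    return replace(GeneratorConfig(), **overrides)


@dataclass
class GroundTruth:
    """What the generator planted, for recovery testing."""

    patients: pd.DataFrame  # patient_id, behaviour_class, mh_baseline, q0..q19
    coefficients: dict


# --------------------------------------------------------------------------
# Helpers


def _raw_coverage(refill_days: np.ndarray, supply: float, total_days: int) -> np.ndarray:
    """Binary per-day coverage from an inventory walk with carryover."""
    cov = np.zeros(total_days)
    carry = 0.0
    ends = np.append(refill_days[1:], total_days)
    for start, end in zip(refill_days, ends):
        supply_in = supply + carry
        length = end - start
        covered = min(float(length), supply_in)
        carry = supply_in - covered
        whole = int(covered)
        cov[start : start + whole] = 1.0
        if whole < length and covered - whole > 0:
            cov[start + whole] = covered - whole
    return cov


def _interp_pattern(pattern: np.ndarray, day: np.ndarray | float) -> np.ndarray:
    """Intended adherence at arbitrary follow-up days (quarter grid)."""
    q = np.asarray(day, dtype=float) / 91.3125  # 365.25 / 4
    return np.interp(q, np.arange(20) + 0.5, pattern)


# --------------------------------------------------------------------------
# Cohort generation


def generate_cohort(config: GeneratorConfig) -> tuple[ClaimsTables, GroundTruth]:
    """Generate the four claims tables plus ground truth.

    Deterministic given ``config.seed``.  Baseline equals the first ART
    claim date by construction; every claim lies inside the configured
    date window and labs only after the lab-availability start.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    start = pd.Timestamp(config.start_date)
    closure = pd.Timestamp(config.closure_date)
    lab_start = pd.Timestamp(config.lab_start_date)
    n = config.n_patients

    pid = np.array([f"P{i:06d}" for i in range(n)])
    sex = np.where(rng.random(n) < config.female_prob, "female", "male")
    age0 = np.clip(rng.normal(config.age_mean, config.age_sd, n), config.age_min, 85.0)
    horizon = int((closure - start) / pd.Timedelta(days=1))
    baseline_off = rng.integers(0, horizon - 200, n)
    baseline = start + pd.to_timedelta(baseline_off, unit="D")
    fu_years = np.exp(rng.normal(config.followup_log_median_years, config.followup_log_sd, n))
    cover_end = baseline + pd.to_timedelta(np.maximum(60, (fu_years * 365.25)).astype(int), unit="D")
    followup_end = pd.Series(cover_end.where(cover_end <= closure, closure))
    cover_start = baseline - pd.to_timedelta(rng.integers(0, 730, n), unit="D")
    birth = baseline - pd.to_timedelta((age0 * 365.25).astype(int), unit="D")
    fu_days = ((followup_end - pd.Series(baseline)) / pd.Timedelta(days=1)).astype(int).to_numpy()
    agegrp = age_to_group(age0)

    # ---- mental-health onsets: latent ever-diagnosed indicator, then
    # per-category draws with within-diagnosed prevalences (anxiety acts
    # as fallback with an exact-margin correction so both the "any" and
    # the anxiety margins hit their targets)
    sexm = np.where(sex == "female", config.mh_sex_multiplier["female"],
                    config.mh_sex_multiplier["male"])
    agem = np.array([config.mh_age_multiplier[a] for a in agegrp])
    mult = sexm * agem
    mult = mult / mult.mean()  # centre so the population-average hits mh_any_prob
    ever_any = rng.random(n) < np.clip(config.mh_any_prob * mult, 0, 1)
    wp = config.mh_within_prevalence
    q_others = np.prod([1.0 - wp[c] for c in MH_CATEGORIES if c != "anxiety"])
    anx_adj = max(0.0, (wp["anxiety"] - q_others) / (1.0 - q_others)) if q_others < 1 else wp["anxiety"]
    cat_draw = {}
    for cat in MH_CATEGORIES:
        p = anx_adj if cat == "anxiety" else wp[cat]
        cat_draw[cat] = ever_any & (rng.random(n) < p)
    none_drawn = ever_any.copy()
    for cat in MH_CATEGORIES:
        none_drawn &= ~cat_draw[cat]
    cat_draw["anxiety"] |= none_drawn  # fallback keeps "any" margin exact
    onset_days: dict[str, np.ndarray] = {}
    for cat in MH_CATEGORIES:
        # onset anywhere from 2 years before baseline to follow-up end
        off = rng.uniform(-730, np.maximum(fu_days - 1, 1)).astype(int)
        onset_days[cat] = np.where(cat_draw[cat], off, 10**9)
    mh_baseline = np.zeros(n, dtype=bool)
    for cat in MH_CATEGORIES:
        mh_baseline |= onset_days[cat] <= 0

    # ---- behaviour classes
    shares = np.asarray(config.class_shares)
    weights = np.tile(shares, (n, 1))
    for j, cls in enumerate(CLASS_NAMES):
        mult = np.ones(n)
        if cls in config.class_mh_multiplier:
            mult = np.where(mh_baseline, config.class_mh_multiplier[cls], 1.0)
        agem = config.class_age_multiplier.get(cls, {})
        if agem:
            mult = mult * np.array([agem.get(a, 1.0) for a in agegrp])
        weights[:, j] *= mult
    weights /= weights.sum(axis=1, keepdims=True)
    # pin the population-average share of each class to class_shares while
    # keeping the relative covariate effects (a few IPF rounds)
    for _ in range(30):
        weights *= shares / weights.mean(axis=0)
        weights /= weights.sum(axis=1, keepdims=True)
    cum = weights.cumsum(axis=1)
    u = rng.random(n)
    cls_idx = (u[:, None] > cum).sum(axis=1)
    behaviour = np.asarray(CLASS_NAMES, dtype=object)[cls_idx]

    # ---- per-patient processes
    pharmacy_rows, dx_rows, lab_rows = [], [], []
    truth_rows = []
    log_decile_rr = np.log(np.asarray(config.vns_decile_rr))
    for i in range(n):
        fu = fu_days[i]
        pattern = CLASS_PATTERNS[behaviour[i]] + rng.normal(0, config.trajectory_noise_sd, 20)
        pattern = np.clip(pattern, 0.05, 1.0)

        # refill schedule: gap tracks supply / intended adherence
        days = [0]
        t = 0.0
        while True:
            a = float(_interp_pattern(pattern, t))
            gap = (config.supply_days / a) * np.exp(rng.normal(0, config.gap_noise_sd))
            t += max(7.0, gap)
            if t >= fu:
                break
            days.append(int(t))
        refills = np.unique(np.asarray(days, dtype=int))
        for d in refills:
            pharmacy_rows.append((pid[i], baseline_off[i] + d, config.art_atc,
                                  config.pills_per_claim, 600))

        # diagnosis claims from onset onwards (visit renewal process)
        for cat in MH_CATEGORIES:
            o = onset_days[cat][i]
            if o >= fu:
                continue
            visit = max(int(o), -int(baseline_off[i]))  # stay inside the date window
            codes = _MH_CODES[cat]
            first = True
            while visit < fu:
                if first or rng.random() < 0.8:
                    code = codes[rng.integers(0, len(codes))]
                    setting = "hospital" if rng.random() < 0.1 else "outpatient"
                    dx_rows.append((pid[i], baseline_off[i] + visit, code, setting))
                first = False
                visit += int(rng.exponential(365.25 / config.mh_visits_per_year)) + 1

        # viral-load tests
        lab_open = int(max(0, (lab_start - baseline[i]) / pd.Timedelta(days=1)))
        if lab_open < fu:
            cov = _raw_coverage(refills, config.supply_days, fu)
            cum_cov = np.concatenate([[0.0], np.cumsum(cov)])
            t = lab_open + rng.exponential(365.25 / config.vl_rate_per_year)
            while t < fu:
                d = int(t)
                lb = max(0, d - 365)
                cma12 = (cum_cov[d] - cum_cov[lb]) / max(1, d - lb)
                pct = cma12 * 100.0
                pos = 0 if pct >= 100.0 else 10 - min(9, int(pct // 10))
                loglin = (np.log(config.vns_base_prob)
                          + log_decile_rr[pos]
                          + np.log(config.vns_age_rr[agegrp[i]])
                          + (np.log(config.vns_male_rr) if sex[i] == "male" else 0.0))
                for cat in MH_CATEGORIES:
                    if onset_days[cat][i] <= d:
                        loglin += np.log(config.vns_mh_direct_rr[cat])
                p = min(0.95, np.exp(loglin))
                if rng.random() < p:
                    value = 400.0 * 10 ** rng.uniform(0, 2.0)
                else:
                    value = 10 ** rng.uniform(0, np.log10(399.0))
                lab_rows.append((pid[i], baseline_off[i] + d, "viral_load", round(value, 1)))
                t += rng.exponential(365.25 / config.vl_rate_per_year)
            # sparse CD4 results (schema completeness; unused in models)
            t = lab_open + rng.exponential(365.25 / max(config.cd4_rate_per_year, 1e-9))
            while t < fu:
                lab_rows.append((pid[i], baseline_off[i] + int(t), "cd4",
                                 float(max(10, int(rng.normal(500, 150))))))
                t += rng.exponential(365.25 / config.cd4_rate_per_year)

        truth_rows.append((pid[i], behaviour[i], bool(mh_baseline[i]), *pattern))

    def _dates(offsets):
        return start + pd.to_timedelta(offsets, unit="D")

    patients = pd.DataFrame({
        "patient_id": pid, "sex": sex, "birth_date": birth,
        "cover_start": cover_start, "cover_end": pd.Series(cover_end),
        "death_date": pd.NaT,
    })
    pharmacy = pd.DataFrame(pharmacy_rows, columns=[
        "patient_id", "day", "atc_code", "pills_dispensed", "strength_mg"])
    pharmacy["dispense_date"] = _dates(pharmacy.pop("day"))
    pharmacy = pharmacy[["patient_id", "dispense_date", "atc_code", "pills_dispensed", "strength_mg"]]
    diagnoses = pd.DataFrame(dx_rows, columns=["patient_id", "day", "icd10_code", "setting"])
    diagnoses["diagnosis_date"] = _dates(diagnoses.pop("day"))
    diagnoses = diagnoses[["patient_id", "diagnosis_date", "icd10_code", "setting"]]
    labs = pd.DataFrame(lab_rows, columns=["patient_id", "day", "test_type", "value"])
    labs["test_date"] = _dates(labs.pop("day"))
    labs = labs[["patient_id", "test_date", "test_type", "value"]]

    truth = pd.DataFrame(
        truth_rows,
        columns=["patient_id", "behaviour_class", "mh_baseline"] + [f"q{j}" for j in range(20)],
    )
    coeffs = {
        "class_shares": dict(zip(CLASS_NAMES, config.class_shares)),
        "class_mh_multiplier": dict(config.class_mh_multiplier),
        "vns_decile_rr": list(config.vns_decile_rr),
        "vns_age_rr": dict(config.vns_age_rr),
        "vns_male_rr": config.vns_male_rr,
        "vns_mh_direct_rr": dict(config.vns_mh_direct_rr),
        "vns_base_prob": config.vns_base_prob,
    }
    return ClaimsTables(patients, pharmacy, diagnoses, labs), GroundTruth(truth, coeffs)


# --------------------------------------------------------------------------
# Direct trajectory scenario (planted four-pattern matrices)


def generate_trajectories(
    n: int = 3000,
    shares: tuple = (23686 / 32254, 4152 / 32254, 2073 / 32254, 2343 / 32254),
    noise_sd: float = 0.08,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Planted four-pattern quarterly trajectory matrix.

    Draws classes i.i.d. from ``shares`` (order: continuous high,
    decreasing, increasing, continuous non-adherence), adds Gaussian
    noise and clips to [0, 1].  Returns (n x 20 matrix, true class
    labels as strings).
    """
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(CLASS_NAMES), size=n, p=np.asarray(shares))
    labels = np.asarray(CLASS_NAMES, dtype=object)[idx]
    base = np.stack([CLASS_PATTERNS[c] for c in labels])
    mat = np.clip(base + rng.normal(0, noise_sd, base.shape), 0.0, 1.0)
    return mat, labels


# --------------------------------------------------------------------------
# Structural simulators for parameter recovery


def simulate_person_period(
    n_patients: int,
    rr: float = 1.21,
    base_rate: float = 0.15,
    exposure_prev: float = 0.38,
    periods: int = 3,
    frailty_sd: float = 0.4,
    seed: int = 0,
) -> pd.DataFrame:
    """Person-period data with an exactly planted marginal risk ratio.

    Each patient carries a time-invariant binary exposure and a
    log-normal frailty with mean one; the per-period outcome probability
    is ``base_rate * rr^exposure * frailty`` (clipped at 0.95), so the
    marginal exposed/unexposed risk ratio equals ``rr`` up to clipping.
    Columns match :func:`hivcma.models.fit_rr_model` expectations.
    """
    rng = np.random.default_rng(seed)
    x = (rng.random(n_patients) < exposure_prev).astype(int)
    u = np.exp(rng.normal(-frailty_sd**2 / 2, frailty_sd, n_patients))
    p = np.clip(base_rate * rr**x * u, 0, 0.95)
    rows = {
        "patient_id": np.repeat(np.arange(n_patients), periods).astype(str),
        "mh_any": np.repeat(x, periods),
        "period_index": np.tile(np.arange(1, periods + 1), n_patients),
        "outcome": (rng.random(n_patients * periods) < np.repeat(p, periods)).astype(int),
    }
    df = pd.DataFrame(rows)
    df["sex"] = np.repeat(np.where(rng.random(n_patients) < 0.5, "female", "male"), periods)
    df["age_group"] = np.repeat(
        rng.choice(np.asarray(AGE_GROUPS, dtype=object), n_patients), periods
    )
    return df


def simulate_mediation(
    n_patients: int = 4000,
    direct_rr: float = 1.0,
    exposure_prev: float = 0.15,
    tests_per_patient: int = 2,
    base_prob: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Viral-load test rows where substance use acts through adherence.

    Substance use shifts the adherence (CMA) distribution downwards;
    non-suppression probability follows the planted decile gradient
    times ``direct_rr`` per exposed row.  With ``direct_rr=1`` the
    exposure effect is purely indirect (mediated by CMA); with
    ``direct_rr>1`` a direct path bypasses CMA.  Output columns fit
    :func:`hivcma.models.mediation_by_cma`.
    """
    rng = np.random.default_rng(seed)
    m = n_patients * tests_per_patient
    su = (rng.random(n_patients) < exposure_prev).astype(int)
    su_rows = np.repeat(su, tests_per_patient)
    cma = np.where(
        su_rows == 1,
        rng.beta(2.2, 1.6, m),   # mean ~0.58 under substance use
        rng.beta(8.0, 1.4, m),   # mean ~0.85 otherwise
    )
    # point mass of perfect adherers so the CMA=100% reference level exists
    perfect = rng.random(m) < np.where(su_rows == 1, 0.10, 0.40)
    cma = np.where(perfect, 1.0, cma)
    decile = cma_decile_category(cma)
    gradient = dict(zip(
        ("100", "90-99", "80-89", "70-79", "60-69", "50-59",
         "40-49", "30-39", "20-29", "10-19", "0-9"),
        (1.0, 1.55, 2.26, 3.00, 3.58, 4.54, 5.41, 6.32, 7.24, 9.96, 15.89),
    ))
    p = base_prob * np.array([gradient[d] for d in decile]) * direct_rr**su_rows
    df = pd.DataFrame({
        "patient_id": np.repeat(np.arange(n_patients), tests_per_patient).astype(str),
        "outcome": (rng.random(m) < np.clip(p, 0, 0.95)).astype(int),
        "cma_decile": decile,
        "mh_substance_use": su_rows,
        "period_index": np.tile(np.arange(1, tests_per_patient + 1), n_patients),
    })
    df["sex"] = np.repeat(np.where(rng.random(n_patients) < 0.55, "female", "male"),
                          tests_per_patient)
    df["age_group"] = np.repeat(
        rng.choice(np.asarray(AGE_GROUPS, dtype=object), n_patients), tests_per_patient
    )
    for cat in MH_CATEGORIES:
        col = f"mh_{cat}"
        if col not in df.columns:
            df[col] = (rng.random(m) < 0.05).astype(int)
    return df
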