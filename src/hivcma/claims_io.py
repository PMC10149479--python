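"""Claims tables: schemas, validation, code classification, eligibility.

Four delimited-text tables form the canonical input (ISO-8601 dates, one
header row):

``patients.csv``
    patient_id, sex {male,female}, birth_date, cover_start, cover_end,
    death_date (blank if alive)
``pharmacy.csv``
    patient_id, dispense_date, atc_code, pills_dispensed, strength_mg
``diagnoses.csv``
    patient_id, diagnosis_date, icd10_code, setting {outpatient,hospital}
``labs.csv``
    patient_id, test_date, test_type {viral_load,cd4}, value

Mental disorders (ICD-10 chapter F) are grouped into six mutually
exclusive categories; antiretroviral pharmacy claims are identified by
five ATC level-4 prefixes; eligibility filters produce per-analysis
cohorts with an exclusion-flow report.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

# --------------------------------------------------------------------------
# Constants

#: ATC level-4 prefixes identifying antiretroviral medication: fixed-dose
#: combinations (J05AR), NNRTIs (J05AG), protease inhibitors (J05AE),
#: integrase inhibitors (J05AJ), and other antivirals (J05AX).
ART_ATC_PREFIXES: tuple[str, ...] = ("J05AR", "J05AG", "J05AE", "J05AJ", "J05AX")

#: Mental-health diagnosis categories.  The six specific categories
#: partition ICD-10 chapter F; "any" is their union.
MH_CATEGORIES: tuple[str, ...] = (
    "organic",
    "substance_use",
    "serious",
    "depression",
    "anxiety",
    "other",
)
MH_ANY = "any"

#: Default database closure date (end of the claims extraction window).
DEFAULT_CLOSURE = pd.Timestamp("2020-06-30")

_ICD10_RE = re.compile(r"^[A-Z]\d{2}(?:\.\d{1,2})?$")

SCHEMAS: dict[str, tuple[str, ...]] = {
    "patients": ("patient_id", "sex", "birth_date", "cover_start", "cover_end", "death_date"),
    "pharmacy": ("patient_id", "dispense_date", "atc_code", "pills_dispensed", "strength_mg"),
    "diagnoses": ("patient_id", "diagnosis_date", "icd10_code", "setting"),
    "labs": ("patient_id", "test_date", "test_type", "value"),
}

_DATE_COLS = {
    "patients": ("birth_date", "cover_start", "cover_end", "death_date"),
    "pharmacy": ("dispense_date",),
    "diagnoses": ("diagnosis_date",),
    "labs": ("test_date",),
}


class SchemaError(ValueError):
    """A table does not conform to the documented schema."""


class CodeError(ValueError):
    """A diagnosis or drug code is malformed."""


# --------------------------------------------------------------------------
# Code classification


def classify_icd10(icd10_code: str) -> frozenset[str]:
    """Map an ICD-10 code to its mental-health categories.

    Grouping: organic mental disorders F00-F09; substance use disorders
    F10-F19; serious mental disorders F20-F29 and F31; depression F32,
    F33 and F34.1; anxiety F40-F48; other mental disorders F30, F34.0,
    F34.8, F34.9 and F50-F99.  Chapter-F codes not explicitly listed
    (bare F34 and its unlisted subcodes, F35-F39) fall into "other" so
    that the whole F chapter is covered; non-F codes return an empty set.

    Raises :class:`CodeError` for syntactically invalid codes.
    """
    code = str(icd10_code).strip().upper()
    if not _ICD10_RE.match(code):
        raise CodeError(f"malformed ICD-10 code: {icd10_code!r}")
    if code[0] != "F":
        return frozenset()
    stem = int(code[1:3])
    if stem <= 9:
        return frozenset({"organic"})
    if stem <= 19:
        return frozenset({"substance_use"})
    if stem <= 29 or stem == 31:
        return frozenset({"serious"})
    if stem in (32, 33):
        return frozenset({"depression"})
    if stem == 34:
        return frozenset({"depression"}) if code == "F34.1" else frozenset({"other"})
    if 40 <= stem <= 48:
        return frozenset({"anxiety"})
    # F30, F35-F39, F49 (unused in ICD-10), F50-F99: residual group
    return frozenset({"other"})


def is_art_claim(atc_code: str, prefixes: tuple[str, ...] = ART_ATC_PREFIXES) -> bool:
    """True iff the ATC code starts with one of the ART level-4 prefixes."""
    return str(atc_code).strip().upper().startswith(tuple(prefixes))


# --------------------------------------------------------------------------
# Defined daily dose lookup

_DDD_CACHE: dict[str, float] | None = None


def load_ddd_table(override: dict[str, float] | None = None) -> dict[str, float]:
    """ATC code -> assumed adult maintenance dose in pills/day.

    Reads the versioned text resource shipped with the package; entries
    in ``override`` take precedence.  Lookup is by longest matching
    prefix (level-5 codes fall back to their level-4 class entry).
    """
    global _DDD_CACHE
    if _DDD_CACHE is None:
        text = resources.files("hivcma.data").joinpath("ddd_default.csv").read_text()
        table = {}
        for line in text.strip().splitlines()[1:]:
            atc, dose = line.split(",")[:2]
            table[atc.strip()] = float(dose)
        _DDD_CACHE = table
    table = dict(_DDD_CACHE)
    if override:
        table.update(override)
    return table


def daily_dose_for(atc_code: str, ddd: dict[str, float]) -> float:
    """Resolve the daily pill dose for an ATC code by longest-prefix match."""
    code = str(atc_code).strip().upper()
    for k in sorted(ddd, key=len, reverse=True):
        if code.startswith(k):
            return ddd[k]
    raise CodeError(f"no defined daily dose for ATC code {atc_code!r}")


# --------------------------------------------------------------------------
# Tables container and IO


@dataclass
class ClaimsTables:
    """The four canonical claims tables as pandas DataFrames."""

    patients: pd.DataFrame
    pharmacy: pd.DataFrame
    diagnoses: pd.DataFrame
    labs: pd.DataFrame

    def copy(self) -> "ClaimsTables":
        return ClaimsTables(
            self.patients.copy(), self.pharmacy.copy(), self.diagnoses.copy(), self.labs.copy()
        )


def validate_tables(tables: ClaimsTables) -> None:
    """Check schemas and basic invariants; raise :class:`SchemaError` on failure."""
    for name in SCHEMAS:
        df = getattr(tables, name)
        missing = set(SCHEMAS[name]) - set(df.columns)
        if missing:
            raise SchemaError(f"{name}: missing columns {sorted(missing)}")
    ph = tables.pharmacy
    if len(ph) and (ph["pills_dispensed"] <= 0).any():
        raise SchemaError("pharmacy: pills_dispensed must be positive")
    labs = tables.labs
    if len(labs) and (labs["value"] < 0).any():
        raise SchemaError("labs: value must be non-negative")
    pat = tables.patients
    if len(pat):
        bad = pat["cover_start"] > pat["cover_end"]
        if bad.any():
            raise SchemaError(f"patients: cover_start > cover_end for {int(bad.sum())} rows")
    for code in tables.diagnoses["icd10_code"].unique():
        if not _ICD10_RE.match(str(code).strip().upper()):
            raise CodeError(f"malformed ICD-10 code: {code!r}")


def read_tables(directory) -> ClaimsTables:
    """Read the four canonical CSV tables from a directory."""
    out = {}
    for name in SCHEMAS:
        df = pd.read_csv(f"{directory}/{name}.csv", dtype={"patient_id": str})
        for col in _DATE_COLS[name]:
            if col in df.columns:
                df[col] = pd.to_datetime(df[col], format="ISO8601")
        out[name] = df
    return ClaimsTables(**out)


def write_tables(tables: ClaimsTables, directory) -> None:
    """Write the four tables as CSV with ISO-8601 dates."""
    import os

    os.makedirs(directory, exist_ok=True)
    for name in SCHEMAS:
        df = getattr(tables, name).copy()
        for col in _DATE_COLS[name]:
            if col in df.columns:
                df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
        df.to_csv(f"{directory}/{name}.csv", index=False)


# --------------------------------------------------------------------------
# Eligibility


@dataclass
class EligibilityResult:
    """Filtered cohort with per-analysis subsets and an exclusion-flow report.

    ``cohort`` carries one row per eligible patient with ``baseline``
    (first ART claim date) and ``followup_end`` (min of cover end, death,
    database closure) columns.  ``analysis_ids`` maps analysis name ->
    eligible patient ids.  ``flow`` lists (step, n_excluded, n_remaining).
    """

    cohort: pd.DataFrame
    analysis_ids: dict[str, pd.Index]
    flow: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return len(self.cohort) == 0


def apply_eligibility(
    tables: ClaimsTables,
    closure: pd.Timestamp = DEFAULT_CLOSURE,
    min_age_years: float = 15.0,
    min_art_days: int = 183,
    min_adherence_days: int = 365,
    min_trajectory_days: int = 1095,
    art_prefixes: tuple[str, ...] = ART_ATC_PREFIXES,
) -> EligibilityResult:
    """Apply the study eligibility filters and report the exclusion flow.

    Base cohort: non-missing sex and birth date; at least two ART claims
    with >= ``min_art_days`` between the first ART claim (baseline) and
    follow-up end; aged >= ``min_age_years`` at baseline.  Per-analysis
    subsets: adherence-factors (follow-up >= 1 year), trajectory
    (>= 3 years), suppression (>= 1 viral-load result during follow-up).
    """
    pat = tables.patients.copy()
    flow: list[tuple[str, int, int]] = []
    n0 = len(pat)
    flow.append(("all patients", 0, n0))

    ok = pat["sex"].isin(["male", "female"]) & pat["birth_date"].notna()
    pat = pat[ok]
    flow.append(("missing sex or birth date", n0 - len(pat), len(pat)))

    ph = tables.pharmacy
    art = ph[ph["atc_code"].map(lambda c: is_art_claim(c, art_prefixes))]
    per = art.groupby("patient_id")["dispense_date"].agg(["min", "count"])
    per.columns = ["baseline", "n_art_claims"]
    pat = pat.merge(per, left_on="patient_id", right_index=True, how="left")
    n = len(pat)
    pat = pat[pat["n_art_claims"].notna()]
    flow.append(("no ART pharmacy claim", n - len(pat), len(pat)))

    end = pat["cover_end"].copy()
    death = pat["death_date"]
    end = end.where(death.isna() | (end <= death), death)
    pat["followup_end"] = end.where(end <= closure, closure)
    pat["followup_days"] = (pat["followup_end"] - pat["baseline"]).dt.days

    n = len(pat)
    age = (pat["baseline"] - pat["birth_date"]).dt.days / 365.25
    pat = pat[age >= min_age_years]
    flow.append((f"aged under {min_age_years:g} at baseline", n - len(pat), len(pat)))

    n = len(pat)
    pat = pat[(pat["n_art_claims"] >= 2) & (pat["followup_days"] >= min_art_days)]
    flow.append((f"on ART under {min_art_days} days", n - len(pat), len(pat)))

    cohort = pat.reset_index(drop=True)
    ids = pd.Index(cohort["patient_id"])

    adh = pd.Index(cohort.loc[cohort["followup_days"] >= min_adherence_days, "patient_id"])
    trj = pd.Index(cohort.loc[cohort["followup_days"] >= min_trajectory_days, "patient_id"])

    vl = tables.labs[tables.labs["test_type"] == "viral_load"]
    vl = vl.merge(cohort[["patient_id", "baseline", "followup_end"]], on="patient_id")
    vl = vl[(vl["test_date"] >= vl["baseline"]) & (vl["test_date"] <= vl["followup_end"])]
    sup = ids.intersection(pd.Index(vl["patient_id"].unique()))

    flow.append(("under 1 year follow-up (adherence-factors)", len(ids) - len(adh), len(adh)))
    flow.append(("under 3 years follow-up (trajectory)", len(ids) - len(trj), len(trj)))
    flow.append(("no viral load measurement (suppression)", len(ids) - len(sup), len(sup)))

    return EligibilityResult(
        cohort=cohort,
        analysis_ids={"adherence": adh, "trajectory": trj, "suppression": sup},
        flow=flow,
    )


# --------------------------------------------------------------------------
# Diagnosis timelines


def build_diagnosis_timeline(
    diagnoses: pd.DataFrame, require_repeat: bool = False
) -> pd.DataFrame:
    """Per-patient, per-category mental-health onset dates.

    Onset is the first qualifying diagnosis date, or — when
    ``require_repeat`` — the first date on which a second diagnosis in
    the category on a *different* date exists.  The ``any`` category
    pools all chapter-F claims.  Returns a frame with columns
    patient_id, category, onset_date.  The derived exposure flag at time
    t (onset <= t) is monotone by construction.
    """
    dx = diagnoses.copy()
    cat_sets = dx["icd10_code"].map(classify_icd10)
    rows = []
    for cat_name in MH_CATEGORIES:
        mask = cat_sets.map(lambda s, c=cat_name: c in s)
        rows.append(dx.loc[mask, ["patient_id", "diagnosis_date"]].assign(category=cat_name))
    any_mask = cat_sets.map(bool)
    rows.append(dx.loc[any_mask, ["patient_id", "diagnosis_date"]].assign(category=MH_ANY))
    long = pd.concat(rows, ignore_index=True) if rows else dx.iloc[:0]
    if long.empty:
        return pd.DataFrame(columns=["patient_id", "category", "onset_date"])

    grouped = long.drop_duplicates().groupby(["patient_id", "category"])["diagnosis_date"]
    if require_repeat:
        onset = grouped.apply(
            lambda s: s.drop_duplicates().nsmallest(2).max()
            if s.nunique() >= 2
            else pd.NaT
        ).dropna()
    else:
        onset = grouped.min()
    out = onset.rename("onset_date").reset_index()
    return out.sort_values(["patient_id", "category"]).reset_index(drop=True)


def exposure_flags(
    timeline: pd.DataFrame, patient_ids: pd.Series, at_dates: pd.Series
) -> pd.DataFrame:
    """Evaluate per-category exposure flags at given (patient, date) pairs.

    Returns one boolean column ``mh_<category>`` per category (plus
    ``mh_any``), aligned with the input series.
    """
    base = pd.DataFrame({"patient_id": patient_ids.values, "at": pd.to_datetime(at_dates).values})
    wide = timeline.pivot(index="patient_id", columns="category", values="onset_date")
    out = {}
    for cat_name in list(MH_CATEGORIES) + [MH_ANY]:
        if cat_name in wide.columns:
            onset = base["patient_id"].map(wide[cat_name])
            out[f"mh_{cat_name}"] = (onset.notna() & (onset <= base["at"])).values
        else:
            out[f"mh_{cat_name}"] = np.zeros(len(base), dtype=bool)
    return pd.DataFrame(out, index=patient_ids.index)
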