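"""ICD-10 grouping, ART claim detection, eligibility and timelines."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hivcma import claims_io
from hivcma.claims_io import (
    ClaimsTables,
    CodeError,
    apply_eligibility,
    build_diagnosis_timeline,
    classify_icd10,
    daily_dose_for,
    exposure_flags,
    is_art_claim,
    load_ddd_table,
)


@pytest.mark.parametrize(
    "code,expected",
    [
        ("F03", {"organic"}),
        ("F10.2", {"substance_use"}),
        ("F20.0", {"serious"}),
        ("F31", {"serious"}),  # bipolar counts as serious, not mood residual
        ("F32", {"depression"}),
        ("F33.1", {"depression"}),
        ("F34.1", {"depression"}),
        ("F34.0", {"other"}),
        ("F34.8", {"other"}),
        ("F30", {"other"}),
        ("F41.1", {"anxiety"}),
        ("F48", {"anxiety"}),
        ("F50.0", {"other"}),
        ("F99", {"other"}),
        ("I10", set()),
        ("N06.1", set()),
    ],
)
def test_icd10_grouping(code, expected):
    assert classify_icd10(code) == expected


@pytest.mark.parametrize("bad", ["", "F3", "f", "F321", "10A", "F32.123"])
def test_icd10_malformed_codes_rejected(bad):
    with pytest.raises(CodeError):
        classify_icd10(bad)


@given(
    stem=st.integers(0, 99),
    sub=st.one_of(st.none(), st.integers(0, 9)),
)
@settings(max_examples=300, deadline=None)
def test_icd10_f_chapter_partition(stem, sub):
    """Every chapter-F code lands in exactly one of the six categories."""
    code = f"F{stem:02d}" + ("" if sub is None else f".{sub}")
    cats = classify_icd10(code)
    assert len(cats) == 1
    assert cats <= set(claims_io.MH_CATEGORIES)


@pytest.mark.parametrize(
    "atc,expected",
    [
        ("J05AR10", True),
        ("J05AG03", True),
        ("J05AE08", True),
        ("J05AJ03", True),
        ("J05AX12", True),
        ("J05AF05", False),  # single-NRTI prefix deliberately not on the list
        ("N06AB03", False),
        ("J05AB01", False),
    ],
)
def test_art_claim_prefixes(atc, expected):
    assert is_art_claim(atc) is expected


def test_ddd_lookup_prefix_fallback():
    ddd = load_ddd_table()
    assert daily_dose_for("J05AR10", ddd) == 1.0  # level-5 falls back to J05AR
    assert daily_dose_for("J05AE08", ddd) == 2.0
    with pytest.raises(CodeError):
        daily_dose_for("A10BA02", ddd)
    assert daily_dose_for("J05AR", load_ddd_table({"J05AR": 2.0})) == 2.0


# --------------------------------------------------------------------------
# Eligibility


def _tables(patients, pharmacy, diagnoses=None, labs=None):
    empty_dx = pd.DataFrame(columns=["patient_id", "diagnosis_date", "icd10_code", "setting"])
    empty_lab = pd.DataFrame(columns=["patient_id", "test_date", "test_type", "value"])
    return ClaimsTables(
        patients,
        pharmacy,
        diagnoses if diagnoses is not None else empty_dx,
        labs if labs is not None else empty_lab,
    )


def _patient(pid="A", sex="female", birth="1980-01-01", start="2014-01-01", end="2019-01-01"):
    return dict(
        patient_id=pid, sex=sex, birth_date=pd.Timestamp(birth),
        cover_start=pd.Timestamp(start), cover_end=pd.Timestamp(end), death_date=pd.NaT,
    )


def _claims(pid, dates, atc="J05AR10", pills=30):
    return pd.DataFrame(
        [dict(patient_id=pid, dispense_date=pd.Timestamp(d), atc_code=atc,
              pills_dispensed=pills, strength_mg=600) for d in dates]
    )


def test_eligibility_thresholds_and_analysis_subsets():
    """200-day ART span with 400-day follow-up: in the adherence-factors
    analysis but not the trajectory analysis; no viral load keeps the
    patient out of the suppression analysis."""
    patients = pd.DataFrame([
        _patient("A", end="2017-02-04"),                       # 400d follow-up
        _patient("B", birth="2002-06-01"),                     # aged 13.6 at baseline
        _patient("C", end="2019-01-01"),                       # long follow-up
    ])
    pharmacy = pd.concat([
        _claims("A", ["2016-01-01", "2016-07-19"]),            # 200 days apart
        _claims("B", ["2016-01-01", "2016-07-19"]),
        _claims("C", ["2016-01-01", "2016-02-01", "2016-03-01"]),
    ])
    labs = pd.DataFrame([
        dict(patient_id="C", test_date=pd.Timestamp("2016-06-01"),
             test_type="viral_load", value=50.0),
    ])
    res = apply_eligibility(_tables(patients, pharmacy, labs=labs))
    assert set(res.cohort["patient_id"]) == {"A", "C"}  # B excluded everywhere (age)
    assert "A" in res.analysis_ids["adherence"]
    assert "A" not in res.analysis_ids["trajectory"]
    assert "C" in res.analysis_ids["trajectory"]
    assert list(res.analysis_ids["suppression"]) == ["C"]
    # baseline is the first ART claim
    assert res.cohort.set_index("patient_id").loc["A", "baseline"] == pd.Timestamp("2016-01-01")


def test_eligibility_is_idempotent():
    patients = pd.DataFrame([_patient("A"), _patient("B", birth="2003-01-01")])
    pharmacy = pd.concat([
        _claims("A", ["2016-01-01", "2016-08-01"]),
        _claims("B", ["2016-01-01", "2016-08-01"]),
    ])
    first = apply_eligibility(_tables(patients, pharmacy))
    again = apply_eligibility(
        _tables(first.cohort[list(claims_io.SCHEMAS["patients"])], pharmacy)
    )
    assert list(again.cohort["patient_id"]) == list(first.cohort["patient_id"])
    # second pass excludes nobody at the cohort-level steps
    assert all(excl == 0 for step, excl, _ in again.flow[1:4])


def test_empty_cohort_is_flagged_not_silent():
    patients = pd.DataFrame([_patient("A", birth="2010-01-01")])
    pharmacy = _claims("A", ["2016-01-01", "2016-08-01"])
    res = apply_eligibility(_tables(patients, pharmacy))
    assert res.empty
    assert res.flow[-1][2] == 0


# --------------------------------------------------------------------------
# Diagnosis timelines


def _dx(pid, dates, code="F32"):
    return pd.DataFrame(
        [dict(patient_id=pid, diagnosis_date=pd.Timestamp(d), icd10_code=code,
              setting="outpatient") for d in dates]
    )


def test_single_claim_onset():
    tl = build_diagnosis_timeline(_dx("A", ["2017-03-01"]))
    dep = tl[(tl.patient_id == "A") & (tl.category == "depression")]
    assert dep["onset_date"].iloc[0] == pd.Timestamp("2017-03-01")


def test_repeat_definition_requires_two_distinct_dates():
    single = build_diagnosis_timeline(_dx("A", ["2017-03-01"]), require_repeat=True)
    same_day = build_diagnosis_timeline(
        _dx("A", ["2017-03-01", "2017-03-01"]), require_repeat=True
    )
    two_days = build_diagnosis_timeline(
        _dx("A", ["2017-03-01", "2017-05-01"]), require_repeat=True
    )
    assert single.empty and same_day.empty
    dep = two_days[two_days.category == "depression"]
    # onset is the date the second, distinct-date diagnosis arrives
    assert dep["onset_date"].iloc[0] == pd.Timestamp("2017-05-01")


def test_exposure_flags_monotone_in_time():
    tl = build_diagnosis_timeline(_dx("A", ["2017-03-01"]))
    dates = pd.Series(pd.date_range("2016-06-01", periods=30, freq="MS"))
    flags = exposure_flags(tl, pd.Series(["A"] * 30), dates)
    dep = flags["mh_depression"].to_numpy()
    assert not dep[0] and dep[-1]
    assert (np.diff(dep.astype(int)) >= 0).all()
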