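"""Continuous medication availability (CMA) with stockpiling carryover.

The adherence signal is built in two steps.  First, each interval between
two consecutive refills — or between the last refill and the end of
follow-up — receives a mean daily adherence value: the number of days
covered by sufficient drug supply divided by the interval length.  Early
refills carry surplus supply over into subsequent intervals (unbounded
stockpiling by default).  Second, follow-up time is split into
consecutive calendar windows of 1, 3, 6 or 12 months and the daily values
are averaged within each window; a trailing window shorter than its
nominal length is dropped.

Supply accounting runs one carryover inventory per distinct ATC code
("per-atc" mode, default) so that multi-component regimens dispensed in
parallel do not multiply-count supply; a day's adherence value is the
maximum over streams of the smoothed per-stream value.  "pooled" mode
merges all claims into a single inventory.

All arithmetic uses whole-day granularity with half-open date ranges
[start, end) and double precision throughout; nothing is rounded before
report formatting.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def claim_duration(pills_dispensed: float, daily_dose_pills: float) -> float:
    """Days of supply in one claim: dispensed pills / assumed daily dose.

    Both inputs must be positive; the result is not rounded.
    """
    if pills_dispensed <= 0:
        raise ValueError(f"pills_dispensed must be positive, got {pills_dispensed}")
    if daily_dose_pills <= 0:
        raise ValueError(f"daily_dose_pills must be positive, got {daily_dose_pills}")
    return pills_dispensed / daily_dose_pills


def build_refill_intervals(
    claims: pd.DataFrame,
    baseline: pd.Timestamp,
    followup_end: pd.Timestamp,
    streams: str = "per-atc",
    carryover_cap_days: float | None = None,
) -> pd.DataFrame:
    """Chain refill intervals with carryover for one patient.

    ``claims`` needs columns ``dispense_date``, ``atc_code`` and
    ``duration_days``.  Same-day claims of one stream pool their
    durations.  Claims on or after ``followup_end`` are dropped with a
    warning; claims before ``baseline`` are an error (baseline is the
    first documented ART use by construction).

    Returns one row per (stream, interval): stream, start_day, end_day
    (day offsets from baseline, half-open), supply_in_days,
    days_covered, carryover_out_days, daily_value.
    """
    total_days = int((followup_end - baseline) / pd.Timedelta(days=1))
    if total_days <= 0:
        raise ValueError("followup_end must be after baseline")
    c = claims.copy()
    c["day"] = ((c["dispense_date"] - baseline) / pd.Timedelta(days=1)).astype(int)
    if (c["day"] < 0).any():
        raise ValueError("claim precedes baseline")
    late = c["day"] >= total_days
    if late.any():
        warnings.warn(f"dropping {int(late.sum())} claim(s) on/after follow-up end")
        c = c[~late]
    if streams == "pooled":
        c = c.assign(stream="pooled")
    elif streams == "per-atc":
        c = c.assign(stream=c["atc_code"].astype(str))
    else:
        raise ValueError(f"unknown streams mode: {streams!r}")

    rows = []
    for stream, grp in c.groupby("stream", sort=True):
        pooled = grp.groupby("day")["duration_days"].sum().sort_index()
        days = pooled.index.to_numpy()
        ends = np.append(days[1:], total_days)
        carry = 0.0
        for start, end, dur in zip(days, ends, pooled.to_numpy()):
            length = float(end - start)
            supply = dur + carry
            if carryover_cap_days is not None:
                supply = min(supply, length + carryover_cap_days)
            covered = min(length, supply)
            carry = supply - covered
            rows.append((stream, int(start), int(end), supply, covered, carry, covered / length))
    return pd.DataFrame(
        rows,
        columns=[
            "stream",
            "start_day",
            "end_day",
            "supply_in_days",
            "days_covered",
            "carryover_out_days",
            "daily_value",
        ],
    )


def daily_adherence(intervals: pd.DataFrame, total_days: int) -> np.ndarray:
    """Per-day adherence values over [0, total_days).

    Each stream's interval daily values are expanded to days; days are
    then combined across streams by taking the maximum.  Days before the
    first refill of every stream (none, by construction, for the stream
    containing the baseline claim) get 0.
    """
    out = np.zeros(total_days)
    for _, grp in intervals.groupby("stream"):
        vals = np.zeros(total_days)
        lengths = (grp["end_day"] - grp["start_day"]).to_numpy()
        expanded = np.repeat(grp["daily_value"].to_numpy(), lengths)
        start = int(grp["start_day"].iloc[0])
        vals[start : start + len(expanded)] = expanded
        np.maximum(out, vals, out=out)
    return out


def window_boundaries(
    baseline: pd.Timestamp, followup_end: pd.Timestamp, window_months: int
) -> list[pd.Timestamp]:
    """Calendar-month window boundaries from baseline up to follow-up end.

    Boundaries advance by ``window_months`` calendar months, clamping the
    day-of-month to month end where needed.  Only boundaries <= follow-up
    end are returned, so the implied final window is always complete.
    """
    bounds = [baseline]
    i = 1
    while True:
        b = baseline + pd.DateOffset(months=window_months * i)
        if b > followup_end:
            break
        bounds.append(b)
        i += 1
    return bounds


def cma_windows(
    intervals: pd.DataFrame,
    baseline: pd.Timestamp,
    followup_end: pd.Timestamp,
    window_months: int,
) -> pd.DataFrame:
    """Average daily adherence over consecutive calendar windows.

    Returns window_index (0-based), window_start, window_end, cma_value
    in [0, 1] and observed_days.  Trailing incomplete windows are
    dropped; an empty interval table yields an empty series.
    """
    if window_months not in (1, 3, 6, 12):
        raise ValueError("window_months must be one of 1, 3, 6, 12")
    total_days = int((followup_end - baseline) / pd.Timedelta(days=1))
    if intervals.empty:
        return pd.DataFrame(
            columns=["window_index", "window_start", "window_end", "cma_value", "observed_days"]
        )
    daily = daily_adherence(intervals, total_days)
    cum = np.concatenate([[0.0], np.cumsum(daily)])
    bounds = window_boundaries(baseline, followup_end, window_months)
    rows = []
    for i in range(len(bounds) - 1):
        s = int((bounds[i] - baseline) / pd.Timedelta(days=1))
        e = int((bounds[i + 1] - baseline) / pd.Timedelta(days=1))
        val = min(1.0, max(0.0, (cum[e] - cum[s]) / (e - s)))  # guard float drift
        rows.append((i, bounds[i], bounds[i + 1], val, e - s))
    return pd.DataFrame(
        rows, columns=["window_index", "window_start", "window_end", "cma_value", "observed_days"]
    )


def flag_non_adherence(series: pd.DataFrame, threshold_pct: int = 80) -> pd.DataFrame:
    """Mark windows with CMA strictly below the threshold as non-adherent.

    The comparison is strict: a CMA of exactly threshold/100 is adherent.
    Thresholds of 80% (primary) and 70%/90% (sensitivity) are the study
    values, but any percentage is accepted.
    """
    out = series.copy()
    out["threshold_pct"] = threshold_pct
    out["non_adherent"] = out["cma_value"] < threshold_pct / 100.0
    return out


# --------------------------------------------------------------------------
# Cohort-level convenience


def patient_cma(
    art_claims: pd.DataFrame,
    baseline: pd.Timestamp,
    followup_end: pd.Timestamp,
    window_months: int,
    ddd: dict[str, float],
    streams: str = "per-atc",
) -> pd.DataFrame:
    """Windowed CMA series for one patient from raw ART claims."""
    from hivcma.claims_io import daily_dose_for

    c = art_claims.copy()
    c["duration_days"] = [
        claim_duration(p, daily_dose_for(a, ddd))
        for p, a in zip(c["pills_dispensed"], c["atc_code"])
    ]
    iv = build_refill_intervals(c, baseline, followup_end, streams=streams)
    return cma_windows(iv, baseline, followup_end, window_months)


def cohort_cma(
    tables,
    cohort: pd.DataFrame,
    window_months: int,
    ddd: dict[str, float] | None = None,
    streams: str = "per-atc",
    art_prefixes: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Windowed CMA for every patient in an eligible cohort.

    ``cohort`` must carry patient_id, baseline and followup_end (as
    produced by :func:`hivcma.claims_io.apply_eligibility`).  Returns a
    long table patient_id x window.
    """
    from hivcma.claims_io import ART_ATC_PREFIXES, is_art_claim, load_ddd_table

    if ddd is None:
        ddd = load_ddd_table()
    prefixes = art_prefixes or ART_ATC_PREFIXES
    ph = tables.pharmacy
    art = ph[ph["atc_code"].map(lambda a: is_art_claim(a, prefixes))]
    by_patient = dict(tuple(art.groupby("patient_id")))
    out = []
    for row in cohort.itertuples(index=False):
        claims = by_patient.get(row.patient_id)
        if claims is None:
            continue
        series = patient_cma(
            claims, row.baseline, row.followup_end, window_months, ddd, streams=streams
        )
        if len(series):
            out.append(series.assign(patient_id=row.patient_id))
    if not out:
        return pd.DataFrame(
            columns=["patient_id", "window_index", "window_start", "window_end", "cma_value", "observed_days"]
        )
    res = pd.concat(out, ignore_index=True)
    return res[["patient_id", "window_index", "window_start", "window_end", "cma_value", "observed_days"]]
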