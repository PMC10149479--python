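"""CMA engine: durations, carryover chaining, windows, thresholds.

The reference for every non-trivial value is a day-by-day pill-inventory
simulation (tests/_oracles.py), kept independent of the interval
arithmetic it checks.
"""

import numpy as np
import pandas as pd
import pytest

from hivcma.adherence import (
    build_refill_intervals,
    claim_duration,
    cma_windows,
    daily_adherence,
    flag_non_adherence,
)

from _oracles import daywalk_daily_values, random_claim_history, window_means

B = pd.Timestamp("2016-01-01")


def _claims(day_durations, atc="J05AR10"):
    return pd.DataFrame(
        [
            dict(dispense_date=B + pd.Timedelta(days=d), atc_code=atc, duration_days=dur)
            for d, dur in day_durations
        ]
    )


@pytest.mark.parametrize(
    "pills,dose,expected",
    [(30, 1.0, 30.0), (60, 2.0, 30.0), (28, 1.5, 28 / 1.5)],
)
def test_claim_duration_is_exact_division(pills, dose, expected):
    assert claim_duration(pills, dose) == pytest.approx(expected, abs=0)


@pytest.mark.parametrize("pills,dose", [(0, 1.0), (30, 0.0), (-5, 1.0)])
def test_claim_duration_rejects_nonpositive(pills, dose):
    with pytest.raises(ValueError):
        claim_duration(pills, dose)


def test_stockpiling_early_refill_keeps_full_coverage():
    """30-day supplies at day 0 and day 15 over 60 days of follow-up:
    the early refill carries 15 days over, so both intervals are fully
    covered (daily value 1.0 each)."""
    iv = build_refill_intervals(_claims([(0, 30.0), (15, 30.0)]), B, B + pd.Timedelta(days=60))
    assert list(iv["daily_value"]) == [1.0, 1.0]
    assert list(iv["carryover_out_days"]) == [15.0, 0.0]
    assert list(iv["days_covered"]) == [15.0, 45.0]


def test_single_refill_dilutes_over_followup():
    iv = build_refill_intervals(_claims([(0, 30.0)]), B, B + pd.Timedelta(days=90))
    assert len(iv) == 1
    assert iv["daily_value"].iloc[0] == pytest.approx(30 / 90, abs=1e-12)


def test_back_to_back_refills_give_perfect_adherence():
    iv = build_refill_intervals(_claims([(0, 30.0), (30, 30.0)]), B, B + pd.Timedelta(days=60))
    assert (iv["daily_value"] == 1.0).all()
    assert (iv["carryover_out_days"] == 0.0).all()


def test_same_day_claims_pool_their_durations():
    iv = build_refill_intervals(
        _claims([(0, 30.0), (0, 30.0)]), B, B + pd.Timedelta(days=60)
    )
    assert len(iv) == 1
    assert iv["supply_in_days"].iloc[0] == 60.0
    assert iv["daily_value"].iloc[0] == 1.0


def test_claim_after_followup_end_dropped_with_warning():
    with pytest.warns(UserWarning, match="dropping"):
        iv = build_refill_intervals(
            _claims([(0, 30.0), (70, 30.0)]), B, B + pd.Timedelta(days=60)
        )
    assert len(iv) == 1


def test_window_mean_is_day_weighted():
    """45 days at 1.0 then 45 days at 0.5 average to 0.75 over a 90-day
    span (checked through a calendar window covering exactly those days)."""
    end = B + pd.DateOffset(months=3)  # 2016-04-01, 91 days
    iv = build_refill_intervals(_claims([(0, 45.0), (45, 23.0)]), B, end)
    series = cma_windows(iv, B, end, 3)
    daily = daily_adherence(iv, 91)
    assert series["cma_value"].iloc[0] == pytest.approx(daily.mean(), abs=1e-12)
    # hand value: 45 covered days, then 23/46 over the rest
    assert series["cma_value"].iloc[0] == pytest.approx((45 * 1.0 + 46 * (23 / 46)) / 91)


def test_trailing_incomplete_window_dropped():
    end = B + pd.Timedelta(days=100)  # one full 3-month window (91d) + 9 days
    iv = build_refill_intervals(_claims([(0, 100.0)]), B, end)
    series = cma_windows(iv, B, end, 3)
    assert len(series) == 1
    assert series["observed_days"].iloc[0] == 91


@pytest.mark.parametrize("multi", [False, True])
@pytest.mark.parametrize("window", [1, 3])
def test_windowed_cma_matches_daywalk_oracle(multi, window):
    rng = np.random.default_rng(20 + multi)
    for _ in range(25):
        claims, baseline, end = random_claim_history(rng, multi_stream=multi)
        iv = build_refill_intervals(claims, baseline, end)
        got = cma_windows(iv, baseline, end, window)["cma_value"].to_numpy()
        want = window_means(daywalk_daily_values(claims, baseline, end), baseline, end, window)
        np.testing.assert_allclose(got, want, atol=1e-9)


def test_conservation_no_pills_invented():
    rng = np.random.default_rng(99)
    for _ in range(50):
        claims, baseline, end = random_claim_history(rng, multi_stream=True)
        iv = build_refill_intervals(claims, baseline, end)
        for _, grp in iv.groupby("stream"):
            dispensed = grp["supply_in_days"].iloc[0] + (
                grp["supply_in_days"].iloc[1:].to_numpy()
                - grp["carryover_out_days"].iloc[:-1].to_numpy()
            ).sum()
            covered = grp["days_covered"].sum()
            leftover = grp["carryover_out_days"].iloc[-1]
            assert covered + leftover <= dispensed + 1e-9


def test_scale_invariance_of_dose_and_pills():
    c1 = _claims([(0, claim_duration(30, 1.0)), (40, claim_duration(30, 1.0))])
    c2 = _claims([(0, claim_duration(60, 2.0)), (40, claim_duration(60, 2.0))])
    end = B + pd.Timedelta(days=120)
    iv1 = build_refill_intervals(c1, B, end)
    iv2 = build_refill_intervals(c2, B, end)
    pd.testing.assert_frame_equal(iv1, iv2)


def test_adding_claim_never_reduces_total_coverage():
    """Extra supply can redistribute coverage between windows but the
    total covered days over follow-up never drop."""
    rng = np.random.default_rng(7)
    end = B + pd.Timedelta(days=365)
    for _ in range(30):
        n = int(rng.integers(1, 6))
        days = np.sort(rng.choice(360, size=n, replace=False))
        base_claims = _claims([(int(d), 30.0) for d in days])
        extra_day = int(rng.integers(0, 360))
        more = pd.concat(
            [base_claims, _claims([(extra_day, float(rng.choice([5, 15, 30])))])]
        ).reset_index(drop=True)
        cov0 = daily_adherence(build_refill_intervals(base_claims, B, end), 365).sum()
        cov1 = daily_adherence(build_refill_intervals(more, B, end), 365).sum()
        assert cov1 >= cov0 - 1e-9


def test_truncation_leaves_pre_truncation_refill_windows_unchanged():
    """Windows lying entirely before the last refill are unaffected by
    moving the follow-up end (the final interval depends on it)."""
    claims = _claims([(0, 30.0), (35, 30.0), (80, 30.0), (300, 30.0)])
    long = cma_windows(build_refill_intervals(claims, B, B + pd.Timedelta(days=400)),
                       B, B + pd.Timedelta(days=400), 1)
    short = cma_windows(build_refill_intervals(claims, B, B + pd.Timedelta(days=340)),
                        B, B + pd.Timedelta(days=340), 1)
    last_refill = B + pd.Timedelta(days=300)
    keep = long["window_end"] <= last_refill
    merged = long[keep].merge(short, on="window_index", suffixes=("_l", "_s"))
    np.testing.assert_allclose(merged["cma_value_l"], merged["cma_value_s"], atol=1e-12)


@pytest.mark.parametrize(
    "cma,threshold,expected",
    [(0.79, 80, True), (0.80, 80, False), (0.85, 90, True), (0.70, 70, False)],
)
def test_non_adherence_threshold_is_strict(cma, threshold, expected):
    series = pd.DataFrame({"cma_value": [cma]})
    out = flag_non_adherence(series, threshold)
    assert bool(out["non_adherent"].iloc[0]) is expected


def test_no_claims_yield_empty_flagged_series():
    series = cma_windows(
        pd.DataFrame(columns=["stream", "start_day", "end_day", "supply_in_days",
                              "days_covered", "carryover_out_days", "daily_value"]),
        B, B + pd.Timedelta(days=365), 3,
    )
    assert series.empty
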