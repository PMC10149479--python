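"""Validation of CMA against viral non-suppression (VNS) via ROC/AUC.

Each viral-load test is paired with the patient's CMA over a 1-, 3-, 6-
or 12-month lookback window ending the day before the test.  VNS is a
viral load at or above a threshold (400 copies/mL primary; 100 and 1000
in sensitivity analyses).  The AUC is the Mann-Whitney probability that
a random non-suppressed test carries a lower CMA than a random
suppressed one (ties count one half); confidence intervals come from a
patient-level cluster bootstrap because patients contribute repeated
tests.  A binormal probit AUC is available as a secondary estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from hivcma.adherence import daily_adherence

VNS_THRESHOLDS = (100, 400, 1000)


@dataclass
class RocResult:
    window_months: int
    vns_threshold: float
    auc: float
    ci_low: float
    ci_high: float
    n_tests: int
    n_patients: int


def lookback_cma(
    daily: np.ndarray, test_day: int, window_months: int
) -> float | None:
    """Mean daily adherence over the lookback window before a test.

    The window spans ``round(window_months * 365.25/12)`` days and ends
    the day before the test (half-open [test_day - L, test_day)).
    Returns None when the window is not fully observed (precedes
    baseline or runs past follow-up end).
    """
    length = int(round(window_months * 365.25 / 12))
    start = test_day - length
    if start < 0 or test_day > len(daily):
        return None
    return float(daily[start:test_day].mean())


def build_validation_pairs(
    daily_by_patient: dict[str, np.ndarray],
    cohort: pd.DataFrame,
    labs: pd.DataFrame,
    window_months: int,
    vns_threshold: float = 400.0,
) -> pd.DataFrame:
    """One (vns, lookback-CMA) pair per viral-load test with full lookback.

    ``daily_by_patient`` maps patient_id to the per-day adherence array
    from :func:`hivcma.adherence.daily_adherence`; ``cohort`` carries
    baseline/followup_end.  Tests whose lookback precedes baseline are
    dropped; the drop count is in ``.attrs['n_dropped']``.
    """
    vl = labs[labs["test_type"] == "viral_load"].merge(
        cohort[["patient_id", "baseline", "followup_end"]], on="patient_id"
    )
    vl = vl[(vl["test_date"] >= vl["baseline"]) & (vl["test_date"] <= vl["followup_end"])]
    rows, dropped = [], 0
    for r in vl.itertuples(index=False):
        daily = daily_by_patient.get(r.patient_id)
        if daily is None:
            dropped += 1
            continue
        day = int((r.test_date - r.baseline) / pd.Timedelta(days=1))
        cma = lookback_cma(daily, day, window_months)
        if cma is None:
            dropped += 1
            continue
        rows.append((r.patient_id, r.test_date, r.value >= vns_threshold, cma))
    out = pd.DataFrame(rows, columns=["patient_id", "test_date", "vns", "cma_before"])
    out.attrs["n_dropped"] = dropped
    return out


def mann_whitney_auc(score: np.ndarray, positive: np.ndarray) -> float:
    """AUC for 'low score predicts positive', ties counted one half."""
    pos = np.asarray(positive, dtype=bool)
    if pos.all() or not pos.any():
        missing = "negative" if pos.all() else "positive"
        raise ValueError(f"AUC undefined: no {missing} (suppressed/non-suppressed) cases")
    # orientation: low CMA predicts non-suppression
    return float(roc_auc_score(pos, -np.asarray(score, dtype=float)))


def empirical_auc(
    pairs: pd.DataFrame,
    window_months: int = 12,
    vns_threshold: float = 400.0,
    n_boot: int = 500,
    seed: int = 0,
) -> RocResult:
    """Clustered-bootstrap empirical AUC of lookback CMA for VNS.

    Point estimate is the Mann-Whitney AUC; the 95% CI is the percentile
    interval over ``n_boot`` resamples of *patients* with replacement
    (repeated tests of one patient stay together).  Deterministic given
    the seed.
    """
    score = pairs["cma_before"].to_numpy(dtype=float)
    y = pairs["vns"].to_numpy(dtype=bool)
    auc = mann_whitney_auc(score, y)
    rng = np.random.default_rng(seed)
    codes, _ = pd.factorize(pairs["patient_id"], sort=True)
    order = np.argsort(codes, kind="stable")
    counts = np.bincount(codes)
    starts = np.concatenate([[0], np.cumsum(counts)])
    idx_pool = [order[starts[i]: starts[i + 1]] for i in range(len(counts))]
    boots = []
    for _ in range(n_boot):
        sample = rng.integers(0, len(idx_pool), size=len(idx_pool))
        idx = np.concatenate([idx_pool[i] for i in sample])
        yb = y[idx]
        if yb.all() or not yb.any():
            continue
        boots.append(mann_whitney_auc(score[idx], yb))
    lo, hi = (np.percentile(boots, [2.5, 97.5]) if boots else (np.nan, np.nan))
    return RocResult(
        window_months=window_months,
        vns_threshold=vns_threshold,
        auc=auc,
        ci_low=float(lo),
        ci_high=float(hi),
        n_tests=len(pairs),
        n_patients=pairs["patient_id"].nunique(),
    )


def binormal_auc(pairs: pd.DataFrame) -> float:
    """Secondary binormal AUC on probit-transformed placement values.

    Scores are mapped through the pooled empirical CDF and a probit
    transform; the binormal AUC is Phi(a / sqrt(1 + b^2)) with a, b from
    the two class means/SDs on that scale.  Assumes both classes present.
    """
    s = pairs["cma_before"].to_numpy(dtype=float)
    y = pairs["vns"].to_numpy(dtype=bool)
    ranks = stats.rankdata(-s) / (len(s) + 1)  # low CMA -> high rank
    z = stats.norm.ppf(ranks)
    m1, s1 = z[y].mean(), z[y].std(ddof=1)
    m0, s0 = z[~y].mean(), z[~y].std(ddof=1)
    a = (m1 - m0) / s1
    b = s0 / s1
    return float(stats.norm.cdf(a / np.sqrt(1.0 + b * b)))


def auc_by_window(
    daily_by_patient: dict[str, np.ndarray],
    cohort: pd.DataFrame,
    labs: pd.DataFrame,
    windows: tuple[int, ...] = (1, 3, 6, 12),
    vns_threshold: float = 400.0,
    n_boot: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """RocResult table across lookback window lengths."""
    rows = []
    for w in windows:
        pairs = build_validation_pairs(daily_by_patient, cohort, labs, w, vns_threshold)
        r = empirical_auc(pairs, w, vns_threshold, n_boot=n_boot, seed=seed)
        rows.append(r.__dict__)
    return pd.DataFrame(rows)
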