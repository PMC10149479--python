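"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's interval arithmetic: supply is
tracked by a day-by-day pill-inventory walk, AUC by exhaustive pair
enumeration, and the clustering criterion by direct evaluation of its
formula.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def daywalk_daily_values(
    claims: pd.DataFrame,
    baseline: pd.Timestamp,
    followup_end: pd.Timestamp,
    streams: str = "per-atc",
) -> np.ndarray:
    """Day-by-day inventory simulation -> smoothed per-day adherence.

    One inventory per stream; each day consumes up to one day of supply
    (fractional remainders allowed).  Within each inter-refill interval
    the raw coverage is replaced by its interval mean; streams combine
    by per-day maximum.
    """
    total = int((followup_end - baseline) / pd.Timedelta(days=1))
    c = claims.copy()
    c["day"] = ((c["dispense_date"] - baseline) / pd.Timedelta(days=1)).astype(int)
    c = c[c["day"] < total]
    key = (lambda _: "pooled") if streams == "pooled" else (lambda a: str(a))
    c["stream"] = c["atc_code"].map(key)
    out = np.zeros(total)
    for _, grp in c.groupby("stream"):
        refills = grp.groupby("day")["duration_days"].sum().to_dict()
        cov = np.zeros(total)
        inv = 0.0
        for d in range(total):
            inv += refills.get(d, 0.0)
            use = min(1.0, inv)
            cov[d] = use
            inv -= use
        smoothed = np.zeros(total)
        days = sorted(refills)
        bounds = days + [total]
        for s, e in zip(bounds[:-1], bounds[1:]):
            smoothed[s:e] = cov[s:e].mean()
        np.maximum(out, smoothed, out=out)
    return out


def window_means(
    daily: np.ndarray,
    baseline: pd.Timestamp,
    followup_end: pd.Timestamp,
    window_months: int,
) -> list[float]:
    """Mean of per-day values over consecutive calendar windows."""
    vals = []
    i = 1
    prev = baseline
    while True:
        b = baseline + pd.DateOffset(months=window_months * i)
        if b > followup_end:
            break
        s = int((prev - baseline) / pd.Timedelta(days=1))
        e = int((b - baseline) / pd.Timedelta(days=1))
        vals.append(float(daily[s:e].mean()))
        prev = b
        i += 1
    return vals


def pairwise_auc(score: np.ndarray, positive: np.ndarray) -> float:
    """Mann-Whitney AUC by exhaustive pair enumeration (low score -> positive)."""
    s = np.asarray(score, dtype=float)
    y = np.asarray(positive, dtype=bool)
    pos, neg = s[y], s[~y]
    wins = 0.0
    for a in pos:
        for b in neg:
            if a < b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def calinski_harabasz(x: np.ndarray, assign: np.ndarray) -> float:
    """CH criterion evaluated directly from its definition."""
    x = np.asarray(x, dtype=float)
    labels = np.unique(assign)
    k, n = len(labels), len(x)
    grand = x.mean(axis=0)
    wss = sum(((x[assign == j] - x[assign == j].mean(axis=0)) ** 2).sum() for j in labels)
    bss = sum(
        (assign == j).sum() * ((x[assign == j].mean(axis=0) - grand) ** 2).sum()
        for j in labels
    )
    return (bss / (k - 1)) / (wss / (n - k))


def random_claim_history(
    rng: np.random.Generator,
    multi_stream: bool = False,
) -> tuple[pd.DataFrame, pd.Timestamp, pd.Timestamp]:
    """Random refill history with early refills, gaps and odd doses."""
    baseline = pd.Timestamp("2015-01-01") + pd.Timedelta(days=int(rng.integers(0, 400)))
    total = int(rng.integers(120, 900))
    followup_end = baseline + pd.Timedelta(days=total)
    atcs = ["J05AR10", "J05AG03"] if multi_stream and rng.random() < 0.7 else ["J05AR10"]
    rows = []
    for atc in atcs:
        day = 0
        while day < total:
            dur = float(rng.choice([14, 28, 30, 30, 60, 18.666666666666668]))
            rows.append((baseline + pd.Timedelta(days=day), atc, dur))
            gap = int(rng.choice([10, 20, 25, 30, 30, 35, 45, 90, 150]))
            day += gap
    claims = pd.DataFrame(rows, columns=["dispense_date", "atc_code", "duration_days"])
    return claims, baseline, followup_end
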