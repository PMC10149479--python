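"""Longitudinal k-means clustering of 3-monthly adherence trajectories.

Patients with at least 3 years (12 quarters) of observed CMA are
clustered on their first 5 years (20 quarters) of 3-monthly CMA values.
Missing tails are imputed with each patient's own observed trajectory
mean.  Clustering is plain Lloyd/EM k-means under Euclidean distance on
the 20-vector (CMA is already on [0, 1], so no standardisation), run
best-of-n-starts, with cluster count chosen between 2 and 6 by the
Calinski-Harabasz (maximise) and Ray-Turi (minimise) criteria.

Fitted centroids are labelled by their early (first 4 quarters) and late
(last 4 quarters) mean adherence relative to a high-adherence threshold:
high->high  continuous_high, high->low  decreasing,
low->high   increasing,      low->low   continuous_non_adherence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_WINDOWS = 20  # five years of 3-month windows
MIN_OBSERVED = 12  # three years


@dataclass
class TrajectoryModel:
    """A fitted longitudinal k-means model."""

    k: int
    centroids: np.ndarray  # (k, n_windows)
    assignments: np.ndarray  # (n,) int cluster ids
    within_ss: float
    between_ss: float
    n_iter: int
    criteria: dict[str, float] = field(default_factory=dict)
    labels: dict[int, str] = field(default_factory=dict)

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.k)


def build_trajectory_matrix(
    cma_3m: pd.DataFrame,
    n_windows: int = N_WINDOWS,
    min_observed: int = MIN_OBSERVED,
) -> tuple[pd.Index, np.ndarray, np.ndarray]:
    """Patients x quarters matrix from a long 3-monthly CMA table.

    ``cma_3m`` has columns patient_id, window_index, cma_value.  Windows
    beyond ``n_windows`` are ignored; patients with fewer than
    ``min_observed`` observed windows are excluded.  Returns (patient
    index, matrix with NaN for missing, observed mask).
    """
    sub = cma_3m[cma_3m["window_index"] < n_windows]
    wide = sub.pivot(index="patient_id", columns="window_index", values="cma_value")
    wide = wide.reindex(columns=range(n_windows))
    keep = wide.notna().sum(axis=1) >= min_observed
    wide = wide[keep]
    mat = wide.to_numpy(dtype=float)
    return wide.index, mat, ~np.isnan(mat)


def impute_trajectory(matrix: np.ndarray) -> np.ndarray:
    """Fill missing values with each row's own observed mean."""
    mat = np.asarray(matrix, dtype=float).copy()
    obs = ~np.isnan(mat)
    if (obs.sum(axis=1) == 0).any():
        raise ValueError("row with no observed values; filter upstream")
    row_means = np.nansum(mat, axis=1) / obs.sum(axis=1)
    idx = np.where(~obs)
    mat[idx] = row_means[idx[0]]
    return mat


def _within_ss(x: np.ndarray, centroids: np.ndarray, assign: np.ndarray) -> float:
    return float(((x - centroids[assign]) ** 2).sum())


def _lloyd(x: np.ndarray, init: np.ndarray, max_iter: int = 200) -> tuple[np.ndarray, np.ndarray, int]:
    """One Lloyd run from given initial centroids.

    Empty clusters are re-seeded from the point farthest from its
    centroid.  The within-cluster SS is non-increasing across
    iterations (asserted).
    """
    centroids = init.copy()
    k = len(centroids)
    prev_assign = None
    prev_ss = np.inf
    for it in range(1, max_iter + 1):
        d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        assign = d2.argmin(axis=1)
        for j in range(k):
            if not (assign == j).any():
                far = ((x - centroids[assign]) ** 2).sum(axis=1).argmax()
                warnings.warn(f"empty cluster {j}; re-seeding from farthest point")
                centroids[j] = x[far]
                assign[far] = j
        for j in range(k):
            centroids[j] = x[assign == j].mean(axis=0)
        ss = _within_ss(x, centroids, assign)
        assert ss <= prev_ss + 1e-9, "within-cluster SS increased"
        if prev_assign is not None and (assign == prev_assign).all():
            return centroids, assign, it
        prev_assign, prev_ss = assign, ss
    return centroids, assign, max_iter


def _kmeanspp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: spread initial centroids by D^2 sampling."""
    n = len(x)
    centroids = np.empty((k, x.shape[1]))
    centroids[0] = x[rng.integers(n)]
    d2 = ((x - centroids[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        probs = d2 / total if total > 0 else np.full(n, 1.0 / n)
        centroids[j] = x[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, ((x - centroids[j]) ** 2).sum(axis=1))
    return centroids


def fit_kmeans_longitudinal(
    matrix: np.ndarray,
    k: int,
    n_starts: int = 5,
    seed: int | np.random.Generator = 0,
    max_iter: int = 200,
) -> TrajectoryModel:
    """Best-of-``n_starts`` Lloyd k-means on a complete trajectory matrix.

    Each start is seeded with k-means++ (D^2 sampling); the run with the
    lowest within-cluster sum of squares wins.  Deterministic given the
    seed.
    """
    x = np.asarray(matrix, dtype=float)
    if np.isnan(x).any():
        raise ValueError("matrix contains missing values; impute first")
    n = len(x)
    if not 2 <= k <= min(6, n):
        raise ValueError(f"k={k} out of range for n={n}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    best = None
    for _ in range(n_starts):
        init = _kmeanspp_init(x, k, rng)
        centroids, assign, n_iter = _lloyd(x, init, max_iter=max_iter)
        ss = _within_ss(x, centroids, assign)
        if best is None or ss < best[0]:
            best = (ss, centroids, assign, n_iter)
    ss, centroids, assign, n_iter = best
    grand = x.mean(axis=0)
    sizes = np.bincount(assign, minlength=k)
    between = float((sizes[:, None] * (centroids - grand) ** 2).sum())
    model = TrajectoryModel(
        k=k, centroids=centroids, assignments=assign,
        within_ss=ss, between_ss=between, n_iter=n_iter,
    )
    model.criteria = dict(zip(("calinski_harabasz", "ray_turi"), quality_criteria(model, x)))
    model.labels = label_patterns(centroids)
    return model


def quality_criteria(model: TrajectoryModel, matrix: np.ndarray) -> tuple[float, float]:
    """(Calinski-Harabasz, Ray-Turi) for a fitted model.

    CH = (between_SS/(k-1)) / (within_SS/(n-k)); larger is better.
    Ray-Turi = mean squared distance of points to their own centroid
    divided by the minimum squared distance between centroid pairs;
    smaller is better.
    """
    x = np.asarray(matrix, dtype=float)
    n, k = len(x), model.k
    if k < 2:
        raise ValueError("criteria undefined for k < 2")
    ch = (model.between_ss / (k - 1)) / (model.within_ss / (n - k))
    mean_d2 = model.within_ss / n
    cd2 = ((model.centroids[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    min_sep = cd2[np.triu_indices(k, 1)].min()
    return float(ch), float(mean_d2 / min_sep)


PATTERN_LABELS = (
    "continuous_high",
    "decreasing",
    "increasing",
    "continuous_non_adherence",
)


def label_patterns(centroids: np.ndarray, threshold: float = 0.8, edge: int = 4) -> dict[int, str]:
    """Name each centroid by its early/late mean adherence.

    "High" means mean CMA >= ``threshold`` over the first/last ``edge``
    windows.  All four early/late combinations map to a pattern name, so
    every centroid receives a label; a flat mid-range centroid (e.g.
    0.5 -> 0.5) classifies as continuous_non_adherence and is flagged
    borderline in a warning when within 0.05 of the threshold.
    """
    labels = {}
    for j, c in enumerate(np.asarray(centroids)):
        early, late = c[:edge].mean(), c[-edge:].mean()
        hi_e, hi_l = early >= threshold, late >= threshold
        if hi_e and hi_l:
            labels[j] = "continuous_high"
        elif hi_e:
            labels[j] = "decreasing"
        elif hi_l:
            labels[j] = "increasing"
        else:
            labels[j] = "continuous_non_adherence"
        if abs(early - threshold) < 0.05 or abs(late - threshold) < 0.05:
            warnings.warn(f"centroid {j} borderline at threshold {threshold}")
    return labels


def select_k(
    matrix: np.ndarray,
    k_range: range = range(2, 7),
    n_starts: int = 5,
    seed: int = 0,
) -> tuple[TrajectoryModel, pd.DataFrame]:
    """Fit k-means over a range of k and tabulate the quality criteria.

    Returns the model with the highest Calinski-Harabasz criterion and
    the per-k criteria table (the Ray-Turi criterion is reported
    alongside for inspection, mirroring a selection that also weighs
    clinical interpretability).
    """
    rng = np.random.default_rng(seed)
    models, rows = {}, []
    for k in k_range:
        m = fit_kmeans_longitudinal(matrix, k, n_starts=n_starts, seed=rng)
        models[k] = m
        rows.append((k, m.criteria["calinski_harabasz"], m.criteria["ray_turi"], m.within_ss))
    table = pd.DataFrame(rows, columns=["k", "calinski_harabasz", "ray_turi", "within_ss"])
    best_k = int(table.loc[table["calinski_harabasz"].idxmax(), "k"])
    return models[best_k], table


def group_shares(model: TrajectoryModel) -> dict[str, float]:
    """Share of patients per labelled pattern (sums to 1)."""
    n = len(model.assignments)
    shares: dict[str, float] = {}
    for j in range(model.k):
        lbl = model.labels.get(j, f"cluster_{j}")
        shares[lbl] = shares.get(lbl, 0.0) + float((model.assignments == j).sum()) / n
    return shares
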