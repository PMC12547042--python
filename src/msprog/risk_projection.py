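"""Whole-population disability distribution, risk stratification, projection.

The trained classifier is applied to the full cohort year by year to track
the disability-class mix over time.  For projection, each patient's
predicted 5-year cumulative hazard H5 is converted into a progression
probability p5 = 1 - exp(-H5); k-means on H5 splits the population into
low / moderate / high risk, with the high-risk threshold defined as the
smallest H5 assigned to the high cluster.  Class transitions over the
horizon are restricted to the adjacent higher class (C3 absorbing) and can
be projected either as expected probability mass (default) or by moving
exactly the high-risk patients (threshold mode).

One-dimensional k-means is solved exactly by dynamic programming over
contiguous partitions: in 1-D, optimal within-cluster-sum-of-squares
clusters are contiguous in sorted order, so the DP optimum is the global
optimum — no restarts needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cohort_features as cf
from .edss import CLASSES
from .edss_net import TrainedClassifier, predict_classes

RISK_LABELS = ("low", "moderate", "high")


# ---------------------------------------------------------------------------
# Yearly class distribution
# ---------------------------------------------------------------------------

def yearly_distribution(
    model: TrainedClassifier,
    included: pd.DataFrame,
    tables: dict[str, pd.DataFrame],
    years,
    dmt_catalog=None,
    code_lists=None,
) -> pd.DataFrame:
    """Predicted class proportions per calendar year.

    For each year, patients with at least one record that year (and entry on
    or before the window start) are scored on features aggregated over the
    window [Jan 1, Jul 1); proportions sum to 1.  Years with no active
    patients are omitted with a warning.
    """
    rows = []
    for year in years:
        y0, y1 = pd.Timestamp(f"{year}-01-01"), pd.Timestamp(f"{year}-12-31")
        active = set()
        for name, col in (("prescriptions", "date"), ("admissions", "admit_date"), ("outpatients", "date")):
            df = tables[name]
            active |= set(df.loc[(df[col] >= y0) & (df[col] <= y1), "patient_id"])
        cohort = included[included["patient_id"].isin(active)].reset_index(drop=True)
        if not len(cohort):
            warnings.warn(f"no active patients in {year}; year omitted", stacklevel=2)
            continue
        feats = cf.build_features(
            cohort, tables, dmt_catalog, code_lists,
            window_start=pd.Series([y0] * len(cohort)),
        )
        pred = predict_classes(model, feats)
        props = pred["predicted_class"].value_counts(normalize=True)
        rows.append({"year": int(year), **{c: float(props.get(c, 0.0)) for c in CLASSES}})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Exact 1-D k-means
# ---------------------------------------------------------------------------

def kmeans_1d(values, k: int = 3, n_restarts: int = 10, seed=None):
    """Optimal 1-D k-means: centroids (ascending) and per-value cluster labels.

    Solved exactly by DP over contiguous partitions of the sorted values, so
    ``n_restarts`` and ``seed`` are inert (accepted for interface
    compatibility with stochastic k-means).  Labels are ordered by centroid,
    making low/moderate/high assignments deterministic.
    """
    v = np.asarray(values, dtype=float).reshape(-1)
    if len(np.unique(v)) < k:
        raise ValueError(f"need at least k={k} distinct values, got {len(np.unique(v))}")
    order = np.argsort(v, kind="mergesort")
    x = v[order]
    n = len(x)
    s1 = np.r_[0.0, np.cumsum(x)]
    s2 = np.r_[0.0, np.cumsum(x * x)]

    def seg_cost(i: np.ndarray, j: int) -> np.ndarray:
        # within-cluster SS of x[i..j] inclusive, vectorised over i
        m = j + 1 - i
        return (s2[j + 1] - s2[i]) - (s1[j + 1] - s1[i]) ** 2 / m

    cost = np.full((k, n), np.inf)
    split = np.zeros((k, n), dtype=int)
    j_all = np.arange(n)
    cost[0] = (s2[j_all + 1] - s2[0]) - (s1[j_all + 1] - s1[0]) ** 2 / (j_all + 1)
    for kk in range(1, k):
        for j in range(kk, n):
            i = np.arange(kk, j + 1)  # first index of the last cluster
            total = cost[kk - 1, i - 1] + seg_cost(i, j)
            best = int(np.argmin(total))
            cost[kk, j] = total[best]
            split[kk, j] = i[best]

    # backtrack cluster boundaries
    bounds = np.empty(k + 1, dtype=int)
    bounds[k] = n
    j = n - 1
    for kk in range(k - 1, 0, -1):
        i = split[kk, j]
        bounds[kk] = i
        j = i - 1
    bounds[0] = 0
    labels_sorted = np.empty(n, dtype=int)
    centroids = np.empty(k)
    for kk in range(k):
        lo, hi = bounds[kk], bounds[kk + 1]
        labels_sorted[lo:hi] = kk
        centroids[kk] = x[lo:hi].mean()
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return centroids, labels


def risk_threshold(values, labels, n_clusters: int = 3) -> float:
    """High-risk threshold: the smallest value assigned to the top cluster."""
    v = np.asarray(values, dtype=float).reshape(-1)
    labels = np.asarray(labels)
    high = labels == n_clusters - 1
    if not high.any():
        raise ValueError("high-risk cluster is empty")
    return float(v[high].min())


def assign_clusters(values, centroids) -> np.ndarray:
    """Nearest-centroid assignment (integer labels ordered by centroid)."""
    v = np.asarray(values, dtype=float).reshape(-1)
    c = np.sort(np.asarray(centroids, dtype=float))
    return np.argmin(np.abs(v[:, None] - c[None, :]), axis=1)


def stratify_risk(h5_values, fit_mask=None) -> tuple[np.ndarray, np.ndarray, float]:
    """Cluster 5-year cumulative hazards into low/moderate/high.

    ``fit_mask`` selects the values used to fit the clusters (e.g. patients
    still able to progress); every value is then assigned to its nearest
    centroid, so the assignment stays a total function of H5.  Returns
    (risk labels as strings, centroids, high-risk threshold).
    """
    v = np.asarray(h5_values, dtype=float).reshape(-1)
    fit_v = v if fit_mask is None else v[np.asarray(fit_mask, dtype=bool)]
    centroids, fit_labels = kmeans_1d(fit_v, k=3)
    labels = assign_clusters(v, centroids)
    return np.array(RISK_LABELS)[labels], centroids, risk_threshold(fit_v, fit_labels)


# ---------------------------------------------------------------------------
# Transition projection
# ---------------------------------------------------------------------------

@dataclass
class TransitionTable:
    """3x3 matrix of population proportions: rows = current class, columns =
    projected class; progression-only (strictly lower-triangular part zero)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("transition table must be 3x3")
        if np.any(m < -1e-12):
            raise ValueError("transition table has negative flows")
        if abs(m.sum() - 1.0) > 1e-9:
            raise ValueError("transition table mass must sum to 1 within 1e-9")
        if np.any(np.tril(m, k=-1) > 1e-12):
            raise ValueError("downward flows are not allowed (progression-only)")
        self.matrix = m

    @property
    def current_marginals(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    @property
    def projected_marginals(self) -> np.ndarray:
        return self.matrix.sum(axis=0)


def project_transitions(profiles: pd.DataFrame, mode: str = "expected", threshold: float | None = None) -> TransitionTable:
    """Project the class mix over the horizon from per-patient risk profiles.

    ``profiles`` needs ``current_class`` and ``p5`` (and ``h5`` in threshold
    mode).  In ``expected`` mode each patient contributes p5 of its mass to
    the adjacent higher class and 1-p5 to staying; in ``threshold`` mode
    patients move iff their h5 reaches the high-risk threshold.  C3 is
    absorbing in both modes.
    """
    n = len(profiles)
    if n == 0:
        raise ValueError("no patients to project")
    cls_idx = profiles["current_class"].map({c: i for i, c in enumerate(CLASSES)})
    if cls_idx.isna().any():
        raise ValueError(f"current_class must be one of {CLASSES}")
    if mode == "expected":
        p_move = profiles["p5"].to_numpy(dtype=float)
        if np.any((p_move < 0) | (p_move > 1)):
            raise ValueError("p5 must lie in [0, 1]")
    elif mode == "threshold":
        if threshold is None:
            raise ValueError("threshold mode requires a threshold value")
        p_move = (profiles["h5"].to_numpy(dtype=float) >= threshold).astype(float)
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'expected' or 'threshold'")
    m = np.zeros((3, 3))
    ci = cls_idx.to_numpy(dtype=int)
    p_move = np.where(ci == 2, 0.0, p_move)  # C3 absorbing
    np.add.at(m, (ci, np.minimum(ci + 1, 2)), p_move / n)
    np.add.at(m, (ci, ci), (1.0 - p_move) / n)
    return TransitionTable(m)


def sankey_export(table: TransitionTable) -> pd.DataFrame:
    """Flow records (source_class, target_class, flow) for Sankey plotting;
    zero flows are omitted."""
    rows = [
        {"source_class": CLASSES[i], "target_class": CLASSES[j], "flow": table.matrix[i, j]}
        for i in range(3)
        for j in range(3)
        if table.matrix[i, j] > 0
    ]
    return pd.DataFrame(rows)


def table_from_flows(flows: pd.DataFrame) -> TransitionTable:
    """Inverse of :func:`sankey_export`."""
    m = np.zeros((3, 3))
    idx = {c: i for i, c in enumerate(CLASSES)}
    for _, r in flows.iterrows():
        m[idx[r["source_class"]], idx[r["target_class"]]] = r["flow"]
    return TransitionTable(m)
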