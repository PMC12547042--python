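"""Evaluation statistics for the classifier and the survival model.

Classification: accuracy, macro-averaged precision/recall/F1 (per-class
values also reported), per-class sensitivity and specificity, with 95%
percentile-bootstrap confidence intervals at the patient level.

Survival: Harrell's concordance index, the Kaplan-Meier product-limit
estimator, and the Integrated Brier Score with inverse-probability-of-
censoring weights estimated by the Kaplan-Meier estimator of the censoring
distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from sklearn.metrics import confusion_matrix as _sk_confusion

from .edss import CLASSES


@dataclass
class StepFunction:
    """Right-continuous step function: value y[i] on [x[i], x[i+1])."""

    x: np.ndarray
    y: np.ndarray
    init_value: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)

    def __call__(self, t, side: str = "right"):
        """Evaluate at t; ``side='left'`` gives the left limit (value just
        before t), used for censoring weights at event times."""
        idx = np.searchsorted(self.x, t, side="right" if side == "right" else "left")
        vals = np.r_[self.init_value, self.y]
        return vals[idx]


# ---------------------------------------------------------------------------
# Classification metrics
# ---------------------------------------------------------------------------

def _encode(labels) -> np.ndarray:
    return pd.Series(labels).map({c: i for i, c in enumerate(CLASSES)}).to_numpy()


def _macro_metrics(cm: np.ndarray) -> dict[str, float]:
    tp = np.diag(cm).astype(float)
    col = cm.sum(axis=0).astype(float)
    row = cm.sum(axis=1).astype(float)
    present = row > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, tp / col, 0.0)
        recall = np.where(row > 0, tp / row, 0.0)
        f1 = np.where(precision + recall > 0, 2 * precision * recall / (precision + recall), 0.0)
    return {
        "accuracy": tp.sum() / cm.sum(),
        "precision": precision[present].mean(),
        "recall": recall[present].mean(),
        "f1": f1[present].mean(),
    }


def classification_report(
    true_labels, predicted_labels, n_boot: int = 1000, seed: int = 0
) -> dict:
    """Full classification report with bootstrap confidence intervals.

    Accuracy is the diagonal fraction of the 3x3 confusion matrix;
    precision/recall/F1 are macro-averaged over observed classes; per-class
    sensitivity is the recall of that class and specificity its true-negative
    rate against the other classes pooled.  95% CIs come from a seeded
    patient-level percentile bootstrap with ``n_boot`` resamples.
    """
    yt, yp = _encode(true_labels), _encode(predicted_labels)
    if len(yt) == 0:
        raise ValueError("empty label vectors")
    if len(yt) != len(yp) or np.isnan(yt.astype(float)).any() or np.isnan(yp.astype(float)).any():
        raise ValueError(f"labels must be equal-length vectors over {CLASSES}")
    k = len(CLASSES)
    cm = _sk_confusion(yt, yp, labels=range(k))
    out = {"confusion_matrix": cm, **_macro_metrics(cm)}

    per_class = {}
    total = cm.sum()
    for i, c in enumerate(CLASSES):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        per_class[c] = {
            "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
            "specificity": tn / (tn + fp) if tn + fp else np.nan,
        }
    out["per_class"] = per_class

    # patient-level percentile bootstrap via the flattened confusion cell index
    rng = np.random.default_rng(seed)
    cell = yt * k + yp
    stats = np.empty((n_boot, 4))
    n = len(cell)
    for b in range(n_boot):
        resampled = cell[rng.integers(0, n, n)]
        bcm = np.bincount(resampled, minlength=k * k).reshape(k, k)
        m = _macro_metrics(bcm)
        stats[b] = (m["accuracy"], m["precision"], m["recall"], m["f1"])
    lo, hi = np.percentile(stats, [2.5, 97.5], axis=0)
    out["ci95"] = {
        name: (float(lo[i]), float(hi[i]))
        for i, name in enumerate(("accuracy", "precision", "recall", "f1"))
    }
    return out


# ---------------------------------------------------------------------------
# Survival metrics
# ---------------------------------------------------------------------------

def concordance_index(times, events, risk_scores) -> float:
    """Harrell's C: fraction of comparable pairs ordered correctly.

    A pair (i, j) with t_i < t_j is comparable iff the earlier subject had
    the event; it is concordant when risk_i > risk_j, and tied risks earn
    half credit.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    risk = np.asarray(risk_scores, dtype=float)
    # vectorised pairwise evaluation; comparable pairs require a strictly
    # earlier observed event, so tied times never enter
    comparable = (times[:, None] < times[None, :]) & (events[:, None] == 1)
    n_pairs = comparable.sum()
    if n_pairs == 0:
        raise ValueError("no comparable pairs to evaluate the concordance index")
    diff = risk[:, None] - risk[None, :]
    concordant = (diff > 0) & comparable
    tied = (diff == 0) & comparable
    return float((concordant.sum() + 0.5 * tied.sum()) / n_pairs)


@dataclass
class KMCurve:
    """Kaplan-Meier product-limit curve with at-risk counts."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def __call__(self, t):
        return StepFunction(self.times, self.survival, init_value=1.0)(t)


def kaplan_meier(times, events) -> KMCurve:
    """Product-limit estimate of the survival function."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("empty sample")
    if np.any(times < 0):
        raise ValueError("negative times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    t = kmf.survival_function_.index.to_numpy(dtype=float)
    s = kmf.survival_function_["KM_estimate"].to_numpy()
    keep = t > 0
    at_risk = kmf.event_table["at_risk"].reindex(t[keep]).to_numpy(dtype=float)
    return KMCurve(t[keep], s[keep], at_risk)


def censoring_survival(times, events) -> StepFunction:
    """KM estimate of the censoring distribution G(t) (events flipped)."""
    times = np.asarray(times, dtype=float)
    cens = 1 - np.asarray(events, dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(times, cens)
    t = kmf.survival_function_.index.to_numpy(dtype=float)
    s = kmf.survival_function_["KM_estimate"].to_numpy()
    keep = t > 0
    return StepFunction(t[keep], s[keep], init_value=1.0)


def brier_scores(surv_probs: np.ndarray, times, events, grid) -> np.ndarray:
    """IPCW Brier score BS(t) at each grid time.

    ``surv_probs[i, j]`` is subject i's predicted S(grid[j]).  Subjects whose
    required censoring-survival weight is zero are dropped from that time
    point with a warning.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    grid = np.asarray(grid, dtype=float)
    surv_probs = np.asarray(surv_probs, dtype=float)
    if surv_probs.shape != (len(times), len(grid)):
        raise ValueError("surv_probs must have shape (n_subjects, len(grid))")
    G = censoring_survival(times, events)
    g_at_event = G(times, side="left")  # G(t_i-)
    n = len(times)
    bs = np.zeros(len(grid))
    dropped = 0
    for j, t in enumerate(grid):
        g_t = float(G(t))
        had_event = (times <= t) & (events == 1)
        still_at_risk = times > t
        w_event = np.where(g_at_event > 0, 1.0 / np.where(g_at_event > 0, g_at_event, 1.0), 0.0)
        dropped += int(np.sum(had_event & (g_at_event == 0)))
        contrib = np.zeros(n)
        contrib[had_event] = surv_probs[had_event, j] ** 2 * w_event[had_event]
        if still_at_risk.any():
            if g_t > 0:
                contrib[still_at_risk] = (1.0 - surv_probs[still_at_risk, j]) ** 2 / g_t
            else:
                dropped += int(still_at_risk.sum())
        bs[j] = contrib.sum() / n
    if dropped:
        warnings.warn(
            f"{dropped} subject-time contributions dropped (censoring survival = 0)",
            stacklevel=2,
        )
    return bs


def integrated_brier_score(surv_probs: np.ndarray, times, events, grid=None) -> float:
    """Trapezoid average of BS(t) over the grid.

    Default grid: 100 evenly spaced points from the first to the last
    observed event time.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if grid is None:
        ev = times[events == 1]
        if len(ev) < 2 or ev.min() == ev.max():
            raise ValueError("cannot build a default grid without two distinct event times")
        grid = np.linspace(ev.min(), ev.max(), 100)
    grid = np.asarray(grid, dtype=float)
    if len(grid) < 2:
        raise ValueError("grid must contain at least two time points")
    bs = brier_scores(surv_probs, times, events, grid)
    return float(np.trapezoid(bs, grid) / (grid[-1] - grid[0]))
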