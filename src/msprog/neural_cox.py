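"""Hybrid neural-network / Cox proportional-hazards progression model.

A feed-forward network (default 32-32-16 hidden units, ReLU) maps a
patient's feature vector to a scalar log-relative risk g(x).  Training
minimises the negative log Cox partial likelihood (Breslow convention for
tied event times) with Adam, full-batch — risk sets are global, so
mini-batching would bias the partial likelihood — with early stopping when
the validation loss plateaus.  Model evaluation uses five outer folds: each
fold's 20% is the test subset and the remaining 80% is split into training
(60% of the total) and validation (20%) portions.

The network only orders patients by risk; absolute survival comes from the
Breslow baseline cumulative hazard

    H0(t) = sum_{event times t_i <= t} d_i / sum_{j in R(t_i)} exp(g_j),

which reduces to the Nelson-Aalen estimator when all scores are equal.
Predicted cumulative hazard is H(t|x) = H0(t) exp(g(x)) and survival
S(t|x) = exp(-H(t|x)).
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from ._mlp import Adam, DenseNet, Scaler
from .eval_metrics import StepFunction, concordance_index, integrated_brier_score

logger = logging.getLogger(__name__)


@dataclass
class SurvivalModelConfig:
    hidden_sizes: tuple[int, ...] = (32, 32, 16)
    learning_rate: float = 0.01
    l2_strength: float = 1e-4
    max_epochs: int = 500
    patience: int = 10
    tol: float = 1e-4
    cv_folds: int = 5
    split_fracs: tuple[float, float, float] = (0.60, 0.20, 0.20)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.split_fracs) - 1.0) > 1e-9:
            raise ValueError("split_fracs must sum to 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")


# ---------------------------------------------------------------------------
# Cox partial likelihood
# ---------------------------------------------------------------------------

def _cox_loss_grad(scores: np.ndarray, times: np.ndarray, events: np.ndarray):
    """Negative log partial likelihood (Breslow ties) and its gradient."""
    scores = np.asarray(scores, dtype=float).reshape(-1)
    times = np.asarray(times, dtype=float).reshape(-1)
    events = np.asarray(events, dtype=int).reshape(-1)
    if not (len(scores) == len(times) == len(events)):
        raise ValueError("scores, times and events must have equal length")
    if events.sum() == 0:
        raise ValueError("Cox partial likelihood is undefined with zero events")

    order = np.argsort(times, kind="mergesort")
    t, g, e = times[order], scores[order], events[order]
    m = g.max()
    eg = np.exp(g - m)
    # risk-set sums: all subjects with t_j >= t_i; within a tied block every
    # subject shares the block-start suffix sum
    suffix = np.cumsum(eg[::-1])[::-1]
    first_of_block = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    block_id = np.cumsum(np.r_[True, t[1:] != t[:-1]]) - 1
    S = suffix[first_of_block][block_id]  # scaled by exp(-m)

    loss = -(np.sum(g[e == 1]) - np.sum(np.log(S[e == 1]) + m))

    # gradient: -e_i + exp(g_i) * sum_{event times t_k <= t_i} d_k / S_k
    contrib = np.zeros(len(t))
    np.add.at(contrib, np.flatnonzero(e == 1), 1.0 / S[e == 1])
    per_block = np.zeros(len(first_of_block))
    np.add.at(per_block, block_id, contrib)
    cum = np.cumsum(per_block)[block_id]
    grad_sorted = -e + eg * cum
    grad = np.empty_like(grad_sorted)
    grad[order] = grad_sorted
    return float(loss), grad


def cox_loss(risk_scores, times, events) -> float:
    """Negative log Cox partial likelihood of a risk-score vector.

    Risk set R(t) = {j : t_j >= t}; tied event times follow the Breslow
    approximation.  Invariant under adding a constant to all scores.
    """
    return _cox_loss_grad(risk_scores, times, events)[0]


# ---------------------------------------------------------------------------
# Breslow baseline hazard
# ---------------------------------------------------------------------------

def breslow_baseline(risk_scores, times, events) -> StepFunction:
    """Baseline cumulative hazard H0 given fitted risk scores.

    With all scores equal this is the Nelson-Aalen estimator (up to the
    common factor exp(g), which cancels in H0 * exp(g)).
    """
    scores = np.asarray(risk_scores, dtype=float).reshape(-1)
    times = np.asarray(times, dtype=float).reshape(-1)
    events = np.asarray(events, dtype=int).reshape(-1)
    order = np.argsort(times, kind="mergesort")
    t, g, e = times[order], scores[order], events[order]
    eg = np.exp(g)
    suffix = np.cumsum(eg[::-1])[::-1]
    first_of_block = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    block_id = np.cumsum(np.r_[True, t[1:] != t[:-1]]) - 1
    S = suffix[first_of_block]
    d = np.zeros(len(first_of_block))
    np.add.at(d, block_id, e)
    event_blocks = d > 0
    h0_times = t[first_of_block][event_blocks]
    h0 = np.cumsum(d[event_blocks] / S[event_blocks])
    return StepFunction(h0_times, h0, init_value=0.0)


# ---------------------------------------------------------------------------
# Model container and training
# ---------------------------------------------------------------------------

@dataclass
class RiskModel:
    net: DenseNet
    scaler: Scaler
    feature_names: list[str]
    baseline: StepFunction
    config: SurvivalModelConfig
    fold_reports: list[dict] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        Path(path).write_bytes(pickle.dumps(self))

    @classmethod
    def load(cls, path: str | Path) -> "RiskModel":
        obj = pickle.loads(Path(path).read_bytes())
        if not isinstance(obj, cls):
            raise TypeError(f"{path} does not contain a RiskModel")
        return obj


def _matrix(features, feature_names=None):
    if isinstance(features, pd.DataFrame):
        if feature_names is None:
            feature_names = [c for c in features.columns if features[c].dtype.kind in "ifb"]
        missing = [c for c in feature_names if c not in features.columns]
        if missing:
            raise ValueError(f"feature schema mismatch; missing columns: {missing}")
        return features[feature_names].to_numpy(dtype=float), feature_names
    X = np.asarray(features, dtype=float)
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(X.shape[1])]
    return X, feature_names


def _fit_net(Xtr, ttr, etr, Xval, tval, evl, config: SurvivalModelConfig, rng) -> DenseNet:
    net = DenseNet(Xtr.shape[1], config.hidden_sizes, 1, rng)
    opt = Adam(net.params, lr=config.learning_rate)
    best_val, best_params, stall = np.inf, None, 0
    n = len(Xtr)
    for _ in range(config.max_epochs):
        out, cache = net.forward(Xtr)
        _, grad = _cox_loss_grad(out[:, 0], ttr, etr)
        opt.step(net.params, net.backward(cache, grad[:, None] / n, l2=config.l2_strength))
        val_out = net.forward(Xval)[0][:, 0]
        val_loss = cox_loss(val_out, tval, evl) / max(evl.sum(), 1)
        if val_loss < best_val - config.tol:
            best_val = val_loss
            best_params = [p.copy() for p in net.params]
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
    if best_params is not None:
        for p, bp in zip(net.params, best_params):
            p[...] = bp
    return net


def risk_scores(model: RiskModel, features) -> np.ndarray:
    X, _ = _matrix(features, model.feature_names)
    return model.net.forward(model.scaler.transform(X))[0][:, 0]


def train_survival(features, times, events, config: SurvivalModelConfig | None = None) -> RiskModel:
    """Train the progression model with outer-fold evaluation.

    Each of the ``cv_folds`` outer folds serves once as the 20% test subset;
    the remaining patients are split 60/20 (of the total) into training and
    validation, stratified by event status.  Per-fold C-index and IBS are
    stored in ``fold_reports``.  The returned model is refit on all samples
    (with an internal stratified 80/20 early-stopping split) and carries the
    Breslow baseline hazard estimated from the full sample.
    """
    config = config or SurvivalModelConfig()
    X, feature_names = _matrix(features)
    times = np.asarray(times, dtype=float).reshape(-1)
    events = np.asarray(events, dtype=int).reshape(-1)
    if np.any(times <= 0):
        raise ValueError("times must be positive")

    folds = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    rng = np.random.default_rng(config.seed)
    val_of_trainval = config.split_fracs[1] / (config.split_fracs[0] + config.split_fracs[1])
    fold_reports = []
    for fold_no, (trainval_idx, test_idx) in enumerate(folds.split(X, events)):
        if events[trainval_idx].sum() < 2:
            raise ValueError(
                f"fold {fold_no}: fewer than 2 events in the training portion; "
                "use folds stratified by event status or more data"
            )
        tr_idx, val_idx = train_test_split(
            trainval_idx,
            test_size=val_of_trainval,
            random_state=config.seed + fold_no,
            stratify=events[trainval_idx],
        )
        scaler = Scaler.fit(X[tr_idx])
        net = _fit_net(
            scaler.transform(X[tr_idx]), times[tr_idx], events[tr_idx],
            scaler.transform(X[val_idx]), times[val_idx], events[val_idx],
            config, rng,
        )
        g_tr = net.forward(scaler.transform(X[tr_idx]))[0][:, 0]
        g_te = net.forward(scaler.transform(X[test_idx]))[0][:, 0]
        h0 = breslow_baseline(g_tr, times[tr_idx], events[tr_idx])
        report = {"fold": fold_no, "n_test": len(test_idx)}
        try:
            report["c_index"] = concordance_index(times[test_idx], events[test_idx], g_te)
        except ValueError:
            report["c_index"] = np.nan
        ev_times = times[test_idx][events[test_idx] == 1]
        if len(ev_times) >= 2 and ev_times.min() < ev_times.max():
            grid = np.linspace(ev_times.min(), ev_times.max(), 100)
            surv = np.exp(-np.outer(np.exp(g_te), h0(grid)))
            report["ibs"] = integrated_brier_score(surv, times[test_idx], events[test_idx], grid)
        else:
            report["ibs"] = np.nan
        fold_reports.append(report)

    # final refit on the full sample
    all_idx = np.arange(len(X))
    tr_idx, val_idx = train_test_split(
        all_idx, test_size=0.2, random_state=config.seed, stratify=events
    )
    scaler = Scaler.fit(X)
    net = _fit_net(
        scaler.transform(X[tr_idx]), times[tr_idx], events[tr_idx],
        scaler.transform(X[val_idx]), times[val_idx], events[val_idx],
        config, rng,
    )
    g_all = net.forward(scaler.transform(X))[0][:, 0]
    baseline = breslow_baseline(g_all, times, events)
    return RiskModel(net, scaler, feature_names, baseline, config, fold_reports)


def breslow_hazard(model: RiskModel, features, times, events) -> StepFunction:
    """Re-estimate the baseline cumulative hazard from a given sample."""
    return breslow_baseline(risk_scores(model, features), times, events)


def predict_cumulative_hazard(model: RiskModel, features, horizon: float) -> np.ndarray:
    """H(horizon | x) = H0(horizon) * exp(g(x)) per patient (months scale)."""
    if horizon < 0:
        raise ValueError("horizon must be non-negative")
    if horizon > model.baseline.x[-1]:
        logger.warning(
            "horizon %.1f beyond last observed event time %.1f; using the last baseline value",
            horizon, model.baseline.x[-1],
        )
    return float(model.baseline(horizon)) * np.exp(risk_scores(model, features))


def predict_survival(model: RiskModel, features, grid) -> np.ndarray:
    """Matrix S(t|x) = exp(-H0(t) exp(g(x))) over a time grid."""
    grid = np.asarray(grid, dtype=float)
    return np.exp(-np.outer(np.exp(risk_scores(model, features)), model.baseline(grid)))


def linear_coefficients(model: RiskModel) -> np.ndarray:
    """Coefficients on the original feature scale for a linear risk model.

    Only defined for ``hidden_sizes=()`` (no hidden layers), where
    g(x) = w . (x - mean)/std + b, i.e. the Cox coefficient for raw feature
    j is w_j / std_j.
    """
    if len(model.net.W) != 1:
        raise ValueError("linear coefficients are only defined for a linear (no-hidden-layer) model")
    return model.net.W[0][:, 0] / model.scaler.std
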