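"""Three-class EDSS classifier.

A feed-forward network (default 64-32 hidden units, ReLU, softmax output)
mapping 6-month administrative feature vectors to the three EDSS classes.
Trained with Adam on categorical cross-entropy, mini-batches of 32, dropout
0.2 and an L2 weight penalty, over a stratified 70/30 train/validation
split.  Continuous features are standardised with training-split statistics
only.  Hyper-parameters can be tuned by exhaustive grid search on the
validation split.
"""

from __future__ import annotations

import itertools
import pickle
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from ._mlp import Adam, DenseNet, Scaler, softmax
from .edss import CLASSES


@dataclass
class ClassifierConfig:
    hidden_sizes: tuple[int, ...] = (64, 32)
    learning_rate: float = 0.001
    batch_size: int = 32
    dropout_rate: float = 0.2
    l2_strength: float = 1e-4
    epochs: int = 10
    train_frac: float = 0.70
    seed: int = 0
    #: hyper-parameter name -> candidate values; supported names:
    #: learning_rate, batch_size, hidden1 (first hidden layer width)
    grid: dict[str, list] | None = None

    def __post_init__(self) -> None:
        if not (0 < self.train_frac < 1):
            raise ValueError("train_frac must be in (0, 1)")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size <= 0 or self.epochs <= 0:
            raise ValueError("batch_size and epochs must be positive")
        if self.l2_strength < 0:
            raise ValueError("l2_strength must be non-negative")


@dataclass
class TrainedClassifier:
    net: DenseNet
    scaler: Scaler
    feature_names: list[str]
    config: ClassifierConfig
    report: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        Path(path).write_bytes(pickle.dumps(self))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedClassifier":
        obj = pickle.loads(Path(path).read_bytes())
        if not isinstance(obj, cls):
            raise TypeError(f"{path} does not contain a TrainedClassifier")
        return obj


def _as_matrix(features: pd.DataFrame, feature_names: list[str] | None = None):
    if feature_names is None:
        feature_names = [c for c in features.columns if features[c].dtype.kind in "ifb"]
    missing = [c for c in feature_names if c not in features.columns]
    extra = [
        c for c in features.columns
        if c not in feature_names and features[c].dtype.kind in "ifb"
    ]
    if missing:
        raise ValueError(f"feature schema mismatch; missing columns: {missing}; extra columns: {extra}")
    return features[feature_names].to_numpy(dtype=float), feature_names


def _encode_labels(labels) -> np.ndarray:
    y = pd.Series(labels).map({c: i for i, c in enumerate(CLASSES)})
    if y.isna().any():
        raise ValueError(f"labels must be in {CLASSES}")
    return y.to_numpy(dtype=int)


def _cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    return float(-np.mean(np.log(probs[np.arange(len(y)), y] + 1e-12)))


def train_classifier(
    features: pd.DataFrame,
    labels,
    config: ClassifierConfig | None = None,
) -> TrainedClassifier:
    """Fit the EDSS classifier on the labelled cohort.

    Deterministic given ``config.seed``.  The split is stratified by class so
    every class present in the data appears in both splits; training aborts
    with an explicit error if a class is absent from the training split.
    """
    config = config or ClassifierConfig()
    X, feature_names = _as_matrix(features)
    y = _encode_labels(labels)
    if len(X) == 0:
        raise ValueError("labelled set is empty")

    idx = np.arange(len(X))
    train_idx, val_idx = train_test_split(
        idx, train_size=config.train_frac, random_state=config.seed, stratify=y
    )
    present = set(np.unique(y))
    if set(np.unique(y[train_idx])) != present:
        raise ValueError(
            "a class is absent from the training split; re-split with stratification "
            "or provide more labelled patients"
        )

    scaler = Scaler.fit(X[train_idx])
    Xtr, ytr = scaler.transform(X[train_idx]), y[train_idx]
    Xval, yval = scaler.transform(X[val_idx]), y[val_idx]

    rng = np.random.default_rng(config.seed)
    net = DenseNet(X.shape[1], config.hidden_sizes, len(CLASSES), rng)
    opt = Adam(net.params, lr=config.learning_rate)
    losses = []
    for _ in range(config.epochs):
        order = rng.permutation(len(Xtr))
        epoch_loss = 0.0
        for start in range(0, len(Xtr), config.batch_size):
            batch = order[start : start + config.batch_size]
            out, cache = net.forward(Xtr[batch], dropout=config.dropout_rate, rng=rng)
            probs = softmax(out)
            epoch_loss += _cross_entropy(probs, ytr[batch]) * len(batch)
            grad = probs.copy()
            grad[np.arange(len(batch)), ytr[batch]] -= 1.0
            grad /= len(batch)
            opt.step(net.params, net.backward(cache, grad, l2=config.l2_strength))
        losses.append(epoch_loss / len(Xtr))

    val_probs = softmax(net.forward(Xval)[0])
    val_acc = float((val_probs.argmax(axis=1) == yval).mean())
    report = {
        "train_idx": train_idx.tolist(),
        "val_idx": val_idx.tolist(),
        "epoch_losses": losses,
        "val_accuracy": val_acc,
    }
    return TrainedClassifier(net, scaler, feature_names, config, report)


def predict_classes(model: TrainedClassifier, features: pd.DataFrame) -> pd.DataFrame:
    """Class probabilities and argmax class for each row.

    Works on unlabelled whole-population features; the schema must match the
    training features.
    """
    X, _ = _as_matrix(features, model.feature_names)
    probs = softmax(model.net.forward(model.scaler.transform(X))[0])
    out = pd.DataFrame(probs, columns=[f"p_{c}" for c in CLASSES])
    if "patient_id" in features.columns:
        out.insert(0, "patient_id", features["patient_id"].to_numpy())
    out["predicted_class"] = np.array(CLASSES)[probs.argmax(axis=1)]
    return out


_GRID_KEYS = ("learning_rate", "batch_size", "hidden1")


def grid_search(
    features: pd.DataFrame, labels, config: ClassifierConfig
) -> tuple[ClassifierConfig, pd.DataFrame]:
    """Exhaustive grid search maximising validation accuracy.

    The grid is the Cartesian product of the candidate lists in
    ``config.grid``; ties are broken by the first candidate in lexicographic
    grid order (sorted keys, candidates in listed order).
    """
    if not config.grid:
        raise ValueError("config.grid is empty")
    for key, values in config.grid.items():
        if key not in _GRID_KEYS:
            raise ValueError(f"unsupported grid key {key!r}; supported: {_GRID_KEYS}")
        if not values:
            raise ValueError(f"grid key {key!r} has no candidate values")
    keys = sorted(config.grid)
    rows = []
    best: tuple[float, ClassifierConfig] | None = None
    for combo in itertools.product(*(config.grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        candidate = replace(config, grid=None)
        if "hidden1" in params:
            h1 = int(params.pop("hidden1"))
            candidate = replace(candidate, hidden_sizes=(h1, *candidate.hidden_sizes[1:]))
        candidate = replace(candidate, **params)
        model = train_classifier(features, labels, candidate)
        acc = model.report["val_accuracy"]
        rows.append({**dict(zip(keys, combo)), "val_accuracy": acc})
        if best is None or acc > best[0]:
            best = (acc, candidate)
    return best[1], pd.DataFrame(rows)
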