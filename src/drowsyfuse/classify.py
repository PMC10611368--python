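"""Train/evaluate per-modality fatigue classifiers on feature tables.

The primary backend is gradient-boosted trees (100 trees, 31 leaves,
learning rate 0.1); SVM and logistic-regression comparators sit behind
the same train/predict contract. Splits are stratified 80/20 and every
step is deterministic given the seed.

Label convention: classifiers always emit {0 alert, 1 fatigued}; the
fusion boundary remaps ECG outputs to {2, 3}.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from drowsyfuse.sigio import FeatureTable

_MODEL_VERSION = 1

GBDT_DEFAULTS = dict(n_estimators=100, max_leaf_nodes=31, learning_rate=0.1)


@dataclass
class TrainConfig:
    backend: str = "gbdt"
    test_fraction: float = 0.2
    seed: int = 0
    params: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.backend not in ("gbdt", "svm", "logistic"):
            raise ValueError("backend must be gbdt, svm, or logistic")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")


@dataclass
class EvalReport:
    accuracy: float
    precision: Dict[str, float]
    recall: Dict[str, float]
    confusion: np.ndarray
    class_order: list
    n_train: int
    n_test: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "confusion": self.confusion.tolist(),
            "class_order": [str(c) for c in self.class_order],
            "n_train": self.n_train,
            "n_test": self.n_test,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass
class Model:
    """A fitted backend plus the schema it was trained against."""

    estimator: object
    feature_names: list
    backend: str
    seed: int
    version: int = _MODEL_VERSION

    def save(self, path: str) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path: str) -> "Model":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if model.version != _MODEL_VERSION:
            raise ValueError(f"model version {model.version} unsupported")
        return model


def split_table(
    table: FeatureTable, cfg: Optional[TrainConfig] = None
) -> Tuple[FeatureTable, FeatureTable]:
    """Stratified random split, deterministic given the seed."""
    cfg = cfg or TrainConfig()
    if table.labels is None:
        raise ValueError("split requires a labeled table")
    if len(np.unique(table.labels)) < 2:
        raise ValueError("need at least 2 classes to split")
    idx = np.arange(table.n_rows)
    train_idx, test_idx = train_test_split(
        idx,
        test_size=cfg.test_fraction,
        random_state=cfg.seed,
        stratify=table.labels,
    )
    mk = lambda ii: FeatureTable(
        table.values[ii], list(table.feature_names), table.labels[ii]
    )
    return mk(np.sort(train_idx)), mk(np.sort(test_idx))


def _make_estimator(cfg: TrainConfig):
    if cfg.backend == "gbdt":
        params = {**GBDT_DEFAULTS, **cfg.params}
        return GradientBoostingClassifier(random_state=cfg.seed, **params)
    if cfg.backend == "svm":
        return SVC(random_state=cfg.seed, **cfg.params)
    return LogisticRegression(random_state=cfg.seed, max_iter=1000, **cfg.params)


def train(table: FeatureTable, cfg: Optional[TrainConfig] = None) -> Model:
    """Fit the configured backend on a labeled feature table."""
    cfg = cfg or TrainConfig()
    if table.labels is None:
        raise ValueError("training requires labels")
    est = _make_estimator(cfg)
    est.fit(table.values, table.labels)
    return Model(est, list(table.feature_names), cfg.backend, cfg.seed)


def predict(model: Model, table: FeatureTable) -> np.ndarray:
    """Predict labels; the table schema must match the training schema."""
    if list(table.feature_names) != model.feature_names:
        raise ValueError(
            f"feature schema mismatch: {list(table.feature_names)} vs "
            f"{model.feature_names}"
        )
    return model.estimator.predict(table.values)


def evaluate(truth: np.ndarray, predicted: np.ndarray,
             n_train: int = 0) -> EvalReport:
    """Accuracy, per-class precision/recall, and confusion counts."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted must align")
    classes = sorted(set(truth) | set(predicted))
    k = len(classes)
    pos = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((k, k), dtype=int)
    for t, p in zip(truth, predicted):
        confusion[pos[t], pos[p]] += 1
    accuracy = float(np.trace(confusion) / len(truth))
    precision, recall = {}, {}
    for c in classes:
        i = pos[c]
        col = confusion[:, i].sum()
        row = confusion[i, :].sum()
        precision[str(c)] = float(confusion[i, i] / col) if col else 0.0
        recall[str(c)] = float(confusion[i, i] / row) if row else 0.0
    return EvalReport(
        accuracy, precision, recall, confusion, classes, n_train, len(truth)
    )


def train_and_evaluate(
    table: FeatureTable, cfg: Optional[TrainConfig] = None
) -> Tuple[Model, EvalReport]:
    """80/20 split, train, and score the held-out part."""
    cfg = cfg or TrainConfig()
    tr, te = split_table(table, cfg)
    model = train(tr, cfg)
    report = evaluate(te.labels, predict(model, te), n_train=tr.n_rows)
    return model, report


def feature_importances(model: Model) -> Dict[str, float]:
    """Normalized (sum-to-1) importances; gbdt backend only."""
    if model.backend != "gbdt":
        raise ValueError("feature importances available for gbdt only")
    raw = np.asarray(model.estimator.feature_importances_, dtype=float)
    total = raw.sum()
    norm = raw / total if total > 0 else raw
    return dict(zip(model.feature_names, norm.tolist()))
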