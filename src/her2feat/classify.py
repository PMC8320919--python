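"""One-vs-all HER2 classification and the evaluation protocols.

The feature representation is validated with two simple learners — one-vs-
rest logistic regression and an SVM — under two protocols: a stratified
70/30 holdout split, and stratified 5-fold cross-validation repeated with
fresh shuffles (50 repeats by default), reporting the mean and standard
deviation of accuracy across trials.  Features are z-scored inside the
training data only; prediction is the argmax of the four binary decision
scores (ties resolve to the lowest class index via numpy argmax).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.multiclass import OneVsRestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .config import PipelineConfig, DEFAULT_CONFIG
from .features import FEATURE_COLUMNS

__all__ = [
    "CLASS_ORDER",
    "ClassificationReport",
    "train_ova",
    "holdout_split",
    "evaluate",
    "repeated_cv",
]

CLASS_ORDER = ("0", "1+", "2+", "3+")


@dataclass(frozen=True)
class ClassificationReport:
    """Confusion matrix (rows = actual, columns = predicted) with per-class
    precision (column-wise), recall (row-wise), F1 and overall accuracy;
    repeated protocols add the per-trial accuracy series."""

    labels: tuple[str, ...]
    confusion: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    accuracy: float
    trial_accuracies: np.ndarray | None = None

    @property
    def accuracy_mean(self) -> float:
        a = self.trial_accuracies
        return float(np.mean(a)) if a is not None else self.accuracy

    @property
    def accuracy_std(self) -> float:
        a = self.trial_accuracies
        return float(np.std(a, ddof=0)) if a is not None else 0.0

    def confusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.confusion, index=list(self.labels),
                            columns=list(self.labels))

    def to_dict(self) -> dict:
        d = {
            "labels": list(self.labels),
            "confusion": self.confusion.tolist(),
            "precision": np.round(self.precision, 6).tolist(),
            "recall": np.round(self.recall, 6).tolist(),
            "f1": np.round(self.f1, 6).tolist(),
            "accuracy": self.accuracy,
        }
        if self.trial_accuracies is not None:
            d["trial_accuracies"] = np.round(self.trial_accuracies, 6).tolist()
            d["accuracy_mean"] = self.accuracy_mean
            d["accuracy_std"] = self.accuracy_std
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _xy(features: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
    if missing:
        raise ValueError(f"feature table lacks columns: {missing[:5]}")
    if "label" not in features.columns or features["label"].isna().any():
        raise ValueError("training requires a fully populated 'label' column")
    return features[list(FEATURE_COLUMNS)].to_numpy(float), features["label"].to_numpy(str)


def _make_pipeline(learner: str, config: PipelineConfig, seed: int) -> Pipeline:
    lc = config.learner
    if learner == "logreg":
        base = LogisticRegression(C=lc.C, max_iter=lc.max_iter,
                                  random_state=seed)
    elif learner == "svm":
        base = SVC(C=lc.C, kernel=lc.svm_kernel, gamma="scale",
                   random_state=seed)
    else:
        raise ValueError(f"unknown learner: {learner!r}")
    return make_pipeline(StandardScaler(), OneVsRestClassifier(base))


def train_ova(features: pd.DataFrame, learner: str = "logreg",
              config: PipelineConfig = DEFAULT_CONFIG, seed: int = 0,
              min_per_class: int = 2) -> Pipeline:
    """Fit one binary one-vs-rest classifier per class on z-scored features.

    Standardisation parameters are learned from the given (training) table
    only.  Classes with fewer than ``min_per_class`` samples are rejected
    by name.
    """
    X, y = _xy(features)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes")
    small = classes[counts < min_per_class]
    if small.size:
        raise ValueError(f"class {small[0]!r} has fewer than "
                         f"{min_per_class} samples")
    model = _make_pipeline(learner, config, seed)
    model.fit(X, y)
    return model


def holdout_split(features: pd.DataFrame, train_frac: float = 0.70,
                  seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified random train/test split (default 70/30), seed-reproducible."""
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie in (0, 1)")
    _, y = _xy(features)
    train, test = train_test_split(features, train_size=train_frac,
                                   stratify=y, random_state=seed)
    return (train.reset_index(drop=True), test.reset_index(drop=True))


def _report_from_predictions(y_true: np.ndarray, y_pred: np.ndarray,
                             labels: Sequence[str],
                             trial_accuracies: np.ndarray | None = None
                             ) -> ClassificationReport:
    labels = tuple(labels)
    index = {c: i for i, c in enumerate(labels)}
    confusion = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        confusion[index[t], index[p]] += 1
    col = confusion.sum(axis=0)
    row = confusion.sum(axis=1)
    diag = np.diag(confusion).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, diag / col, 0.0)
        recall = np.where(row > 0, diag / row, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    accuracy = float(diag.sum() / max(confusion.sum(), 1))
    return ClassificationReport(labels=labels, confusion=confusion,
                                precision=precision, recall=recall, f1=f1,
                                accuracy=accuracy,
                                trial_accuracies=trial_accuracies)


def evaluate(model: Pipeline, test: pd.DataFrame) -> ClassificationReport:
    """Confusion matrix and per-class precision/recall/F1 on a test table."""
    X, y = _xy(test)
    if len(y) == 0:
        raise ValueError("test set is empty")
    known = set(model.classes_)
    unseen = sorted(set(y) - known)
    if unseen:
        raise ValueError(f"test set contains label unseen in training: {unseen[0]!r}")
    # report axes span model classes in ordinal order, plus any extras
    labels = [c for c in CLASS_ORDER if c in known]
    labels += sorted(known - set(labels))
    y_pred = model.predict(X)
    return _report_from_predictions(y, y_pred, labels)


def repeated_cv(features: pd.DataFrame, learner: str = "logreg",
                folds: int = 5, repeats: int = 50, seed: int = 0,
                config: PipelineConfig = DEFAULT_CONFIG
                ) -> ClassificationReport:
    """Stratified k-fold cross-validation repeated with fresh shuffles.

    Each trial pools the out-of-fold predictions of one k-fold pass into a
    single accuracy; the report carries the per-trial accuracy series (for
    mean/std across repeats) and the confusion matrix of the final trial.
    All randomness flows from ``seed``.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    X, y = _xy(features)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("cross-validation requires at least 2 classes")
    small = classes[counts < folds]
    if small.size:
        raise ValueError(f"class {small[0]!r} has fewer samples than folds")
    ss = np.random.SeedSequence(seed)
    trial_seeds = ss.generate_state(repeats) % (2**31)
    accuracies = np.empty(repeats)
    last_true: np.ndarray | None = None
    last_pred: np.ndarray | None = None
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(trial_seeds[r]))
        y_pred = np.empty(len(y), dtype=y.dtype)
        for train_idx, test_idx in skf.split(X, y):
            model = _make_pipeline(learner, config, int(trial_seeds[r]))
            model.fit(X[train_idx], y[train_idx])
            y_pred[test_idx] = model.predict(X[test_idx])
        accuracies[r] = (y_pred == y).mean()
        last_true, last_pred = y, y_pred
    labels = [c for c in CLASS_ORDER if c in classes]
    labels += sorted(set(classes) - set(labels))
    return _report_from_predictions(last_true, last_pred, labels,
                                    trial_accuracies=accuracies)
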