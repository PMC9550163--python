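"""Feature fusion, classification, evaluation protocol and ablations.

The evaluation protocol mirrors common practice for a modest labelled
dataset: a stratified 80/20 holdout split, with all model comparisons run
as stratified 5-fold cross-validation inside the 80% training portion and
the untouched 20% reserved for a single final evaluation — the only
composition of the two that avoids test leakage.

Classifier roster: random forest (the default), logistic regression,
Gaussian naive Bayes, k-nearest neighbours and gradient-boosted trees.
Features are z-scored (fit on training folds only) for the scale-sensitive
models (LR, KNN); tree ensembles receive raw features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import mutual_info_score, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "CLASSIFIERS",
    "FusedVector",
    "EvalReport",
    "fuse",
    "fuse_tables",
    "make_classifier",
    "cross_validate",
    "holdout_protocol",
    "metrics_from_confusion",
    "select_features",
    "run_ablation",
]

CLASSIFIERS: tuple[str, ...] = ("RF", "LR", "NB", "KNN", "XGB")


@dataclass(frozen=True)
class FusedVector:
    """Handcrafted block followed by CNN block, lengths recorded."""

    values: np.ndarray
    qfem_len: int
    cnn_len: int

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if self.qfem_len < 1 or self.cnn_len < 1:
            raise ValueError("both feature blocks must be nonempty")
        if vals.ndim != 1 or vals.size != self.qfem_len + self.cnn_len:
            raise ValueError(
                f"fused length {vals.size} != {self.qfem_len} + {self.cnn_len}"
            )
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size


def fuse(qfem_values: np.ndarray, cnn_values: np.ndarray) -> FusedVector:
    """Concatenate the handcrafted and CNN feature blocks, in that order."""
    q = np.atleast_1d(np.asarray(qfem_values, dtype=np.float64))
    c = np.atleast_1d(np.asarray(cnn_values, dtype=np.float64))
    if q.size == 0 or c.size == 0:
        raise ValueError("both feature blocks must be nonempty")
    return FusedVector(values=np.concatenate([q, c]), qfem_len=q.size, cnn_len=c.size)


def fuse_tables(qfem_table: np.ndarray, cnn_table: np.ndarray) -> np.ndarray:
    """Row-wise fusion of two aligned feature matrices."""
    q = np.asarray(qfem_table, dtype=np.float64)
    c = np.asarray(cnn_table, dtype=np.float64)
    if q.shape[0] != c.shape[0]:
        raise ValueError("feature tables have different numbers of rows")
    if q.shape[1] == 0 or c.shape[1] == 0:
        raise ValueError("both feature blocks must be nonempty")
    return np.hstack([q, c])


def make_classifier(name: str, seed: int = 0):
    """Instantiate a roster classifier with the package defaults."""
    if name == "RF":
        return RandomForestClassifier(
            n_estimators=100, criterion="gini", max_features="sqrt", random_state=seed
        )
    if name == "LR":
        return make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=2000, random_state=seed)  # L2 default
        )
    if name == "NB":
        return GaussianNB()
    if name == "KNN":
        return make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=5, metric="euclidean"))
    if name == "XGB":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=100, max_depth=6, random_state=seed, verbosity=0, eval_metric="mlogloss"
        )
    raise ValueError(f"unknown classifier {name!r}; expected one of {CLASSIFIERS}")


@dataclass
class EvalReport:
    """Pooled cross-validation evaluation.

    The confusion matrix accumulates out-of-fold predictions over all
    folds; every summary metric is recomputed from it. ROC curves are
    one-vs-rest on the pooled out-of-fold class-probability scores.
    """

    classes: tuple[str, ...]
    confusion: np.ndarray  # raw counts, rows = true class
    fold_accuracies: list[float]
    roc: dict[str, dict] = dc_field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return int(self.confusion.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())

    @property
    def confusion_normalized(self) -> np.ndarray:
        rows = self.confusion.sum(axis=1, keepdims=True)
        return self.confusion / np.maximum(rows, 1)

    @property
    def per_class(self) -> pd.DataFrame:
        return metrics_from_confusion(self.confusion, self.classes)["per_class"]

    @property
    def macro_precision(self) -> float:
        return float(self.per_class["precision"].mean())

    @property
    def macro_recall(self) -> float:
        return float(self.per_class["recall"].mean())

    @property
    def macro_f1(self) -> float:
        return float(self.per_class["f1"].mean())

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "per_class": self.per_class.to_dict(orient="index"),
            "confusion": self.confusion.tolist(),
            "confusion_normalized": self.confusion_normalized.tolist(),
            "fold_accuracies": self.fold_accuracies,
            "roc_auc": {c: self.roc[c]["auc"] for c in self.roc},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def confusion_to_csv(self, path, normalized: bool = False) -> None:
        cm = self.confusion_normalized if normalized else self.confusion
        pd.DataFrame(cm, index=list(self.classes), columns=list(self.classes)).to_csv(path)


def metrics_from_confusion(confusion: np.ndarray, classes: Sequence[str] | None = None) -> dict:
    """Per-class precision/recall/F1 plus macro averages and accuracy,
    all derived from a (true x predicted) count matrix."""
    cm = np.asarray(confusion, dtype=np.float64)
    n = cm.shape[0]
    if classes is None:
        classes = [str(i) for i in range(n)]
    tp = np.diag(cm)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.maximum(denom, 1e-300), 0.0)
    per_class = pd.DataFrame(
        {"precision": precision, "recall": recall, "f1": f1}, index=list(classes)
    )
    return {
        "per_class": per_class,
        "macro_precision": float(precision.mean()),
        "macro_recall": float(recall.mean()),
        "macro_f1": float(f1.mean()),
        "accuracy": float(tp.sum() / cm.sum()),
    }


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=np.float64)
    return np.asarray(features, dtype=np.float64)


def cross_validate(
    features,
    labels: Sequence[str],
    classifier: str = "RF",
    k: int = 5,
    seed: int = 0,
) -> EvalReport:
    """Stratified k-fold cross-validation with pooled out-of-fold scoring."""
    X = _as_matrix(features)
    y = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    classes = tuple(sorted(np.unique(y)))
    counts = pd.Series(y).value_counts()
    if counts.min() < k:
        raise ValueError(
            f"class {counts.idxmin()!r} has {counts.min()} samples, fewer than k={k} folds"
        )
    cm = np.zeros((len(classes), len(classes)), dtype=np.int64)
    cls_index = {c: i for i, c in enumerate(classes)}
    # integer-encode labels: gradient-boosting backends require it
    y_enc = np.array([cls_index[c] for c in y])
    fold_accuracies: list[float] = []
    oof_scores = np.zeros((len(y), len(classes)))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(X, y_enc):
        model = make_classifier(classifier, seed=seed)
        model.fit(X[train_idx], y_enc[train_idx])
        pred = model.predict(X[test_idx])
        proba = model.predict_proba(X[test_idx])
        model_classes = list(model.classes_)
        for c_i in range(len(classes)):
            oof_scores[test_idx, c_i] = proba[:, model_classes.index(c_i)]
        fold_accuracies.append(float(np.mean(pred == y_enc[test_idx])))
        for t, p in zip(y_enc[test_idx], pred):
            cm[t, p] += 1

    roc: dict[str, dict] = {}
    for c_i, c in enumerate(classes):
        fpr, tpr, _ = roc_curve((y == c).astype(int), oof_scores[:, c_i])
        roc[c] = {"fpr": fpr.tolist(), "tpr": tpr.tolist(), "auc": float(sk_auc(fpr, tpr))}
    return EvalReport(classes=classes, confusion=cm, fold_accuracies=fold_accuracies, roc=roc)


def holdout_protocol(features, labels: Sequence[str], split_ratio: float = 0.8, seed: int = 0):
    """Stratified train/test split; model selection belongs inside the
    training portion, the test portion is evaluated once."""
    X = _as_matrix(features)
    y = np.asarray(labels)
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, train_size=split_ratio, stratify=y, random_state=seed
    )
    train_idx, test_idx = np.sort(train_idx), np.sort(test_idx)
    return (X[train_idx], y[train_idx], train_idx), (X[test_idx], y[test_idx], test_idx)


# ---------------------------------------------------------- feature selection


def _discretize(X: np.ndarray, bins: int = 10) -> np.ndarray:
    out = np.zeros(X.shape, dtype=np.int32)
    for j in range(X.shape[1]):
        col = X[:, j]
        edges = np.unique(np.quantile(col, np.linspace(0, 1, bins + 1)[1:-1]))
        out[:, j] = np.searchsorted(edges, col, side="right")
    return out


def select_features(
    features,
    labels: Sequence[str],
    method: str = "mrmr",
    k_keep: int = 200,
    seed: int = 0,
    bins: int = 10,
) -> tuple[np.ndarray, list[int]]:
    """Reduce a feature table to ``k_keep`` columns.

    ``mrmr`` greedily maximises mutual-information relevance minus mean
    redundancy against the already-selected set, on quantile-discretized
    features. ``rfe`` repeatedly drops the lowest-importance decile by
    random-forest importance until ``k_keep`` columns remain. Returns the
    reduced table and the kept column indices (selection order for mRMR,
    ascending for RFE).
    """
    X = _as_matrix(features)
    y = np.asarray(labels)
    d = X.shape[1]
    if not (1 <= k_keep <= d):
        raise ValueError(f"k_keep must be in [1, {d}]")
    if k_keep == d:
        return X.copy(), list(range(d))

    if method == "mrmr":
        Xd = _discretize(X, bins=bins)
        relevance = np.array([mutual_info_score(y, Xd[:, j]) for j in range(d)])
        selected = [int(np.argmax(relevance))]
        remaining = set(range(d)) - set(selected)
        red_sum = np.zeros(d)
        while len(selected) < k_keep:
            last = selected[-1]
            for j in remaining:
                red_sum[j] += mutual_info_score(Xd[:, j], Xd[:, last])
            rem = np.array(sorted(remaining))
            score = relevance[rem] - red_sum[rem] / len(selected)
            pick = int(rem[np.argmax(score)])
            selected.append(pick)
            remaining.discard(pick)
        return X[:, selected], selected

    if method == "rfe":
        kept = np.arange(d)
        while len(kept) > k_keep:
            rf = RandomForestClassifier(n_estimators=100, random_state=seed)
            rf.fit(X[:, kept], y)
            drop_n = min(max(1, len(kept) // 10), len(kept) - k_keep)
            order = np.argsort(rf.feature_importances_)
            kept = np.delete(kept, order[:drop_n])
        kept = np.sort(kept)
        return X[:, kept], kept.tolist()

    raise ValueError(f"unknown selection method {method!r}; expected 'mrmr' or 'rfe'")


# ----------------------------------------------------------------- ablations


def run_ablation(
    feature_sets: Mapping[str, tuple[np.ndarray, Sequence[str]]],
    classifiers: Sequence[str] = ("RF",),
    k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validate every (condition, classifier) cell of an ablation grid.

    ``feature_sets`` maps a condition name (e.g. ``qfem_median_steps8``,
    ``fused``) to a (feature matrix, labels) pair. Emits one tidy row per
    condition per classifier per fold, plus the pooled accuracy, suitable
    for CSV export.
    """
    rows = []
    for condition, (X, y) in feature_sets.items():
        for clf in classifiers:
            report = cross_validate(X, y, classifier=clf, k=k, seed=seed)
            for fold_i, acc in enumerate(report.fold_accuracies):
                rows.append(
                    {
                        "condition": condition,
                        "classifier": clf,
                        "fold": fold_i,
                        "fold_accuracy": acc,
                        "pooled_accuracy": report.accuracy,
                        "macro_f1": report.macro_f1,
                    }
                )
    return pd.DataFrame(rows)
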