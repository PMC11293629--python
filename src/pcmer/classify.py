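"""Supervised classification over physicochemical chaos-game features.

Eight basic classifier configurations (logistic regression, decision tree,
Gaussian naive Bayes, LDA, MLP, linear SVC and the two nearest-centroid
variants) evaluated with stratified k-fold cross-validation and the four
standard metrics: accuracy, precision, recall, F1.  Macro averages are
primary (class counts above the finest level are unbalanced); weighted
averages are recorded alongside.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    precision_recall_fscore_support,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import NearestCentroid
from sklearn.neural_network import MLPClassifier
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .core import Mode, encode_pcmer
from .io import LabeledDataset

__all__ = [
    "CLASSIFIER_NAMES",
    "ClassifierSpec",
    "CVReport",
    "make_estimator",
    "build_feature_matrix",
    "cross_validate",
    "sweep",
]

CLASSIFIER_NAMES: tuple[str, ...] = (
    "logistic_regression",
    "decision_tree",
    "gaussian_nb",
    "lda",
    "mlp",
    "linear_svc",
    "nearest_centroid_mean",
    "nearest_centroid_median",
)


@dataclass(frozen=True)
class ClassifierSpec:
    """A named classifier configuration; hyperparameters override defaults."""

    name: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ValueError(
                f"unknown classifier {self.name!r}; choose from {CLASSIFIER_NAMES}"
            )


def make_estimator(spec: ClassifierSpec, seed: int | None = None):
    """Instantiate the scikit-learn estimator behind a spec.

    Defaults: logistic regression with L2, one-vs-rest, tol 1e-4, C=1
    (max_iter raised to 1000 so lbfgs converges on raw count features);
    decision tree with Gini impurity; MLP with one 100-neuron ReLU hidden
    layer, Adam, alpha 1e-4, learning rate 1e-3, 200 epochs; linear SVC
    with L2 penalty; nearest centroid with class means (euclidean) or
    class medians (manhattan).  Everything else stays at library defaults.
    """
    hp = dict(spec.hyperparameters)
    name = spec.name
    if name == "logistic_regression":
        # the library default penalty is already L2; passing it explicitly is
        # deprecated in recent scikit-learn, so the default is relied upon
        base = LogisticRegression(
            tol=1e-4, C=1.0, max_iter=hp.pop("max_iter", 1000), **hp
        )
        return OneVsRestClassifier(base)
    if name == "decision_tree":
        return DecisionTreeClassifier(criterion="gini", random_state=seed, **hp)
    if name == "gaussian_nb":
        return GaussianNB(**hp)
    if name == "lda":
        return LinearDiscriminantAnalysis(**hp)
    if name == "mlp":
        return MLPClassifier(
            hidden_layer_sizes=(100,),
            activation="relu",
            solver="adam",
            alpha=1e-4,
            learning_rate_init=1e-3,
            max_iter=200,
            random_state=seed,
            **hp,
        )
    if name == "linear_svc":
        return LinearSVC(penalty="l2", random_state=seed, **hp)
    if name == "nearest_centroid_mean":
        return NearestCentroid(metric="euclidean", **hp)
    if name == "nearest_centroid_median":
        # the manhattan metric makes sklearn use per-class medians
        return NearestCentroid(metric="manhattan", **hp)
    raise AssertionError(name)


@dataclass
class CVReport:
    """Per-fold and mean metrics from one cross-validated configuration."""

    classifier: str
    k: int
    n_folds: int
    seed: int
    classes: list[str]
    fold_metrics: pd.DataFrame  # columns: accuracy, precision/recall/f1 macro+weighted
    confusion: np.ndarray  # summed over folds, rows = true class

    @property
    def mean_metrics(self) -> dict[str, float]:
        return {c: float(self.fold_metrics[c].mean()) for c in self.fold_metrics}

    @property
    def accuracy(self) -> float:
        return self.mean_metrics["accuracy"]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "classifier": self.classifier,
            "k": self.k,
            "n_folds": self.n_folds,
            "seed": self.seed,
            "classes": self.classes,
            "fold_metrics": self.fold_metrics.to_dict(orient="list"),
            "mean_metrics": self.mean_metrics,
            "confusion": self.confusion.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    def confusion_to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.confusion, index=self.classes, columns=self.classes).to_csv(
            path, sep="\t"
        )


def build_feature_matrix(
    dataset: LabeledDataset, k: int, mode: Mode = "all_positions"
) -> tuple[np.ndarray, np.ndarray]:
    """Encode every record; row i is record i's concatenated 3 * 2**k profile."""
    rows = []
    for rec in dataset.records:
        try:
            rows.append(encode_pcmer(rec.residues, k, mode).concat())
        except ValueError as exc:
            raise ValueError(f"failed to encode record {rec.id!r}: {exc}") from exc
    return np.vstack(rows).astype(float), np.asarray(dataset.labels)


def _fold_metrics(y_true, y_pred) -> dict[str, float]:
    out = {"accuracy": accuracy_score(y_true, y_pred)}
    for avg in ("macro", "weighted"):
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, average=avg, zero_division=0
        )
        out[f"precision_{avg}"] = p
        out[f"recall_{avg}"] = r
        out[f"f1_{avg}"] = f
    return out


def cross_validate(
    features: np.ndarray,
    labels: np.ndarray,
    spec: ClassifierSpec,
    n_folds: int = 10,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold cross-validation of one classifier configuration.

    Folds are generated from ``seed``; the model is fit on the train split
    only and metrics are computed on each fold's test predictions, then
    averaged arithmetically.  If the smallest class has fewer members than
    ``n_folds``, the fold count is lowered to that size with a warning.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("cross-validation needs at least 2 classes")
    smallest = int(counts.min())
    if smallest < n_folds:
        warnings.warn(
            f"smallest class has {smallest} members; lowering folds "
            f"from {n_folds} to {smallest}",
            stacklevel=2,
        )
        n_folds = smallest
    if n_folds < 2:
        raise ValueError("need every class to have at least 2 members")

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    per_fold = []
    confusion = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for train_idx, test_idx in skf.split(features, labels):
        model = make_estimator(spec, seed=seed)
        model.fit(features[train_idx], labels[train_idx])
        pred = model.predict(features[test_idx])
        per_fold.append(_fold_metrics(labels[test_idx], pred))
        confusion += confusion_matrix(labels[test_idx], pred, labels=classes)
    return CVReport(
        classifier=spec.name,
        k=-1,  # filled by sweep()/callers that know the encoding k
        n_folds=n_folds,
        seed=seed,
        classes=[str(c) for c in classes],
        fold_metrics=pd.DataFrame(per_fold),
        confusion=confusion,
    )


def sweep(
    dataset: LabeledDataset,
    k_values: list[int],
    specs: list[ClassifierSpec],
    n_folds: int = 10,
    seed: int = 0,
    mode: Mode = "all_positions",
) -> list[CVReport]:
    """One CV report per (k, classifier), encodings computed once per k.

    Reports come back in the deterministic order of the (k, spec) product,
    k outermost.
    """
    reports = []
    for k in k_values:
        X, y = build_feature_matrix(dataset, k, mode)
        for spec in specs:
            report = cross_validate(X, y, spec, n_folds=n_folds, seed=seed)
            report.k = k
            reports.append(report)
    return reports
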