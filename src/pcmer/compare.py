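"""Distance-based sequence comparison and its evaluation.

Profiles are compared by Manhattan (L1) distance over all 3 * 2**k cells.
A labeled distance matrix is scored two ways: leave-one-out retrieval AUC
(for each query, rank all other sequences by ascending distance and score
the same-label / different-label ROC; report the unweighted mean over
queries) and Pearson correlation between two distance matrices over the
strict upper triangle.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr
from sklearn.metrics import roc_auc_score

from .core import PCmerProfile

__all__ = [
    "DistanceMatrix",
    "ComparisonReport",
    "manhattan_distance",
    "pairwise_distances",
    "retrieval_auc",
    "matrix_correlation",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with a zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} ids")
        if not np.isfinite(v).all():
            raise ValueError("distance matrix contains non-finite values")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index.astype(str)) != list(df.columns.astype(str)):
            raise ValueError(f"{path}: row and column ids differ")
        return cls(ids=[str(i) for i in df.index], values=df.to_numpy(dtype=float))


@dataclass
class ComparisonReport:
    """Evaluation of one distance matrix: AUC and optional correlation."""

    auc: float
    correlation: float | None = None
    n_queries: int = 0
    notes: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "auc": self.auc,
            "correlation": self.correlation,
            "n_queries": self.n_queries,
            "notes": self.notes,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _check_comparable(a: PCmerProfile, b: PCmerProfile) -> None:
    if a.k != b.k:
        raise ValueError(f"profiles have different k: {a.k} vs {b.k}")
    if a.mode != b.mode:
        raise ValueError(f"profiles have different modes: {a.mode} vs {b.mode}")
    if a.normalized != b.normalized:
        raise ValueError("cannot mix normalized and raw-count profiles")


def manhattan_distance(a: PCmerProfile, b: PCmerProfile) -> float:
    """Sum of absolute cell differences over all three scheme blocks."""
    _check_comparable(a, b)
    return float(np.abs(a.concat() - b.concat()).sum())


def pairwise_distances(
    profiles: list[PCmerProfile], ids: list[str]
) -> DistanceMatrix:
    """All-vs-all Manhattan distances, as a :class:`DistanceMatrix`."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    if len(profiles) != len(ids):
        raise ValueError(f"{len(profiles)} profiles but {len(ids)} ids")
    for p in profiles[1:]:
        _check_comparable(profiles[0], p)
    X = np.vstack([p.concat() for p in profiles]).astype(float)
    return DistanceMatrix(ids=list(ids), values=cdist(X, X, metric="cityblock"))


def retrieval_auc(dmat: DistanceMatrix, labels: list[str]) -> float:
    """Leave-one-out retrieval AUC of a labeled distance matrix.

    For each query, all other sequences are ranked by ascending distance;
    same-label pairs are positives and the ROC AUC of that ranking is
    computed (ties get midranks).  Queries whose class has no other member
    are excluded with a warning.  Returns the unweighted mean over queries.
    """
    labels_arr = np.asarray(labels)
    if len(labels_arr) != dmat.n:
        raise ValueError(f"{len(labels_arr)} labels for {dmat.n} ids")
    if len(set(labels)) < 2:
        raise ValueError("need at least 2 distinct classes")
    aucs = []
    skipped = 0
    for i in range(dmat.n):
        mask = np.ones(dmat.n, dtype=bool)
        mask[i] = False
        y = (labels_arr[mask] == labels_arr[i]).astype(int)
        if y.sum() == 0:
            skipped += 1
            continue
        # smaller distance = more similar, so score is the negated distance
        aucs.append(roc_auc_score(y, -dmat.values[i, mask]))
    if skipped:
        warnings.warn(
            f"{skipped} single-member-class queries excluded from retrieval AUC",
            stacklevel=2,
        )
    if not aucs:
        raise ValueError("no query has a same-class partner")
    return float(np.mean(aucs))


def matrix_correlation(a: DistanceMatrix, b: DistanceMatrix) -> float:
    """Pearson correlation of two distance matrices over the upper triangle."""
    if a.ids != b.ids:
        raise ValueError("distance matrices must share ids in the same order")
    if a.n < 3:
        raise ValueError("need at least 3 sequences for a correlation")
    iu = np.triu_indices(a.n, k=1)
    x, y = a.values[iu], b.values[iu]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: a matrix has zero variance")
    return float(pearsonr(x, y).statistic)
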