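"""Cross-validated accuracy curves and planted-feature recovery metrics.

Protocol: stratified 5-fold cross-validation with a linear SVM (C = 1) and
a 1-nearest-neighbor classifier, evaluated on top-k feature prefixes over a
grid of feature counts (default 10, 20, ..., 100).  The ranking is computed
on the full dataset before cross-validation — a filter-style protocol whose
optimistic bias is deliberate and documented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import LinearSVC

from drfs.core_io import DataMatrix
from drfs.selection import top_k

DEFAULT_GRID = tuple(range(10, 101, 10))
DEFAULT_PARAM_GRID = (0.001, 0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)
DESK_PARAM_GRID = (0.01, 1.0, 100.0)

CLASSIFIERS = ("svm", "1nn")


def _make_classifier(name: str):
    if name in ("svm", "linear-svm-C1"):
        # one-vs-rest linear SVM with fixed C=1
        return LinearSVC(C=1.0, max_iter=10000)
    if name in ("1nn", "one-nn"):
        return KNeighborsClassifier(n_neighbors=1)
    raise ValueError(f"unknown classifier {name!r}")


@dataclass
class AccuracyCurve:
    feature_counts: list[int]
    accuracies: dict[str, list[float]]
    seed: int = 0
    metadata: dict = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"n_features": self.feature_counts})
        for clf, vals in self.accuracies.items():
            df[clf] = vals
        return df

    def write_tsv(self, path) -> None:
        self.frame().to_csv(path, sep="\t", index=False)


def cv_accuracy(
    X: DataMatrix,
    feature_subset: Sequence[int],
    classifier: str = "svm",
    folds: int = 5,
    seed: int = 0,
) -> float:
    """Mean stratified k-fold test accuracy on a fixed feature subset.

    The subset is an input, not refit per fold: selection happens upstream
    on the full data.  Folds shrink (with a warning) if the smallest class
    has fewer members than requested folds.
    """
    subset = np.asarray(feature_subset, dtype=int)
    if subset.size == 0:
        raise ValueError("feature subset is empty")
    if subset.min() < 0 or subset.max() >= X.n_features:
        raise ValueError("feature subset index out of range")
    min_count = int(X.class_counts().min())
    if min_count < folds:
        warnings.warn(
            f"smallest class has {min_count} samples; reducing folds "
            f"{folds} -> {min_count}",
            stacklevel=2,
        )
        folds = max(2, min_count)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = cross_val_score(
        _make_classifier(classifier), X.values[:, subset], X.labels, cv=skf
    )
    return float(scores.mean())


def accuracy_curve(
    X: DataMatrix,
    ranking: np.ndarray,
    grid: Sequence[int] = DEFAULT_GRID,
    classifiers: Sequence[str] = CLASSIFIERS,
    folds: int = 5,
    seed: int = 0,
) -> AccuracyCurve:
    """cv_accuracy at each top-k prefix of the ranking, per classifier."""
    d = len(ranking)
    clipped = [k for k in grid if k <= d]
    if len(clipped) < len(grid):
        warnings.warn(f"feature-count grid clipped to <= d={d}", stacklevel=2)
    accs: dict[str, list[float]] = {c: [] for c in classifiers}
    for k in clipped:
        subset = top_k(ranking, k)
        for c in classifiers:
            accs[c].append(cv_accuracy(X, subset, classifier=c, folds=folds, seed=seed))
    return AccuracyCurve(feature_counts=list(clipped), accuracies=accs, seed=seed)


def recovery_auroc(scores: np.ndarray, ground_truth: Sequence[int]) -> float:
    """AUROC of the scores as a detector of the planted feature set."""
    scores = np.asarray(scores, dtype=float)
    d = scores.shape[0]
    truth = np.zeros(d, dtype=int)
    truth[np.asarray(list(ground_truth), dtype=int)] = 1
    n_pos = truth.sum()
    if n_pos == 0 or n_pos == d:
        raise ValueError("ground truth must be neither empty nor all features")
    return float(roc_auc_score(truth, scores))
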