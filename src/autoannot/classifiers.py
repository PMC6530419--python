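"""Per-label binary classifier families and grid-search tuning.

Four families: Bernoulli naive Bayes, RBF-kernel support vector
classifier, logistic regression (liblinear coordinate descent), and
k-nearest neighbors.  Default hyperparameter grids:

* bernoulli_nb: additive smoothing alpha in {0.01, 0.1, 1, 10}
* svc_rbf:      C in {1, 10, 100} x gamma in {0.01, 0.1, 1}
* logreg:       C in {0.01, 0.1, 1, 10, 100} x penalty in {l1, l2}
  (C is inverse regularization strength: larger = weaker penalty)
* knn:          k in {1, 3, 5, 7, 9} x metric in {manhattan, euclidean}
                x weights in {uniform, distance}

Tuning is an exhaustive grid search under 3-fold stratified CV inside
the training fold, scored by F1 of the positive class; ties go to the
first grid point in canonical order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Any, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import BernoulliNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

__all__ = ["ClassifierSpec", "TrainedModel", "DEFAULT_GRIDS", "FAMILIES",
           "grid_points", "tune", "fit", "predict"]

FAMILIES = ("bernoulli_nb", "svc_rbf", "logreg", "knn")

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "bernoulli_nb": {"alpha": [0.01, 0.1, 1, 10]},
    "svc_rbf": {"C": [1, 10, 100], "gamma": [0.01, 0.1, 1]},
    "logreg": {"C": [0.01, 0.1, 1, 10, 100], "penalty": ["l1", "l2"]},
    "knn": {
        "n_neighbors": [1, 3, 5, 7, 9],
        "metric": ["manhattan", "euclidean"],
        "weights": ["uniform", "distance"],
    },
}


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family plus its tuning grid."""

    family: str
    grid: Mapping[str, Sequence] | None = None
    inner_folds: int = 3

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown classifier family {self.family!r}")
        if self.grid is not None and not self.grid:
            raise ValueError("grid must be nonempty")

    @property
    def effective_grid(self) -> dict[str, list]:
        return dict(self.grid) if self.grid is not None else DEFAULT_GRIDS[self.family]


@dataclass
class TrainedModel:
    family: str
    params: dict[str, Any]
    estimator: Any
    provenance: dict = field(default_factory=dict)


def grid_points(spec: ClassifierSpec) -> list[dict[str, Any]]:
    """Grid points in canonical order (parameter insertion order, row-major)."""
    grid = spec.effective_grid
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in product(*(grid[k] for k in keys))]


def _make_estimator(family: str, params: Mapping[str, Any], seed: int = 0):
    if family == "bernoulli_nb":
        # binarize=0.0: presence/absence, invariant to tf magnitude
        return BernoulliNB(binarize=0.0, **params)
    if family == "svc_rbf":
        return SVC(kernel="rbf", **params)
    if family == "logreg":
        params = dict(params)
        # express the L1/L2 choice through l1_ratio (penalty= is deprecated)
        penalty = params.pop("penalty", "l2")
        params.setdefault("l1_ratio", 1.0 if penalty == "l1" else 0.0)
        return LogisticRegression(solver="liblinear", random_state=seed,
                                  max_iter=1000, **params)
    if family == "knn":
        return KNeighborsClassifier(algorithm="brute", **params)
    raise ValueError(family)


def tune(
    spec: ClassifierSpec,
    X: sp.spmatrix | np.ndarray,
    y: np.ndarray,
    seed: int = 0,
) -> dict[str, Any]:
    """Best grid point by mean inner-CV F1 of the positive class.

    Raises on single-class ``y`` (degenerate fold).  Ties break to the
    first point in canonical grid order.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("tune: training labels contain a single class")
    points = grid_points(spec)
    if len(points) == 1:
        return points[0]
    n_splits = min(spec.inner_folds, int(counts.min()))
    if n_splits < 2:
        # too few positives for an inner split: score on the training data
        scores = []
        for params in points:
            est = _make_estimator(spec.family, params, seed)
            est.fit(X, y)
            scores.append(f1_score(y, est.predict(X), zero_division=0))
        return points[int(np.argmax(scores))]
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    splits = list(cv.split(np.zeros(len(y)), y))
    best_score, best_params = -1.0, points[0]
    for params in points:
        fold_scores = []
        for train_idx, test_idx in splits:
            if len(np.unique(y[train_idx])) < 2:
                continue
            est = _make_estimator(spec.family, params, seed)
            est.fit(X[train_idx], y[train_idx])
            fold_scores.append(
                f1_score(y[test_idx], est.predict(X[test_idx]), zero_division=0)
            )
        score = float(np.mean(fold_scores)) if fold_scores else 0.0
        if score > best_score:
            best_score, best_params = score, params
    return best_params


def fit(
    spec: ClassifierSpec,
    params: Mapping[str, Any],
    X: sp.spmatrix | np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    provenance: dict | None = None,
) -> TrainedModel:
    est = _make_estimator(spec.family, params, seed)
    est.fit(X, y)
    return TrainedModel(
        family=spec.family,
        params=dict(params),
        estimator=est,
        provenance=provenance or {},
    )


def predict(model: TrainedModel, X: sp.spmatrix | np.ndarray) -> np.ndarray:
    """Binary predictions; probabilistic families threshold at 0.5."""
    n_fit = model.estimator.n_features_in_
    if X.shape[1] != n_fit:
        raise ValueError(
            f"feature dimension mismatch: model fitted with {n_fit}, got {X.shape[1]}"
        )
    if model.family in ("bernoulli_nb", "logreg"):
        proba = model.estimator.predict_proba(X)[:, 1]
        return (proba > 0.5).astype(np.int8)
    return np.asarray(model.estimator.predict(X), dtype=np.int8)
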