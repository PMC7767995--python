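"""Tuned downstream classifiers: logistic regression, RBF SVM, decision tree.

Each family is tuned by exhaustive grid search minimizing the mean
cross-validation misclassification error (stratified, seeded folds), then
refit on the full training set:

* LR — ridge-penalized logistic regression over a path of 100 log-spaced
  regularization strengths (lambda = 1/C).
* SVM — radial-basis kernel; gamma over seven log-spaced values from 1e-6
  to 1e1, cost C in {1, 2, 3, 4, 5} (a 7 x 5 grid).
* DT — CART over min split {2, 5, 10}, min bucket {1, 3, 7}, max depth
  {2, 4, 6, 30} and complexity (cost-complexity alpha) {0.001, 0.01, 0.1}.

Ties in CV error are broken by grid order (first wins), so the search is
fully deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Any

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

__all__ = ["ClassifierSpec", "TunedClassifier", "tune_and_train", "predict"]

_FAMILIES = ("lr", "svm", "dt")


def _default_grid(family: str) -> dict[str, list]:
    if family == "lr":
        return {"C": list(np.logspace(-4, 4, 100))}
    if family == "svm":
        return {
            "gamma": list(np.logspace(-6, 1, 7)),
            "C": [1.0, 2.0, 3.0, 4.0, 5.0],
        }
    if family == "dt":
        return {
            "min_samples_split": [2, 5, 10],
            "min_samples_leaf": [1, 3, 7],
            "max_depth": [2, 4, 6, 30],
            "ccp_alpha": [0.001, 0.01, 0.1],
        }
    raise ValueError(f"unknown classifier family {family!r}; expected one of {_FAMILIES}")


@dataclass
class ClassifierSpec:
    """A classifier family plus its hyperparameter grid and seed."""

    family: str
    hyper_grid: dict[str, list] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.family = self.family.lower()
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if not self.hyper_grid:
            self.hyper_grid = _default_grid(self.family)
        if any(len(v) == 0 for v in self.hyper_grid.values()):
            raise ValueError("hyperparameter grid axes must be non-empty")

    def grid_points(self) -> list[dict[str, Any]]:
        """Cartesian product of the grid axes, in lexicographic grid order."""
        keys = list(self.hyper_grid)
        return [dict(zip(keys, combo)) for combo in product(*(self.hyper_grid[k] for k in keys))]

    def build(self, params: dict[str, Any]) -> BaseEstimator:
        if self.family == "lr":
            return LogisticRegression(solver="lbfgs", max_iter=2000, **params)
        if self.family == "svm":
            return SVC(kernel="rbf", random_state=self.seed, **params)
        return DecisionTreeClassifier(random_state=self.seed, **params)


class TunedClassifier(BaseEstimator, ClassifierMixin):
    """Grid-search-tuned binary classifier over one of the three families.

    ``fit`` evaluates every grid point with ``cv``-fold stratified
    cross-validation, keeps the point with minimum mean misclassification
    error (first in grid order on ties) and refits it on all samples.
    ``predict_proba``/``predict`` report the case probability and the
    0.5-thresholded hard label.

    Attributes
    ----------
    best_params_ : dict
        Chosen hyperparameters.
    cv_errors_ : ndarray
        Mean CV error per grid point, in grid order.
    estimator_ : sklearn estimator
        Final refit model.
    """

    def __init__(self, family: str = "lr", cv: int = 5, random_state: int = 0,
                 hyper_grid: dict | None = None):
        self.family = family
        self.cv = cv
        self.random_state = random_state
        self.hyper_grid = hyper_grid

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or X.shape[1] == 0:
            raise ValueError("feature matrix must be 2-D with at least one column")
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training labels contain a single class")
        if not self.cv >= 2 or len(y) < self.cv:
            raise ValueError("need N >= folds >= 2")

        spec = ClassifierSpec(self.family, dict(self.hyper_grid or {}), seed=self.random_state)
        points = spec.grid_points()
        splitter = StratifiedKFold(
            n_splits=self.cv, shuffle=True, random_state=self.random_state
        )
        folds = list(splitter.split(X, y))

        errors = np.empty(len(points))
        for gi, params in enumerate(points):
            fold_err = []
            for tr, va in folds:
                model = spec.build(params).fit(X[tr], y[tr])
                fold_err.append(float(np.mean(model.predict(X[va]) != y[va])))
            errors[gi] = np.mean(fold_err)

        best = int(np.argmin(errors))  # argmin keeps the first minimum: grid-order ties
        self.best_params_ = points[best]
        self.cv_errors_ = errors
        self.grid_points_ = points
        self.classes_ = classes
        self.estimator_ = spec.build(self.best_params_).fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def _case_scores(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"dimension mismatch: fitted with {self.n_features_in_} features, "
                f"got {X.shape[1]}"
            )
        est = self.estimator_
        if hasattr(est, "predict_proba"):
            proba = est.predict_proba(X)
            case_col = int(np.where(est.classes_ == 1)[0][0])
            return proba[:, case_col]
        # SVM: sigmoid-squashed decision margin -- monotone in the margin and
        # 0.5 exactly on the decision boundary, so the 0.5-thresholded label
        # agrees with the fitted decision function
        margin = est.decision_function(X)
        if est.classes_[1] != 1:
            margin = -margin
        return 1.0 / (1.0 + np.exp(-margin))

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        s = self._case_scores(X)
        return np.column_stack([1.0 - s, s])

    def decision_scores(self, X) -> np.ndarray:
        """Case-probability score in [0, 1] for each row."""
        check_is_fitted(self, "estimator_")
        return self._case_scores(X)

    def predict(self, X) -> np.ndarray:
        """Hard labels: score >= 0.5 counts as a positive (case) call."""
        return (self.decision_scores(X) >= 0.5).astype(int)


def tune_and_train(
    features: np.ndarray,
    labels: np.ndarray,
    spec: ClassifierSpec | str,
    folds: int = 5,
) -> TunedClassifier:
    """Functional wrapper: grid-tune ``spec`` and refit on all samples."""
    if isinstance(spec, str):
        spec = ClassifierSpec(spec)
    clf = TunedClassifier(
        family=spec.family, cv=folds, random_state=spec.seed,
        hyper_grid=spec.hyper_grid,
    )
    return clf.fit(features, labels)


def predict(model: TunedClassifier, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores (case probability) and 0.5-thresholded labels."""
    scores = model.decision_scores(features)
    return scores, (scores >= 0.5).astype(int)
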