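"""Evaluation protocol: splits, metrics, and the pipeline-level grid search.

The protocol mirrors a standard small-cohort benchmark: a stratified
80/20 train/test split; fivefold cross-validation on the training set to
tune the pipeline parameters (perplexity *per*, iterations *iter*, output
dimensionality *dim*, neighbor count *k*) by mean CV accuracy; and final
reporting of ACC, nMCC, AUC and AUPR on the held-out test set.  Held-out
folds and test samples are always embedded with the out-of-sample rule —
they never influence bandwidth calibration, the map, or tuning.

Metrics: ACC = (TP+TN)/M and MCC come from the 0.5-thresholded confusion
counts (MCC with a zero denominator is defined as 0); nMCC = (MCC+1)/2
rescales MCC to [0, 1]; AUC is the trapezoidal area under the ROC curve
and AUPR the step-interpolated area under the precision-recall curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from math import sqrt

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.model_selection import train_test_split as _sk_split

from .classify import ClassifierSpec, tune_and_train
from .composition import CompositionTable
from .mapper import AitchisonTSNE

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "PipelineGrid",
    "train_test_split",
    "compute_metrics",
    "cv_grid_search",
    "run_experiment",
]

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricsReport:
    acc: float
    mcc: float
    nmcc: float
    auc: float | None
    aupr: float | None
    n_samples: int
    n_cases: int
    confusion: ConfusionCounts

    def as_dict(self) -> dict:
        return {
            "acc": self.acc,
            "mcc": self.mcc,
            "nmcc": self.nmcc,
            "auc": self.auc,
            "aupr": self.aupr,
            "n_samples": self.n_samples,
            "n_cases": self.n_cases,
        }


@dataclass
class PipelineGrid:
    """Axes of the pipeline grid search plus the evaluation protocol knobs."""

    per_values: list[float] = field(default_factory=lambda: [30.0])
    iter_values: list[int] = field(default_factory=lambda: [1000])
    dim_values: list[int] = field(default_factory=lambda: [2, 3, 5, 7])
    k_values: list[int] = field(default_factory=lambda: [7])
    folds: int = 5
    split_ratio: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("per_values", "iter_values", "dim_values", "k_values"):
            if not getattr(self, name):
                raise ValueError(f"grid axis {name} is empty")
        if not 0 < self.split_ratio < 1:
            raise ValueError("split_ratio must lie in (0, 1)")

    def points(self) -> list[tuple[float, int, int, int]]:
        return list(product(self.per_values, self.iter_values, self.dim_values, self.k_values))


def train_test_split(
    table: CompositionTable, ratio: float = 0.8, seed: int = 0
) -> tuple[CompositionTable, CompositionTable]:
    """Stratified split into train/test subtables (train fraction = ratio)."""
    if table.labels is None:
        raise ValueError("split requires labels")
    counts = np.bincount(table.labels, minlength=2)
    if np.any(counts < 2):
        raise ValueError(f"each class needs >= 2 members, got counts {counts.tolist()}")
    idx = np.arange(table.n_samples)
    tr, te = _sk_split(
        idx, train_size=ratio, stratify=table.labels, random_state=seed, shuffle=True
    )
    return table.subset(np.sort(tr)), table.subset(np.sort(te))


def compute_metrics(scores: np.ndarray, labels: np.ndarray) -> MetricsReport:
    """ACC/MCC/nMCC from 0.5-thresholded counts; AUC and AUPR from scores.

    With single-class labels AUC and AUPR are undefined and reported as
    ``None`` rather than 0.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.size == 0:
        raise ValueError("scores and labels must be equal-length, non-empty")
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("scores must lie in [0, 1]")

    pred = (scores >= 0.5).astype(int)  # ties at 0.5 count as positive calls
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    cm = ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)

    acc = (tp + tn) / cm.total
    denom = sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = ((tp * tn - fp * fn) / denom) if denom > 0 else 0.0
    nmcc = (mcc + 1.0) / 2.0

    if np.unique(labels).size < 2:
        auc: float | None = None
        aupr: float | None = None
    else:
        auc = float(roc_auc_score(labels, scores))
        aupr = float(average_precision_score(labels, scores))

    return MetricsReport(
        acc=float(acc), mcc=float(mcc), nmcc=float(nmcc), auc=auc, aupr=aupr,
        n_samples=int(cm.total), n_cases=int(np.sum(labels == 1)), confusion=cm,
    )


def _fit_fold_pipeline(
    train: CompositionTable,
    per: float,
    n_iter: int,
    dim: int,
    k: int,
    metric: str,
    seed: int,
) -> AitchisonTSNE:
    mapper = AitchisonTSNE(
        n_components=dim, perplexity=per, max_iter=n_iter,
        metric=metric, k_neighbors=k, random_state=seed,
    )
    return mapper.fit(train.values, sample_ids=train.sample_ids)


def cv_grid_search(
    table: CompositionTable,
    grid: PipelineGrid,
    classifier_spec: ClassifierSpec | str = "lr",
    metric: str = "aitchison",
) -> tuple[dict, pd.DataFrame]:
    """Tune (per, iter, dim, k) by mean fivefold CV accuracy on ``table``.

    For every grid point and fold, t-SNE is fit on the in-fold portion
    only, the held-out fold is embedded with the out-of-sample rule, and
    the classifier is tuned/trained on the in-fold embedding.  Returns the
    argmax point (ties -> first in grid order) and the full CV table; a
    failed grid point is recorded with a missing score, never dropped.
    """
    if isinstance(classifier_spec, str):
        classifier_spec = ClassifierSpec(classifier_spec, seed=grid.seed)
    if table.labels is None:
        raise ValueError("grid search requires labels")
    minority = int(np.bincount(table.labels, minlength=2).min())
    if grid.folds > minority:
        raise ValueError(
            f"folds ({grid.folds}) exceeds minority-class count ({minority})"
        )
    points = grid.points()

    if len(points) == 1:
        per, n_iter, dim, k = points[0]
        row = {"per": per, "iter": n_iter, "dim": dim, "k": k, "mean_cv_acc": np.nan}
        return (
            {"per": per, "iter": n_iter, "dim": dim, "k": k},
            pd.DataFrame([row]),
        )

    splitter = StratifiedKFold(n_splits=grid.folds, shuffle=True, random_state=grid.seed)
    folds = list(splitter.split(table.values, table.labels))

    rows = []
    for per, n_iter, dim, k in points:
        accs: list[float] = []
        failed = False
        for tr_idx, va_idx in folds:
            tr, va = table.subset(tr_idx), table.subset(va_idx)
            try:
                mapper = _fit_fold_pipeline(tr, per, n_iter, dim, k, metric, grid.seed)
                clf = tune_and_train(mapper.embedding_, tr.labels, classifier_spec,
                                     folds=grid.folds)
                pred = clf.predict(mapper.transform(va.values))
                accs.append(float(np.mean(pred == va.labels)))
            except (ValueError, FloatingPointError) as exc:  # record, don't skip silently
                logger.warning("grid point per=%s iter=%s dim=%s k=%s failed: %s",
                               per, n_iter, dim, k, exc)
                failed = True
                break
        mean_acc = np.nan if failed else float(np.mean(accs))
        logger.info("grid point per=%s iter=%s dim=%s k=%s -> mean CV ACC %s",
                    per, n_iter, dim, k, mean_acc)
        rows.append({"per": per, "iter": n_iter, "dim": dim, "k": k,
                     "mean_cv_acc": mean_acc})

    cv_table = pd.DataFrame(rows)
    scores = cv_table["mean_cv_acc"].to_numpy()
    if np.all(np.isnan(scores)):
        raise RuntimeError("every grid point failed")
    best = int(np.nanargmax(scores))  # first maximum in grid order
    best_row = cv_table.iloc[best]
    best_params = {"per": float(best_row["per"]), "iter": int(best_row["iter"]),
                   "dim": int(best_row["dim"]), "k": int(best_row["k"])}
    return best_params, cv_table


def run_experiment(
    table: CompositionTable,
    grid: PipelineGrid,
    families: tuple[str, ...] = ("lr", "svm", "dt"),
    metric: str = "aitchison",
    include_high_dim_baseline: bool = False,
) -> dict:
    """End-to-end benchmark: split, tune on train, evaluate on held-out test.

    For each classifier family: tune (per, iter, dim, k) by CV on the
    training split, refit t-SNE on the full training split with the chosen
    parameters, embed the test split out-of-sample, tune/train the
    classifier on the training embedding and score the test embedding.
    Optionally also evaluates the same families on the original
    high-dimensional (closed) features.

    Returns a dict with per-family ``MetricsReport``s, chosen parameters
    and CV tables; a pure function of (table, grid, seed).
    """
    train, test = train_test_split(table, grid.split_ratio, grid.seed)
    result: dict = {"metric": metric, "families": {}, "n_train": train.n_samples,
                    "n_test": test.n_samples}

    for family in families:
        spec = ClassifierSpec(family, seed=grid.seed)
        best, cv_table = cv_grid_search(train, grid, spec, metric=metric)
        mapper = _fit_fold_pipeline(
            train, best["per"], best["iter"], best["dim"], best["k"], metric, grid.seed
        )
        clf = tune_and_train(mapper.embedding_, train.labels, spec, folds=grid.folds)
        scores = clf.decision_scores(mapper.transform(test.values))
        report = compute_metrics(scores, test.labels)
        result["families"][family] = {
            "params": best, "cv_table": cv_table, "report": report,
        }

    if include_high_dim_baseline:
        result["high_dim"] = {}
        tr_closed = train.closed().values
        te_closed = test.closed().values
        for family in families:
            spec = ClassifierSpec(family, seed=grid.seed)
            clf = tune_and_train(tr_closed, train.labels, spec, folds=grid.folds)
            scores = clf.decision_scores(te_closed)
            result["high_dim"][family] = compute_metrics(scores, test.labels)

    return result
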