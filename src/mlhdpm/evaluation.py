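"""Confusion-matrix metrics and stratified k-fold cross-validation.

Class 1 ("disease present") is the positive class throughout.  Any metric
whose denominator is zero (e.g. precision with no positive predictions) is
reported as 0 and flagged in ``undefined`` rather than raising, so summary
tables stay total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .records_io import DomainError


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise DomainError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    tpr: float
    fpr: float
    specificity: float
    f_score: float
    undefined: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "tpr": self.tpr,
            "fpr": self.fpr,
            "specificity": self.specificity,
            "f_score": self.f_score,
            "undefined": list(self.undefined),
        }


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Standard 2x2 counts with class 1 positive."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise DomainError("label vectors differ in length")
    for arr in (y_true, y_pred):
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise DomainError("labels must be binary {0,1}")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def _ratio(num: int, den: int, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision, sensitivity (TPR), FPR, specificity and F-score.

    fpr + specificity = 1 exactly whenever TN+FP > 0.
    """
    if c.n == 0:
        raise DomainError("cannot compute metrics from zero counts")
    undefined: list[str] = []
    accuracy = (c.TP + c.TN) / c.n
    precision = _ratio(c.TP, c.TP + c.FP, "precision", undefined)
    tpr = _ratio(c.TP, c.TP + c.FN, "tpr", undefined)
    fpr = _ratio(c.FP, c.FP + c.TN, "fpr", undefined)
    specificity = _ratio(c.TN, c.TN + c.FP, "specificity", undefined)
    if precision + tpr == 0:
        undefined.append("f_score")
        f_score = 0.0
    else:
        f_score = 2 * precision * tpr / (precision + tpr)
    return MetricsReport(accuracy=accuracy, precision=precision, tpr=tpr,
                         fpr=fpr, specificity=specificity, f_score=f_score,
                         undefined=undefined)


def evaluate_predictions(y_true, y_pred) -> MetricsReport:
    """Convenience: confusion + metrics in one call."""
    return compute_metrics(confusion(y_true, y_pred))


def mean_report(reports: list[MetricsReport]) -> MetricsReport:
    """Unweighted mean of metric values over folds."""
    if not reports:
        raise DomainError("no reports to average")
    keys = ("accuracy", "precision", "tpr", "fpr", "specificity", "f_score")
    means = {k: float(np.mean([getattr(r, k) for r in reports])) for k in keys}
    undefined = sorted({u for r in reports for u in r.undefined})
    return MetricsReport(undefined=undefined, **means)


def kfold_evaluate(pipeline_factory: Callable[[], object], X, y, k: int = 10,
                   seed: int = 0) -> tuple[MetricsReport, list[MetricsReport]]:
    """Stratified k-fold CV: each fold serves as the test set once and the
    metrics are averaged over the k iterations.

    ``pipeline_factory`` returns a fresh estimator-like object with
    ``fit(X, y)`` and ``predict(X)``; anything the estimator does to the
    training data (scaling, resampling) therefore stays inside the fold.
    """
    X = X.values if hasattr(X, "values") and not isinstance(X, np.ndarray) else np.asarray(X)
    y = np.asarray(y, dtype=int)
    n = len(y)
    if k < 2:
        raise DomainError("k must be at least 2")
    if k > n:
        raise DomainError(f"k={k} exceeds sample count {n}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports: list[MetricsReport] = []
    for train_idx, test_idx in skf.split(X, y):
        model = pipeline_factory()
        model.fit(X[train_idx], y[train_idx])
        preds = np.asarray(model.predict(X[test_idx]), dtype=int)
        reports.append(evaluate_predictions(y[test_idx], preds))
    return mean_report(reports), reports


def metrics_table(train: MetricsReport, test: MetricsReport) -> str:
    """Plain-text two-row metric table (train/test x six metrics)."""
    keys = ("accuracy", "precision", "tpr", "fpr", "specificity", "f_score")
    header = "split     " + "".join(f"{k:>12}" for k in keys)
    rows = [header]
    for name, rep in (("train", train), ("test", test)):
        rows.append(f"{name:<10}" + "".join(f"{getattr(rep, k):>12.4f}" for k in keys))
    return "\n".join(rows)
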