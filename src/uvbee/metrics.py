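"""Confusion matrix and classification / regression evaluation metrics.

Conventions match the usual chemometric reporting style:

* the confusion matrix has actual classes on the rows and predicted classes on
  the columns;
* recall, precision and accuracy are reported as percentages, the F-score on
  the 0-1 scale;
* the regression metrics (RMSEP, REP, R^2) treat the integer class code as the
  response, which is how mixture mole-fraction classes are conventionally
  summarized by a regression line.

Classes without any actual (or predicted) samples yield 0-valued recall
(or precision) with a warning rather than an exception, so small synthetic
runs degrade gracefully.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "ClassMetricsReport",
    "RegressionMetricsReport",
    "build_confusion",
    "class_metrics",
    "regression_metrics",
]


@dataclass
class ConfusionMatrix:
    """k x k count table; ``counts[i, j]`` = actual class i+1 predicted as j+1."""

    counts: np.ndarray
    class_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.class_labels is not None and len(self.class_labels) != self.counts.shape[0]:
            raise ValueError("class_labels length must match matrix size")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def format_table(self) -> str:
        """Human-readable table, rows = actual, columns = predicted."""
        labels = self.class_labels or [str(i + 1) for i in range(self.n_classes)]
        width = max(9, max(len(l) for l in labels) + 2)
        lines = ["actual \\ predicted".ljust(19)
                 + "".join(l.rjust(width) for l in labels)]
        for i, row in enumerate(self.counts):
            lines.append(labels[i].ljust(19)
                         + "".join(str(v).rjust(width) for v in row))
        return "\n".join(lines)


@dataclass
class ClassMetricsReport:
    """Per-class recall/precision (percent), F-score (0-1) and overall accuracy."""

    recall_percent: np.ndarray
    precision_percent: np.ndarray
    f_score: np.ndarray
    accuracy_percent: float
    class_labels: list[str] | None = None

    def to_dict(self) -> dict:
        labels = self.class_labels or [
            str(i + 1) for i in range(len(self.recall_percent))]
        return {
            "per_class": {
                label: {
                    "recall_percent": float(r),
                    "precision_percent": float(p),
                    "f_score": float(f),
                }
                for label, r, p, f in zip(labels, self.recall_percent,
                                          self.precision_percent, self.f_score)
            },
            "accuracy_percent": float(self.accuracy_percent),
        }


@dataclass
class RegressionMetricsReport:
    """RMSEP, REP (percent of the mean actual value) and R^2."""

    rmsep: float
    rep_percent: float
    r_squared: float

    def to_dict(self) -> dict:
        return {"rmsep": self.rmsep, "rep_percent": self.rep_percent,
                "r_squared": self.r_squared}


def build_confusion(actual: Sequence[int], predicted: Sequence[int], k: int,
                    class_labels: list[str] | None = None) -> ConfusionMatrix:
    """Count table from 1-based label vectors of equal length."""
    actual = np.asarray(actual, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if actual.size == 0:
        raise ValueError("empty label vectors")
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted must have equal length")
    for name, vec in (("actual", actual), ("predicted", predicted)):
        if vec.min() < 1 or vec.max() > k:
            raise ValueError(f"{name} labels must lie in 1..{k}")
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (actual - 1, predicted - 1), 1)
    return ConfusionMatrix(counts, class_labels)


def class_metrics(cm: ConfusionMatrix) -> ClassMetricsReport:
    """Recall, precision, F-score and accuracy from a confusion matrix.

    ``recall_j = 100 N_jj / row_j``, ``precision_j = 100 N_jj / col_j``,
    ``F_j = 2 p r / (p + r)`` on the 0-1 scale,
    ``accuracy = 100 trace / total``. Zero rows/columns give 0 with a warning.
    """
    counts = cm.counts
    total = counts.sum()
    if total == 0:
        raise ValueError("confusion matrix is all zero")
    diag = np.diag(counts).astype(float)
    row_sums = counts.sum(axis=1).astype(float)
    col_sums = counts.sum(axis=0).astype(float)

    recall = np.zeros(cm.n_classes)
    precision = np.zeros(cm.n_classes)
    for j in range(cm.n_classes):
        if row_sums[j] == 0:
            warnings.warn(f"class {j + 1} has no actual samples; recall set to 0")
        else:
            recall[j] = 100.0 * diag[j] / row_sums[j]
        if col_sums[j] == 0:
            warnings.warn(f"class {j + 1} has no predicted samples; precision set to 0")
        else:
            precision[j] = 100.0 * diag[j] / col_sums[j]

    with np.errstate(invalid="ignore"):
        denom = recall + precision
        f = np.where(denom > 0, 2 * recall * precision / denom / 100.0, 0.0)

    accuracy = 100.0 * diag.sum() / total
    return ClassMetricsReport(recall, precision, f, float(accuracy), cm.class_labels)


def regression_metrics(actual: Sequence[float],
                       predicted: Sequence[float]) -> RegressionMetricsReport:
    """RMSEP, REP and R^2 of predicted against actual values.

    ``RMSEP = sqrt(mean((y_act - y_pred)^2))``,
    ``REP = 100 RMSEP / mean(y_act)``,
    ``R^2 = 1 - SS_res / SS_tot`` with ``SS_tot`` around the mean actual value.
    """
    y = np.asarray(actual, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.size == 0 or y.shape != yhat.shape:
        raise ValueError("actual and predicted must be equal-length, non-empty")
    residual = y - yhat
    rmsep = float(np.sqrt(np.mean(residual ** 2)))
    ybar = float(y.mean())
    if ybar == 0:
        raise ValueError("REP undefined: mean of actual values is zero")
    rep = 100.0 * rmsep / ybar
    ss_tot = float(np.sum((y - ybar) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined: actual values have zero variance")
    r2 = 1.0 - float(np.sum(residual ** 2)) / ss_tot
    return RegressionMetricsReport(rmsep, rep, r2)
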