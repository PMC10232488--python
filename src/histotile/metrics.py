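"""Confusion matrices and classification metrics for tile evaluation."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """K x K counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match {k} classes"
            )
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def save_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.counts, index=self.class_names,
                     columns=self.class_names).to_csv(path, sep="\t")


def confusion_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, class_names: list[str]
) -> ConfusionMatrix:
    counts = _sk_confusion(y_true, y_pred, labels=class_names)
    return ConfusionMatrix(counts=counts, class_names=list(class_names))


@dataclass
class MetricsReport:
    overall_accuracy: float
    per_class: pd.DataFrame  # index class, columns precision/recall/f1

    def save_csv(self, path: str | Path) -> None:
        out = self.per_class.copy()
        out.loc["__overall__"] = [self.overall_accuracy] * out.shape[1]
        out.to_csv(path)


def confusion_metrics(matrix: ConfusionMatrix) -> MetricsReport:
    """Accuracy, per-class precision/recall/F1 from a confusion matrix.

    Precision of a class with an empty predicted column is defined as 0
    (with a warning); F1 is 0 whenever precision + recall is 0.
    """
    counts = matrix.counts
    total = counts.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    diag = np.diag(counts).astype(float)
    col = counts.sum(axis=0).astype(float)
    row = counts.sum(axis=1).astype(float)
    empty_cols = col == 0
    if empty_cols.any():
        logger.warning(
            "no predictions for class(es) %s; precision set to 0",
            [matrix.class_names[i] for i in np.flatnonzero(empty_cols)],
        )
    precision = np.divide(diag, col, out=np.zeros_like(diag), where=col > 0)
    recall = np.divide(diag, row, out=np.zeros_like(diag), where=row > 0)
    pr = precision + recall
    f1 = np.divide(2 * precision * recall, pr, out=np.zeros_like(diag), where=pr > 0)
    per_class = pd.DataFrame(
        {"precision": precision, "recall": recall, "f1": f1},
        index=matrix.class_names,
    )
    return MetricsReport(overall_accuracy=float(diag.sum() / total),
                         per_class=per_class)
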