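"""Classification metric suite shared by offline and streaming evaluation.

Accuracy, support-weighted F1 and precision, and a per-true-class
row-normalised 3×3 confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import accuracy_score, confusion_matrix, f1_score, precision_score

from edapain.labels import Label

N_CLASSES = len(Label)


@dataclass
class MetricsReport:
    accuracy: float
    weighted_f1: float
    weighted_precision: float
    confusion: np.ndarray          # row-normalised per true class
    confusion_counts: np.ndarray   # raw counts
    n_samples: int
    provenance: dict = field(default_factory=dict)

    def summary(self) -> str:
        return (f"accuracy={self.accuracy:.4f} weighted_f1={self.weighted_f1:.4f} "
                f"weighted_precision={self.weighted_precision:.4f} (n={self.n_samples})")


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray, provenance: dict | None = None) -> MetricsReport:
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    if y_true.size == 0:
        raise ValueError("cannot score an empty prediction set")
    labels = list(range(N_CLASSES))
    counts = confusion_matrix(y_true, y_pred, labels=labels)
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        normalised = np.where(row_sums > 0, counts / row_sums, 0.0)
    return MetricsReport(
        accuracy=float(accuracy_score(y_true, y_pred)),
        weighted_f1=float(f1_score(y_true, y_pred, labels=labels, average="weighted", zero_division=0)),
        weighted_precision=float(precision_score(y_true, y_pred, labels=labels, average="weighted", zero_division=0)),
        confusion=normalised,
        confusion_counts=counts,
        n_samples=int(y_true.size),
        provenance=provenance or {},
    )
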