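"""Task metrics: AUC/PRAUC for the binary tasks, balanced accuracy and
macro F1 for the three-class task."""

from __future__ import annotations

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    balanced_accuracy_score,
    f1_score,
    roc_auc_score,
)

__all__ = ["evaluate"]


def evaluate(scores: np.ndarray, labels: np.ndarray, task: str) -> dict[str, float]:
    """Compute the metrics for one task.

    Tasks ``"A"`` and ``"B"`` expect per-example probabilities of class 1 and
    report AUC and PRAUC (average precision). Task ``"C"`` expects an
    (n, 3) probability matrix, takes hard labels by argmax and reports
    balanced accuracy and macro F1.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if task in ("A", "B"):
        if scores.ndim != 1 or scores.shape[0] != labels.shape[0]:
            raise ValueError("binary tasks need aligned 1-D scores")
        present = np.unique(labels)
        if present.size < 2:
            raise ValueError(
                f"AUC undefined: only class(es) {present.tolist()} present"
            )
        return {
            "AUC": float(roc_auc_score(labels, scores)),
            "PRAUC": float(average_precision_score(labels, scores)),
        }
    if task == "C":
        if scores.ndim != 2 or scores.shape[1] != 3:
            raise ValueError("task C needs (n, 3) probability scores")
        predicted = scores.argmax(axis=1)
        return {
            "balanced_accuracy": float(balanced_accuracy_score(labels, predicted)),
            "macro_f1": float(f1_score(labels, predicted, average="macro")),
        }
    raise ValueError(f"unknown task {task!r}")
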