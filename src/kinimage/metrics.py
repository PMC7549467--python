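"""Evaluation metrics shared by the CNN and the flat baselines.

Accuracy is the fraction of correct predictions.  Because both labelings
are class-imbalanced, ROC AUC is the headline metric: standard binary AUC
on the positive-class score for two classes, macro-averaged one-vs-rest
for three.  Precision and recall are macro-averaged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    precision_score,
    recall_score,
    roc_auc_score,
)

from .errors import InvalidArgumentError


@dataclass
class EvalMetrics:
    auc: float
    accuracy: float
    precision: float
    recall: float
    confusion: np.ndarray
    classes: List[str]
    n: int

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "confusion": self.confusion.tolist(),
            "classes": list(self.classes),
            "n": self.n,
        }


def compute_metrics(y_true: np.ndarray, proba: np.ndarray, classes: np.ndarray) -> EvalMetrics:
    """Metrics from true labels and per-class probability scores.

    ``proba`` columns follow ``classes`` (sorted label order).  With
    constant scores the AUC degenerates to 0.5 (no ranking information).
    """
    y_true = np.asarray(y_true)
    proba = np.asarray(proba, dtype=float)
    if len(y_true) == 0:
        raise InvalidArgumentError("empty evaluation set")
    if proba.shape != (len(y_true), len(classes)):
        raise InvalidArgumentError(
            f"proba shape {proba.shape} does not match {len(y_true)} x {len(classes)}"
        )
    classes = list(classes)
    y_pred = np.asarray(classes)[proba.argmax(axis=1)]

    present = np.unique(y_true)
    if len(present) < 2:
        auc = 0.5  # single-class evaluation set carries no ranking task
    elif len(classes) == 2:
        score = proba[:, 1]
        if np.allclose(score, score[0]):
            auc = 0.5
        else:
            auc = float(roc_auc_score((y_true == classes[1]).astype(int), score))
    else:
        auc = float(
            roc_auc_score(y_true, proba, multi_class="ovr", average="macro", labels=classes)
        )

    return EvalMetrics(
        auc=auc,
        accuracy=float(accuracy_score(y_true, y_pred)),
        precision=float(precision_score(y_true, y_pred, average="macro", zero_division=0)),
        recall=float(recall_score(y_true, y_pred, average="macro", zero_division=0)),
        confusion=confusion_matrix(y_true, y_pred, labels=classes),
        classes=classes,
        n=len(y_true),
    )


def auc_chance_band(n_pos: int, n_neg: int, alpha: float = 0.05) -> tuple:
    """Two-sided null band for the AUC of an uninformative classifier.

    Under the null the AUC is a scaled Mann-Whitney U statistic with
    variance (n1 + n2 + 1) / (12 n1 n2); the band is 0.5 +/- z * sd.
    """
    if n_pos < 1 or n_neg < 1:
        raise InvalidArgumentError("need at least one example of each class")
    from scipy.stats import norm

    sd = np.sqrt((n_pos + n_neg + 1.0) / (12.0 * n_pos * n_neg))
    z = norm.ppf(1.0 - alpha / 2.0)
    return 0.5 - z * sd, 0.5 + z * sd
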