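"""Flat comparison classifiers: random forest, linear SVM, logistic
regression.

Each consumes the same normalized activity images as the CNN, flattened to
32*12*C vectors, with the same split protocol and metrics: RF with 100
trees of maximum depth 10, a linear-kernel margin classifier and a
multinomial logistic regression, the latter two at library-default
regularization (recorded in the results).  Margin/decision scores are
mapped through a softmax to probability-like values for the AUC.
"""

from __future__ import annotations

import numpy as np
from scipy.special import softmax
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

from .dataset import LabeledDataset
from .errors import InvalidArgumentError
from .metrics import compute_metrics
from .model import BaseClassifier, ClassificationResults

BASELINE_KINDS = ("RF", "LSV", "LR")


def _make_estimator(kind: str, seed: int):
    if kind == "RF":
        return RandomForestClassifier(n_estimators=100, max_depth=10, random_state=seed)
    if kind == "LSV":
        return LinearSVC(random_state=seed)
    if kind == "LR":
        return LogisticRegression(max_iter=2000, random_state=seed)
    raise InvalidArgumentError(f"unknown baseline kind {kind!r}; expected one of {BASELINE_KINDS}")


class BaselineClassifier(BaseClassifier):
    """One of the three flat baselines over a labeled dataset."""

    def __init__(
        self,
        dataset: LabeledDataset,
        kind: str,
        val_fraction: float = 0.2,
        group_by_participant: bool = False,
    ):
        super().__init__(dataset, val_fraction, group_by_participant)
        if kind not in BASELINE_KINDS:
            raise InvalidArgumentError(
                f"unknown baseline kind {kind!r}; expected one of {BASELINE_KINDS}"
            )
        self.kind = kind
        self.estimator = None

    def fit(self, seed: int = 0, split=None) -> ClassificationResults:
        train_idx, val_idx = split if split is not None else self.split(seed)
        X = self.dataset.flattened()
        y = self.dataset.y
        self.estimator = _make_estimator(self.kind, seed)
        self.estimator.fit(X[train_idx], y[train_idx])
        proba = self._predict_proba(X[val_idx])
        metrics = compute_metrics(y[val_idx], proba, self.estimator.classes_)
        params = self.estimator.get_params()
        recorded = {
            k: v for k, v in params.items()
            if k in ("n_estimators", "max_depth", "C", "penalty", "max_iter")
        }
        return ClassificationResults(
            kind=self.kind,
            metrics=metrics,
            train_idx=train_idx,
            val_idx=val_idx,
            params=recorded,
            seed=seed,
            scheme=self.dataset.scheme,
            channel_order=tuple(self.dataset.channel_order),
        )

    def _predict_proba(self, X: np.ndarray) -> np.ndarray:
        if hasattr(self.estimator, "predict_proba"):
            return self.estimator.predict_proba(X)
        scores = self.estimator.decision_function(X)
        if scores.ndim == 1:  # binary margin -> two-column scores
            scores = np.stack([-scores, scores], axis=1)
        return softmax(scores, axis=1)


def train_baseline(
    kind: str,
    dataset: LabeledDataset,
    seed: int = 0,
    val_fraction: float = 0.2,
    group_by_participant: bool = False,
    split=None,
) -> ClassificationResults:
    """Fit one baseline and return its validation results."""
    model = BaselineClassifier(dataset, kind, val_fraction, group_by_participant)
    return model.fit(seed=seed, split=split)
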