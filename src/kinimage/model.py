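"""Model / Results base classes.

Classifiers follow the fitted-model convention: a model object is built
from a :class:`~kinimage.dataset.LabeledDataset` plus configuration, its
``fit(seed)`` performs the train/validation split and the training run,
and returns a :class:`ClassificationResults` carrying validation metrics,
the confusion matrix, split bookkeeping and a ``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .dataset import LabeledDataset
from .errors import InvalidArgumentError
from .metrics import EvalMetrics
from .split import make_split


@dataclass
class ClassificationResults:
    """Outcome of one fitted classifier."""

    kind: str
    metrics: EvalMetrics
    train_idx: np.ndarray
    val_idx: np.ndarray
    params: dict
    seed: int
    scheme: str = ""
    channel_order: tuple = ()
    history: Optional[list] = None
    extras: dict = field(default_factory=dict)

    @property
    def auc(self) -> float:
        return self.metrics.auc

    @property
    def accuracy(self) -> float:
        return self.metrics.accuracy

    def as_dict(self) -> dict:
        out = {
            "kind": self.kind,
            "scheme": self.scheme,
            "channel_order": list(self.channel_order),
            "seed": self.seed,
            "params": self.params,
            "n_train": int(len(self.train_idx)),
            "n_val": int(len(self.val_idx)),
            **self.metrics.as_dict(),
        }
        if self.extras:
            out["extras"] = self.extras
        return out

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)

    def summary(self) -> str:
        m = self.metrics
        lines = [
            f"{self.kind} classification results".center(58),
            "=" * 58,
            f"{'Scheme:':<22}{self.scheme or '-':>36}",
            f"{'Markers:':<22}{','.join(self.channel_order) or '-':>36}",
            f"{'Train / validation:':<22}{f'{len(self.train_idx)} / {len(self.val_idx)}':>36}",
            f"{'Seed:':<22}{self.seed:>36}",
            "-" * 58,
            f"{'AUC:':<22}{m.auc:>36.4f}",
            f"{'Accuracy:':<22}{m.accuracy:>36.4f}",
            f"{'Precision (macro):':<22}{m.precision:>36.4f}",
            f"{'Recall (macro):':<22}{m.recall:>36.4f}",
            "-" * 58,
            "Confusion matrix (rows = true):",
        ]
        header = " " * 8 + "".join(f"{c:>8}" for c in m.classes)
        lines.append(header)
        for cls, row in zip(m.classes, m.confusion):
            lines.append(f"{cls:>8}" + "".join(f"{v:>8d}" for v in row))
        lines.append("=" * 58)
        return "\n".join(lines)


class BaseClassifier:
    """Shared split handling for the CNN and the flat baselines."""

    kind = "base"

    def __init__(
        self,
        dataset: LabeledDataset,
        val_fraction: float = 0.2,
        group_by_participant: bool = False,
    ):
        if len(dataset) == 0:
            raise InvalidArgumentError("dataset is empty")
        self.dataset = dataset
        self.val_fraction = val_fraction
        self.group_by_participant = group_by_participant
        self.classes = np.unique(dataset.y)

    def split(self, seed: int):
        return make_split(
            self.dataset.y,
            self.dataset.participants,
            self.val_fraction,
            seed,
            self.group_by_participant,
        )

    def fit(self, seed: int = 0) -> ClassificationResults:  # pragma: no cover
        raise NotImplementedError
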