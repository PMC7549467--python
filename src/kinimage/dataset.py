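"""Labeled collections of activity images."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .errors import InvalidArgumentError

#: the two labeling schemes: 3-class limb type, 2-class participant group
SCHEMES = ("limb3", "group2")

LIMB3_CLASSES = ("HUL", "NPUL", "PUL")
GROUP2_CLASSES = ("G1", "G2")


@dataclass
class LabeledDataset:
    """Activity images with class labels under one labeling scheme.

    ``X`` has shape (n, 12, width, channels); ``y`` holds string class
    labels; ``participants`` the participant id of each image (used for
    subject-grouped splitting); ``scheme`` is ``"limb3"`` (HUL / NPUL /
    PUL) or ``"group2"`` (G1 / G2).
    """

    X: np.ndarray
    y: np.ndarray
    channel_order: List[str]
    participants: np.ndarray
    scheme: str = ""
    recording_ids: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        self.participants = np.asarray(self.participants)
        if self.X.ndim != 4:
            raise InvalidArgumentError(f"X must be (n, 12, width, C), got {self.X.shape}")
        if not (len(self.X) == len(self.y) == len(self.participants)):
            raise InvalidArgumentError("X, y and participants must have equal length")

    def __len__(self) -> int:
        return len(self.y)

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.y)

    @property
    def n_channels(self) -> int:
        return self.X.shape[3]

    def class_counts(self) -> Dict[str, int]:
        labels, counts = np.unique(self.y, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def flattened(self) -> np.ndarray:
        """Images as flat vectors (time-major within each row, rows stacked,
        channels last) — the input representation of the flat baselines."""
        return self.X.reshape(len(self), -1)

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            self.X[idx],
            self.y[idx],
            list(self.channel_order),
            self.participants[idx],
            self.scheme,
            None if self.recording_ids is None else self.recording_ids[idx],
            dict(self.meta),
        )
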