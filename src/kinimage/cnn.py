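"""The activity-image CNN classifier.

Architecture (valid-mode 3x3 convolutions, ReLU, 2x2 max-pooling)::

    conv(f_Conv1) -> pool -> conv(f_Conv2) -> pool -> flatten
        -> dense(out_Dense1, ReLU) -> dropout(d_Drop1)
        -> dense(n_classes, softmax)

trained with Adam on multi-class cross-entropy.  The six tunable
hyperparameters are the learning rate ``lr``, epoch count ``ep``, the two
convolution filter counts, the dropout rate and the hidden dense width.
Training is deterministic given the seed (single-threaded numpy; weight
init, batch order and dropout masks all come from one generator).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .dataset import LabeledDataset
from .errors import InvalidArgumentError
from .metrics import compute_metrics
from .model import BaseClassifier, ClassificationResults
from .nn import Adam, SmallCNN, cross_entropy


@dataclass(frozen=True)
class Hyperparameters:
    """The six searched CNN hyperparameters."""

    lr: float = 1e-3
    ep: int = 100
    f_conv1: int = 16
    f_conv2: int = 16
    d_drop1: float = 0.1
    out_dense1: int = 32

    def __post_init__(self) -> None:
        if not self.lr > 0:
            raise InvalidArgumentError("lr must be > 0")
        if self.ep < 1:
            raise InvalidArgumentError("ep must be >= 1")
        if self.f_conv1 < 1 or self.f_conv2 < 1 or self.out_dense1 < 1:
            raise InvalidArgumentError("layer widths must be >= 1")
        if not 0.0 <= self.d_drop1 < 1.0:
            raise InvalidArgumentError("d_drop1 must be in [0, 1)")

    def as_dict(self) -> dict:
        return asdict(self)


DEFAULT_HYPERPARAMETERS = Hyperparameters()


def build_model(
    h: Hyperparameters, n_channels: int, n_classes: int, seed: int = 0,
    height: int = 12, width: int = 32,
) -> SmallCNN:
    """Instantiate the (untrained) network for the given image geometry."""
    if n_classes < 2:
        raise InvalidArgumentError("need at least 2 classes")
    rng = np.random.default_rng(seed)
    return SmallCNN(
        (height, width, n_channels), n_classes,
        h.f_conv1, h.f_conv2, h.out_dense1, h.d_drop1, rng,
    )


def train_network(
    model: SmallCNN,
    X: np.ndarray,
    y_index: np.ndarray,
    h: Hyperparameters,
    rng: np.random.Generator,
    batch_size: int = 32,
    X_val: np.ndarray | None = None,
    y_val_index: np.ndarray | None = None,
) -> list:
    """Run the Adam training loop; returns the per-epoch history."""
    n = X.shape[0]
    eye = np.eye(model.n_classes)
    optimizer = Adam(model.params, h.lr)
    history = []
    for epoch in range(h.ep):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            batch = order[start : start + batch_size]
            probs = model.forward(X[batch], train=True, rng=rng)
            onehot = eye[y_index[batch]]
            losses.append(cross_entropy(probs, onehot))
            grads = model.backward(onehot)
            optimizer.step(model.params, grads)
        entry = {"epoch": epoch, "loss": float(np.mean(losses))}
        if X_val is not None and y_val_index is not None:
            val_probs = model.predict_proba(X_val)
            entry["val_loss"] = cross_entropy(val_probs, eye[y_val_index])
            entry["val_accuracy"] = float((val_probs.argmax(1) == y_val_index).mean())
        history.append(entry)
    return history


class ActivityImageCNN(BaseClassifier):
    """CNN model over a labeled activity-image dataset.

    Parameters
    ----------
    dataset : LabeledDataset
        Images and labels under one labeling scheme.
    hyperparameters : Hyperparameters, optional
    val_fraction : float
        Hold-out fraction (default 0.2, i.e. an 80/20 split).
    group_by_participant : bool
        Hold out whole participants instead of stratifying recordings.
    batch_size : int
        Mini-batch size for Adam (default 32).
    track_validation : bool
        Record validation loss/accuracy per epoch in the history.
    """

    kind = "CNN"

    def __init__(
        self,
        dataset: LabeledDataset,
        hyperparameters: Hyperparameters = DEFAULT_HYPERPARAMETERS,
        val_fraction: float = 0.2,
        group_by_participant: bool = False,
        batch_size: int = 32,
        track_validation: bool = False,
    ):
        super().__init__(dataset, val_fraction, group_by_participant)
        self.hyperparameters = hyperparameters
        self.batch_size = batch_size
        self.track_validation = track_validation
        self.network: SmallCNN | None = None

    def fit(self, seed: int = 0, split=None) -> ClassificationResults:
        """Split, train and evaluate; returns validation-set results.

        ``split`` may carry precomputed ``(train_idx, val_idx)`` so several
        models can share the exact same partition.
        """
        h = self.hyperparameters
        train_idx, val_idx = split if split is not None else self.split(seed)
        ds = self.dataset
        class_to_index = {c: i for i, c in enumerate(self.classes)}
        y_index = np.array([class_to_index[c] for c in ds.y])

        rng = np.random.default_rng(seed)
        self.network = build_model(
            h, ds.n_channels, len(self.classes),
            seed=int(rng.integers(2**31)),
            height=ds.X.shape[1], width=ds.X.shape[2],
        )
        history = train_network(
            self.network,
            ds.X[train_idx], y_index[train_idx], h, rng,
            batch_size=self.batch_size,
            X_val=ds.X[val_idx] if self.track_validation else None,
            y_val_index=y_index[val_idx] if self.track_validation else None,
        )
        metrics = self.evaluate(ds.subset(val_idx))
        return ClassificationResults(
            kind=self.kind,
            metrics=metrics,
            train_idx=train_idx,
            val_idx=val_idx,
            params=h.as_dict(),
            seed=seed,
            scheme=ds.scheme,
            channel_order=tuple(ds.channel_order),
            history=history,
            extras={"n_parameters": self.network.n_parameters},
        )

    def evaluate(self, examples: LabeledDataset):
        """Validation metrics of the fitted network on ``examples``."""
        if self.network is None:
            raise InvalidArgumentError("model is not fitted")
        if len(examples) == 0:
            raise InvalidArgumentError("empty evaluation set")
        proba = self.network.predict_proba(examples.X)
        return compute_metrics(examples.y, proba, self.classes)


def train_model(
    dataset: LabeledDataset,
    hyperparameters: Hyperparameters = DEFAULT_HYPERPARAMETERS,
    seed: int = 0,
    val_fraction: float = 0.2,
    group_by_participant: bool = False,
    split=None,
    track_validation: bool = False,
) -> ClassificationResults:
    """One-call convenience wrapper: build, fit and evaluate the CNN."""
    model = ActivityImageCNN(
        dataset, hyperparameters, val_fraction, group_by_participant,
        track_validation=track_validation,
    )
    return model.fit(seed=seed, split=split)
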