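"""Labeling schemes and the marker-ablation experiment matrix.

Two classification tasks are defined over a cohort:

* ``limb3`` — limb type: HUL (healthy upper limb, both limbs of every
  control), NPUL (non-paretic limb of stroke participants), PUL (paretic
  limb).  For the reference design (35 stroke / 19 control participants,
  3 activities) the class sizes are 114 / 105 / 105.
* ``group2`` — participant group: G1 (every limb of every stroke
  participant) vs G2 (controls); reference sizes 210 / 114.

The ablation runs the CNN and the three flat baselines over subsets of
the four markers (hand FN, forearm LEP, arm MPH, shoulder ACR) to locate
the body segment carrying the discriminative information.  All rows of
one ablation share a single frozen split so differences reflect marker
information, not split luck.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .baselines import BASELINE_KINDS, train_baseline
from .cnn import DEFAULT_HYPERPARAMETERS, Hyperparameters, train_model
from .dataset import LabeledDataset
from .encoding import assemble_image
from .errors import InvalidArgumentError
from .preprocess import DEFAULT_CONFIG, PreprocessConfig, preprocess_recording
from .recording import UPPER_LIMB_MARKERS
from .split import make_split
from .synthetic import Cohort

#: the eight marker configurations of the ablation matrix
DEFAULT_MARKER_SETS = (
    ("FN",),
    ("LEP",),
    ("MPH",),
    ("ACR",),
    ("LEP", "MPH"),
    ("FN", "LEP", "MPH"),
    ("LEP", "MPH", "ACR"),
    ("FN", "LEP", "MPH", "ACR"),
)

ALL_MODELS = ("CNN",) + BASELINE_KINDS


def label_recording(group: str, limb_role: str, scheme: str) -> str:
    """Class label of one recording under a labeling scheme."""
    if scheme == "group2":
        if group not in ("G1", "G2"):
            raise InvalidArgumentError(f"unknown group {group!r}")
        return group
    if scheme == "limb3":
        if group == "G2":
            return "HUL"
        if limb_role == "paresis":
            return "PUL"
        if limb_role == "non-paresis":
            return "NPUL"
        raise InvalidArgumentError(
            f"cannot label limb_role {limb_role!r} in group {group!r} under limb3"
        )
    raise InvalidArgumentError(f"unknown labeling scheme {scheme!r}")


def assign_labels(metadata: pd.DataFrame, scheme: str) -> np.ndarray:
    """Vector of class labels for a cohort metadata table."""
    required = {"group", "role"}
    missing = required - set(metadata.columns)
    if missing:
        raise InvalidArgumentError(f"metadata missing columns: {sorted(missing)}")
    if metadata[["group", "role"]].isna().any().any():
        raise InvalidArgumentError("metadata contains recordings with missing group/role")
    return np.array(
        [label_recording(g, r, scheme) for g, r in zip(metadata["group"], metadata["role"])]
    )


def label_dataset(cohort: Cohort, images: Sequence, scheme: str) -> LabeledDataset:
    """Attach scheme labels to pre-assembled images of a cohort."""
    labels = assign_labels(cohort.metadata, scheme)
    if len(images) != len(labels):
        raise InvalidArgumentError("one image per cohort recording required")
    X = np.stack([img.values for img in images])
    return LabeledDataset(
        X,
        labels,
        list(images[0].channel_order),
        cohort.metadata["participant_id"].to_numpy(),
        scheme,
        recording_ids=cohort.metadata["file"].to_numpy(),
    )


def build_dataset(
    cohort: Cohort,
    markers: Sequence[str] = UPPER_LIMB_MARKERS,
    scheme: str = "group2",
    config: PreprocessConfig = DEFAULT_CONFIG,
) -> LabeledDataset:
    """Full pipeline: preprocess every recording, encode the requested
    markers, label under ``scheme``.  An empty cohort yields an empty
    dataset with the declared channel geometry."""
    if not cohort.recordings:
        return LabeledDataset(
            np.zeros((0, 12, config.resample_n, len(markers))),
            np.array([], dtype=str),
            list(markers),
            np.array([], dtype=str),
            scheme,
        )
    images = [
        assemble_image(preprocess_recording(rec, config), markers, width=config.resample_n)
        for rec in cohort.recordings
    ]
    return label_dataset(cohort, images, scheme)


def select_channels(dataset: LabeledDataset, markers: Sequence[str]) -> LabeledDataset:
    """Channel-subset view of a dataset encoded with more markers."""
    try:
        idx = [dataset.channel_order.index(m) for m in markers]
    except ValueError as exc:
        raise InvalidArgumentError(f"marker not in dataset channels: {exc}") from None
    return LabeledDataset(
        dataset.X[:, :, :, idx],
        dataset.y,
        list(markers),
        dataset.participants,
        dataset.scheme,
        dataset.recording_ids,
        dict(dataset.meta),
    )


def run_ablation(
    cohort: Cohort,
    scheme: str = "group2",
    marker_sets: Sequence[Sequence[str]] = DEFAULT_MARKER_SETS,
    hyperparameters: Hyperparameters = DEFAULT_HYPERPARAMETERS,
    seed: int = 0,
    models: Sequence[str] = ALL_MODELS,
    val_fraction: float = 0.2,
    group_by_participant: bool = False,
    config: PreprocessConfig = DEFAULT_CONFIG,
    search: Optional[object] = None,
    search_calls: int = 40,
) -> pd.DataFrame:
    """Run the marker-configuration experiment matrix.

    Encodes the union of requested markers once, then trains every model
    on every marker subset with one frozen split.  When ``search`` is a
    :class:`~kinimage.hyperopt.SearchSpace`, the CNN hyperparameters are
    re-optimized per marker set (``search_calls`` objective evaluations);
    otherwise the supplied ``hyperparameters`` are reused for every row.

    Returns a tidy report: one row per (marker set, model) with
    auc/accuracy/precision/recall and split sizes, in the given order.
    """
    union: list = []
    for ms in marker_sets:
        bad = [m for m in ms if m not in UPPER_LIMB_MARKERS]
        if bad:
            raise InvalidArgumentError(f"unknown markers {bad}; choose from {UPPER_LIMB_MARKERS}")
        union.extend(m for m in ms if m not in union)
    full = build_dataset(cohort, union, scheme, config)
    split = make_split(
        full.y, full.participants, val_fraction, seed, group_by_participant
    )

    rows = []
    for ms in marker_sets:
        ds = select_channels(full, ms)
        h_row = hyperparameters
        if search is not None and "CNN" in models:
            from .hyperopt import make_cnn_objective, optimize

            opt = optimize(
                make_cnn_objective(ds, base_seed=seed, split=split),
                space=search, n_calls=search_calls, seed=seed,
            )
            h_row = opt.best
        for model in models:
            if model == "CNN":
                res = train_model(ds, h_row, seed=seed, split=split)
            elif model in BASELINE_KINDS:
                res = train_baseline(model, ds, seed=seed, split=split)
            else:
                raise InvalidArgumentError(f"unknown model {model!r}")
            rows.append(
                {
                    "markers": ",".join(ms),
                    "model": model,
                    "auc": res.metrics.auc,
                    "accuracy": res.metrics.accuracy,
                    "precision": res.metrics.precision,
                    "recall": res.metrics.recall,
                    "n_train": len(res.train_idx),
                    "n_val": len(res.val_idx),
                }
            )
    return pd.DataFrame(rows)
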