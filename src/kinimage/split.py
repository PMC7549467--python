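"""Train/validation splitting (80/20 by default).

Two protocols: stratified at recording level (closest to a plain
stratified hold-out), and grouped by participant so that no subject
contributes to both partitions — the leakage-safe protocol, since the two
limbs and three activities of one person are strongly correlated.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from .errors import SplitError


def _check_coverage(y: np.ndarray, train_idx: np.ndarray, val_idx: np.ndarray) -> None:
    classes = set(np.unique(y).tolist())
    if len(classes) < 2:
        raise SplitError("dataset contains a single class")
    for name, idx in (("training", train_idx), ("validation", val_idx)):
        missing = classes - set(np.unique(y[idx]).tolist())
        if missing:
            raise SplitError(f"classes {sorted(missing)} absent from the {name} partition")


def stratified_split(
    y: np.ndarray, val_fraction: float = 0.2, seed: int = 0
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-class shuffled hold-out at recording level."""
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    train, val = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_val = max(1, int(round(val_fraction * len(idx))))
        val.append(idx[:n_val])
        train.append(idx[n_val:])
    train_idx = np.sort(np.concatenate(train))
    val_idx = np.sort(np.concatenate(val))
    _check_coverage(y, train_idx, val_idx)
    return train_idx, val_idx


def participant_split(
    y: np.ndarray, participants: np.ndarray, val_fraction: float = 0.2, seed: int = 0
) -> Tuple[np.ndarray, np.ndarray]:
    """Hold out whole participants, stratified by each participant's label
    profile (e.g. stroke vs control), so every class appears on both sides."""
    y = np.asarray(y)
    participants = np.asarray(participants)
    rng = np.random.default_rng(seed)
    profile = {}
    for pid in np.unique(participants):
        profile[pid] = tuple(sorted(np.unique(y[participants == pid]).tolist()))
    strata: dict = {}
    for pid, prof in profile.items():
        strata.setdefault(prof, []).append(pid)

    val_pids = []
    for prof in sorted(strata):
        pids = np.array(sorted(strata[prof]))
        rng.shuffle(pids)
        n_val = max(1, int(round(val_fraction * len(pids))))
        val_pids.extend(pids[:n_val].tolist())
    val_mask = np.isin(participants, val_pids)
    train_idx = np.flatnonzero(~val_mask)
    val_idx = np.flatnonzero(val_mask)
    _check_coverage(y, train_idx, val_idx)
    return train_idx, val_idx


def make_split(
    y: np.ndarray,
    participants: np.ndarray,
    val_fraction: float = 0.2,
    seed: int = 0,
    group_by_participant: bool = False,
) -> Tuple[np.ndarray, np.ndarray]:
    if group_by_participant:
        return participant_split(y, participants, val_fraction, seed)
    return stratified_split(y, val_fraction, seed)
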