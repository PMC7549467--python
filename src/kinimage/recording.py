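"""In-memory representation of one marker-trajectory recording.

A :class:`Recording` holds the per-frame 3D positions (mm) of a set of
optical-capture markers for one functional movement — here, lifting and
lowering an object with one hand — together with the sampling interval and
the clinical metadata needed for labeling (participant, group, limb role,
activity).

Coordinate convention (configurable elsewhere, fixed here for generated
data): axis 0 = X, lateral (left of the body midline is negative);
axis 1 = Y, vertical; axis 2 = Z, anterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict

import numpy as np

from .errors import InvalidArgumentError

#: Canonical (side-stripped) marker names of the upper-limb kinematic chain:
#: index-finger nail, lateral epicondyle, mid-humerus, acromion.
UPPER_LIMB_MARKERS = ("FN", "LEP", "MPH", "ACR")

#: All side-stripped marker names this package recognises as "already unified".
KNOWN_UNIFIED_MARKERS = frozenset({"FN", "LEP", "MPH", "ACR", "CLAV", "RS", "US"})

AXIS_INDEX = {"x": 0, "y": 1, "z": 2}

GROUPS = ("G1", "G2")
LIMB_ROLES = ("paresis", "non-paresis", "left", "right")
ACTIVITIES = ("DG", "SC", "LC")


@dataclass
class RecordingMeta:
    """Metadata attached to one recording.

    ``group`` is ``"G1"`` (post-stroke) or ``"G2"`` (control); ``limb_role``
    is ``paresis``/``non-paresis`` for G1 limbs and ``left``/``right`` for
    G2 limbs.  ``extras`` carries free-form provenance (e.g. the synthetic
    generator stores the ground-truth onset/offset sample indices there).
    """

    participant_id: str = ""
    group: str = ""
    limb_role: str = ""
    activity: str = ""
    side: str = ""
    extras: dict = field(default_factory=dict)

    def copy(self) -> "RecordingMeta":
        return replace(self, extras=dict(self.extras))


@dataclass
class Recording:
    """One functional movement: marker name -> (N+1, 3) position array in mm.

    All marker series must share the same length; the sampling interval
    ``sample_interval`` is in seconds (0.01 s for 100 Hz capture).
    """

    markers: Dict[str, np.ndarray]
    sample_interval: float
    meta: RecordingMeta = field(default_factory=RecordingMeta)

    def __post_init__(self) -> None:
        if not self.markers:
            raise InvalidArgumentError("recording must contain at least one marker")
        if not np.isfinite(self.sample_interval) or self.sample_interval <= 0:
            raise InvalidArgumentError(
                f"sample_interval must be positive, got {self.sample_interval}"
            )
        lengths = set()
        for name, arr in self.markers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise InvalidArgumentError(
                    f"marker {name!r}: expected (n, 3) positions, got {arr.shape}"
                )
            if not np.isfinite(arr).all():
                raise InvalidArgumentError(f"marker {name!r} contains NaN/inf samples")
            self.markers[name] = arr
            lengths.add(arr.shape[0])
        if len(lengths) != 1:
            raise InvalidArgumentError(f"marker series lengths differ: {sorted(lengths)}")

    @property
    def n_samples(self) -> int:
        return next(iter(self.markers.values())).shape[0]

    @property
    def duration(self) -> float:
        """Total spanned time (N intervals) in seconds."""
        return (self.n_samples - 1) * self.sample_interval

    @property
    def marker_names(self) -> list:
        return list(self.markers)

    def copy(self) -> "Recording":
        return Recording(
            {k: v.copy() for k, v in self.markers.items()},
            self.sample_interval,
            self.meta.copy(),
        )

    def marker(self, name: str) -> np.ndarray:
        """Look up a marker, accepting either the exact name or a side-stripped
        base name (``"FN"`` matches ``"FNR"``/``"FNL"``)."""
        if name in self.markers:
            return self.markers[name]
        candidates = [m for m in self.markers if m[:-1] == name and m[-1] in "LR"]
        if len(candidates) == 1:
            return self.markers[candidates[0]]
        raise KeyError(name)
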