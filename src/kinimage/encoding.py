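"""Derivative-feature "activity image" encoding of one movement.

Each clipped, side-unified recording is turned into a fixed-size image:
width 32 (time), height 12 (feature rows), depth C (one channel per
marker, 1-4).  The 12 rows per marker are, per coordinate axis, the chain

    d_i = |p_i - p_{i-1}|            (displacement, mm)
    v_i = (d_i - d_{i-1}) / T'       (velocity feature, mm/s)
    a_i = (v_i - v_{i-1}) / T'       (acceleration feature, mm/s^2)
    j_i = (a_i - a_{i-1}) / T'       (jerk feature, mm/s^3)

computed from the position signal resampled to 32 samples.  Note the chain
differentiates the absolute displacement series, not the signed position —
this makes every row invariant to lateral mirroring by construction.  T'
is the effective interval of the resampled signal: clipped duration
divided by 31, which preserves physical feature magnitudes across
movements of different durations.

The chained differences yield 31/30/29/28 samples from 32 positions while
the image width is fixed at 32; each row is left-padded by replicating its
first value, which keeps late time samples aligned across rows.  Finally
every row is min-max normalized to [0, 1] independently, per recording; a
constant row maps to all zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import json
import os

import numpy as np

from .errors import InvalidArgumentError
from .preprocess import DEFAULT_CONFIG, resample_linear
from .recording import Recording

AXES = ("x", "y", "z")
FEATURES = ("d", "v", "a", "j")

#: row names in axis-major order: (d,v,a,j) for x, then y, then z
ROW_NAMES_AXIS_MAJOR = tuple(f"{f}_{ax}" for ax in AXES for f in FEATURES)
#: alternative feature-major order: (x,y,z) for d, then v, a, j
ROW_NAMES_FEATURE_MAJOR = tuple(f"{f}_{ax}" for f in FEATURES for ax in AXES)

IMAGE_HEIGHT = 12


@dataclass
class FeatureBlock:
    """The 12 normalized feature rows of one marker: array (12, width)."""

    values: np.ndarray
    row_names: Sequence[str]
    marker: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != IMAGE_HEIGHT:
            raise InvalidArgumentError(f"expected (12, width) block, got {self.values.shape}")
        if not np.isfinite(self.values).all():
            raise InvalidArgumentError("feature block contains non-finite values")


@dataclass
class ActivityImage:
    """One movement as an image: values (12, width, C) in [0, 1]."""

    values: np.ndarray
    channel_order: List[str]
    label: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[0] != IMAGE_HEIGHT:
            raise InvalidArgumentError(
                f"expected (12, width, channels) image, got {self.values.shape}"
            )
        if self.values.shape[2] != len(self.channel_order):
            raise InvalidArgumentError("channel_order length must match image depth")

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def depth(self) -> int:
        return self.values.shape[2]


def displacement_series(positions: np.ndarray) -> np.ndarray:
    """Per-axis displacement: absolute first difference, length n-1."""
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 1 or positions.shape[0] < 2:
        raise InvalidArgumentError("need a 1-D series of length >= 2")
    return np.abs(np.diff(positions))


def difference_rate(series: np.ndarray, t_prime: float) -> np.ndarray:
    """First difference divided by the sampling interval, length n-1.

    Applied once to the displacement series it gives the velocity feature;
    chained again, acceleration; a third time, jerk.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or series.shape[0] < 2:
        raise InvalidArgumentError("need a 1-D series of length >= 2")
    if not t_prime > 0:
        raise InvalidArgumentError(f"sampling interval must be > 0, got {t_prime}")
    return np.diff(series) / t_prime


def minmax_normalize(series: np.ndarray) -> np.ndarray:
    """Map a series affinely onto [0, 1]; a constant series maps to zeros
    (a constant feature carries no information and a zero row avoids the
    division by zero)."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise InvalidArgumentError("cannot normalize an empty series")
    lo, hi = series.min(), series.max()
    if hi == lo:
        return np.zeros_like(series)
    return (series - lo) / (hi - lo)


def _left_pad(series: np.ndarray, width: int) -> np.ndarray:
    pad = width - series.shape[0]
    if pad < 0:
        raise InvalidArgumentError("series longer than target width")
    return np.concatenate([np.full(pad, series[0]), series])


def encode_marker(
    rec: Recording,
    marker: str,
    width: int = DEFAULT_CONFIG.resample_n,
    row_order: str = "axis",
    normalize: bool = True,
) -> FeatureBlock:
    """Encode one marker of a clipped, unified recording into a 12-row block.

    Per axis: resample the position signal to ``width`` samples, then chain
    displacement -> velocity -> acceleration -> jerk with the effective
    interval ``T' = clipped duration / (width - 1)``; left-pad each series
    back to ``width`` by edge replication; min-max normalize each row
    independently (skipped when ``normalize=False``, for dataset-global
    normalization schemes).
    """
    try:
        positions = rec.marker(marker)
    except KeyError:
        raise InvalidArgumentError(f"marker {marker!r} not present in recording") from None
    if row_order not in ("axis", "feature"):
        raise InvalidArgumentError("row_order must be 'axis' or 'feature'")

    t_prime = rec.duration / (width - 1)
    per_axis = {}
    for ai, axis in enumerate(AXES):
        p = resample_linear(positions[:, ai], width)
        d = displacement_series(p)
        v = difference_rate(d, t_prime)
        a = difference_rate(v, t_prime)
        j = difference_rate(a, t_prime)
        per_axis[axis] = {"d": d, "v": v, "a": a, "j": j}

    row_names = ROW_NAMES_AXIS_MAJOR if row_order == "axis" else ROW_NAMES_FEATURE_MAJOR
    rows = []
    for name in row_names:
        feat, axis = name.split("_")
        series = _left_pad(per_axis[axis][feat], width)
        rows.append(minmax_normalize(series) if normalize else series)
    return FeatureBlock(np.stack(rows), row_names, marker=marker)


def assemble_image(
    rec: Recording,
    markers: Sequence[str],
    width: int = DEFAULT_CONFIG.resample_n,
    row_order: str = "axis",
    label: Optional[str] = None,
) -> ActivityImage:
    """Stack one :class:`FeatureBlock` per marker as image channels, in the
    given order: 1 marker -> grey-scale analogue, 4 markers -> RGBA
    analogue (12 x width x 4)."""
    if not 1 <= len(markers) <= 4:
        raise InvalidArgumentError("between 1 and 4 markers required")
    if len(set(markers)) != len(markers):
        raise InvalidArgumentError("duplicate markers in channel list")
    blocks = [encode_marker(rec, m, width=width, row_order=row_order) for m in markers]
    values = np.stack([b.values for b in blocks], axis=2)
    return ActivityImage(values, list(markers), label=label, meta={"row_order": row_order})


def save_image(image: ActivityImage, path: str) -> None:
    """Serialize to ``<path>.npz`` plus a ``<path>.json`` sidecar holding
    channel order, label and provenance."""
    base, _ = os.path.splitext(path)
    np.savez(base + ".npz", values=image.values)
    with open(base + ".json", "w") as fh:
        json.dump(
            {"channel_order": image.channel_order, "label": image.label, "meta": image.meta},
            fh,
            indent=2,
        )


def load_image(path: str) -> ActivityImage:
    base, _ = os.path.splitext(path)
    values = np.load(base + ".npz")["values"]
    with open(base + ".json") as fh:
        sidecar = json.load(fh)
    return ActivityImage(
        values, sidecar["channel_order"], sidecar.get("label"), sidecar.get("meta", {})
    )


def plot_image(image: ActivityImage, path: Optional[str] = None):
    """Render the image channels as heat maps (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, image.depth, figsize=(3 * image.depth, 3), squeeze=False)
    for c in range(image.depth):
        ax = axes[0, c]
        ax.imshow(image.values[:, :, c], aspect="auto", vmin=0, vmax=1, cmap="viridis")
        ax.set_title(image.channel_order[c])
        ax.set_xlabel("time sample")
        if c == 0:
            ax.set_ylabel("feature row")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
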