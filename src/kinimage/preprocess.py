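"""Trajectory preprocessing: movement clipping, side unification, resampling.

Raw recordings contain rest periods before and after the movement.  The
clipping stage finds the movement window from the smoothed speed of a
reference marker (the finger marker by default), using the standard
kinematic-onset convention: the first sustained crossing of a fraction of
peak speed, refined by backtracking to a near-zero speed floor.  One
temporal window is applied to all markers and axes so the three coordinate
signals stay aligned for feature stacking.

Side unification reflects left-limb recordings across the lateral axis so
every movement is expressed as a right-limb movement, and strips the L/R
suffix from marker names.  Resampling maps each clipped coordinate signal
onto a fixed number of samples (32) by linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DetectionFailureError, InvalidArgumentError
from .recording import AXIS_INDEX, KNOWN_UNIFIED_MARKERS, Recording


@dataclass(frozen=True)
class ClipBounds:
    """Inclusive sample window ``[start_index, end_index]`` applied to every
    marker and axis of one recording (0-based)."""

    start_index: int
    end_index: int

    def __post_init__(self) -> None:
        if not 0 <= self.start_index < self.end_index:
            raise InvalidArgumentError(
                f"require 0 <= start < end, got ({self.start_index}, {self.end_index})"
            )


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable preprocessing parameters.

    ``speed_fraction`` is the onset threshold as a fraction of the peak
    smoothed speed; ``min_hold_s`` how long speed must stay above it to
    count as movement; ``backtrack_fraction`` the near-zero floor the
    detector walks back to; ``smooth_window`` the moving-average width in
    samples; ``resample_n`` the fixed output length; ``mirror_axis`` the
    lateral axis negated during side unification.
    """

    reference_marker: str = "FN"
    speed_fraction: float = 0.05
    min_hold_s: float = 0.1
    backtrack_fraction: float = 0.005
    smooth_window: int = 5
    resample_n: int = 32
    mirror_axis: str = "x"


DEFAULT_CONFIG = PreprocessConfig()


def _smoothed_speed(rec: Recording, marker: str, window: int) -> np.ndarray:
    pos = rec.marker(marker)
    vel = np.diff(pos, axis=0) / rec.sample_interval
    speed = np.linalg.norm(vel, axis=1)
    if window > 1:
        kernel = np.ones(window) / window
        speed = np.convolve(speed, kernel, mode="same")
    return speed


def detect_movement_bounds(
    rec: Recording,
    reference_marker: str = DEFAULT_CONFIG.reference_marker,
    speed_fraction: float = DEFAULT_CONFIG.speed_fraction,
    min_hold: float = DEFAULT_CONFIG.min_hold_s,
    smooth_window: int = DEFAULT_CONFIG.smooth_window,
    backtrack_fraction: float = DEFAULT_CONFIG.backtrack_fraction,
) -> ClipBounds:
    """Find the movement window of a recording.

    Start: the first sample where the smoothed reference-marker speed
    exceeds ``speed_fraction * peak`` and stays above it for ``min_hold``
    seconds, backtracked to the last preceding sample below
    ``backtrack_fraction * peak`` (so the detected onset sits at the true
    beginning of the speed rise rather than at the threshold crossing).
    End: the symmetric construction from the tail.  Raises
    :class:`DetectionFailureError` when the recording never moves.
    """
    if rec.duration <= 2.0 * min_hold:
        raise InvalidArgumentError("recording shorter than twice min_hold")
    speed = _smoothed_speed(rec, reference_marker, smooth_window)
    peak = float(speed.max())
    if peak <= 0.0:
        raise DetectionFailureError("constant recording: speed is identically zero")
    threshold = speed_fraction * peak
    hold = max(1, int(round(min_hold / rec.sample_interval)))

    above = speed > threshold
    if not above.any():
        raise DetectionFailureError("speed never exceeds the onset threshold")

    sustained = _first_sustained(above, hold)
    if sustained is None:
        raise DetectionFailureError("no sustained movement above the onset threshold")
    sustained_end = len(above) - 1 - _first_sustained(above[::-1], hold)

    floor = backtrack_fraction * peak
    start = sustained
    while start > 0 and speed[start - 1] > floor:
        start -= 1
    end = sustained_end
    while end < len(speed) - 1 and speed[end + 1] > floor:
        end += 1

    # speed[i] describes the interval between samples i and i+1
    return ClipBounds(start, min(end + 1, rec.n_samples - 1))


def _first_sustained(mask: np.ndarray, hold: int):
    """Index of the first run of at least ``hold`` consecutive True values."""
    run = 0
    for i, m in enumerate(mask):
        run = run + 1 if m else 0
        if run >= hold:
            return i - hold + 1
    return None


def clip(rec: Recording, bounds: ClipBounds) -> Recording:
    """Truncate every marker to the inclusive window; metadata preserved."""
    if bounds.end_index > rec.n_samples - 1:
        raise InvalidArgumentError(
            f"bounds {bounds} out of range for {rec.n_samples} samples"
        )
    markers = {
        name: arr[bounds.start_index : bounds.end_index + 1].copy()
        for name, arr in rec.markers.items()
    }
    return Recording(markers, rec.sample_interval, rec.meta.copy())


def unify_side(rec: Recording, mirror_axis: str = DEFAULT_CONFIG.mirror_axis) -> Recording:
    """Express the recording as a right-limb movement with side-free names.

    Left recordings (all marker names ending in ``L``) have their lateral
    axis negated; right recordings are returned with coordinates untouched.
    In both cases the trailing side letter is stripped (``FNL`` -> ``FN``).
    Applying the function to an already-unified recording is the identity.
    """
    names = list(rec.markers)
    suffixes = {n[-1] for n in names}
    already_unified = all(n in KNOWN_UNIFIED_MARKERS for n in names)
    if already_unified or not suffixes <= {"L", "R"}:
        if suffixes <= {"L", "R"} and not already_unified:
            raise InvalidArgumentError(f"mixed-side marker set: {names}")
        return rec.copy()
    if len(suffixes) != 1:
        raise InvalidArgumentError(f"mixed-side marker set: {names}")
    side = suffixes.pop()
    axis = AXIS_INDEX[mirror_axis]
    sign = np.ones(3)
    if side == "L":
        sign[axis] = -1.0
    markers = {}
    for name in names:
        base = name[:-1]
        if base in markers:
            raise InvalidArgumentError(f"duplicate marker after side stripping: {base}")
        markers[base] = rec.markers[name] * sign
    return Recording(markers, rec.sample_interval, rec.meta.copy())


def resample_linear(series: np.ndarray, n_out: int = DEFAULT_CONFIG.resample_n) -> np.ndarray:
    """Resample a scalar series to ``n_out`` samples by linear interpolation
    at uniformly spaced fractional positions over ``[0, len-1]``.  Endpoints
    are preserved exactly; outputs are convex combinations of neighbours,
    so the resampled series stays within the input's range."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or series.shape[0] < 2:
        raise InvalidArgumentError("series must be 1-D with length >= 2")
    if n_out < 2:
        raise InvalidArgumentError("n_out must be >= 2")
    if series.shape[0] == n_out:
        return series.copy()
    positions = np.linspace(0.0, series.shape[0] - 1.0, n_out)
    return np.interp(positions, np.arange(series.shape[0]), series)


def preprocess_recording(rec: Recording, config: PreprocessConfig = DEFAULT_CONFIG) -> Recording:
    """detect -> clip -> unify: the standard preparation before encoding."""
    bounds = detect_movement_bounds(
        rec,
        reference_marker=config.reference_marker,
        speed_fraction=config.speed_fraction,
        min_hold=config.min_hold_s,
        smooth_window=config.smooth_window,
        backtrack_fraction=config.backtrack_fraction,
    )
    return unify_side(clip(rec, bounds), config.mirror_axis)
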