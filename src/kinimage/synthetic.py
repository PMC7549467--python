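"""Synthetic cohorts of upper-limb lifting movements.

Generates marker-trajectory recordings that emulate the study design of a
clinical lifting experiment: participants lift an object (a small cylinder
SC or large cylinder LC to head height, or a glass DG to mouth height) and
lower it again, once per recording, captured at 100 Hz with four reflective
markers along the limb — index-finger nail (FN), lateral epicondyle (LEP),
mid-humerus (MPH) and acromion (ACR).

The healthy movement model is the minimum-jerk point-to-point profile, the
standard description of smooth reaching.  Post-stroke deficits are injected
as a :class:`ClassEffect`: longer movement time (``duration_factor``),
reduced and flattened peak velocity (``peak_velocity_factor``),
fragmentation of the lift into overlapping sub-movements
(``n_submovements`` — the classic smoothness/jerk deficit), band-limited
action tremor (``tremor_amplitude``, 4-12 Hz, enveloped by movement speed),
and extra proximal displacement of MPH/ACR (``proximal_compensation``,
emulating compensatory trunk/shoulder strategies).  Stroke participants get
a strong effect on the paretic limb and a milder one on the non-paretic
limb; controls move with a null effect.

Everything is deterministic given the seed.  Left-hand recordings are exact
lateral mirrors of the right-hand construction (X negated), so side
unification downstream is exactly invertible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .errors import InvalidArgumentError
from .recording import Recording, RecordingMeta, UPPER_LIMB_MARKERS

# ---------------------------------------------------------------------------
# movement geometry (mm, s): canonical right-handed lift at a table
# ---------------------------------------------------------------------------

#: resting position of each marker (X lateral, Y vertical, Z anterior), mm
BASE_POSITION = {
    "FN": np.array([230.0, 950.0, 250.0]),
    "LEP": np.array([210.0, 1100.0, 60.0]),
    "MPH": np.array([190.0, 1250.0, 20.0]),
    "ACR": np.array([170.0, 1400.0, 0.0]),
}

#: fraction of the hand displacement each marker inherits along the chain
MARKER_GAIN = {"FN": 1.0, "LEP": 0.55, "MPH": 0.30, "ACR": 0.12}

#: markers receiving the proximal-compensation surplus
PROXIMAL_MARKERS = ("MPH", "ACR")

#: per-activity lift height (mm), anterior reach (mm) and base lift time (s)
ACTIVITY_PARAMS = {
    "DG": {"lift_mm": 250.0, "reach_mm": 150.0, "lift_s": 1.2},
    "SC": {"lift_mm": 400.0, "reach_mm": 80.0, "lift_s": 1.3},
    "LC": {"lift_mm": 400.0, "reach_mm": 80.0, "lift_s": 1.4},
}

_LATERAL_DRIFT_MM = 30.0  # small X excursion accompanying the reach
_TOP_HOLD_S = 0.25  # pause at the top of the lift
_REST_PAD_RANGE_S = (0.5, 1.0)  # uniform rest padding at each end
_TREMOR_BAND_HZ = (4.0, 12.0)
_TRAP_RAMP = 0.08  # ramp fraction of the smoothed-trapezoid velocity profile

_MINJERK_PEAK = 1.875  # peak speed of the unit minimum-jerk profile, x A/D
_TRAP_PEAK = 1.0 / (1.0 - _TRAP_RAMP)  # peak speed of the trapezoid profile


# ---------------------------------------------------------------------------
# effect and cohort configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassEffect:
    """Kinematic deficit applied to one limb class.

    A null effect (all factors 1, amplitudes 0) reproduces the healthy
    minimum-jerk movement.  ``affected_markers`` optionally restricts the
    velocity-profile, sub-movement and tremor components to a subset of
    markers (``duration_factor`` always acts globally, since it sets the
    shared time base of the recording); ``None`` means all markers.
    """

    duration_factor: float = 1.0
    peak_velocity_factor: float = 1.0
    n_submovements: int = 1
    tremor_amplitude: float = 0.0
    proximal_compensation: float = 0.0
    affected_markers: Optional[FrozenSet[str]] = None

    def __post_init__(self) -> None:
        if not self.duration_factor > 0:
            raise InvalidArgumentError("duration_factor must be > 0")
        if not self.peak_velocity_factor > 0:
            raise InvalidArgumentError("peak_velocity_factor must be > 0")
        if int(self.n_submovements) != self.n_submovements or self.n_submovements < 1:
            raise InvalidArgumentError("n_submovements must be an integer >= 1")
        if self.tremor_amplitude < 0:
            raise InvalidArgumentError("tremor_amplitude must be >= 0")
        if self.proximal_compensation < 0:
            raise InvalidArgumentError("proximal_compensation must be >= 0")
        if self.affected_markers is not None:
            object.__setattr__(self, "affected_markers", frozenset(self.affected_markers))

    @classmethod
    def null(cls) -> "ClassEffect":
        return cls()

    @property
    def is_null(self) -> bool:
        return (
            self.duration_factor == 1.0
            and self.peak_velocity_factor == 1.0
            and self.n_submovements == 1
            and self.tremor_amplitude == 0.0
            and self.proximal_compensation == 0.0
        )

    def affects(self, marker: str) -> bool:
        return self.affected_markers is None or marker in self.affected_markers


#: default deficit magnitudes: strong on the paretic limb, mild bilaterally
PARETIC_EFFECT = ClassEffect(
    duration_factor=1.5,
    peak_velocity_factor=0.6,
    n_submovements=3,
    tremor_amplitude=1.5,
    proximal_compensation=0.3,
)
NONPARETIC_EFFECT = ClassEffect(
    duration_factor=1.15,
    peak_velocity_factor=0.85,
    n_submovements=2,
    tremor_amplitude=0.5,
    proximal_compensation=0.1,
)
CONTROL_EFFECT = ClassEffect.null()


@dataclass(frozen=True)
class CohortConfig:
    """Study design: 35 stroke x 2 limbs and 19 controls x 2 limbs, each
    recorded once per activity (DG, SC, LC) -> 324 recordings by default."""

    n_stroke: int = 35
    n_control: int = 19
    activities: Sequence[str] = ("DG", "SC", "LC")
    paretic_effect: ClassEffect = PARETIC_EFFECT
    nonparetic_effect: ClassEffect = NONPARETIC_EFFECT
    control_effect: ClassEffect = CONTROL_EFFECT
    sample_rate: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stroke < 0 or self.n_control < 0:
            raise InvalidArgumentError("cohort sizes must be >= 0")
        if not self.activities:
            raise InvalidArgumentError("at least one activity required")
        bad = [a for a in self.activities if a not in ACTIVITY_PARAMS]
        if bad:
            raise InvalidArgumentError(f"unknown activity codes: {bad}")
        if self.sample_rate <= 0:
            raise InvalidArgumentError("sample_rate must be > 0")

    @property
    def n_recordings(self) -> int:
        return (self.n_stroke * 2 + self.n_control * 2) * len(self.activities)


@dataclass
class Cohort:
    """Generated recordings plus the cohort metadata table (one row each:
    participant_id, group, limb, role, activity, file)."""

    recordings: list
    metadata: pd.DataFrame
    config: CohortConfig

    def __len__(self) -> int:
        return len(self.recordings)


# ---------------------------------------------------------------------------
# movement profiles
# ---------------------------------------------------------------------------


def min_jerk_profile(amplitude: float, duration: float, n: int) -> np.ndarray:
    """Sample the minimum-jerk point-to-point profile.

    ``x(t) = A (10 tau^3 - 15 tau^4 + 6 tau^5)`` with ``tau = t/duration``,
    evaluated at ``n`` uniformly spaced times over ``[0, duration]``.  The
    endpoints are exactly 0 and ``amplitude``; velocity and acceleration
    vanish at both ends; the peak speed is ``1.875 A / duration``.
    """
    if n < 2:
        raise InvalidArgumentError(f"need n >= 2 samples, got {n}")
    if not duration > 0:
        raise InvalidArgumentError(f"duration must be > 0, got {duration}")
    if not np.isfinite(amplitude):
        raise InvalidArgumentError("amplitude must be finite")
    tau = np.linspace(0.0, 1.0, n)
    return amplitude * _minjerk_shape(tau)


def _minjerk_shape(tau: np.ndarray) -> np.ndarray:
    tau = np.clip(tau, 0.0, 1.0)
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)


def _trapezoid_shape(tau: np.ndarray, ramp: float = _TRAP_RAMP) -> np.ndarray:
    """C2 smoothed-trapezoid unit profile: quintic-smoothstep velocity ramps
    of width ``ramp`` around a constant-velocity plateau.  Peak speed
    ``1/(1-ramp)`` (vs 1.875 for minimum jerk), used to flatten velocity
    profiles when emulating reduced peak velocity."""
    tau = np.clip(tau, 0.0, 1.0)
    vp = 1.0 / (1.0 - ramp)

    def ramp_integral(u):  # integral of 6u^5-15u^4+10u^3
        return u**6 - 3.0 * u**5 + 2.5 * u**4

    out = np.empty_like(tau)
    lo = tau <= ramp
    hi = tau >= 1.0 - ramp
    mid = ~(lo | hi)
    out[lo] = vp * ramp * ramp_integral(tau[lo] / ramp)
    out[mid] = vp * (ramp * 0.5 + (tau[mid] - ramp))
    out[hi] = 1.0 - vp * ramp * ramp_integral((1.0 - tau[hi]) / ramp)
    return out


def velocity_blend_weight(peak_velocity_factor: float) -> float:
    """Weight of the minimum-jerk component that yields the requested peak
    speed ratio.  The blend spans peak ratios [~0.58, 1.0]; values below are
    clipped to the flattest profile."""
    w = (_MINJERK_PEAK * peak_velocity_factor - _TRAP_PEAK) / (_MINJERK_PEAK - _TRAP_PEAK)
    return float(np.clip(w, 0.0, 1.0))


def _segment_shape(tau: np.ndarray, pv_weight: float) -> np.ndarray:
    if pv_weight >= 1.0:
        return _minjerk_shape(tau)
    return pv_weight * _minjerk_shape(tau) + (1.0 - pv_weight) * _trapezoid_shape(tau)


def _segment(t: np.ndarray, onset: float, amplitude: float, duration: float,
             n_sub: int, pv_weight: float) -> np.ndarray:
    """One lift (or lower) stroke starting at ``onset``: either a single
    smooth profile or ``n_sub`` overlapping sub-profiles of amplitude
    ``amplitude / n_sub`` staggered across the stroke (movement
    fragmentation raises the jerk cost while preserving endpoints)."""
    if n_sub <= 1:
        return amplitude * _segment_shape((t - onset) / duration, pv_weight)
    d_sub = duration * (1.0 + n_sub) / (2.0 * n_sub)
    step = (duration - d_sub) / (n_sub - 1)
    out = np.zeros_like(t)
    for i in range(n_sub):
        o = onset + i * step
        out += (amplitude / n_sub) * _segment_shape((t - o) / d_sub, pv_weight)
    return out


def _band_limited_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-variance noise band-passed to the physiological tremor band."""
    white = rng.standard_normal(n)
    nyq = fs / 2.0
    hi = min(_TREMOR_BAND_HZ[1], 0.95 * nyq)
    lo = min(_TREMOR_BAND_HZ[0], 0.5 * hi)
    sos = butter(2, [lo / nyq, hi / nyq], btype="band", output="sos")
    shaped = sosfiltfilt(sos, white)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


# ---------------------------------------------------------------------------
# recording and cohort generation
# ---------------------------------------------------------------------------


def generate_recording(
    activity: str,
    limb_side: str,
    effect: ClassEffect,
    seed: int,
    sample_rate: float = 100.0,
    meta: Optional[RecordingMeta] = None,
) -> Recording:
    """Generate one lifting-and-lowering recording (4 markers).

    The recording is always constructed right-handed and mirrored (X
    negated, marker suffix L) for ``limb_side="left"``, so a left/right
    pair with the same seed and effect is an exact lateral mirror.  Rest
    padding of 0.5-1.0 s is added at both ends; the ground-truth movement
    onset/offset sample indices are stored in ``meta.extras``.
    """
    if activity not in ACTIVITY_PARAMS:
        raise InvalidArgumentError(f"unknown activity code {activity!r}")
    if limb_side not in ("left", "right"):
        raise InvalidArgumentError(f"limb_side must be 'left' or 'right', got {limb_side!r}")

    rng = np.random.default_rng(seed)
    params = ACTIVITY_PARAMS[activity]
    fs = sample_rate
    dt = 1.0 / fs

    pad0 = rng.uniform(*_REST_PAD_RANGE_S)
    pad1 = rng.uniform(*_REST_PAD_RANGE_S)
    d_lift = params["lift_s"] * effect.duration_factor
    d_lower = d_lift
    t_total = pad0 + d_lift + _TOP_HOLD_S + d_lower + pad1
    n = int(round(t_total * fs)) + 1
    t = np.arange(n) * dt

    lower_onset = pad0 + d_lift + _TOP_HOLD_S
    w_eff = velocity_blend_weight(effect.peak_velocity_factor)

    def hand_curves(pv_weight: float, n_sub: int) -> np.ndarray:
        """(n, 3) hand displacement relative to rest.  Sub-movement
        fragmentation acts on the vertical axis (the main movement axis);
        the velocity-profile flattening acts on every axis."""
        y = _segment(t, pad0, params["lift_mm"], d_lift, n_sub, pv_weight) - _segment(
            t, lower_onset, params["lift_mm"], d_lower, n_sub, pv_weight
        )
        d_reach = 0.6 * d_lift
        reach = _segment(t, pad0, 1.0, d_reach, 1, pv_weight) - _segment(
            t, lower_onset + (d_lower - d_reach), 1.0, d_reach, 1, pv_weight
        )
        z = params["reach_mm"] * reach
        x = _LATERAL_DRIFT_MM * reach
        return np.stack([x, y, z], axis=1)

    curves_eff = hand_curves(w_eff, effect.n_submovements)
    curves_null = curves_eff if effect.is_null else hand_curves(1.0, 1)

    # speed envelope for tremor: tremor rides on the movement, not on rest
    vel = np.gradient(curves_eff, dt, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    peak = speed.max()
    envelope = speed / peak if peak > 0 else speed

    markers = {}
    for name in UPPER_LIMB_MARKERS:
        gain = MARKER_GAIN[name]
        if name in PROXIMAL_MARKERS:
            gain *= 1.0 + (effect.proximal_compensation if effect.affects(name) else 0.0)
        curves = curves_eff if effect.affects(name) else curves_null
        traj = BASE_POSITION[name] + gain * curves
        if effect.tremor_amplitude > 0 and effect.affects(name):
            amp = effect.tremor_amplitude * MARKER_GAIN[name]
            noise = np.stack(
                [_band_limited_noise(rng, n, fs) for _ in range(3)], axis=1
            )
            traj = traj + amp * envelope[:, None] * noise
        elif effect.tremor_amplitude > 0:
            # keep the rng stream identical whether or not this marker is
            # affected, so marker-restricted effects stay comparable
            for _ in range(3):
                _band_limited_noise(rng, n, fs)
        markers[name + "R"] = traj

    if limb_side == "left":
        markers = {
            name[:-1] + "L": traj * np.array([-1.0, 1.0, 1.0]) for name, traj in markers.items()
        }

    meta = meta.copy() if meta is not None else RecordingMeta()
    meta.side = limb_side
    meta.activity = meta.activity or activity
    meta.extras.update(
        {
            "onset_index": int(round(pad0 * fs)),
            "offset_index": int(round((lower_onset + d_lower) * fs)),
            "seed": int(seed),
        }
    )
    return Recording(markers, dt, meta)


_ROLE_EFFECT = {
    "paresis": "paretic_effect",
    "non-paresis": "nonparetic_effect",
    "left": "control_effect",
    "right": "control_effect",
}

_META_COLUMNS = ["participant_id", "group", "limb", "role", "activity", "file"]


def _cohort_plan(config: CohortConfig) -> list:
    """One dict per recording: metadata plus the child seed that makes the
    cohort bit-reproducible.  The paretic side of each stroke participant
    is drawn pseudo-randomly from the cohort seed."""
    rng = np.random.default_rng(config.seed)
    plan = []

    def add(pid: str, group: str, side: str, role: str) -> None:
        for act in config.activities:
            plan.append(
                {
                    "participant_id": pid,
                    "group": group,
                    "limb": side,
                    "role": role,
                    "activity": act,
                    "file": f"{pid}_{side}_{act}.csv",
                    "seed": int(rng.integers(2**31)),
                }
            )

    for i in range(config.n_stroke):
        pid = f"S{i + 1:03d}"
        paretic_side = "left" if rng.random() < 0.5 else "right"
        other = "right" if paretic_side == "left" else "left"
        add(pid, "G1", paretic_side, "paresis")
        add(pid, "G1", other, "non-paresis")

    for i in range(config.n_control):
        pid = f"C{i + 1:03d}"
        add(pid, "G2", "left", "left")
        add(pid, "G2", "right", "right")

    return plan


def cohort_metadata(config: CohortConfig) -> pd.DataFrame:
    """The cohort metadata table alone, without simulating trajectories —
    enough for class-count arithmetic and labeling checks."""
    return pd.DataFrame(_cohort_plan(config), columns=_META_COLUMNS)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full cohort described by ``config``.

    Stroke participants (group G1) contribute a paretic and a non-paretic
    limb; the paretic side is assigned pseudo-randomly per participant.
    Controls (G2) contribute plain left and right limbs.  Every recording
    gets its own child seed, so the cohort is bit-reproducible from
    ``config.seed``.
    """
    plan = _cohort_plan(config)
    recordings = []
    for row in plan:
        effect = getattr(config, _ROLE_EFFECT[row["role"]])
        meta = RecordingMeta(
            participant_id=row["participant_id"],
            group=row["group"],
            limb_role=row["role"],
            activity=row["activity"],
            side=row["limb"],
        )
        recordings.append(
            generate_recording(
                row["activity"], row["limb"], effect, row["seed"], config.sample_rate, meta
            )
        )
    metadata = pd.DataFrame(plan, columns=_META_COLUMNS)
    assert len(recordings) == config.n_recordings
    return Cohort(recordings, metadata, config)


def null_cohort_config(**overrides) -> CohortConfig:
    """A cohort in which all three limb classes move identically (null
    effects everywhere): the negative control for every classifier."""
    defaults = dict(
        paretic_effect=ClassEffect.null(),
        nonparetic_effect=ClassEffect.null(),
        control_effect=ClassEffect.null(),
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)
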