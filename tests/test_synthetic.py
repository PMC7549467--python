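"""Generator: minimum-jerk kinematics, deficit effects, cohort arithmetic."""

import numpy as np
import pytest

from kinimage import ClassEffect, CohortConfig, generate_cohort, generate_recording, min_jerk_profile
from kinimage.errors import InvalidArgumentError
from kinimage.synthetic import (
    NONPARETIC_EFFECT,
    PARETIC_EFFECT,
    cohort_metadata,
    velocity_blend_weight,
)


def mean_squared_jerk(series: np.ndarray, dt: float) -> float:
    """Independent finite-difference jerk cost: third difference / dt^3."""
    jerk = np.diff(series, n=3) / dt**3
    return float(np.mean(jerk**2))


class TestMinJerkProfile:
    def test_zero_amplitude_is_flat(self):
        assert np.all(min_jerk_profile(0.0, 1.0, 32) == 0.0)

    def test_boundary_conditions_and_monotonicity(self):
        x = min_jerk_profile(120.0, 1.5, 64)
        assert x[0] == 0.0
        assert x[-1] == pytest.approx(120.0)
        assert np.all(np.diff(x) >= 0.0)

    def test_peak_velocity_matches_brute_force_maximum(self):
        # closed form: v(tau) = A/D * (30 tau^2 - 60 tau^3 + 30 tau^4),
        # maximized on a dense grid by brute force
        amplitude, duration = 250.0, 1.3
        tau = np.linspace(0.0, 1.0, 200_001)
        v_closed = amplitude / duration * 30.0 * tau**2 * (1.0 - tau) ** 2
        expected_peak = v_closed.max()
        assert expected_peak == pytest.approx(1.875 * amplitude / duration, rel=1e-9)

        x = min_jerk_profile(amplitude, duration, 20_001)
        dt = duration / 20_000
        observed_peak = np.abs(np.diff(x) / dt).max()
        assert observed_peak == pytest.approx(expected_peak, rel=1e-3)

    @pytest.mark.parametrize("kwargs", [dict(n=1), dict(duration=0.0), dict(duration=-1.0)])
    def test_invalid_arguments(self, kwargs):
        args = dict(amplitude=1.0, duration=1.0, n=32)
        args.update(kwargs)
        with pytest.raises(InvalidArgumentError):
            min_jerk_profile(**args)


class TestGenerateRecording:
    def test_deterministic_given_seed(self):
        a = generate_recording("DG", "right", ClassEffect.null(), seed=5)
        b = generate_recording("DG", "right", ClassEffect.null(), seed=5)
        assert a.marker_names == b.marker_names
        for m in a.markers:
            assert np.array_equal(a.markers[m], b.markers[m])

    def test_left_right_pair_is_exact_lateral_mirror(self):
        right = generate_recording("SC", "right", PARETIC_EFFECT, seed=3)
        left = generate_recording("SC", "left", PARETIC_EFFECT, seed=3)
        for m in right.markers:
            lm = m[:-1] + "L"
            assert np.array_equal(left.markers[lm][:, 0], -right.markers[m][:, 0])
            assert np.array_equal(left.markers[lm][:, 1:], right.markers[m][:, 1:])

    def test_submovement_fragmentation_raises_jerk_cost(self):
        smooth = generate_recording(
            "SC", "right", ClassEffect(n_submovements=1), seed=8
        )
        fragmented = generate_recording(
            "SC", "right", ClassEffect(n_submovements=3), seed=8
        )
        y_smooth = smooth.marker("FN")[:, 1]
        y_frag = fragmented.marker("FN")[:, 1]
        assert mean_squared_jerk(y_smooth, smooth.sample_interval) < mean_squared_jerk(
            y_frag, fragmented.sample_interval
        )

    def test_duration_factor_lengthens_movement(self):
        base = generate_recording("DG", "right", ClassEffect.null(), seed=2)
        slow = generate_recording("DG", "right", ClassEffect(duration_factor=1.5), seed=2)
        span = lambda r: r.meta.extras["offset_index"] - r.meta.extras["onset_index"]
        assert span(slow) > span(base)

    def test_peak_velocity_factor_monotonically_reduces_peak_speed(self):
        peaks = []
        for pv in (1.0, 0.85, 0.6):
            rec = generate_recording(
                "SC", "right", ClassEffect(peak_velocity_factor=pv), seed=4
            )
            vel = np.diff(rec.marker("FN"), axis=0) / rec.sample_interval
            peaks.append(np.linalg.norm(vel, axis=1).max())
        assert peaks[0] > peaks[1] > peaks[2]

    def test_blend_weight_endpoints(self):
        assert velocity_blend_weight(1.0) == pytest.approx(1.0)
        assert 0.0 < velocity_blend_weight(0.85) < 1.0

    def test_marker_restricted_effect_leaves_other_markers_clean(self):
        eff = ClassEffect(
            peak_velocity_factor=0.6, n_submovements=3, tremor_amplitude=1.5,
            affected_markers=frozenset({"MPH"}),
        )
        affected = generate_recording("SC", "right", eff, seed=6)
        clean = generate_recording("SC", "right", ClassEffect.null(), seed=6)
        assert np.allclose(affected.marker("FN"), clean.marker("FN"))
        assert not np.allclose(affected.marker("MPH"), clean.marker("MPH"))

    def test_unknown_activity_rejected(self):
        with pytest.raises(InvalidArgumentError):
            generate_recording("XX", "right", ClassEffect.null(), seed=0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(duration_factor=0.0),
            dict(peak_velocity_factor=-1.0),
            dict(n_submovements=0),
            dict(tremor_amplitude=-0.1),
            dict(proximal_compensation=-0.5),
        ],
    )
    def test_effect_validation(self, kwargs):
        with pytest.raises(InvalidArgumentError):
            ClassEffect(**kwargs)


class TestGenerateCohort:
    def test_default_cohort_arithmetic(self):
        meta = cohort_metadata(CohortConfig(seed=0))
        assert len(meta) == (35 * 2 + 19 * 2) * 3 == 324
        assert (meta.role == "paresis").sum() == 105

    def test_minimal_cohort(self):
        cohort = generate_cohort(
            CohortConfig(n_stroke=0, n_control=1, activities=("DG",), seed=1)
        )
        assert len(cohort) == 2
        assert set(cohort.metadata.group) == {"G2"}

    def test_cohort_is_bit_reproducible(self):
        cfg = CohortConfig(n_stroke=2, n_control=1, activities=("LC",), seed=13)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        assert a.metadata.equals(b.metadata)
        for ra, rb in zip(a.recordings, b.recordings):
            for m in ra.markers:
                assert np.array_equal(ra.markers[m], rb.markers[m])

    def test_nonparetic_effect_is_milder_than_paretic(self):
        # defaults: milder slowing, higher residual peak velocity, fewer
        # sub-movements, less tremor on the non-paretic side
        assert NONPARETIC_EFFECT.duration_factor < PARETIC_EFFECT.duration_factor
        assert NONPARETIC_EFFECT.peak_velocity_factor > PARETIC_EFFECT.peak_velocity_factor
        assert NONPARETIC_EFFECT.n_submovements < PARETIC_EFFECT.n_submovements
        assert NONPARETIC_EFFECT.tremor_amplitude < PARETIC_EFFECT.tremor_amplitude
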