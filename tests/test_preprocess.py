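"""Clipping, side unification and resampling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kinimage import (
    ClassEffect,
    ClipBounds,
    Recording,
    clip,
    detect_movement_bounds,
    generate_recording,
    resample_linear,
    unify_side,
)
from kinimage.errors import DetectionFailureError, InvalidArgumentError
from kinimage.synthetic import NONPARETIC_EFFECT, PARETIC_EFFECT


def brute_force_interp(series, n_out):
    """Independent two-point interpolation oracle."""
    L = len(series)
    out = np.empty(n_out)
    for k in range(n_out):
        pos = k * (L - 1) / (n_out - 1)
        i = int(np.floor(pos))
        if i >= L - 1:
            out[k] = series[-1]
        else:
            frac = pos - i
            out[k] = (1 - frac) * series[i] + frac * series[i + 1]
    return out


class TestResampleLinear:
    def test_linear_ramp_stays_on_the_line(self):
        out = resample_linear(np.arange(100.0), 32)
        assert out[0] == 0.0 and out[-1] == 99.0
        np.testing.assert_allclose(out, np.linspace(0.0, 99.0, 32), rtol=1e-12)

    def test_length_32_input_is_identity(self):
        x = np.random.default_rng(0).normal(size=32)
        np.testing.assert_array_equal(resample_linear(x, 32), x)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.normal(size=rng.integers(2, 200))
            n_out = int(rng.integers(2, 64))
            np.testing.assert_allclose(
                resample_linear(x, n_out), brute_force_interp(x, n_out), rtol=1e-12, atol=1e-12
            )

    @given(seed=st.integers(0, 2**16), n_in=st.integers(2, 100), n_out=st.integers(2, 64))
    def test_output_bounded_by_input_range(self, seed, n_in, n_out):
        x = np.random.default_rng(seed).normal(size=n_in)
        out = resample_linear(x, n_out)
        assert out.min() >= x.min() - 1e-12
        assert out.max() <= x.max() + 1e-12

    def test_too_short_input_rejected(self):
        with pytest.raises(InvalidArgumentError):
            resample_linear(np.array([1.0]), 32)


class TestDetectMovementBounds:
    @pytest.mark.parametrize("effect", [ClassEffect.null(), NONPARETIC_EFFECT, PARETIC_EFFECT])
    def test_onset_recovered_within_5_samples(self, effect):
        for seed in range(30):
            rec = generate_recording("SC", "right", effect, seed=seed)
            bounds = detect_movement_bounds(rec)
            assert abs(bounds.start_index - rec.meta.extras["onset_index"]) <= 5
            assert abs(bounds.end_index - rec.meta.extras["offset_index"]) <= 5

    def test_constant_recording_fails_detection(self):
        rec = Recording({"FNR": np.ones((300, 3))}, 0.01)
        with pytest.raises(DetectionFailureError):
            detect_movement_bounds(rec, reference_marker="FNR")

    def test_recording_without_padding_yields_full_range(self):
        rec = generate_recording("SC", "right", ClassEffect.null(), seed=0)
        tight = clip(
            rec,
            ClipBounds(rec.meta.extras["onset_index"], rec.meta.extras["offset_index"]),
        )
        bounds = detect_movement_bounds(tight)
        assert bounds.start_index <= 5
        assert bounds.end_index >= tight.n_samples - 1 - 5

    def test_redetection_on_clipped_output_is_near_identity(self):
        rec = generate_recording("DG", "right", ClassEffect.null(), seed=3)
        clipped = clip(rec, detect_movement_bounds(rec))
        again = detect_movement_bounds(clipped)
        assert again.start_index <= 5
        assert again.end_index >= clipped.n_samples - 1 - 5


class TestClip:
    def test_full_range_is_identity(self):
        rec = generate_recording("DG", "right", ClassEffect.null(), seed=1)
        out = clip(rec, ClipBounds(0, rec.n_samples - 1))
        for m in rec.markers:
            np.testing.assert_array_equal(out.markers[m], rec.markers[m])

    def test_inclusive_bounds_convention(self):
        rec = Recording({"FNR": np.arange(300.0).reshape(100, 3)}, 0.01)
        assert clip(rec, ClipBounds(10, 20)).n_samples == 11

    def test_out_of_range_bounds_rejected(self):
        rec = Recording({"FNR": np.zeros((50, 3))}, 0.01)
        with pytest.raises(InvalidArgumentError):
            clip(rec, ClipBounds(0, 50))
        with pytest.raises(InvalidArgumentError):
            ClipBounds(20, 10)


class TestUnifySide:
    def test_right_recording_coordinates_unchanged_names_stripped(self):
        rec = generate_recording("SC", "right", ClassEffect.null(), seed=2)
        out = unify_side(rec)
        assert set(out.markers) == {"FN", "LEP", "MPH", "ACR"}
        for m in rec.markers:
            np.testing.assert_array_equal(out.markers[m[:-1]], rec.markers[m])

    def test_mirror_pair_identical_after_unification(self):
        right = generate_recording("SC", "right", PARETIC_EFFECT, seed=9)
        left = generate_recording("SC", "left", PARETIC_EFFECT, seed=9)
        ur, ul = unify_side(right), unify_side(left)
        for m in ur.markers:
            np.testing.assert_array_equal(ur.markers[m], ul.markers[m])

    def test_left_vertical_and_anterior_axes_preserved(self):
        left = generate_recording("DG", "left", ClassEffect.null(), seed=4)
        out = unify_side(left)
        for m in left.markers:
            np.testing.assert_array_equal(out.markers[m[:-1]][:, 1:], left.markers[m][:, 1:])
            np.testing.assert_array_equal(out.markers[m[:-1]][:, 0], -left.markers[m][:, 0])

    def test_double_application_is_identity(self):
        left = generate_recording("LC", "left", ClassEffect.null(), seed=5)
        once = unify_side(left)
        twice = unify_side(once)
        assert set(twice.markers) == set(once.markers)
        for m in once.markers:
            np.testing.assert_array_equal(twice.markers[m], once.markers[m])

    def test_mixed_side_marker_set_rejected(self):
        rec = Recording({"FNL": np.zeros((10, 3)), "LEPR": np.zeros((10, 3))}, 0.01)
        with pytest.raises(InvalidArgumentError):
            unify_side(rec)
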