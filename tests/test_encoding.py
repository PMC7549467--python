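"""Feature chains, normalization and activity-image assembly."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kinimage import (
    ClassEffect,
    Recording,
    assemble_image,
    clip,
    detect_movement_bounds,
    encode_marker,
    generate_recording,
    unify_side,
)
from kinimage.encoding import (
    IMAGE_HEIGHT,
    displacement_series,
    difference_rate,
    load_image,
    minmax_normalize,
    save_image,
)
from kinimage.errors import InvalidArgumentError
from kinimage.synthetic import PARETIC_EFFECT


def preprocessed(activity="SC", side="right", effect=None, seed=0):
    rec = generate_recording(activity, side, effect or ClassEffect.null(), seed=seed)
    return unify_side(clip(rec, detect_movement_bounds(rec)))


class TestDisplacementSeries:
    def test_hand_example(self):
        np.testing.assert_array_equal(
            displacement_series(np.array([0.0, 1.0, 3.0, 2.0])), [1.0, 2.0, 1.0]
        )

    def test_constant_series_gives_zeros(self):
        assert np.all(displacement_series(np.full(10, 3.3)) == 0.0)

    @given(seed=st.integers(0, 2**16), n=st.integers(2, 50))
    def test_matches_elementwise_oracle(self, seed, n):
        p = np.random.default_rng(seed).normal(size=n)
        oracle = np.array([abs(p[i] - p[i - 1]) for i in range(1, n)])
        np.testing.assert_allclose(displacement_series(p), oracle, rtol=1e-15)
        assert np.all(displacement_series(p) >= 0.0)

    def test_time_reversal_reverses_displacement(self):
        p = np.random.default_rng(3).normal(size=40)
        np.testing.assert_allclose(
            displacement_series(p[::-1]), displacement_series(p)[::-1], rtol=1e-15
        )


class TestDifferenceRate:
    def test_hand_example(self):
        np.testing.assert_allclose(
            difference_rate(np.array([1.0, 2.0, 4.0]), 0.5), [2.0, 4.0]
        )

    def test_constant_input_gives_zeros(self):
        assert np.all(difference_rate(np.full(8, 2.0), 0.1) == 0.0)

    def test_chained_three_times_equals_third_difference_oracle(self):
        rng = np.random.default_rng(11)
        t = 0.037
        for _ in range(50):
            d = rng.normal(size=rng.integers(4, 64))
            chained = difference_rate(difference_rate(difference_rate(d, t), t), t)
            oracle = np.diff(d, n=3) / t**3
            np.testing.assert_allclose(chained, oracle, rtol=1e-9)

    def test_non_positive_interval_rejected(self):
        with pytest.raises(InvalidArgumentError):
            difference_rate(np.array([1.0, 2.0]), 0.0)


class TestMinMaxNormalize:
    def test_simple_example(self):
        np.testing.assert_allclose(minmax_normalize(np.array([2.0, 4.0, 6.0])), [0.0, 0.5, 1.0])

    def test_constant_series_maps_to_zeros(self):
        assert np.all(minmax_normalize(np.full(5, 5.0)) == 0.0)

    @given(
        seed=st.integers(0, 2**16),
        a=st.floats(0.1, 100.0),
        b=st.floats(-50.0, 50.0),
    )
    def test_affine_invariance(self, seed, a, b):
        x = np.random.default_rng(seed).normal(size=20)
        np.testing.assert_allclose(
            minmax_normalize(a * x + b), minmax_normalize(x), atol=1e-9
        )


class TestEncodeMarker:
    def test_block_dimensions_are_12_by_32(self):
        block = encode_marker(preprocessed(), "FN")
        assert block.values.shape == (IMAGE_HEIGHT, 32)

    def test_values_normalized_and_rows_attain_bounds(self):
        block = encode_marker(preprocessed(effect=PARETIC_EFFECT, seed=5), "FN")
        assert block.values.min() >= 0.0 and block.values.max() <= 1.0
        for row in block.values:
            if row.max() > row.min():
                assert row.min() == 0.0 and row.max() == 1.0

    def test_stationary_marker_encodes_to_zero_block(self):
        rec = Recording({"FN": np.ones((50, 3)) * 7.0}, 0.01)
        block = encode_marker(rec, "FN")
        assert np.all(block.values == 0.0)

    def test_mirror_pair_blocks_identical(self):
        r = preprocessed(side="right", effect=PARETIC_EFFECT, seed=21)
        l = preprocessed(side="left", effect=PARETIC_EFFECT, seed=21)
        for marker in ("FN", "LEP", "MPH", "ACR"):
            np.testing.assert_array_equal(
                encode_marker(r, marker).values, encode_marker(l, marker).values
            )

    def test_missing_marker_rejected(self):
        with pytest.raises(InvalidArgumentError):
            encode_marker(preprocessed(), "CLAV")

    def test_row_orders(self):
        rec = preprocessed()
        axis_major = encode_marker(rec, "FN", row_order="axis")
        feature_major = encode_marker(rec, "FN", row_order="feature")
        assert axis_major.row_names[:4] == ("d_x", "v_x", "a_x", "j_x")
        assert feature_major.row_names[:3] == ("d_x", "d_y", "d_z")
        np.testing.assert_array_equal(
            axis_major.values[0], feature_major.values[0]  # both start with d_x
        )


class TestAssembleImage:
    def test_single_marker_greyscale_depth(self):
        img = assemble_image(preprocessed(), ["FN"])
        assert img.values.shape == (12, 32, 1)

    def test_four_marker_rgba_depth(self):
        img = assemble_image(preprocessed(), ["FN", "LEP", "MPH", "ACR"])
        assert img.values.shape == (12, 32, 4)
        assert img.channel_order == ["FN", "LEP", "MPH", "ACR"]

    def test_channel_permutation_permutes_values_only(self):
        rec = preprocessed(seed=2)
        a = assemble_image(rec, ["FN", "MPH"])
        b = assemble_image(rec, ["MPH", "FN"])
        np.testing.assert_array_equal(a.values[:, :, 0], b.values[:, :, 1])
        np.testing.assert_array_equal(a.values[:, :, 1], b.values[:, :, 0])

    def test_unknown_and_duplicate_markers_rejected(self):
        rec = preprocessed()
        with pytest.raises(InvalidArgumentError):
            assemble_image(rec, ["FN", "XX"])
        with pytest.raises(InvalidArgumentError):
            assemble_image(rec, ["FN", "FN"])

    def test_pipeline_is_deterministic(self):
        a = assemble_image(preprocessed(seed=17), ["FN", "LEP"])
        b = assemble_image(preprocessed(seed=17), ["FN", "LEP"])
        np.testing.assert_array_equal(a.values, b.values)

    def test_save_load_round_trip(self, tmp_path):
        img = assemble_image(preprocessed(seed=1), ["FN", "ACR"], label="G2")
        save_image(img, str(tmp_path / "img"))
        back = load_image(str(tmp_path / "img"))
        np.testing.assert_array_equal(back.values, img.values)
        assert back.channel_order == img.channel_order
        assert back.label == "G2"
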