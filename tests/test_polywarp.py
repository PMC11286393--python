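"""Warp-engine tests: monomial basis, coordinate mapping, warping, scaling."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyreg import (
    ParameterRanges,
    PolynomialTransform,
    QuadraticTransform,
    WarpConfig,
    denormalize_params,
    design_vector,
    identity_transform,
    invert_coords,
    map_coords,
    normalize_params,
    rescale_transform,
    warp_image,
    warp_mask,
)
from polyreg.polywarp import monomial_exponents, n_terms

from conftest import random_small_transform, warp_oracle


class TestDesignVector:
    @pytest.mark.parametrize("x, y, degree, expected", [
        (2, 3, 2, [4, 9, 6, 2, 3, 1]),
        (0, 0, 2, [0, 0, 0, 0, 0, 1]),
        (5, -1, 1, [5, -1, 1]),
    ])
    def test_known_values(self, x, y, degree, expected):
        assert design_vector(x, y, degree).tolist() == expected

    @pytest.mark.parametrize("degree", [0, 6, -1])
    def test_unsupported_degree_rejected(self, degree):
        with pytest.raises(ValueError, match="degree"):
            design_vector(1, 1, degree)

    @pytest.mark.parametrize("degree", [1, 2, 3, 4, 5])
    def test_basis_size_and_constant_term(self, degree):
        v = design_vector(1.5, -2.5, degree)
        assert v.shape == (n_terms(degree),)
        assert v[-1] == 1.0
        assert len(monomial_exponents(degree)) == n_terms(degree)

    def test_vectorized_matches_scalar(self, rng):
        xs = rng.uniform(-5, 5, size=(3, 4))
        ys = rng.uniform(-5, 5, size=(3, 4))
        batch = design_vector(xs, ys, 2)
        for i in range(3):
            for j in range(4):
                np.testing.assert_allclose(
                    batch[i, j], design_vector(xs[i, j], ys[i, j], 2))


class TestIdentityAndMapping:
    def test_identity_quadratic_structure(self):
        t = identity_transform(2)
        assert isinstance(t, QuadraticTransform)
        expected = np.zeros((2, 6))
        expected[0, 3] = expected[1, 4] = 1.0
        np.testing.assert_array_equal(t.Q, expected)

    def test_identity_degree1_coefficients(self):
        t = identity_transform(1)
        assert t.coeffs_u.tolist() == [1, 0, 0]
        assert t.coeffs_v.tolist() == [0, 1, 0]

    @pytest.mark.parametrize("degree", [1, 2, 3, 4, 5])
    def test_identity_maps_points_to_themselves(self, degree):
        u, v = map_coords(identity_transform(degree), 7.0, 3.0)
        assert (u, v) == (7.0, 3.0)

    def test_translation_term(self):
        Q = QuadraticTransform.identity().Q
        Q[0, 5], Q[1, 5] = 2.0, -1.0
        u, v = map_coords(QuadraticTransform(Q), 0.0, 0.0)
        assert (u, v) == (2.0, -1.0)

    def test_pure_quadratic_term(self):
        Q = np.zeros((2, 6))
        Q[0, 0] = 0.01
        u, v = map_coords(QuadraticTransform(Q), 10.0, 4.0)
        assert u == pytest.approx(1.0)
        assert v == 0.0

    def test_nonfinite_coefficients_rejected(self):
        Q = np.zeros((2, 6))
        Q[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            QuadraticTransform(Q)

    def test_wrong_coefficient_count_rejected(self):
        with pytest.raises(ValueError, match="coefficients"):
            PolynomialTransform(2, [1, 0, 0], [0, 1, 0])


class TestWarpImage:
    def test_identity_reproduces_image_exactly(self, random_image):
        np.testing.assert_array_equal(
            warp_image(random_image, identity_transform(2)), random_image)

    def test_matches_scalar_loop_oracle(self, rng):
        for _ in range(50):
            img = rng.uniform(0, 255, size=(16, 16))
            t = random_small_transform(rng)
            expected = warp_oracle(img, t.Q.tolist())
            np.testing.assert_allclose(warp_image(img, t), expected, atol=1e-6)

    def test_translation_moves_content_backward(self):
        img = np.zeros((4, 4))
        img[1, 1] = 200.0
        Q = QuadraticTransform.identity().Q
        Q[0, 5] = 1.0  # u = x + 1: output column 0 samples source column 1
        out = warp_image(img, QuadraticTransform(Q))
        assert out[1, 0] == 200.0
        assert out[1, 1] == 0.0

    def test_all_zero_image_stays_zero(self, rng):
        out = warp_image(np.zeros((8, 8)), random_small_transform(rng))
        np.testing.assert_array_equal(out, 0.0)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            warp_image(np.zeros((0, 0)), identity_transform(2))

    def test_degree_nesting(self, random_image):
        """A quadratic transform with zero quadratic part equals its affine core."""
        affine = PolynomialTransform(1, [1.03, -0.05, 2.0], [0.04, 0.97, -1.0])
        Q = np.array([[0, 0, 0, 1.03, -0.05, 2.0], [0, 0, 0, 0.04, 0.97, -1.0]])
        np.testing.assert_allclose(
            warp_image(random_image, QuadraticTransform(Q)),
            warp_image(random_image, affine), atol=1e-9)

    def test_fill_fraction_monotone_in_translation(self, random_image):
        fracs = []
        for shift in [0, 2, 5, 9, 14]:
            Q = QuadraticTransform.identity().Q
            Q[0, 5] = shift
            out = warp_image(random_image + 1.0, QuadraticTransform(Q),
                             WarpConfig(fill_value=0.0))
            fracs.append(np.mean(out == 0.0))
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))

    def test_uint8_dtype_preserved(self, rng):
        img = rng.integers(0, 256, size=(12, 12), dtype=np.uint8)
        out = warp_image(img, random_small_transform(rng))
        assert out.dtype == np.uint8

    def test_rgb_image_supported(self, rng):
        img = rng.uniform(0, 255, size=(10, 10, 3))
        out = warp_image(img, identity_transform(2))
        np.testing.assert_array_equal(out, img)


class TestWarpMask:
    @staticmethod
    def _disc(n=32, r=10):
        y, x = np.mgrid[0:n, 0:n]
        return (((x - n // 2) ** 2 + (y - n // 2) ** 2) <= r * r).astype(np.uint8)

    def test_identity_on_full_mask(self):
        mask = np.ones((8, 8), dtype=np.uint8)
        np.testing.assert_array_equal(warp_mask(mask, identity_transform(2)), mask)

    def test_translation_matches_nearest_oracle_and_stays_binary(self):
        mask = self._disc()
        Q = QuadraticTransform.identity().Q
        Q[0, 5] = 5.0
        out = warp_mask(mask, QuadraticTransform(Q))
        np.testing.assert_array_equal(out, warp_oracle(mask, Q.tolist(), "nearest"))
        assert set(np.unique(out)) <= {0, 1}
        # backward convention: content appears shifted left by 5 px
        assert out[16, 16 - 5] == mask[16, 16]
        assert out.sum() > 0

    def test_extreme_transform_empties_mask(self):
        Q = QuadraticTransform.identity().Q
        Q[:, 5] = 10_000.0
        np.testing.assert_array_equal(warp_mask(self._disc(), QuadraticTransform(Q)), 0)

    def test_non_binary_input_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            warp_mask(np.full((4, 4), 3), identity_transform(2))


class TestNormalization:
    def test_endpoints_and_midpoint(self, small_ranges):
        assert normalize_params(small_ranges.mins, small_ranges).tolist() == [0.0] * 12
        assert normalize_params(small_ranges.maxs, small_ranges).tolist() == [1.0] * 12
        mid = (small_ranges.mins + small_ranges.maxs) / 2
        np.testing.assert_allclose(normalize_params(mid, small_ranges), 0.5)

    def test_degenerate_range_rejected(self):
        ranges = ParameterRanges.pinned_identity()
        with pytest.raises(ValueError, match="degenerate"):
            normalize_params(QuadraticTransform.identity(), ranges)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=12, max_size=12))
    def test_round_trip_is_exact_inverse(self, z):
        ranges = ParameterRanges.default(64)
        q = denormalize_params(np.array(z), ranges)
        back = normalize_params(q, ranges)
        np.testing.assert_allclose(back, z, atol=1e-9)


class TestInversionAndRescaling:
    def test_invert_recovers_grid_coordinates(self, rng):
        t = random_small_transform(rng)
        y, x = np.mgrid[2:14, 2:14].astype(float)
        u, v = map_coords(t, x, y)
        xb, yb = invert_coords(t, u, v)
        np.testing.assert_allclose(xb, x, atol=1e-6)
        np.testing.assert_allclose(yb, y, atol=1e-6)

    def test_rescale_commutes_with_coordinate_scaling(self, rng):
        t = random_small_transform(rng)
        sx, sy = 4.0, 2.0
        t2 = rescale_transform(t, sx, sy)
        x, y = 5.0, 7.0
        u, v = map_coords(t, x, y)
        u2, v2 = map_coords(t2, x * sx, y * sy)
        assert u2 == pytest.approx(u * sx, rel=1e-12)
        assert v2 == pytest.approx(v * sy, rel=1e-12)

    def test_rescale_identity_is_identity(self):
        t = rescale_transform(QuadraticTransform.identity(), 4.0)
        np.testing.assert_array_equal(t.Q, QuadraticTransform.identity().Q)


class TestSerialization:
    def test_dict_round_trip_bit_identical(self, rng):
        t = random_small_transform(rng)
        d = json.loads(json.dumps(t.to_dict()))
        t2 = PolynomialTransform.from_dict(d)
        np.testing.assert_array_equal(t.Q, t2.Q)
        assert d["mapping"] == "backward"
        assert d["coordinate_units"] == "pixel"
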