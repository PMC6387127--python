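import numpy as np
import pytest

from fmsccd.contour_io import SampledContour
from fmsccd.descriptors import (
    asd,
    ccd,
    default_asd_scales,
    dft_magnitude,
    dynamic_centroids,
    fasd,
    fccd,
    fmsccd,
    global_centroid,
    msccd,
)

from .conftest import circle_contour, random_simple_contour, sampled_from_points, square_contour


def naive_dft_magnitude(seq):
    """Independent O(N^2) double-loop oracle for the normalized DFT magnitude."""
    n = len(seq)
    out = np.empty(n)
    for k in range(n):
        acc = 0.0 + 0.0j
        for i in range(n):
            acc += seq[i] * np.exp(-2j * np.pi * i * k / n)
        out[k] = abs(acc) / n
    return out


def _similarity(points, angle, scale, shift):
    rot = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
    return (points @ rot.T) * scale + np.asarray(shift)


class TestGlobalCentroid:
    def test_regular_pentagon_center(self):
        theta = 2 * np.pi * np.arange(5) / 5
        pts = np.column_stack([3 + np.cos(theta), -2 + np.sin(theta)])
        c = global_centroid(sampled_from_points(pts, 2))
        np.testing.assert_allclose(c, [3.0, -2.0], atol=1e-12)

    def test_plain_mean(self):
        pts = np.array([[0, 0], [2, 0], [2, 2], [0, 2], [1, 1.0]])
        np.testing.assert_allclose(
            global_centroid(sampled_from_points(pts, 2)), [1.0, 1.0]
        )

    def test_translation_linearity(self, rng):
        contour = random_simple_contour(rng, 4)
        c0 = global_centroid(contour)
        moved = sampled_from_points(contour.points + [5.5, -2.5], 4)
        np.testing.assert_allclose(global_centroid(moved), c0 + [5.5, -2.5], atol=1e-12)


class TestCCD:
    def test_circle_all_ones(self):
        for t0 in (3, 6, 9):
            values = ccd(circle_contour(t0, radius=7.5)).values
            np.testing.assert_allclose(values, 1.0, atol=1e-12)

    def test_mean_is_one(self, rng):
        values = ccd(random_simple_contour(rng, 6)).values
        assert values.mean() == pytest.approx(1.0, abs=1e-9)
        assert np.all(values > 0)

    def test_ellipse_extrema(self):
        n = 2**5 + 1
        theta = 2 * np.pi * np.arange(n) / n
        pts = np.column_stack([2 * np.cos(theta), np.sin(theta)])  # 2:1 ellipse
        values = ccd(sampled_from_points(pts, 5)).values
        assert values.argmax() == 0  # major-axis endpoint sampled at theta=0
        x = pts[values.argmin(), 0]
        assert abs(x) < 0.5  # minima near the minor axis

    def test_five_point_oracle(self):
        pts = np.array([[0, 0], [4, 0], [5, 3], [2, 5], [-1, 3.0]])
        contour = sampled_from_points(pts, 2)
        centroid = pts.mean(axis=0)
        d = np.array([np.hypot(*(p - centroid)) for p in pts])
        expected = d / d.mean()
        np.testing.assert_allclose(ccd(contour).values, expected, atol=1e-12)

    def test_degenerate(self):
        with pytest.raises(ValueError, match="degenerate contour"):
            ccd(sampled_from_points(np.ones((5, 2)), 2))

    def test_similarity_invariance(self, rng):
        contour = random_simple_contour(rng, 6)
        base = ccd(contour).values
        moved = sampled_from_points(
            _similarity(contour.points, 1.1, 0.37, [9.0, -1.0]), 6
        )
        np.testing.assert_allclose(ccd(moved).values, base, atol=1e-9)


class TestDynamicCentroids:
    def test_h0_equals_global(self, rng):
        contour = random_simple_contour(rng, 5)
        dc = dynamic_centroids(contour, 0)
        np.testing.assert_allclose(dc, np.tile(global_centroid(contour), (33, 1)), atol=1e-9)

    def test_circle_centroids_on_radial_ray(self):
        contour = circle_contour(5, radius=2.0)
        for h in range(5):
            dc = dynamic_centroids(contour, h)
            # symmetric window: centroid is a scalar multiple of the point
            cross = contour.points[:, 0] * dc[:, 1] - contour.points[:, 1] * dc[:, 0]
            np.testing.assert_allclose(cross, 0.0, atol=1e-9)

    def test_brute_force_window_oracle(self):
        contour = square_contour(3)
        n, t0, h = 9, 3, 2
        half = 2 ** (t0 - h - 1)
        expected = np.empty((n, 2))
        for i in range(n):
            window = [contour.points[(i + j) % n] for j in range(-half, half + 1)]
            expected[i] = np.mean(window, axis=0)
        np.testing.assert_allclose(dynamic_centroids(contour, h), expected, atol=1e-12)

    def test_invalid_level(self):
        contour = square_contour(3)
        with pytest.raises(ValueError, match="invalid level"):
            dynamic_centroids(contour, 3)
        with pytest.raises(ValueError, match="invalid level"):
            dynamic_centroids(contour, -1)


class TestMSCCD:
    def test_row0_equals_ccd_exactly(self, rng):
        contour = random_simple_contour(rng, 6)
        feature = msccd(contour, 3)
        np.testing.assert_array_equal(feature.levels[0], ccd(contour).values)

    def test_circle_rows_constant(self):
        feature = msccd(circle_contour(6, radius=4.0), 4)
        for row in feature.levels:
            assert row.std() < 1e-9

    def test_invalid_H(self):
        contour = square_contour(3)
        with pytest.raises(ValueError, match="invalid H"):
            msccd(contour, 3)  # t0-1 == 2
        with pytest.raises(ValueError, match="invalid H"):
            msccd(contour, -1)

    def test_shared_global_normalization(self, rng):
        # every level is divided by the same global-centroid distance sum
        contour = random_simple_contour(rng, 5)
        feature = msccd(contour, 2)
        centroid = contour.points.mean(axis=0)
        d_uc = np.linalg.norm(contour.points - centroid, axis=1)
        dc = dynamic_centroids(contour, 2)
        d_h = np.linalg.norm(contour.points - dc, axis=1)
        np.testing.assert_allclose(
            feature.levels[2], d_h * contour.n_points / d_uc.sum(), atol=1e-12
        )

    def test_similarity_invariance(self, rng):
        contour = random_simple_contour(rng, 6)
        base = msccd(contour, 4).levels
        moved = sampled_from_points(
            _similarity(contour.points, -0.4, 3.1, [0.5, 0.5]), 6
        )
        np.testing.assert_allclose(msccd(moved, 4).levels, base, atol=1e-9)

    def test_cyclic_shift_covariance(self, rng):
        contour = random_simple_contour(rng, 5)
        base = msccd(contour, 3).levels
        shifted = sampled_from_points(np.roll(contour.points, 7, axis=0), 5)
        np.testing.assert_allclose(
            msccd(shifted, 3).levels, np.roll(base, 7, axis=1), atol=1e-9
        )


class TestDFTMagnitude:
    def test_constant_sequence_dc_only(self):
        out = dft_magnitude(np.full(17, 3.25))
        assert out[0] == pytest.approx(3.25, abs=1e-12)
        np.testing.assert_allclose(out[1:], 0.0, atol=1e-12)

    def test_cyclic_shift_invariance(self, rng):
        seq = rng.normal(size=33)
        np.testing.assert_allclose(
            dft_magnitude(seq), dft_magnitude(np.roll(seq, 11)), atol=1e-9
        )

    def test_naive_oracle_length17(self, rng):
        seq = rng.normal(size=17)
        np.testing.assert_allclose(dft_magnitude(seq), naive_dft_magnitude(seq), atol=1e-9)

    @pytest.mark.parametrize("n", [5, 9, 17, 33])
    def test_naive_oracle_lengths(self, n, rng):
        seq = rng.normal(size=n)
        np.testing.assert_allclose(dft_magnitude(seq), naive_dft_magnitude(seq), atol=1e-9)


class TestSpectra:
    def test_circle_dc_only(self):
        feature = msccd(circle_contour(6), 3)
        spec = fmsccd(feature, 50)
        np.testing.assert_allclose(spec.coeffs[:, 0], feature.levels.mean(axis=1), atol=1e-9)
        np.testing.assert_allclose(spec.coeffs[:, 1:], 0.0, atol=1e-9)

    def test_k50_gives_51_coeffs(self, rng):
        contour = random_simple_contour(rng, 9)
        spec = fmsccd(msccd(contour, 6), 50)
        assert spec.coeffs.shape == (7, 51)

    def test_fccd_equals_fmsccd_h0(self, rng):
        contour = random_simple_contour(rng, 6)
        a = fccd(ccd(contour), 20).coeffs
        b = fmsccd(msccd(contour, 0), 20).coeffs
        np.testing.assert_array_equal(a, b)

    def test_invalid_K(self, rng):
        contour = random_simple_contour(rng, 4)
        with pytest.raises(ValueError, match="invalid K"):
            fccd(ccd(contour), 17)
        with pytest.raises(ValueError, match="invalid K"):
            fccd(ccd(contour), -1)

    def test_start_shift_leaves_spectrum(self, rng):
        contour = random_simple_contour(rng, 6)
        shifted = sampled_from_points(np.roll(contour.points, 13, axis=0), 6)
        np.testing.assert_allclose(
            fmsccd(msccd(contour, 4), 50).coeffs,
            fmsccd(msccd(shifted, 4), 50).coeffs,
            atol=1e-9,
        )


class TestASD:
    def test_circle_constant_rows(self):
        contour = circle_contour(6)
        feature = asd(contour, [1, 4, 16])
        for row in feature.angles:
            assert row.std() < 1e-9

    def test_square_corner_quarter(self):
        contour = square_contour(4)  # starts exactly at a corner
        feature = asd(contour, [1])
        assert feature.angles[0, 0] == pytest.approx(0.25, abs=1e-9)

    def test_decagon_atan2_oracle(self, rng):
        n = 2**3 + 1
        theta = 2 * np.pi * np.arange(n) / n
        r = 1 + rng.uniform(-0.2, 0.2, size=n)
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        contour = sampled_from_points(pts, 3)
        s = 2
        feature = asd(contour, [s])
        for i in range(n):
            fore = pts[(i + s) % n] - pts[i]
            aft = pts[(i - s) % n] - pts[i]
            ang = np.arctan2(
                fore[0] * aft[1] - fore[1] * aft[0], fore @ aft
            ) % (2 * np.pi)
            assert feature.angles[0, i] == pytest.approx(ang / (2 * np.pi), abs=1e-12)

    def test_values_in_unit_interval(self, rng):
        feature = asd(random_simple_contour(rng, 6), default_asd_scales(6, 4))
        assert np.all(feature.angles >= 0.0)
        assert np.all(feature.angles < 1.0)

    def test_invalid_scale(self):
        contour = square_contour(3)
        with pytest.raises(ValueError, match="invalid ASD scale"):
            asd(contour, [0])
        with pytest.raises(ValueError, match="invalid ASD scale"):
            asd(contour, [5])  # (9-1)/2 == 4 is the max

    def test_default_scales(self):
        assert default_asd_scales(9, 6) == (128, 64, 32, 16, 8, 4)

    def test_similarity_invariance(self, rng):
        contour = random_simple_contour(rng, 6)
        base = asd(contour, [2, 8]).angles
        moved = sampled_from_points(
            _similarity(contour.points, 2.2, 5.0, [-3.0, 2.0]), 6
        )
        np.testing.assert_allclose(asd(moved, [2, 8]).angles, base, atol=1e-9)

    def test_fasd_shapes_and_shift_invariance(self, rng):
        contour = random_simple_contour(rng, 6)
        feature = asd(contour, [2, 8])
        spec = fasd(feature, 30)
        assert spec.coeffs.shape == (2, 31)
        shifted = sampled_from_points(np.roll(contour.points, 5, axis=0), 6)
        np.testing.assert_allclose(
            fasd(asd(shifted, [2, 8]), 30).coeffs, spec.coeffs, atol=1e-9
        )
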