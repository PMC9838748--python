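import numpy as np
import pytest

from dyespec import (
    DiffHistogram,
    analyze_dye_photo,
    generate_texture_image,
    glcm_contrast,
    glcm_homogeneity,
    glcm_horizontal,
    normalize_minmax,
    pearson,
    rgb_to_gray,
)
from dyespec.texture_metrics import CoocMatrix, TextureError

from conftest import glcm_metrics_bruteforce


class TestRgbToGray:
    @pytest.mark.parametrize(
        "pixel,expected",
        [((255, 255, 255), 255), ((0, 0, 0), 0), ((1, 1, 2), 1), ((10, 20, 31), 20)],
    )
    def test_integer_channel_average(self, pixel, expected):
        rgb = np.array([[pixel]], dtype=np.uint8)
        assert rgb_to_gray(rgb)[0, 0] == expected

    def test_no_uint8_overflow_on_bright_pixels(self):
        rgb = np.full((4, 4, 3), 255, dtype=np.uint8)
        assert np.all(rgb_to_gray(rgb) == 255)

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(TextureError, match="RGB"):
            rgb_to_gray(np.zeros((4, 4, 4), dtype=np.uint8))

    def test_wrong_depth_rejected(self):
        with pytest.raises(TextureError, match="8-bit"):
            rgb_to_gray(np.zeros((4, 4, 3), dtype=np.uint16))


class TestNormalizeMinmax:
    def test_midpoint_rounds_half_away_from_zero(self):
        g = np.array([[10, 15, 20]], dtype=np.uint8)
        out = normalize_minmax(g)
        assert list(out[0]) == [0, 128, 255]  # round(5 * 25.5) = 128

    def test_full_range_image_is_fixed_point(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
        g[0, 0], g[0, 1] = 0, 255
        np.testing.assert_array_equal(normalize_minmax(g), g)

    def test_constant_image_rejected(self):
        with pytest.raises(TextureError, match="constant"):
            normalize_minmax(np.full((4, 4), 7, dtype=np.uint8))

    def test_masked_region_sets_the_stretch(self):
        g = np.array([[0, 100, 200]], dtype=np.uint8)
        mask = np.array([[False, True, True]])
        out = normalize_minmax(g, mask=mask)
        assert out[0, 1] == 0 and out[0, 2] == 255


class TestGlcmHorizontal:
    def test_single_pair(self):
        P = glcm_horizontal(np.array([[5, 7]], dtype=np.uint8))
        assert P.p[5, 7] == 1.0 and P.p.sum() == 1.0 and P.total_pairs == 1

    def test_constant_row_is_diagonal(self):
        P = glcm_horizontal(np.full((1, 9), 3, dtype=np.uint8))
        assert P.p[3, 3] == 1.0

    def test_hand_enumerated_two_by_three(self):
        g = np.array([[0, 1, 1], [0, 0, 1]], dtype=np.uint8)
        P = glcm_horizontal(g)
        assert P.total_pairs == 4
        assert P.p[0, 0] == 0.25 and P.p[0, 1] == 0.5 and P.p[1, 1] == 0.25
        assert glcm_contrast(P) == pytest.approx(0.5)
        assert glcm_homogeneity(P) == pytest.approx(0.75)

    def test_asymmetry_preserved(self):
        P = glcm_horizontal(np.array([[2, 9]], dtype=np.uint8))
        assert P.p[2, 9] == 1.0 and P.p[9, 2] == 0.0

    def test_single_column_rejected(self):
        with pytest.raises(TextureError, match="two columns"):
            glcm_horizontal(np.zeros((4, 1), dtype=np.uint8))

    def test_masked_pairs_skip_gaps(self):
        g = np.array([[0, 50, 100, 150]], dtype=np.uint8)
        mask = np.array([[True, True, False, True]])
        P = glcm_horizontal(g, mask=mask)
        # only (0, 50) survives: pairs spanning the masked pixel are dropped
        assert P.total_pairs == 1 and P.p[0, 50] == 1.0


class TestMetricsBounds:
    def test_diagonal_only_matrix(self):
        p = np.zeros((256, 256))
        p[10, 10] = 0.4
        p[200, 200] = 0.6
        P = CoocMatrix(p=p, total_pairs=10)
        assert glcm_contrast(P) == 0.0
        assert glcm_homogeneity(P) == 1.0

    def test_homogeneity_one_iff_contrast_zero(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            g = rng.integers(0, 256, size=(8, 8)).astype(np.uint8)
            P = glcm_horizontal(g)
            c, h = glcm_contrast(P), glcm_homogeneity(P)
            assert 0.0 <= c <= 255.0**2
            assert 0.0 < h <= 1.0
            assert (c == 0.0) == (h == 1.0)

    def test_monotone_degradation_under_growing_jitter(self):
        """More neighbor jitter: homogeneity falls, contrast rises (in mean)."""
        rng = np.random.default_rng(42)
        mean_c, mean_h = [], []
        for amp in (1, 3, 6, 10):
            cs, hs = [], []
            for _ in range(200):
                g = 128 + rng.integers(-amp, amp + 1, size=(12, 24))
                P = glcm_horizontal(g.astype(np.uint8))
                cs.append(glcm_contrast(P))
                hs.append(glcm_homogeneity(P))
            mean_c.append(np.mean(cs))
            mean_h.append(np.mean(hs))
        assert all(a < b for a, b in zip(mean_c, mean_c[1:]))
        assert all(a > b for a, b in zip(mean_h, mean_h[1:]))


class TestOracleEquivalence:
    def test_agrees_with_bruteforce_on_random_images(self):
        """Dual route: vectorized GLCM vs exhaustive pair enumeration."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            rows = int(rng.integers(2, 65))
            cols = int(rng.integers(2, 65))
            g = rng.integers(0, 256, size=(rows, cols)).astype(np.uint8)
            P = glcm_horizontal(g)
            c_ref, h_ref, n_ref = glcm_metrics_bruteforce(g)
            assert P.total_pairs == n_ref == rows * (cols - 1)
            assert glcm_contrast(P) == pytest.approx(c_ref, rel=1e-12)
            assert glcm_homogeneity(P) == pytest.approx(h_ref, abs=1e-12)

    def test_matrix_matches_skimage(self):
        """Independent library cross-check of the co-occurrence counts."""
        from skimage.feature import graycomatrix, graycoprops

        rng = np.random.default_rng(11)
        g = rng.integers(0, 256, size=(32, 48)).astype(np.uint8)
        P = glcm_horizontal(g)
        ref = graycomatrix(g, [1], [0], levels=256, symmetric=False, normed=True)
        np.testing.assert_allclose(P.p, ref[:, :, 0, 0], atol=1e-15)
        assert glcm_contrast(P) == pytest.approx(
            float(graycoprops(ref, "contrast")[0, 0]), rel=1e-12
        )

    def test_masked_roi_agrees_with_bruteforce(self):
        rng = np.random.default_rng(5)
        g = rng.integers(0, 256, size=(20, 30)).astype(np.uint8)
        mask = rng.random((20, 30)) < 0.7
        P = glcm_horizontal(g, mask=mask)
        c_ref, h_ref, n_ref = glcm_metrics_bruteforce(g, mask)
        assert P.total_pairs == n_ref
        assert glcm_contrast(P) == pytest.approx(c_ref, abs=1e-12)
        assert glcm_homogeneity(P) == pytest.approx(h_ref, abs=1e-12)


class TestPrintedValueFixtures:
    def test_dark_pink_fixture_metrics(self):
        hist = DiffHistogram({2: 38275, 3: 16533, 0: 45192}, 100000)
        img = generate_texture_image(hist, 100, 1001)
        tex = analyze_dye_photo(img)
        assert tex.contrast == pytest.approx((38275 * 4 + 16533 * 9) / 100000)
        assert tex.homogeneity == pytest.approx(
            45192 / 100000 + 38275 / 300000 + 16533 / 400000
        )
        assert round(tex.contrast, 3) == 3.019
        assert round(tex.homogeneity, 4) == 0.6208

    def test_white_fixture_metrics(self):
        hist = DiffHistogram({1: 9300, 2: 525, 0: 1990175}, 2000000)
        img = generate_texture_image(hist, 2000, 1001)
        tex = analyze_dye_photo(img)
        assert round(tex.homogeneity, 4) == 0.9975
        assert round(tex.contrast, 4) == 0.0057


class TestPearson:
    def test_perfect_anticorrelation(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert pearson(x, -2 * x + 5) == pytest.approx(-1.0)

    def test_identity_correlation(self):
        x = np.array([0.3, 1.2, 7.7])
        assert pearson(x, x) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # direct covariance arithmetic: cov = 3/2, sd_x = 1, sd_y = sqrt(7/3)
        x, y = [1.0, 2.0, 3.0], [1.0, 2.0, 4.0]
        expected = (3 / 2) / (1.0 * np.sqrt(7 / 3))
        assert pearson(x, y) == pytest.approx(expected)
        assert round(pearson(x, y), 3) == 0.982

    def test_constant_input_rejected(self):
        with pytest.raises(TextureError, match="constant"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_short_input_rejected(self):
        with pytest.raises(TextureError, match="3 points"):
            pearson([1.0, 2.0], [3.0, 4.0])


class TestAnalyzeDyePhoto:
    def test_rgb_input_goes_through_gray_conversion(self):
        rng = np.random.default_rng(2)
        rgb = rng.integers(0, 256, size=(16, 20, 3)).astype(np.uint8)
        gray = rgb_to_gray(rgb)
        a = analyze_dye_photo(rgb)
        b = analyze_dye_photo(gray)
        assert a == b

    def test_constant_roi_surfaces_normalization_error(self):
        g = np.full((8, 8), 100, dtype=np.uint8)
        with pytest.raises(TextureError, match="constant"):
            analyze_dye_photo(g)

    def test_empty_roi_rejected(self):
        g = np.zeros((8, 8), dtype=np.uint8)
        with pytest.raises(TextureError, match="no pixels"):
            analyze_dye_photo(g, roi_mask=np.zeros((8, 8), bool))
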