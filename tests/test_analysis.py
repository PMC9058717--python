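"""Per-set PCA, 8-bit rescaling, pseudo-colouring, ROI statistics and the
reflectance-analyte regression."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.decomposition import PCA as SkPCA

import ledmsi as L

from conftest import brute_roi_mean, get_band


def _stack(arrays, names=None):
    names = names or [str(i) for i in range(len(arrays))]
    return L.SpectralStack([
        L.BandImage(np.asarray(a, dtype=np.uint8), n)
        for a, n in zip(arrays, names)])


def _random_stack(rng, n_bands, h, w):
    return _stack([rng.integers(0, 256, (h, w)) for _ in range(n_bands)])


class TestPCA:
    def test_rank_one_stack_explained_by_first_component(self):
        rng = np.random.default_rng(1)
        b1 = rng.integers(10, 60, (16, 16))
        stack = _stack([b1, 3 * b1 + 7])
        result = L.pca_per_set(stack)
        assert result.explained_variance_ratio[0] == pytest.approx(1.0)
        assert result.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(2, 6))
    def test_matches_svd_oracle_on_random_stacks(self, seed, n_bands):
        """Eigenvalues, loadings and scores agree with an independent
        SVD-based PCA (sklearn) to 1e-8 relative."""
        rng = np.random.default_rng(seed)
        stack = _random_stack(rng, n_bands, 16, 16)
        result = L.pca_per_set(stack)
        x = stack.as_array().reshape(-1, n_bands)
        oracle = SkPCA(n_components=n_bands).fit(x)
        scale = result.eigenvalues[0]
        np.testing.assert_allclose(result.eigenvalues,
                                   oracle.explained_variance_,
                                   rtol=1e-8, atol=1e-8 * scale)
        np.testing.assert_allclose(result.explained_variance_ratio,
                                   oracle.explained_variance_ratio_, atol=1e-8)
        oracle_scores = oracle.transform(x)
        for k in range(n_bands):
            load = oracle.components_[k]
            sign = np.sign(load[np.argmax(np.abs(load))]) or 1.0
            np.testing.assert_allclose(result.loadings[:, k], sign * load,
                                       atol=1e-8)
            np.testing.assert_allclose(result.pc_images[k].ravel(),
                                       sign * oracle_scores[:, k],
                                       atol=1e-6 * max(scale, 1.0))

    def test_reconstruction_from_all_components(self):
        rng = np.random.default_rng(7)
        stack = _random_stack(rng, 4, 12, 12)
        result = L.pca_per_set(stack)
        x = stack.as_array().reshape(-1, 4)
        scores = result.pc_images.reshape(4, -1).T
        np.testing.assert_allclose(scores @ result.loadings.T,
                                   x - result.band_means, atol=1e-8)

    def test_translation_invariance_of_scores(self):
        rng = np.random.default_rng(3)
        arrays = [rng.integers(0, 200, (10, 10)) for _ in range(3)]
        shifted = [arrays[0] + 50] + arrays[1:]
        a = L.pca_per_set(_stack(arrays))
        b = L.pca_per_set(_stack(shifted))
        np.testing.assert_allclose(a.pc_images, b.pc_images, atol=1e-9)
        assert b.band_means[0] - a.band_means[0] == pytest.approx(50.0)

    def test_constant_stack_rejected(self):
        stack = _stack([np.full((8, 8), 40), np.full((8, 8), 90)])
        with pytest.raises(L.DegenerateStackError):
            L.pca_per_set(stack)

    def test_colonies_visible_in_pca1_but_not_in_rgb_at_six_hours(self):
        """Young colonies alter only NIR bands: separable by PCA on the
        band stack while invisible in the white-light reference."""
        scene = L.make_fixture("colonies", size_px=(160, 160), t=6.0, seed=11)
        # Flat field so background score variance is noise, not gradient.
        device = L.SimulatedDevice(scene, diffuse_fraction=1.0)
        bands = [get_band(n) for n in ("660", "880", "950")]
        stack = L.capture_set(device, L.CapturePlan(bands=bands), 0, seed=2)
        result = L.pca_per_set(stack)
        pca1 = result.pc_images[0]

        colony_mask = sum(c.mask for c in scene.components[1:]) > 0.5
        assert colony_mask.sum() > 20
        agar_mask = ~colony_mask
        agar_mask[scene.components[0].mask > 0] = False  # exclude divider

        pca_contrast = abs(pca1[colony_mask].mean() - pca1[agar_mask].mean())
        sem = pca1[agar_mask].std() / np.sqrt(colony_mask.sum())
        assert pca_contrast > 2.0 * pca1[agar_mask].std()  # above texture
        assert pca_contrast > 20.0 * sem                   # and significant

        rgb = L.capture_band(device, L.WHT, seed=3)
        gray = L.to_grayscale(rgb.pixels).astype(float)
        rgb_contrast = abs(gray[colony_mask].mean() - gray[agar_mask].mean())
        assert rgb_contrast < 1.0  # below one gray level: invisible
        assert pca_contrast > 20.0 * rgb_contrast


class TestRescaleTo8Bit:
    def test_linear_map_of_symmetric_scores(self):
        img = L.rescale_to_8bit(np.array([[-1.0, 0.0, 1.0]]))
        assert img.pixels.tolist() == [[0, 128, 255]]  # 127.5 rounds to even

    def test_constant_image_maps_to_zero(self):
        img = L.rescale_to_8bit(np.full((4, 4), 3.7))
        assert np.all(img.pixels == 0)

    def test_identity_on_full_range_ramp(self):
        ramp = np.arange(256, dtype=float).reshape(16, 16)
        assert np.array_equal(L.rescale_to_8bit(ramp).pixels,
                              ramp.astype(np.uint8))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            L.rescale_to_8bit(np.array([[np.nan, 1.0]]))


class TestPseudoColor:
    @pytest.mark.parametrize("v,expected_bin", [(0, 0), (128, 3), (255, 5)])
    def test_six_shade_binning(self, v, expected_bin):
        img = np.full((2, 2), v, dtype=np.uint8)
        assert np.all(L.pseudo_color(img, 6).indices == expected_bin)

    def test_uniform_image_uses_single_bin(self):
        pc = L.pseudo_color(np.full((8, 8), 77, dtype=np.uint8), 6)
        assert len(np.unique(pc.indices)) == 1

    def test_palette_has_distinct_colors_and_rgb_shape(self):
        pc = L.pseudo_color(np.arange(256, dtype=np.uint8).reshape(16, 16), 6)
        assert len(set(pc.palette)) == 6
        assert pc.to_rgb().shape == (16, 16, 3)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 255), st.integers(0, 255), st.integers(2, 12))
    def test_binning_is_monotone(self, v1, v2, n_shades):
        lo, hi = sorted((v1, v2))
        img = np.array([[lo, hi]], dtype=np.uint8)
        bins = L.pseudo_color(img, n_shades).indices
        assert bins[0, 0] <= bins[0, 1]

    def test_invalid_shade_count_rejected(self):
        with pytest.raises(ValueError):
            L.pseudo_color(np.zeros((2, 2), dtype=np.uint8), 1)


class TestRoiMean:
    def test_uniform_image(self):
        img = np.full((20, 20), 37, dtype=np.uint8)
        assert L.roi_mean(img, (9.5, 9.5), 5.0) == 37.0

    def test_half_off_image_matches_enumeration(self):
        rng = np.random.default_rng(5)
        img = rng.integers(0, 256, (24, 24)).astype(np.uint8)
        got = L.roi_mean(img, (0.0, 12.0), 6.0)
        assert got == pytest.approx(brute_roi_mean(img, (0.0, 12.0), 6.0))

    def test_tiny_radius_selects_single_pixel(self):
        img = np.arange(64, dtype=np.uint8).reshape(8, 8)
        assert L.roi_mean(img, (3.0, 2.0), 0.4) == float(img[2, 3])

    def test_empty_roi_rejected(self):
        img = np.zeros((8, 8), dtype=np.uint8)
        with pytest.raises(ValueError):
            L.roi_mean(img, (3.5, 3.5), 0.4)  # between pixel centres


class TestAnalyteFit:
    def test_perfect_negative_line(self):
        x = np.arange(10.0)
        fit = L.fit_reflectance_analyte(x, -2.0 * x + 5.0)
        assert fit.slope == pytest.approx(-2.0)
        assert fit.pearson_r == pytest.approx(-1.0)

    def test_three_point_hand_ols(self):
        fit = L.fit_reflectance_analyte([0.0, 1.0, 2.0], [0.0, 2.0, 4.0])
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0)
        assert fit.pearson_r == pytest.approx(1.0)
        assert fit.n == 3

    def test_synthetic_nitrogen_negative_association(self):
        nitrogen, mgv, labels = L.simulate_nitrogen_mgv(seed=123)
        assert len(nitrogen) == 120 and len(set(labels)) == 4
        fit = L.fit_reflectance_analyte(mgv, nitrogen)
        assert fit.slope < 0 and fit.pearson_r < 0

    def test_known_slope_recovered_within_three_stderr(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(50, 220, 120)
        true_slope = -0.02
        y = 6.0 + true_slope * x + rng.normal(0, 0.3, x.size)
        fit = L.fit_reflectance_analyte(x, y)
        assert abs(fit.slope - true_slope) < 3.0 * fit.stderr

    @pytest.mark.parametrize("x,y", [
        ([1.0, 2.0], [1.0, 2.0]),              # too few
        ([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]),    # zero x variance
    ])
    def test_invalid_inputs_rejected(self, x, y):
        with pytest.raises(ValueError):
            L.fit_reflectance_analyte(x, y)
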