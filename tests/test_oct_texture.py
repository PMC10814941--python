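"""OCT texture chain against exhaustive pair-counting and filter oracles."""

import numpy as np
import pytest
from scipy import ndimage

from dermafuse import octtexture as oct


def scan(pixels, axial=5.34, lateral=7.32):
    return oct.BScan(np.asarray(pixels), axial, lateral)


def full_roi(img):
    a = np.asarray(img)
    return oct.TextureROI(0, 0, a.shape[0], a.shape[1])


ALL_CONFIGS = [(a, d) for a in (0, 45, 90, 135) for d in (1, 5, 9)]


def brute_force_glcm(window, angle_deg, distance_px, levels=256, symmetric=True):
    """Double-loop pair enumeration; zero pixels excluded from pairs."""
    offs = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}[angle_deg]
    dr, dc = offs[0] * distance_px, offs[1] * distance_px
    counts = np.zeros((levels, levels))
    h, w = window.shape
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                i, j = int(window[r, c]), int(window[r2, c2])
                if i > 0 and j > 0:
                    counts[i, j] += 1
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    return counts / total if total else counts


class TestBackgroundThreshold:
    def test_constant_region(self):
        s = scan(np.full((10, 10), 5, dtype=np.uint8))
        assert oct.estimate_background_threshold(s, full_roi(s.pixels)) == 5.0

    def test_two_values(self):
        s = scan(np.array([[3, 7], [3, 7]], dtype=np.uint8))
        # mean 5, population std 2
        assert oct.estimate_background_threshold(s, full_roi(s.pixels)) == 7.0

    def test_matches_brute_force(self, rng):
        vals = rng.integers(0, 40, size=(25, 40)).astype(np.uint8)
        s = scan(vals)
        got = oct.estimate_background_threshold(s, full_roi(vals))
        v = vals.astype(float).ravel()
        expected = v.mean() + np.sqrt(((v - v.mean()) ** 2).mean())
        assert got == pytest.approx(expected, abs=1e-9)


class TestThresholdFilter:
    def test_le_semantics(self):
        s = scan(np.array([[10, 20, 30]] * 2, dtype=np.uint8))
        out = oct.threshold_filter(s, 20.0)
        assert out.pixels[0].tolist() == [0, 0, 30]

    def test_threshold_255_zeroes_everything(self, rng):
        s = scan(rng.integers(0, 256, (8, 8)).astype(np.uint8))
        assert not oct.threshold_filter(s, 255.0).pixels.any()

    def test_threshold_zero_only_hits_zeros(self, rng):
        img = rng.integers(1, 256, (8, 8)).astype(np.uint8)
        s = scan(img)
        assert np.array_equal(oct.threshold_filter(s, 0.0).pixels, img)


class TestDenoise:
    def test_constant_image_unchanged(self):
        s = scan(np.full((12, 12), 77, dtype=np.uint8))
        assert np.array_equal(oct.denoise(s).pixels, s.pixels)

    def test_isolated_bright_pixel_erased(self):
        img = np.zeros((9, 9), dtype=np.uint8)
        img[4, 4] = 200
        assert not oct.denoise(scan(img)).pixels.any()

    def test_matches_composed_filter_oracle(self, rng):
        img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        # independent min-filter: explicit reflect padding + window minimum
        padded = np.pad(img, 1, mode="reflect")
        eroded = np.empty_like(img)
        for r in range(16):
            for c in range(16):
                eroded[r, c] = padded[r : r + 3, c : c + 3].min()
        smooth = ndimage.gaussian_filter(eroded.astype(float), 1.5, truncate=4.0)
        expected = np.clip(np.rint(smooth), 0, 255).astype(np.uint8)
        assert np.array_equal(oct.denoise(scan(img)).pixels, expected)


class TestFirstOrderStats:
    def test_small_set_population_moments(self):
        img = np.array([[1, 2], [3, 4]], dtype=np.uint8)
        mean, std, skew, kurt = oct.first_order_stats(scan(img), full_roi(img))
        assert mean == pytest.approx(2.5)
        assert std == pytest.approx(np.sqrt(1.25))  # ~1.1180
        assert skew == pytest.approx(0.0, abs=1e-12)  # symmetric set
        assert kurt == pytest.approx(1.64)

    def test_zero_pixels_excluded(self):
        img = np.array([[0, 0, 1], [2, 3, 4]], dtype=np.uint8)
        mean, *_ = oct.first_order_stats(scan(img), full_roi(img))
        assert mean == pytest.approx(2.5)

    def test_zero_variance_flags_zero(self):
        img = np.full((4, 4), 9, dtype=np.uint8)
        with pytest.warns(UserWarning):
            _, std, skew, kurt = oct.first_order_stats(scan(img), full_roi(img))
        assert (std, skew, kurt) == (0.0, 0.0, 0.0)

    def test_degenerate_roi_raises(self):
        img = np.zeros((4, 4), dtype=np.uint8)
        img[0, 0] = 5
        with pytest.raises(oct.DegenerateRoiError):
            oct.first_order_stats(scan(img), full_roi(img))


class TestShannonEntropy:
    def test_constant_roi_zero_bits(self):
        img = np.full((5, 5), 13, dtype=np.uint8)
        assert oct.shannon_entropy(scan(img), full_roi(img)) == 0.0

    def test_two_equal_levels_one_bit(self):
        img = np.array([[10, 20]] * 4, dtype=np.uint8)
        assert oct.shannon_entropy(scan(img), full_roi(img)) == pytest.approx(1.0)

    def test_direct_summation(self):
        # frequencies 1/2, 1/4, 1/8, 1/8 -> 1.75 bits
        vals = [1] * 4 + [2] * 2 + [3] + [4]
        img = np.asarray(vals, dtype=np.uint8).reshape(2, 4)
        assert oct.shannon_entropy(scan(img), full_roi(img)) == pytest.approx(1.75)


class TestGlcm:
    def test_constant_roi_single_diagonal_entry(self):
        img = np.full((12, 12), 9, dtype=np.uint8)
        for a, d in ALL_CONFIGS:
            m = oct.compute_glcm(scan(img), full_roi(img), a, d)
            assert m.p[9, 9] == pytest.approx(1.0)
            assert m.p.sum() == pytest.approx(1.0)

    def test_two_row_image_horizontal_pairs(self):
        img = np.array([[1, 1], [2, 2]], dtype=np.uint8)
        m = oct.compute_glcm(scan(img), full_roi(img), 0, 1)
        assert m.p[1, 1] == pytest.approx(0.5)
        assert m.p[2, 2] == pytest.approx(0.5)

    def test_matches_brute_force_on_random_rois(self, rng):
        # exhaustive pair-enumeration oracle across all 12 configurations
        for trial in range(55):
            h, w = int(rng.integers(12, 17)), int(rng.integers(12, 17))
            img = rng.integers(0, 32, (h, w)).astype(np.uint8)
            s = scan(img)
            for a, d in ALL_CONFIGS:
                got = oct.compute_glcm(s, full_roi(img), a, d)
                expected = brute_force_glcm(img, a, d)
                assert np.allclose(got.p, expected, atol=1e-12), (trial, a, d)

    def test_normalization_and_symmetry(self, rng):
        img = rng.integers(0, 256, (14, 14)).astype(np.uint8)
        for a, d in ALL_CONFIGS:
            m = oct.compute_glcm(scan(img), full_roi(img), a, d)
            assert m.p.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.allclose(m.p, m.p.T)

    def test_zero_exclusion_in_pairs(self):
        img = np.array([[5, 0, 5]], dtype=np.uint8)
        m = oct.compute_glcm(scan(np.vstack([img, img])), oct.TextureROI(0, 0, 2, 3), 0, 2)
        # only the (5, 5) pair at distance 2 survives; pairs through 0 don't exist
        assert m.p[5, 5] == pytest.approx(1.0)


class TestHaralick:
    @staticmethod
    def glcm_from(p):
        return oct.CoocMatrix(np.asarray(p, dtype=float), 0, 1)

    def test_degenerate_single_entry(self):
        p = np.zeros((4, 4))
        p[2, 2] = 1.0
        e, c, corr, ent, h = oct.haralick_features(self.glcm_from(p))
        assert (e, c, corr, ent, h) == (1.0, 0.0, 1.0, 0.0, 1.0)

    def test_two_diagonal_entries(self):
        p = np.zeros((2, 2))
        p[0, 0] = p[1, 1] = 0.5
        e, c, corr, ent, h = oct.haralick_features(self.glcm_from(p))
        assert e == pytest.approx(0.5)
        assert c == pytest.approx(0.0)
        assert corr == pytest.approx(1.0)  # cov = var = 0.25
        assert ent == pytest.approx(1.0)
        assert h == pytest.approx(1.0)

    def test_anti_diagonal_entries(self):
        p = np.zeros((2, 2))
        p[0, 1] = p[1, 0] = 0.5
        _, c, corr, _, _ = oct.haralick_features(self.glcm_from(p))
        assert c == pytest.approx(1.0)
        assert corr == pytest.approx(-1.0)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            oct.haralick_features(self.glcm_from(np.ones((3, 3))))


class TestFeatureVector:
    def test_names_are_65_and_unique(self):
        names = oct.oct_feature_names()
        assert len(names) == 65
        assert len(set(names)) == 65
        # 12 GLCM configurations x 5 Haralick features
        glcm_names = [n for n in names if n.startswith(tuple(oct.HARALICK_NAMES))]
        assert len(glcm_names) == 60

    def test_extract_wires_stages_in_order(self, rng):
        img = np.vstack([
            rng.integers(60, 200, (110, 64)),
            rng.integers(0, 12, (30, 64)),
        ]).astype(np.uint8)
        s = scan(img)
        roi = oct.TextureROI(0, 0, 104, 60)
        bg = oct.TextureROI(112, 0, 26, 64)
        out = oct.extract_oct_features(s, roi, bg)
        assert len(out) == 65
        # stage-wise recomputation with the documented order
        assert out["shannon_entropy"] == pytest.approx(oct.shannon_entropy(s, roi))
        thr = oct.estimate_background_threshold(s, bg)
        proc = oct.denoise(oct.threshold_filter(s, thr))
        mean, std, skew, kurt = oct.first_order_stats(proc, roi)
        assert out["fos_mean"] == pytest.approx(mean)
        assert out["fos_kurtosis"] == pytest.approx(kurt)
        g = oct.compute_glcm(proc, roi, 45, 5)
        e, c, corr, ent, h = oct.haralick_features(g)
        assert out["contrast_a45_d5"] == pytest.approx(c)
        assert out["homogeneity_a45_d5"] == pytest.approx(h)

    def test_constant_roi_energy_one_contrast_zero(self):
        img = np.vstack([
            np.full((110, 64), 150, dtype=np.uint8),
            np.zeros((30, 64), dtype=np.uint8),
        ])
        s = scan(img)
        out = oct.extract_oct_features(
            s, oct.TextureROI(0, 0, 104, 60), oct.TextureROI(112, 0, 26, 64)
        )
        for a in (0, 45, 90, 135):
            for d in (1, 5, 9):
                assert out[f"energy_a{a}_d{d}"] == pytest.approx(1.0)
                assert out[f"contrast_a{a}_d{d}"] == pytest.approx(0.0)

    def test_roi_minimum_physical_size_enforced(self):
        img = np.full((150, 64), 100, dtype=np.uint8)
        s = scan(img)
        small = oct.TextureROI(0, 0, 50, 60)  # 267 um deep: too shallow
        with pytest.raises(ValueError):
            oct.extract_oct_features(s, small, oct.TextureROI(120, 0, 20, 60))

    def test_gray_level_shift_invariance(self, rng):
        base = rng.integers(20, 100, (40, 40)).astype(np.uint8)
        shift = 50
        roi = oct.TextureROI(0, 0, 40, 40)
        s1, s2 = scan(base), scan(base + shift)
        m1, m2 = (oct.first_order_stats(s, roi) for s in (s1, s2))
        assert m2[0] - m1[0] == pytest.approx(shift)
        for a, d in ((0, 1), (90, 5)):
            g1 = oct.compute_glcm(s1, roi, a, d)
            g2 = oct.compute_glcm(s2, roi, a, d)
            f1 = oct.haralick_features(g1)
            f2 = oct.haralick_features(g2)
            for k in (1, 2, 3, 4):  # contrast, correlation, entropy, homogeneity
                assert f2[k] == pytest.approx(f1[k], abs=1e-9)

    def test_contrast_decreases_with_correlation_length(self, rng):
        from scipy.stats import spearmanr

        from dermafuse.synthetic import ClassGeneratorParams, generate_bscan

        lengths = [1.0, 2.0, 4.0, 6.0, 8.0]
        contrasts = []
        for L in lengths:
            p = ClassGeneratorParams(
                melanin_slope=0.1, hemoglobin_dip_depth=0.1, nir_slope=-1e-4,
                texture_correlation_length_px=L, texture_contrast=25.0,
                mean_intensity=140.0, shape_eccentricity=0.3,
                boundary_roughness=0.1, size_mm=4.0,
            )
            vals = []
            for _ in range(6):
                s, roi, bg = generate_bscan(p, rng)
                out = oct.extract_oct_features(s, roi, bg)
                vals.append(out["contrast_a0_d1"])
            contrasts.append(np.mean(vals))
        rho, _ = spearmanr(lengths, contrasts)
        assert rho < 0
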