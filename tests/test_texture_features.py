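import numpy as np
import pytest

from eustex import (FEATURE_CATEGORIES, FEATURE_NAMES,
                    REFERENCE_SELECTED_FEATURES, SUBBANDS, Glcm,
                    WaveletPyramid, compute_glcm, extract_all,
                    glcm_features, glds_features, glrlm_features,
                    gradient_features, histogram_features, laws_features,
                    quantize, wavelet_decompose, wavelet_features)
from eustex.texture_features import gradient_magnitude, reconstruct, _SOBEL_COL
from oracles import (brute_convolve_valid, brute_glcm, brute_glcm_features,
                     brute_glds, brute_glrlm, brute_glrlm_features,
                     brute_histogram_moments)

CONSTANT = np.full((16, 16), 97, dtype=np.uint8)
CHECKER = np.indices((16, 16)).sum(axis=0) % 2
CHECKER_IMG = (CHECKER * 255).astype(np.uint8)


def random_image(seed, shape=(8, 8), levels=8):
    return np.random.default_rng(seed).integers(0, levels, size=shape)


class TestHistogram:
    def test_constant_image_degenerate_profile(self):
        f = histogram_features(CONSTANT)
        assert f["hist_std"] == 0.0
        assert f["hist_energy"] == 1.0
        assert f["hist_entropy"] == 0.0
        assert f["hist_skewness"] == 0.0 and f["hist_kurtosis"] == 0.0

    def test_two_equal_bins(self):
        img = np.zeros((16, 16), dtype=np.uint8)
        img[:, 8:] = 255
        f = histogram_features(img)
        assert f["hist_entropy"] == pytest.approx(1.0)
        assert f["hist_energy"] == pytest.approx(0.5)
        assert f["hist_range"] == 255.0

    def test_moments_match_per_pixel_oracle(self, rng):
        img = rng.integers(0, 256, size=(32, 32)).astype(np.uint8)
        got = histogram_features(img)
        want = brute_histogram_moments(img)
        for k, v in want.items():
            assert got[k] == pytest.approx(v, abs=1e-10)


class TestGlcm:
    def test_constant_image_single_cell(self):
        q = quantize(np.full((2, 2), 5, dtype=np.uint8), 4)
        m = compute_glcm(q, distance=1)
        assert m.p[0, 0] == pytest.approx(1.0)
        assert m.p.sum() == pytest.approx(1.0)

    def test_checkerboard_horizontal_alternation(self):
        q = quantize(CHECKER_IMG, 2)
        m = compute_glcm(q, distance=1, directions=[(0, 1)])
        assert m.p[0, 1] == pytest.approx(0.5)
        assert m.p[1, 0] == pytest.approx(0.5)
        assert m.p[0, 0] == m.p[1, 1] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matrix_matches_pair_enumeration(self, seed):
        img = random_image(seed)
        q = quantize(img.astype(np.uint8), 8)
        m = compute_glcm(q, distance=1)
        want = brute_glcm(q.pixels, 8, [(0, 1), (-1, 1), (-1, 0), (-1, -1)])
        np.testing.assert_allclose(m.p, want, atol=1e-12)

    def test_matrix_matches_skimage(self):
        """Cross-check the construction against an external implementation."""
        from skimage.feature import graycomatrix
        img = random_image(3, shape=(12, 12), levels=6).astype(np.uint8)
        q = quantize(img, int(img.max()) + 1)
        m = compute_glcm(q, distance=1, directions=[(0, 1)])
        ref = graycomatrix(q.pixels.astype(np.uint8), [1], [0],
                           levels=q.levels, symmetric=True, normed=True)
        np.testing.assert_allclose(m.p, ref[:, :, 0, 0], atol=1e-12)

    def test_single_cell_features(self):
        m = Glcm(np.array([[1.0]]), levels=1, distance=1, directions=((0, 1),))
        f = glcm_features(m)
        assert f["asm"] == 1.0 and f["max_probability"] == 1.0
        assert f["contrast"] == 0.0 and f["entropy"] == 0.0
        assert f["dissimilarity"] == 0.0

    def test_checkerboard_features(self):
        q = quantize(CHECKER_IMG, 2)
        f = glcm_features(compute_glcm(q, 1, directions=[(0, 1)]))
        assert f["contrast"] == pytest.approx(1.0)
        assert f["dissimilarity"] == pytest.approx(1.0)
        assert f["asm"] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_features_match_formula_oracle(self, seed):
        q = quantize(random_image(seed).astype(np.uint8), 8)
        m = compute_glcm(q, distance=1)
        got = glcm_features(m)
        want = brute_glcm_features(m.p)
        for k in want:
            assert got[k] == pytest.approx(want[k], abs=1e-10), k

    @pytest.mark.parametrize("seed", range(5))
    def test_invariants(self, seed):
        g = 8
        q = quantize(random_image(seed, levels=256).astype(np.uint8), g)
        m = compute_glcm(q, distance=1)
        f = glcm_features(m)
        np.testing.assert_allclose(m.p, m.p.T, atol=1e-12)
        assert m.p.sum() == pytest.approx(1.0, abs=1e-12)
        assert f["contrast"] >= 0
        assert 0 < f["asm"] <= 1
        assert 0 <= f["entropy"] <= 2 * np.log2(g)

    def test_distance_larger_than_image_rejected(self):
        q = quantize(CHECKER_IMG, 2)
        with pytest.raises(ValueError):
            compute_glcm(q, distance=16)


class TestGlrlm:
    def test_single_run_of_four(self):
        q = quantize(np.array([[5, 5, 5, 5]], dtype=np.uint8), 8)
        f = glrlm_features(q, directions=[(0, 1)])
        assert f["glrlm_lre"] == pytest.approx(16.0)
        assert f["glrlm_sre"] == pytest.approx(1.0 / 16.0)
        assert f["glrlm_rp"] == pytest.approx(0.25)

    def test_checkerboard_all_unit_runs(self):
        q = quantize(CHECKER_IMG, 2)
        f = glrlm_features(q, directions=[(0, 1), (-1, 0)])
        assert f["glrlm_lre"] == pytest.approx(1.0)
        assert f["glrlm_sre"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_run_enumeration_oracle(self, seed):
        q = quantize(random_image(seed, levels=4).astype(np.uint8), 4)
        got = glrlm_features(q)
        r = brute_glrlm(q.pixels, 4, [(0, 1), (-1, 1), (-1, 0), (-1, -1)])
        want = brute_glrlm_features(r, q.pixels.size)
        for k in want:
            assert got[k] == pytest.approx(want[k], abs=1e-10), k


class TestGlds:
    def test_constant_image(self):
        q = quantize(CONSTANT, 8)
        f = glds_features(q)
        assert f["glds_mean"] == 0.0 and f["glds_variance"] == 0.0
        assert f["glds_asm"] == 1.0

    def test_checkerboard_horizontal_only(self):
        q = quantize(CHECKER_IMG, 2)
        f = glds_features(q, displacements=[(0, 1)])
        assert f["glds_mean"] == pytest.approx(1.0)
        assert f["glds_variance"] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_difference_histogram_oracle(self, seed):
        q = quantize(random_image(seed).astype(np.uint8), 8)
        got = glds_features(q)
        want = brute_glds(q.pixels, 8, [(0, 1), (-1, 1), (-1, 0), (-1, -1)])
        for k in want:
            assert got[k] == pytest.approx(want[k], abs=1e-10), k


class TestWavelet:
    def test_structure_64x64(self, rng):
        img = rng.integers(0, 256, size=(64, 64)).astype(np.uint8)
        p = wavelet_decompose(img)
        assert set(p.subbands) == set(SUBBANDS)
        assert max(p.subbands["ca3"].shape) <= 14  # 8 + db4 boundary padding

    def test_constant_image_vanishing_details(self):
        p = wavelet_decompose(CONSTANT)
        for sb in SUBBANDS[:-1]:
            assert np.abs(p.subbands[sb]).max() < 1e-8
        assert np.ptp(p.subbands["ca3"]) < 1e-8

    def test_reconstruction_round_trip(self, rng):
        img = rng.integers(0, 256, size=(48, 40)).astype(np.uint8)
        p = wavelet_decompose(img)
        rec = reconstruct(p)[:48, :40]
        np.testing.assert_allclose(rec, img.astype(float), atol=1e-8)

    def test_uniform_energy_entropy(self):
        bands = {sb: np.zeros((4, 4)) for sb in SUBBANDS}
        bands["cv1"] = np.ones((4, 4))            # 16 equal-magnitude coefs
        f = wavelet_features(WaveletPyramid(bands))
        assert f["wav_entropy_cv1"] == pytest.approx(np.log2(16))

    def test_single_nonzero_coefficient_entropy_zero(self):
        bands = {sb: np.zeros((4, 4)) for sb in SUBBANDS}
        bands["cd2"][1, 2] = 3.0
        f = wavelet_features(WaveletPyramid(bands))
        assert f["wav_entropy_cd2"] == 0.0
        assert f["wav_std_cd2"] > 0

    def test_random_subband_matches_direct_formula(self, rng):
        c = rng.standard_normal((6, 5))
        bands = {sb: np.zeros((4, 4)) for sb in SUBBANDS}
        bands["ch3"] = c
        f = wavelet_features(WaveletPyramid(bands))
        q = c.ravel() ** 2 / (c ** 2).sum()
        assert f["wav_entropy_ch3"] == pytest.approx(-(q * np.log2(q)).sum())
        assert f["wav_std_ch3"] == pytest.approx(c.std())
        assert f["wav_energy_ch3"] == pytest.approx((c ** 2).mean())


class TestLawsAndGradient:
    def test_constant_zero_sum_masks_silent(self):
        f = laws_features(CONSTANT)
        for name, val in f.items():
            if name == "laws_l3l3":
                assert val == pytest.approx(1.0)
            else:
                assert val == pytest.approx(0.0, abs=1e-12)

    def test_ramp_directionality(self):
        ramp = np.tile(np.arange(0, 160, 10, dtype=np.uint8), (16, 1))
        f = laws_features(ramp)
        assert f["laws_l3e3"] > 1e-3        # horizontal edge kernel responds
        assert f["laws_e3l3"] == pytest.approx(0.0, abs=1e-12)

    def test_laws_matches_direct_convolution(self, rng):
        img = rng.integers(0, 256, size=(12, 12)).astype(np.uint8)
        f = laws_features(img)
        l3 = np.array([1.0, 2.0, 1.0])
        e3 = np.array([-1.0, 0.0, 1.0])
        denom = np.abs(brute_convolve_valid(img.astype(float),
                                            np.outer(l3, l3))).mean()
        want = np.abs(brute_convolve_valid(img.astype(float),
                                           np.outer(l3, e3))).mean() / denom
        assert f["laws_l3e3"] == pytest.approx(want, abs=1e-10)

    def test_gradient_constant_image(self):
        f = gradient_features(CONSTANT)
        assert f["grad_mean"] == 0.0 and f["grad_max"] == 0.0
        assert f["grad_edge_fraction"] == 0.0

    def test_gradient_step_edge(self):
        img = np.zeros((16, 16), dtype=np.uint8)
        img[:, 8:] = 200
        f = gradient_features(img)
        mag = gradient_magnitude(img)
        # responding band straddles the step between columns 7 and 8
        assert mag[:, 6:8].min() > 0
        assert f["grad_max"] == mag.max()
        assert f["grad_edge_fraction"] == pytest.approx(
            (mag > 0.1 * mag.max()).mean())

    def test_gradient_matches_direct_convolution(self, rng):
        img = rng.integers(0, 256, size=(10, 10)).astype(float)
        gc = brute_convolve_valid(img, _SOBEL_COL)
        gr = brute_convolve_valid(img, _SOBEL_COL.T)
        np.testing.assert_allclose(gradient_magnitude(img.astype(np.uint8)),
                                   np.hypot(gr, gc), atol=1e-10)


class TestExtractAll:
    def test_inventory_shape(self, rng):
        img = rng.integers(0, 256, size=(32, 32)).astype(np.uint8)
        vec = extract_all(img)
        assert len(vec) == 105
        assert list(vec.index) == list(FEATURE_NAMES)
        assert len(set(FEATURE_CATEGORIES.values())) == 9
        assert set(REFERENCE_SELECTED_FEATURES) <= set(vec.index)

    def test_constant_image_all_finite(self):
        vec = extract_all(np.full((32, 32), 7, dtype=np.uint8))
        assert np.isfinite(vec.to_numpy()).all()

    def test_deterministic(self, rng):
        img = rng.integers(0, 256, size=(24, 24)).astype(np.uint8)
        v1, v2 = extract_all(img), extract_all(img.copy())
        assert (v1 == v2).all()

    def test_noise_monotonically_raises_contrast_and_gradient(self):
        """Stronger additive noise raises co-occurrence contrast (on a fixed
        grey scale: the per-image min-max quantizer deliberately removes the
        amplitude scale) and the gradient mean."""
        from eustex import QuantizedImage, compute_glcm, glcm_features
        base = np.full((32, 32), 120, dtype=float)
        gen = np.random.default_rng(9)
        noise = gen.standard_normal((32, 32))
        prev_contrast, prev_grad = -1.0, -1.0
        for amp in (4.0, 12.0, 36.0):  # keep 3 sigma inside [0, 255]
            img = np.clip(base + amp * noise, 0, 255).astype(np.uint8)
            q = QuantizedImage(img // 4, 64)   # fixed 0-255 -> 64-bin map
            contrast = glcm_features(compute_glcm(q, 1))["contrast"]
            grad = extract_all(img)["grad_mean"]
            assert contrast > prev_contrast
            assert grad > prev_grad
            prev_contrast, prev_grad = contrast, grad

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            extract_all(np.zeros((4, 4), dtype=np.uint8))
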