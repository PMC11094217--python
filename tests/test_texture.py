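import numpy as np
import pytest

from hossnf import synth, texture
from hossnf.exceptions import ConfigError, InputError, ValidationError
from hossnf.texture import (FEATURE_NAMES, GaborBankConfig, GLCMConfig,
                            extract_features, gabor_features, gabor_kernel,
                            glcm, glcm_stats, lbp_codes, lbp_histogram,
                            quantize, standardize_features)


def brute_glcm(q, dr, dc, levels):
    """Pair-enumeration oracle, independent of scikit-image."""
    C = np.zeros((levels, levels))
    H, W = q.shape
    for r in range(H):
        for c in range(W):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < H and 0 <= c2 < W:
                C[q[r, c], q[r2, c2]] += 1
    C = C + C.T
    return C / C.sum()


def brute_stats(P):
    """Double-loop Haralick oracle."""
    n = P.shape[0]
    con = en = ent = mux = muy = 0.0
    for i in range(n):
        for j in range(n):
            con += (i - j) ** 2 * P[i, j]
            en += P[i, j] ** 2
            if P[i, j] > 0:
                ent -= P[i, j] * np.log2(P[i, j])
            mux += i * P[i, j]
            muy += j * P[i, j]
    vx = vy = cov = 0.0
    for i in range(n):
        for j in range(n):
            vx += (i - mux) ** 2 * P[i, j]
            vy += (j - muy) ** 2 * P[i, j]
            cov += (i - mux) * (j - muy) * P[i, j]
    corr = 1.0 if vx <= 0 or vy <= 0 else cov / np.sqrt(vx * vy)
    return con, en, ent, corr


class TestGLCM:
    def test_constant_image_single_entry(self):
        img = np.full((8, 8), 100, dtype=np.uint8)
        P = glcm(img, 1, 0.0)
        level = quantize(img, 8)[0, 0]
        assert P[level, level] == 1.0 and P.sum() == pytest.approx(1.0)

    def test_two_pixel_pair(self):
        P = glcm(np.array([[0, 255]], dtype=np.uint8), 1, 0.0, GLCMConfig(levels=2))
        np.testing.assert_allclose(P, [[0.0, 0.5], [0.5, 0.0]])

    def test_normalization(self, noisy_phantom):
        img, _ = noisy_phantom
        for d, a in [(1, 0.0), (2, 45.0), (1, 90.0), (2, 135.0)]:
            assert glcm(img, d, a).sum() == pytest.approx(1.0)

    def test_symmetric_equals_opposite_angle(self, noisy_phantom):
        img, _ = noisy_phantom
        for a in (0.0, 45.0, 90.0, 135.0):
            np.testing.assert_allclose(glcm(img, 1, a), glcm(img, 1, a + 180.0),
                                       atol=1e-15)

    def test_displacement_larger_than_image(self):
        with pytest.raises(InputError):
            glcm(np.zeros((1, 1), dtype=np.uint8), 1, 0.0)

    def test_matches_pair_enumeration_oracle(self, rng):
        for _ in range(10):
            img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
            for d, a in [(1, 0.0), (1, 45.0), (2, 90.0), (2, 135.0)]:
                dr = int(round(d * np.sin(np.deg2rad(a))))
                dc = int(round(d * np.cos(np.deg2rad(a))))
                np.testing.assert_allclose(
                    glcm(img, d, a), brute_glcm(quantize(img, 8), dr, dc, 8),
                    atol=1e-12,
                )


class TestGlcmStats:
    def test_constant_image_conventions(self):
        img = np.full((8, 8), 33, dtype=np.uint8)
        s = glcm_stats(glcm(img, 1, 0.0))
        assert s == (0.0, 1.0, 0.0, 1.0)

    def test_checkerboard_pair_hand_values(self):
        P = np.array([[0.0, 0.5], [0.5, 0.0]])
        s = glcm_stats(P)
        assert s.contrast == pytest.approx(1.0)
        assert s.energy == pytest.approx(0.5)
        assert s.entropy == pytest.approx(1.0)      # one bit
        assert s.correlation == pytest.approx(-1.0)

    def test_bounds(self, rng):
        for _ in range(20):
            img = rng.integers(0, 256, (12, 12)).astype(np.uint8)
            s = glcm_stats(glcm(img, 1, 0.0))
            assert 0.0 < s.energy <= 1.0
            assert s.entropy >= 0.0
            assert -1.0 <= s.correlation <= 1.0 + 1e-12

    def test_unnormalized_matrix_rejected(self):
        with pytest.raises(ValidationError):
            glcm_stats(np.ones((4, 4)))


class TestLBP:
    def test_constant_image_all_ones_class(self):
        hist = lbp_histogram(np.full((8, 8), 7, dtype=np.uint8))
        assert hist[8] == 1.0 and hist.sum() == pytest.approx(1.0)

    def test_single_bright_center_neighbor_codes(self):
        # brute-force the 8 codes around an isolated bright pixel
        img = np.zeros((5, 5), dtype=np.uint8)
        img[2, 2] = 255
        codes = lbp_codes(img)
        # center pixel: every neighbor (0) fails "neighbor >= 255" -> code 0
        assert codes[1, 1] == 0
        offsets = {(0, 1): 0, (-1, 1): 1, (-1, 0): 2, (-1, -1): 3,
                   (0, -1): 4, (1, -1): 5, (1, 0): 6, (1, 1): 7}
        for (dr, dc), bit in offsets.items():
            # neighbor at (2+dr, 2+dc) sees the bright pixel in direction
            # (-dr, -dc); all its other neighbors are equal (>=) -> all bits set
            r, c = 2 + dr, 2 + dc
            if 1 <= r <= 3 and 1 <= c <= 3:
                assert codes[r - 1, c - 1] == 255

    def test_histogram_sums_to_one(self, noisy_phantom):
        img, _ = noisy_phantom
        assert lbp_histogram(img).sum() == pytest.approx(1.0)

    def test_invariant_to_monotone_remap(self, rng):
        img = rng.integers(0, 128, (16, 16)).astype(np.uint8)
        # strictly increasing remap of the used value range [0, 127]
        lut = np.sort(rng.choice(256, size=128, replace=False)).astype(np.uint8)
        remapped = lut[img]
        np.testing.assert_allclose(lbp_histogram(img), lbp_histogram(remapped))


class TestGabor:
    def test_center_value_before_dc_removal(self):
        k = gabor_kernel(5, 0.6, 45.0, zero_dc=False)
        assert k[2, 2] == pytest.approx(1.0)

    def test_theta_plus_180_identical(self):
        np.testing.assert_allclose(gabor_kernel(5, 0.3, 30.0),
                                   gabor_kernel(5, 0.3, 210.0), atol=1e-15)

    def test_zero_dc(self):
        for f in (0.3, 0.6):
            for th in (0.0, 45.0, 90.0, 135.0):
                assert abs(gabor_kernel(5, f, th).sum()) < 1e-12

    def test_even_kernel_rejected(self):
        with pytest.raises(ConfigError):
            gabor_kernel(4, 0.6, 0.0)

    def test_constant_image_zero_features(self):
        feats = gabor_features(np.full((16, 16), 99, dtype=np.uint8))
        np.testing.assert_allclose(feats, 0.0, atol=1e-12)

    def test_orientation_selectivity_on_grating(self):
        cols = np.arange(32)
        row = np.clip(np.rint(127 + 100 * np.cos(2 * np.pi * 0.6 * cols)), 0, 255)
        img = np.tile(row, (32, 1)).astype(np.uint8)
        feats = dict(zip([n for n in FEATURE_NAMES if n.startswith("gabor")],
                         gabor_features(img)))
        assert feats["gabor_f0.6_o0_mean"] > feats["gabor_f0.6_o90_mean"]


class TestFeatureVector:
    def test_length_and_finite(self, clean_phantom):
        img, _ = clean_phantom
        vec = extract_features(img)
        assert vec.shape == (58,)
        assert np.all(np.isfinite(vec))
        assert len(FEATURE_NAMES) == 58

    def test_deterministic_across_renderings(self):
        spec = synth.default_spec("low_grade_dysplasia", seed=21)
        a = extract_features(synth.render_cell(spec)[0])
        b = extract_features(synth.render_cell(spec)[0])
        np.testing.assert_array_equal(a, b)

    def test_lbp_bins_sum_to_one(self, noisy_phantom):
        img, _ = noisy_phantom
        vec = extract_features(img)
        lbp = vec[32:42]
        assert lbp.sum() == pytest.approx(1.0)

    def test_severe_vs_normal_contrast_separation(self):
        """High-grade dysplasia phantoms carry more chromatin texture than
        normal squamous ones; distance-2 GLCM contrast on the cell ROI must
        separate the two groups (two-sample check, 20 phantoms each)."""
        from hossnf import segment

        idx = [i for i, n in enumerate(FEATURE_NAMES)
               if n.startswith("glcm_d2") and n.endswith("contrast")]

        def contrasts(label):
            vals = []
            for s in range(20):
                img, mask = synth.render_cell(synth.default_spec(label, seed=s))
                roi = segment.extract_roi(img, mask, margin=2)
                vals.append(extract_features(roi)[idx].mean())
            return np.asarray(vals)

        hgd = contrasts("high_grade_dysplasia")
        ns = contrasts("normal_squamous")
        se = np.sqrt(hgd.var() / len(hgd) + ns.var() / len(ns))
        assert hgd.mean() - ns.mean() > 3 * se


class TestStandardize:
    def test_zero_mean_unit_sd(self, rng):
        X = rng.normal(3.0, 2.0, (40, 6))
        tf, Xs = standardize_features(X)
        np.testing.assert_allclose(Xs.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Xs.std(axis=0), 1.0, atol=1e-12)

    def test_constant_feature_dropped(self, rng):
        X = rng.normal(0, 1, (20, 3))
        X[:, 1] = 5.0
        tf, Xs = standardize_features(X)
        assert Xs.shape == (20, 2)
        assert 1 not in tf.kept_idx

    def test_stored_transform_reproduces_training_output(self, rng):
        X = rng.normal(0, 1, (15, 4))
        tf, Xs = standardize_features(X)
        np.testing.assert_allclose(tf.apply(X), Xs)

    def test_top_k_selection_keeps_highest_variance(self, rng):
        X = rng.normal(0, 1, (30, 5))
        X[:, 2] *= 10.0
        tf, Xs = standardize_features(X, top_k=2)
        assert 2 in tf.select_idx and Xs.shape[1] == 2

    def test_too_few_vectors(self):
        with pytest.raises(ValidationError):
            standardize_features(np.zeros((1, 3)))
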