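import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tumorkit.image_io import Image
from tumorkit.phantom import PhantomConfig, generate_phantom
from tumorkit.texture import (ANGLE_OFFSETS, GLCMConfig, IGNORED, compute_glcm,
                              extract_features, glcm_features, normalize_glcm,
                              quantize)


def brute_glcm(grid, levels, distance, angle, symmetric):
    """Exhaustive double-loop pair enumeration; the counting oracle."""
    dr, dc = (distance * o for o in ANGLE_OFFSETS[angle])
    counts = np.zeros((levels, levels), dtype=np.int64)
    h, w = grid.shape
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                i, j = grid[r, c], grid[r2, c2]
                if i != IGNORED and j != IGNORED:
                    counts[i, j] += 1
                    if symmetric:
                        counts[j, i] += 1
    return counts


def brute_features(p):
    """Literal double sums over all (i, j); the feature oracle."""
    L = p.shape[0]
    idx = np.arange(L)
    contrast = dissim = homog = energy = 0.0
    for i in range(L):
        for j in range(L):
            contrast += p[i, j] * (i - j) ** 2
            dissim += p[i, j] * abs(i - j)
            homog += p[i, j] / (1 + (i - j) ** 2)
            energy += p[i, j] ** 2
    pi, pj = p.sum(axis=1), p.sum(axis=0)
    mi, mj = (idx * pi).sum(), (idx * pj).sum()
    vi = ((idx - mi) ** 2 * pi).sum()
    vj = ((idx - mj) ** 2 * pj).sum()
    corr = sum(p[i, j] * (i - mi) * (j - mj) for i in range(L)
               for j in range(L)) / np.sqrt(vi * vj) if vi > 0 and vj > 0 else 1.0
    return contrast, dissim, homog, energy, corr


class TestQuantize:
    def test_two_level_threshold(self):
        img = Image(np.array([[0.0, 0.49], [0.5, 1.0]]), "unit")
        np.testing.assert_array_equal(quantize(img, 2),
                                      [[0, 0], [1, 1]])

    def test_constant_maps_to_single_level(self):
        img = Image(np.full((5, 5), 0.4), "unit")
        assert len(np.unique(quantize(img, 32))) == 1

    def test_matches_floor_formula_oracle(self, rng):
        vals = rng.random((12, 12))
        img = Image(vals, "unit")
        L = 32
        expected = np.floor(np.minimum(vals, 1 - 1e-12) * L).astype(int)
        np.testing.assert_array_equal(quantize(img, L), expected)

    def test_masked_pixels_flagged(self):
        img = Image(np.full((3, 3), 0.5), "unit")
        mask = np.eye(3, dtype=bool)
        grid = quantize(img, 4, mask)
        assert np.all(grid[~mask] == IGNORED)
        assert np.all(grid[mask] == 2)

    def test_too_few_levels(self):
        with pytest.raises(ValueError):
            quantize(Image(np.zeros((3, 3)), "unit"), 1)


class TestComputeGlcm:
    def test_single_pair_asymmetric(self):
        cfg = GLCMConfig(levels=2, symmetric=False)
        g = compute_glcm(np.array([[0, 1]]), cfg, 0)
        assert g.counts[0, 1] == 1 and g.counts.sum() == 1

    def test_single_pair_symmetric(self):
        cfg = GLCMConfig(levels=2, symmetric=True)
        g = compute_glcm(np.array([[0, 1]]), cfg, 0)
        assert g.counts[0, 1] == 1 and g.counts[1, 0] == 1

    @pytest.mark.parametrize("angle", [0, 45, 90, 135])
    @pytest.mark.parametrize("symmetric", [True, False])
    def test_matches_enumeration_oracle(self, angle, symmetric, rng):
        grid = rng.integers(0, 8, (8, 8))
        cfg = GLCMConfig(levels=8, symmetric=symmetric)
        got = compute_glcm(grid, cfg, angle)
        np.testing.assert_array_equal(
            got.counts, brute_glcm(grid, 8, 1, angle, symmetric))

    def test_masked_matches_enumeration_oracle(self, rng):
        grid = rng.integers(0, 4, (8, 8))
        grid[rng.random((8, 8)) < 0.4] = IGNORED
        cfg = GLCMConfig(levels=4, symmetric=True)
        for angle in (0, 45, 90, 135):
            np.testing.assert_array_equal(
                compute_glcm(grid, cfg, angle).counts,
                brute_glcm(grid, 4, 1, angle, True))

    def test_agrees_with_skimage_reference(self, rng):
        from skimage.feature import graycomatrix
        grid = rng.integers(0, 6, (10, 10))
        cfg = GLCMConfig(levels=6, symmetric=True)
        ref = graycomatrix(grid.astype(np.uint8), [1],
                           [0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
                           levels=6, symmetric=True)
        # this package measures angles with the row axis pointing up, the
        # reference with it pointing down: the two diagonals swap labels
        for a_idx, angle in enumerate((0, 135, 90, 45)):
            np.testing.assert_array_equal(
                compute_glcm(grid, cfg, angle).counts, ref[:, :, 0, a_idx])

    def test_too_small_grid_yields_degenerate(self):
        cfg = GLCMConfig(levels=2)
        g = compute_glcm(np.array([[0]]), cfg, 0)
        assert g.degenerate and g.n_pairs == 0
        assert not g.probabilities.any()


class TestNormalizeGlcm:
    def test_probabilities_sum_to_one(self, rng):
        grid = rng.integers(0, 4, (8, 8))
        g = compute_glcm(grid, GLCMConfig(levels=4), 0)
        assert abs(g.probabilities.sum() - 1.0) < 1e-12
        np.testing.assert_allclose(g.probabilities,
                                   g.counts / g.n_pairs)


class TestGlcmFeatures:
    def test_constant_image_closed_form(self):
        img = Image(np.full((6, 6), 0.5), "unit")
        g = compute_glcm(quantize(img, 4), GLCMConfig(levels=4), 0)
        f = glcm_features(g)
        assert f.contrast == 0 and f.dissimilarity == 0
        assert f.homogeneity == 1.0 and f.energy == 1.0
        assert f.correlation == 1.0 and f.correlation_degenerate
        assert f.entropy == 0.0

    def test_checkerboard_closed_form(self):
        board = np.indices((4, 4)).sum(axis=0) % 2
        g = compute_glcm(board, GLCMConfig(levels=2, symmetric=True), 0)
        f = glcm_features(g)
        assert abs(f.contrast - 1.0) < 1e-10
        assert abs(f.dissimilarity - 1.0) < 1e-10
        assert abs(f.homogeneity - 0.5) < 1e-10
        assert abs(f.energy - 0.5) < 1e-10
        assert abs(f.correlation - (-1.0)) < 1e-10

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_double_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        grid = rng.integers(0, 5, (7, 7))
        g = compute_glcm(grid, GLCMConfig(levels=5), 0)
        f = glcm_features(g)
        c, k, h, e, corr = brute_features(g.probabilities)
        assert abs(f.contrast - c) < 1e-10
        assert abs(f.dissimilarity - k) < 1e-10
        assert abs(f.homogeneity - h) < 1e-10
        assert abs(f.energy - e) < 1e-10
        assert abs(f.correlation - corr) < 1e-10

    def test_agrees_with_skimage_graycoprops(self, rng):
        from skimage.feature import graycomatrix, graycoprops
        grid = rng.integers(0, 8, (12, 12)).astype(np.uint8)
        ref = graycomatrix(grid, [1], [0], levels=8, symmetric=True)
        f = glcm_features(compute_glcm(grid.astype(int),
                                       GLCMConfig(levels=8), 0))
        for mine, name in [(f.contrast, "contrast"),
                           (f.dissimilarity, "dissimilarity"),
                           (f.homogeneity, "homogeneity"),
                           (f.energy, "ASM"),
                           (f.correlation, "correlation")]:
            assert abs(mine - graycoprops(ref, name)[0, 0]) < 1e-10

    def test_degenerate_glcm_rejected(self):
        g = compute_glcm(np.array([[0]]), GLCMConfig(levels=2), 0)
        with pytest.raises(ValueError):
            glcm_features(g)


class TestExtractFeatures:
    def test_constant_image_any_mask(self):
        img = Image(np.full((8, 8), 0.7), "unit")
        mask = np.zeros((8, 8), bool)
        mask[2:6, 2:6] = True
        f = extract_features(img, mask)
        assert f.contrast == 0 and f.dissimilarity == 0
        assert f.homogeneity == 1.0 and f.energy == 1.0

    def test_single_angle_equals_average_of_one(self, rng):
        img = Image(rng.random((16, 16)), "unit")
        a = extract_features(img, None, GLCMConfig(angles=(90,)))
        grid = quantize(img, 32)
        b = glcm_features(compute_glcm(grid, GLCMConfig(angles=(90,)), 90))
        assert a.contrast == b.contrast and a.correlation == b.correlation

    def test_transpose_invariance_for_0_90_pair(self, rng):
        img = Image(rng.random((12, 12)), "unit")
        cfg = GLCMConfig(angles=(0, 90))
        f1 = extract_features(img, None, cfg)
        f2 = extract_features(Image(img.pixels.T.copy(), "unit"), None, cfg)
        assert abs(f1.contrast - f2.contrast) < 1e-12
        assert abs(f1.correlation - f2.correlation) < 1e-12

    def test_contrast_at_least_dissimilarity_with_offdiagonal_mass(self, rng):
        # |i-j| >= 1 on all off-diagonal cells implies (i-j)^2 >= |i-j|
        for seed in range(5):
            grid = np.random.default_rng(seed).integers(0, 6, (10, 10))
            f = glcm_features(compute_glcm(grid, GLCMConfig(levels=6), 0))
            assert f.contrast >= f.dissimilarity - 1e-12

    def test_tumor_texture_raises_contrast(self):
        """Tumor ROIs carry more co-occurrence contrast than brain tissue.

        Driven by tumor_texture_sigma > background_texture_sigma in the
        phantom generator; checked as a mean over seeds.
        """
        cfg = PhantomConfig(size=64)
        tumor_c, brain_c = [], []
        for seed in range(20):
            pt = generate_phantom(cfg, "tumor", seed=seed)
            tumor_c.append(extract_features(pt.image, pt.mask).contrast)
            pn = generate_phantom(cfg, "non_tumor", seed=seed)
            brain = pn.image.pixels > 0.1
            # equally sized ROI: erode the brain to a comparable patch
            rr, cc = np.where(brain)
            sel = np.zeros_like(brain)
            n_roi = int(pt.mask.sum())
            sel[rr[:n_roi], cc[:n_roi]] = True
            brain_c.append(extract_features(pn.image, sel).contrast)
        assert np.mean(tumor_c) > np.mean(brain_c)

    def test_empty_mask_rejected(self):
        img = Image(np.full((8, 8), 0.5), "unit")
        with pytest.raises(ValueError, match="empty ROI"):
            extract_features(img, np.zeros((8, 8), bool))
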