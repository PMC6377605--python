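"""Shape, first-order, texture and fractal feature unit tests."""

import math

import numpy as np
import pytest

from conftest import random_level_grid
from oracles import (
    naive_glcm,
    naive_glcm_stats,
    naive_glrlm,
    naive_glrlm_stats,
    naive_ngtdm,
    naive_ngtdm_stats,
)
from rpvkit.features.firstorder import first_order_features
from rpvkit.features.fractal import box_counting_dimension, fractal_features
from rpvkit.features.shape import shape_features, sphericity_from_volume_area
from rpvkit.features.texture import (
    GLRLMatrix,
    NGTDMatrix,
    glcm_features,
    glcm_matrix,
    glrlm_features,
    glrlm_matrix,
    ngtdm_features,
    ngtdm_matrix,
)
from rpvkit.imaging import SegmentationMask
from rpvkit.preprocess import DiscretizedVolume, discretize_fixed_binwidth


def _disc(levels, ng):
    return DiscretizedVolume(levels=levels, bin_width=25.0, anchor=0.0, ng=ng)


class TestShape:
    def test_voxelized_sphere_approaches_unit_sphericity(self):
        n, r = 48, 20
        g = np.mgrid[:n, :n, :n].astype(float) - (n - 1) / 2
        sphere = (g**2).sum(axis=0) <= r**2
        f = shape_features(SegmentationMask(sphere.astype(np.uint8), (1, 1, 1)))
        assert 0.97 <= f["sphericity"] <= 1.0
        assert f["max_diameter_3d"] == pytest.approx(2 * r, rel=0.03)
        assert f["volume"] == pytest.approx(4 / 3 * math.pi * r**3, rel=0.05)

    def test_cube_sphericity_closed_form(self):
        # continuous cube: V = a^3, A = 6 a^2
        a = 10.0
        got = sphericity_from_volume_area(a**3, 6 * a**2)
        assert got == pytest.approx(math.pi ** (1 / 3) * 6 ** (2 / 3) / 6, abs=1e-12)

    def test_single_voxel_volume(self):
        m = np.zeros((5, 5, 5))
        m[2, 2, 2] = 1
        f = shape_features(SegmentationMask(m, (1, 1, 1)))
        assert f["volume"] == 1.0
        assert f["max_diameter_3d"] == 0.0

    def test_rotation_invariance_with_permuted_spacing(self):
        g = np.mgrid[:20, :20, :20].astype(float)
        blob = ((g[0] - 9) ** 2 + (g[1] - 10) ** 2 + (g[2] - 8) ** 2) < 36
        f1 = shape_features(SegmentationMask(blob.astype(np.uint8), (1, 2, 3)))
        rot = np.rot90(blob, axes=(0, 1))
        f2 = shape_features(SegmentationMask(rot.astype(np.uint8), (2, 1, 3)))
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], rel=1e-5)


class TestFirstOrder:
    def test_constant_sample(self):
        f = first_order_features(np.array([5.0, 5.0, 5.0]))
        assert f["Imedian"] == 5 and f["Ivariance"] == 0
        assert f["Ientropy"] == 0 and f["Iuniformity"] == 1

    def test_even_count_median_is_midpoint(self):
        assert first_order_features(np.array([1.0, 2, 3, 4]))["Imedian"] == 2.5

    def test_histogram_entropy_hand_example(self):
        # values {0, 0, 30, 60} at width 25 -> bins (2,1,1)/4 -> 1.5 bits
        f = first_order_features(np.array([0.0, 0, 30, 60]), bin_width=25.0)
        assert f["Ientropy"] == pytest.approx(1.5, abs=1e-12)
        assert f["Iuniformity"] == pytest.approx(0.25 + 0.0625 + 0.0625, abs=1e-12)

    def test_permutation_invariance(self, rng):
        v = rng.normal(size=100)
        a = first_order_features(v)
        b = first_order_features(rng.permutation(v))
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-12, abs=1e-12), k

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            first_order_features(np.array([]))


class TestTextureOracles:
    """Vectorized matrices and statistics vs naive enumeration."""

    def test_matrices_and_stats_match_bruteforce(self, rng):
        for _ in range(25):
            levels, ng = random_level_grid(rng)
            nv = int((levels > 0).sum())

            counts = glcm_matrix(levels, ng).counts
            assert np.array_equal(counts, naive_glcm(levels, ng))
            got = glcm_features(_disc(levels, ng))
            want = naive_glcm_stats(counts)
            for k in want:
                assert got[k] == pytest.approx(want[k], rel=1e-10, abs=1e-12), k

            rmat = glrlm_matrix(levels, ng)
            assert np.array_equal(rmat.counts, naive_glrlm(levels, ng))
            got = glrlm_features(_disc(levels, ng))
            want = naive_glrlm_stats(rmat.counts, nv, 13)
            for k in want:
                assert got[k] == pytest.approx(want[k], rel=1e-10, abs=1e-12), k

            n_i, s_i = naive_ngtdm(levels, ng)
            nmat = ngtdm_matrix(levels, ng)
            assert np.allclose(nmat.n_i, n_i) and np.allclose(nmat.s_i, s_i)
            got = ngtdm_features(_disc(levels, ng))
            want = naive_ngtdm_stats(n_i, s_i)
            for k in want:
                assert got[k] == pytest.approx(want[k], rel=1e-10, abs=1e-12), k

    def test_run_conservation(self, rng):
        for _ in range(10):
            levels, ng = random_level_grid(rng)
            m = glrlm_matrix(levels, ng)
            j = np.arange(1, m.counts.shape[1] + 1)
            assert (m.counts * j).sum() == 13 * (levels > 0).sum()


class TestTextureHandExamples:
    def test_glrlm_2d_toy_srlgle(self):
        # rows [1,1,2] and [2,2,3], horizontal runs only:
        # runs {(1,2),(2,1),(2,2),(3,1)}, R = 4
        grid = np.array([[1, 1, 2], [2, 2, 3]])
        levels = np.transpose(grid, (1, 0))[:, :, None]  # runs along axis 0
        m = glrlm_matrix(levels, 3, directions=((1, 0, 0),))
        f = glrlm_features(m)
        assert f["SRLGLE"] == pytest.approx((1 / 4) * (1 / 4 + 1 / 4 + 1 / 16 + 1 / 9), abs=1e-12)
        assert m.total_runs == 4

    def test_constant_image_single_run(self):
        n = 7
        levels = np.ones((n, 1, 1), dtype=int)
        f = glrlm_features(glrlm_matrix(levels, 1, directions=((1, 0, 0),)))
        assert f["SRE"] == pytest.approx(1 / n**2)
        assert f["RP"] == pytest.approx(1 / n)

    def test_glcm_2d_toy(self):
        # [[1,2],[1,2]], pairing along the level-changing axis only:
        # p(1,2) = p(2,1) = 0.5 -> contrast 1, energy 0.5
        levels = np.array([[[1], [2]], [[1], [2]]])  # shape (2,2,1)
        m = glcm_matrix(levels, 2, directions=((0, 1, 0),))
        stats = glcm_features(m)
        assert stats["contrast"] == pytest.approx(1.0)
        assert stats["energy"] == pytest.approx(0.5)

    def test_glcm_constant_region(self):
        levels = np.ones((4, 4, 4), dtype=int)
        f = glcm_features(_disc(levels, 1))
        assert f["contrast"] == 0.0 and f["energy"] == 1.0 and f["correlation"] == 0.0

    def test_glcm_gray_flip_preserves_contrast(self, rng):
        levels, ng = random_level_grid(rng)
        flipped = np.where(levels > 0, ng + 1 - levels, 0)
        a = glcm_features(_disc(levels, ng))
        b = glcm_features(_disc(flipped, ng))
        assert a["contrast"] == pytest.approx(b["contrast"], rel=1e-12)

    def test_ngtdm_2d_toy_contrast(self):
        levels = np.ones((3, 3, 1), dtype=int)
        levels[1, 1, 0] = 2
        f = ngtdm_features(ngtdm_matrix(levels, 2))
        expected = (0.5 * 2 * (8 / 81)) * ((1 / 9) * (1 + 32 / 15))
        assert f["Contra"] == pytest.approx(expected, rel=1e-12)

    def test_ngtdm_constant_region_zero_contrast(self):
        levels = np.ones((4, 4, 4), dtype=int)
        assert ngtdm_features(ngtdm_matrix(levels, 1))["Contra"] == 0.0

    def test_checkerboard_exceeds_blocks(self):
        g = np.indices((6, 6, 1)).sum(axis=0)
        checker = (g % 2 + 1).astype(int)
        blocks = np.ones((6, 6, 1), dtype=int)
        blocks[3:, :, :] = 2
        fc = ngtdm_features(ngtdm_matrix(checker, 2))
        fb = ngtdm_features(ngtdm_matrix(blocks, 2))
        assert fc["Contra"] > fb["Contra"]


class TestFractal:
    @pytest.mark.parametrize(
        "shape, lo, hi",
        [((32, 32, 32), 2.8, 3.0), ((32, 32, 1), 1.8, 2.1), ((32, 1, 1), 0.9, 1.1)],
    )
    def test_analytic_limits(self, shape, lo, hi):
        fd = box_counting_dimension(np.ones(shape, bool))
        assert lo <= fd <= hi

    def test_too_small_set_flagged_nan(self):
        assert np.isnan(box_counting_dimension(np.ones((2, 2, 2), bool)))

    def test_threshold_summary(self):
        vox = np.zeros((32, 32, 32))
        vox[8:24, 8:24, 8:24] = 100.0
        mask = np.ones((32, 32, 32), bool)
        disc = discretize_fixed_binwidth(vox, mask, 25.0)
        f = fractal_features(disc)
        assert f["max"] >= f["mean"] >= 0
        assert f["sd"] >= 0
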