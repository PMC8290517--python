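"""GLCM and GLRLM features against brute-force enumeration oracles."""

import numpy as np
import pytest

from gliomics import DiscretizationConfig, glcm_features, glrlm_features
from gliomics.features import GLCM_NAMES, GLRLM_NAMES
from gliomics.features.texture import RoiTextureContext, _glrlm_counts, _glrlm_features_single

from _oracles import glcm_features_bruteforce, glrlm_features_bruteforce
from conftest import full_mask, make_mask, make_volume


def random_roi(rng, shape=(3, 3, 3), n_levels=4, p_mask=0.8):
    vol = make_volume(rng.integers(1, n_levels + 1, size=shape).astype(float))
    mask = make_mask((rng.uniform(size=shape) < p_mask).astype(np.uint8))
    if mask.values.sum() == 0:
        mask.values[0, 0, 0] = 1
    return vol, mask


class TestGlcm:
    def test_feature_names(self, rng):
        vol, mask = random_roi(rng)
        f = glcm_features(vol, mask, DiscretizationConfig(4))
        assert tuple(sorted(f)) == tuple(sorted(GLCM_NAMES)) and len(f) == 22

    def test_constant_roi_degenerate_values(self):
        vol = make_volume(np.full((3, 3, 3), 7.0))
        f = glcm_features(vol, full_mask((3, 3, 3)))
        assert f["Contrast"] == 0.0 and f["Dissimilarity"] == 0.0
        assert f["Maximum Probability"] == 1.0 and f["GLCM Energy"] == 1.0
        assert f["Informational Measure of Correlation 1"] == 0.0

    def test_two_by_two_checker_golden(self):
        """Hand enumeration: P = [[1/6, 1/3], [1/3, 1/6]] at 2 levels."""
        vol = make_volume(np.array([[[1.0], [2.0]], [[2.0], [1.0]]]))
        f = glcm_features(vol, full_mask((2, 2, 1)), DiscretizationConfig(2))
        assert f["Contrast"] == pytest.approx(2 / 3)
        assert f["GLCM Energy"] == pytest.approx(5 / 18)
        assert f["Maximum Probability"] == pytest.approx(1 / 3)
        assert f["Dissimilarity"] == pytest.approx(2 / 3)

    @pytest.mark.parametrize("seed", range(6))
    def test_oracle_equivalence_small_rois(self, seed):
        """<= 27-voxel ROIs match exhaustive pair enumeration to 1e-10 relative."""
        rng = np.random.default_rng(seed)
        vol, mask = random_roi(rng, n_levels=5)
        ours = glcm_features(vol, mask, DiscretizationConfig(5))
        oracle = glcm_features_bruteforce(vol.values, mask.values, 5)
        for name in GLCM_NAMES:
            assert ours[name] == pytest.approx(oracle[name], rel=1e-10, abs=1e-12), name

    def test_checkerboard_contrast_exceeds_smoothed(self):
        g = np.indices((6, 6, 6)).sum(axis=0) % 2
        checker = make_volume(g.astype(float))
        from scipy import ndimage

        smooth = make_volume(ndimage.uniform_filter(g.astype(float), 3))
        mask = full_mask((6, 6, 6))
        cfg = DiscretizationConfig(8)
        assert glcm_features(checker, mask, cfg)["Contrast"] > glcm_features(smooth, mask, cfg)["Contrast"]

    @pytest.mark.parametrize("axes", [(0, 1), (0, 2), (1, 2)])
    def test_rotation_90_invariance(self, rng, axes):
        vol, mask = random_roi(rng, shape=(5, 5, 5))
        cfg = DiscretizationConfig(4)
        a = glcm_features(vol, mask, cfg)
        b = glcm_features(
            make_volume(np.rot90(vol.values, axes=axes).copy()),
            make_mask(np.rot90(mask.values, axes=axes).copy()),
            cfg,
        )
        for name in GLCM_NAMES:
            assert a[name] == pytest.approx(b[name], abs=1e-8), name

    def test_intensity_shift_invariance(self, rng):
        vol, mask = random_roi(rng, shape=(4, 4, 4))
        cfg = DiscretizationConfig(6)
        a = glcm_features(vol, mask, cfg)
        b = glcm_features(make_volume(vol.values * 3.0 + 100.0), mask, cfg)
        for name in GLCM_NAMES:
            assert a[name] == pytest.approx(b[name], abs=1e-10), name


class TestGlrlm:
    def test_feature_names(self, rng):
        vol, mask = random_roi(rng)
        f = glrlm_features(vol, mask, DiscretizationConfig(4))
        assert tuple(sorted(f)) == tuple(sorted(GLRLM_NAMES)) and len(f) == 11

    def test_single_run_closed_form(self):
        """Constant 1xN line along one direction: one run of length N."""
        n = 5
        arr = np.full((n, 1, 1), 2.0)
        ctx = RoiTextureContext(np.ones((n, 1, 1)))
        # direction (1,0,0) is the first run order
        order, brk = ctx.run_orders[0]
        lv = np.ones(n, dtype=np.int64)
        counts = _glrlm_counts(lv[order], brk, 1)
        f = _glrlm_features_single(counts, n)
        assert f["Long Run Emphasis"] == pytest.approx(n**2)
        assert f["Run Percentage"] == pytest.approx(1.0 / n)

    def test_two_runs_golden(self):
        """1D values (1,1,2,2,2): runs {(1,2),(2,3)} along the axis."""
        ctx = RoiTextureContext(np.ones((5, 1, 1)))
        order, brk = ctx.run_orders[0]
        lv = np.array([1, 1, 2, 2, 2], dtype=np.int64)
        f = _glrlm_features_single(_glrlm_counts(lv[order], brk, 2), 5)
        assert f["Short Run Emphasis"] == pytest.approx((1 / 4 + 1 / 9) / 2)
        assert f["Long Run Emphasis"] == pytest.approx((4 + 9) / 2)
        assert f["Run Percentage"] == pytest.approx(2 / 5)
        assert f["Long Run High Gray Level Emphasis"] == pytest.approx((1 * 4 + 4 * 9) / 2)

    @pytest.mark.parametrize("seed", range(6))
    def test_oracle_equivalence_small_rois(self, seed):
        rng = np.random.default_rng(100 + seed)
        vol, mask = random_roi(rng, n_levels=3)
        ours = glrlm_features(vol, mask, DiscretizationConfig(3))
        oracle = glrlm_features_bruteforce(vol.values, mask.values, 3)
        for name in GLRLM_NAMES:
            assert ours[name] == pytest.approx(oracle[name], rel=1e-10), name

    def test_run_percentage_bounds(self, rng):
        for seed in range(4):
            vol, mask = random_roi(np.random.default_rng(seed), shape=(4, 4, 4))
            rp = glrlm_features(vol, mask, DiscretizationConfig(4))["Run Percentage"]
            assert 0.0 < rp <= 1.0

    def test_rotation_90_invariance(self, rng):
        vol, mask = random_roi(rng, shape=(4, 5, 4))
        cfg = DiscretizationConfig(4)
        a = glrlm_features(vol, mask, cfg)
        b = glrlm_features(
            make_volume(np.rot90(vol.values, axes=(0, 1)).copy()),
            make_mask(np.rot90(mask.values, axes=(0, 1)).copy()),
            cfg,
        )
        for name in GLRLM_NAMES:
            assert a[name] == pytest.approx(b[name], abs=1e-8), name
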