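"""Phantom cohort generator: determinism, geometry, class structure."""

import numpy as np
import pytest
from scipy import stats

from gliomics import (
    CohortSpec,
    DiscretizationConfig,
    clinical_table,
    generate_cohort,
    glcm_features,
    planted_feature_table,
    sample_tumor_mask,
)
from gliomics.errors import InfeasibleGeometryError, InvalidSpecError
from gliomics.features import shape_features


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_codel": 0},
            {"n_noncodel": -1},
            {"voxel_size_mm": 0.0},
            {"homogeneity_gap": -0.5},
            {"image_shape": (0, 10, 10)},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(InvalidSpecError):
            CohortSpec(**kwargs)

    def test_codeletion_implies_idh_mutant(self):
        recs = generate_cohort(CohortSpec(n_codel=3, n_noncodel=3, image_shape=(32,) * 3, seed=0))
        for r in recs:
            if r.label_1p19q == 1:
                assert r.idh == "mutant"


class TestTumorMask:
    def test_volume_within_ten_percent(self):
        rng = np.random.default_rng(0)
        mask = sample_tumor_mask((40, 40, 40), 1.0, 1.0, rng)
        assert 900 <= mask.n_voxels <= 1100

    def test_study_scale_volume(self):
        # 59.87 cm3 at 1-mm isotropic voxels
        rng = np.random.default_rng(1)
        mask = sample_tumor_mask((128, 128, 128), 1.0, 59.87, rng)
        assert 53883 <= mask.n_voxels <= 65857

    def test_sphere_constrained_axes_give_high_sphericity(self):
        rng = np.random.default_rng(2)
        mask = sample_tumor_mask((48, 48, 48), 1.0, 20.0, rng, axis_ratios=(1.0, 1.0, 1.0))
        assert shape_features(mask)["Sphericity"] >= 0.94

    def test_connected(self):
        from scipy import ndimage

        rng = np.random.default_rng(3)
        mask = sample_tumor_mask((40, 40, 40), 1.0, 5.0, rng)
        _, n = ndimage.label(mask.values)
        assert n == 1

    def test_infeasible_target_raises(self):
        rng = np.random.default_rng(4)
        with pytest.raises(InfeasibleGeometryError):
            sample_tumor_mask((16, 16, 16), 1.0, 59.87, rng)
        with pytest.raises(InfeasibleGeometryError):
            sample_tumor_mask((16, 16, 16), 1.0, -1.0, rng)


class TestCohort:
    def test_class_counts_exact(self):
        spec = CohortSpec(n_codel=5, n_noncodel=7, image_shape=(32,) * 3, seed=7)
        recs = generate_cohort(spec)
        labels = [r.label_1p19q for r in recs]
        assert len(recs) == 12 and sum(labels) == 5

    def test_seeded_determinism(self):
        spec = CohortSpec(n_codel=3, n_noncodel=3, image_shape=(32,) * 3, seed=1)
        a = generate_cohort(spec)
        b = generate_cohort(spec)
        for ra, rb in zip(a, b):
            assert ra.age_y == rb.age_y and ra.sex == rb.sex
            np.testing.assert_array_equal(ra.mask.values, rb.mask.values)
            for ch in ra.channels:
                np.testing.assert_array_equal(ra.channels[ch].values, rb.channels[ch].values)

    def test_channels_aligned_and_mask_nonempty(self, small_cohort):
        _, recs = small_cohort
        for r in recs:
            assert r.mask.n_voxels > 0
            shapes = {ch.values.shape for ch in r.channels.values()}
            assert shapes == {r.mask.values.shape}

    def test_written_cohort_roundtrip(self, tmp_path):
        spec = CohortSpec(n_codel=2, n_noncodel=2, image_shape=(24,) * 3, seed=3)
        recs = generate_cohort(spec, out_dir=tmp_path)
        assert (tmp_path / "clinical.csv").exists()
        from gliomics import load_mask

        m = load_mask(recs[0].mask_path)
        np.testing.assert_array_equal(m.values, recs[0].mask.values)

    def test_age_same_law_between_classes(self):
        # pooled over a few seeds: two-sample test should be non-significant
        ages1, ages0 = [], []
        for seed in range(3):
            spec = CohortSpec(n_codel=10, n_noncodel=10, image_shape=(24,) * 3, seed=seed)
            tab = clinical_table(generate_cohort(spec))
            ages1 += tab[tab.label_1p19q == 1].age.tolist()
            ages0 += tab[tab.label_1p19q == 0].age.tolist()
        p = stats.ttest_ind(ages1, ages0).pvalue
        assert p > 0.01


def _t2_texture(records, name):
    cfg = DiscretizationConfig(16)
    vals = np.array(
        [glcm_features(r.channels["T2WI"], r.mask, cfg)[name] for r in records]
    )
    y = np.array([r.label_1p19q for r in records])
    return vals[y == 1], vals[y == 0]


class TestTextureContrast:
    def test_homogeneity_contrast_direction_and_monotonicity(self):
        """Codeleted tumors show lower IMC2 and lower Cluster Tendency, and the
        class gap in IMC2 grows with the homogeneity knob."""
        gaps = {}
        for g in (0.6, 2.0):
            spec = CohortSpec(
                n_codel=6, n_noncodel=6, image_shape=(36,) * 3, homogeneity_gap=g, seed=42
            )
            recs = generate_cohort(spec)
            imc1, imc0 = _t2_texture(recs, "Informational Measure of Correlation 2")
            ct1, ct0 = _t2_texture(recs, "Cluster Tendency")
            gaps[g] = imc0.mean() - imc1.mean()
            assert ct1.mean() < ct0.mean()  # lower cluster tendency for codeletion
        assert gaps[0.6] > 0  # lower IMC for codeletion
        assert gaps[2.0] > gaps[0.6]

    def test_zero_gap_identical_distribution(self):
        """At gap 0 the class texture laws coincide (non-significant over seeds)."""
        diffs = []
        for seed in range(5):
            spec = CohortSpec(
                n_codel=5, n_noncodel=5, image_shape=(32,) * 3, homogeneity_gap=0.0, seed=seed
            )
            recs = generate_cohort(spec)
            h1, h0 = _t2_texture(recs, "Informational Measure of Correlation 2")
            diffs.extend(h1 - h0.mean())
        p = stats.ttest_1samp(diffs, 0.0).pvalue
        assert p > 0.01


def test_planted_table_structure():
    df, y, idh = planted_feature_table(n_codel=10, n_noncodel=14, n_signal=3, n_noise=5, seed=0)
    assert df.shape == (24, 3 + 5 + 2)
    assert y.sum() == 10
    assert (idh == "wildtype").sum() == round(16 / 92 * 14)
    # planted columns separate the classes, noise columns do not (in expectation)
    m = df.groupby(y).mean()
    assert (m.loc[1, [f"signal_{i}" for i in (1, 2, 3)]] > m.loc[0, [f"signal_{i}" for i in (1, 2, 3)]]).all()
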