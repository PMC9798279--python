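import numpy as np
import pytest

from hipposbm.synthetic import (
    Blob,
    PlacementError,
    SizingError,
    SyntheticConfig,
    default_blob_spec,
    generate_dataset,
    make_roi_mask,
    make_sources,
    make_subjects_and_loadings,
    synthesize_volumes,
)
from hipposbm.volume_io import apply_mask_and_stack


class TestRoiMask:
    def test_default_voxel_count_near_4115(self, default_mask):
        # 3 cc at 0.9 mm isotropic voxels
        assert abs(default_mask.n_voxels - 4115) / 4115 < 0.01

    def test_1mm_voxel_count_near_3000(self):
        mask = make_roi_mask((44, 52, 36), 1.0, seed=0)
        assert abs(mask.n_voxels - 3000) / 3000 < 0.01

    def test_mirror_symmetric(self, default_mask):
        assert np.array_equal(default_mask.values, default_mask.values[::-1, :, :])

    def test_two_disjoint_lobes(self, default_mask):
        from scipy import ndimage

        _, n = ndimage.label(default_mask.values, structure=np.ones((3, 3, 3)))
        assert n == 2

    def test_grid_too_small_raises(self):
        with pytest.raises(SizingError):
            make_roi_mask((10, 12, 10), 0.9, seed=0, total_volume_cc=3.0)

    def test_deterministic_given_seed(self):
        a = make_roi_mask((32, 38, 26), 0.9, seed=3, total_volume_cc=1.2)
        b = make_roi_mask((32, 38, 26), 0.9, seed=3, total_volume_cc=1.2)
        assert np.array_equal(a.values, b.values)


class TestSources:
    def test_standardized_in_mask(self, default_mask):
        S = make_sources(default_mask, default_blob_spec(default_mask), seed=0)
        assert np.all(np.abs(S.mean(axis=1)) < 1e-9)
        assert np.all(np.abs(S.std(axis=1) - 1) < 1e-9)

    def test_bilateral_source_suprathreshold_in_both_lobes(self, default_mask):
        S = make_sources(default_mask, default_blob_spec(default_mask), seed=0)
        coords = default_mask.voxel_index_map()
        mid = (default_mask.shape[0] - 1) / 2.0
        left = coords[:, 0] < mid
        z = S[0]  # bilateral by layout
        assert (np.abs(z[left]) > 3).sum() > 0
        assert (np.abs(z[~left]) > 3).sum() > 0

    def test_disjoint_blobs_nearly_uncorrelated(self, default_mask):
        curve = default_mask.lobe_axis_mm
        spec = [
            Blob(tuple(curve[10]), 1.5, "left"),
            Blob(tuple(curve[-10]), 1.5, "left"),
        ]
        S = make_sources(default_mask, spec, seed=1)
        assert abs(np.corrcoef(S)[0, 1]) < 0.05

    def test_default_layout_pairwise_correlation_bounded(self, default_mask):
        S = make_sources(default_mask, default_blob_spec(default_mask), seed=2)
        C = np.abs(np.corrcoef(S))
        np.fill_diagonal(C, 0)
        assert C.max() < 0.3

    def test_longitudinal_source_has_multiple_axis_bumps(self, default_mask):
        spec = default_blob_spec(default_mask)
        S = make_sources(default_mask, spec, seed=0)
        coords = default_mask.voxel_index_map()
        z = S[4]  # longitudinal by layout
        supra_y = coords[np.abs(z) > 3, 1]
        assert np.ptp(supra_y) > 8  # spans the long axis, not a single bump

    def test_blob_outside_mask_raises(self, default_mask):
        with pytest.raises(PlacementError):
            make_sources(default_mask, [Blob((0.5, 0.5, 0.5), 1.0, "left")], seed=0)


class TestSubjectsAndLoadings:
    def test_null_effect_means_near_zero(self):
        cfg = SyntheticConfig(group_effect=(0.0,) * 7, seed=5)
        _, A = make_subjects_and_loadings(cfg)
        se = 1 / np.sqrt(A.shape[0])
        assert np.all(np.abs(A.mean(axis=0)) < 3 * se)

    def test_planted_difference_recovered_at_large_n(self):
        cfg = SyntheticConfig(
            n_subjects_per_group=(1000, 1000),
            group_effect=(1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
            seed=17,
        )
        table, A = make_subjects_and_loadings(cfg)
        mdd = (table["group"] == "MDD").to_numpy()
        diff = A[mdd, 0].mean() - A[~mdd, 0].mean()
        assert 0.86 <= diff <= 1.14  # 3 sigma band, SE ~= 0.045

    def test_covariates_confounded_by_default(self):
        table, _ = make_subjects_and_loadings(SyntheticConfig(seed=3))
        mdd = table["group"] == "MDD"
        assert table.loc[mdd, "age"].mean() > table.loc[~mdd, "age"].mean() + 5
        assert table.loc[mdd, "education_years"].mean() < table.loc[~mdd, "education_years"].mean()

    def test_age_within_configured_range(self):
        table, _ = make_subjects_and_loadings(SyntheticConfig(seed=4))
        mdd = table["group"] == "MDD"
        assert table.loc[mdd, "age"].between(22, 73).all()
        assert table.loc[~mdd, "age"].between(20, 65).all()

    def test_seeded_rerun_identical(self):
        t1, A1 = make_subjects_and_loadings(SyntheticConfig(seed=9))
        t2, A2 = make_subjects_and_loadings(SyntheticConfig(seed=9))
        assert t1.equals(t2)
        assert np.array_equal(A1, A2)

    def test_negative_sd_rejected(self):
        from hipposbm.synthetic import CovariateSpec

        with pytest.raises(ValueError):
            CovariateSpec(50, -1.0, (20, 70), 12, 2.0, 0.5)


class TestVolumes:
    def test_noise_free_identity(self, small_dataset):
        cfg = small_dataset.config
        vols = synthesize_volumes(
            small_dataset.truth.A_true, small_dataset.truth.S_true, small_dataset.mask, 0.0
        )
        dm = apply_mask_and_stack(vols, small_dataset.mask)
        assert np.allclose(dm.X, small_dataset.truth.A_true @ small_dataset.truth.S_true)

    def test_residual_noise_sd_in_chi_band(self, default_mask):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((156, 2))
        S = make_sources(default_mask, default_blob_spec(default_mask, 2), seed=0)
        vols = synthesize_volumes(A, S, default_mask, 0.5, seed=1)
        dm = apply_mask_and_stack(vols, default_mask)
        resid = dm.X - A @ S
        per_voxel_sd = resid.std(axis=0)
        # with n=156 the sampling SD of a voxel's SD is ~0.5/sqrt(2*156)=0.028,
        # so the bulk (but not the extremes over ~4100 voxels) stays in band
        assert 0.44 <= per_voxel_sd.mean() <= 0.56
        assert np.mean((per_voxel_sd >= 0.44) & (per_voxel_sd <= 0.56)) >= 0.95

    def test_identical_seed_identical_volumes(self, default_mask):
        rng = np.random.default_rng(2)
        A = rng.standard_normal((3, 2))
        S = make_sources(default_mask, default_blob_spec(default_mask, 2), seed=0)
        v1 = synthesize_volumes(A, S, default_mask, 0.3, seed=7)
        v2 = synthesize_volumes(A, S, default_mask, 0.3, seed=7)
        assert all(np.array_equal(a.values, b.values) for a, b in zip(v1, v2))

    def test_out_of_mask_voxels_zero(self, small_dataset):
        vol = small_dataset.volumes[0]
        assert np.all(vol.values[~small_dataset.mask.values] == 0)

    def test_dimension_mismatch_raises(self, default_mask):
        S = make_sources(default_mask, default_blob_spec(default_mask, 2), seed=0)
        with pytest.raises(ValueError):
            synthesize_volumes(np.zeros((5, 3)), S, default_mask, 0.1)

    def test_smoothed_noise_option_runs(self, default_mask):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((2, 2))
        S = make_sources(default_mask, default_blob_spec(default_mask, 2), seed=0)
        vols = synthesize_volumes(A, S, default_mask, 0.5, seed=1, noise_fwhm_mm=2.0)
        dm = apply_mask_and_stack(vols, default_mask)
        resid = dm.X - A @ S
        # rescaled to the requested in-mask SD per subject
        assert resid.std(axis=1) == pytest.approx([0.5, 0.5], rel=0.01)


class TestConfigAndDeterminism:
    def test_group_effect_length_enforced(self):
        with pytest.raises(ValueError):
            SyntheticConfig(k_sources=3, group_effect=(0.5,))

    def test_generate_dataset_reproducible(self):
        from conftest import small_config

        d1 = generate_dataset(small_config(seed=21))
        d2 = generate_dataset(small_config(seed=21))
        assert d1.table.equals(d2.table)
        assert np.array_equal(d1.truth.S_true, d2.truth.S_true)
        assert all(
            np.array_equal(a.values, b.values) for a, b in zip(d1.volumes, d2.volumes)
        )
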