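import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hipposbm.synthetic import SyntheticConfig, generate_dataset, make_roi_mask
from hipposbm.volume_io import apply_mask_and_stack, gaussian_smooth

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def small_config(**overrides) -> SyntheticConfig:
    """Reduced-scale study: smaller grid/ROI, 30+32 subjects, 4 sources."""
    kwargs = dict(
        grid_shape=(32, 38, 26),
        voxel_size_mm=0.9,
        total_volume_cc=1.2,
        n_subjects_per_group=(30, 32),
        k_sources=4,
        group_effect=(0.8, -0.8, 0.0, 0.0),
        noise_sd=0.25,
        seed=11,
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


@pytest.fixture(scope="session")
def default_mask():
    """Full-scale bilateral ROI: ~4115 voxels at 0.9 mm."""
    return make_roi_mask(seed=1)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(small_config())


@pytest.fixture(scope="session")
def small_data_matrix(small_dataset):
    smoothed = [gaussian_smooth(v, 3.0) for v in small_dataset.volumes]
    return apply_mask_and_stack(
        smoothed, small_dataset.mask, list(small_dataset.table["subject_id"])
    )


@pytest.fixture(scope="session")
def default_dataset():
    """Full-scale study conditions: ~4115 voxels, 77+79 subjects, 7 sources."""
    return generate_dataset(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def default_decomposition(default_dataset):
    """Single Infomax run on the unsmoothed full-scale matrix at true K."""
    from hipposbm import sbm

    ds = default_dataset
    dm = apply_mask_and_stack(ds.volumes, ds.mask, list(ds.table["subject_id"]))
    Xc, _ = sbm.center_matrix(dm.X)
    Z, _, dw = sbm.pca_whiten(Xc, ds.config.k_sources)
    W, S, _ = sbm.infomax_ica(Z, seed=100)
    A, S = sbm.back_reconstruct(Xc, S, dw, W)
    return ds, A, S


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
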