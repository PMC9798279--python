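"""Seeded synthetic data: a bilateral ROI, planted spatial sources, subject
tables with confounded covariates, and noisy grey-matter volumes.

The generator emulates the statistical structure the analysis assumes: a
subjects-by-voxels matrix that is (up to additive voxel noise) a product of
per-subject loading coefficients and spatially sparse, approximately
independent sources confined to a bilateral region of interest. Two groups
(MDD and HS) differ by a mean shift in the loadings of selected components
and, by default, by age/sex/education distributions, so that
covariate-adjusted inference is actually exercised.

Everything is a pure function of (config, seed): identical seeds reproduce
identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .volume_io import ROIMask, VolumeGrid, scatter_to_volume, voxel_count, write_mask, write_volume

__all__ = [
    "Blob",
    "CovariateSpec",
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticDataset",
    "SizingError",
    "PlacementError",
    "make_roi_mask",
    "default_blob_spec",
    "make_sources",
    "make_subjects_and_loadings",
    "synthesize_volumes",
    "generate_dataset",
    "write_dataset",
]

Laterality = Literal["left", "right", "bilateral", "longitudinal"]


class SizingError(ValueError):
    """Grid too small to hold the requested ROI."""


class PlacementError(ValueError):
    """A source blob falls entirely outside the mask."""


@dataclass(frozen=True)
class Blob:
    """One planted source shape: a Gaussian bump (or a homotopic/axial set).

    center_mm is in the grid's mm frame (voxel (0,0,0) centre at the origin);
    radius_mm is the Gaussian sigma of the bump.
    """

    center_mm: tuple[float, float, float]
    radius_mm: float
    laterality: Laterality

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("blob radius must be positive")


@dataclass(frozen=True)
class CovariateSpec:
    """Per-group covariate distributions (defaults mirror a first-episode
    drug-naive MDD cohort vs healthy subjects: older, less educated patients)."""

    age_mean: float
    age_sd: float
    age_range: tuple[float, float]
    education_mean: float
    education_sd: float
    p_female: float

    def __post_init__(self) -> None:
        if self.age_sd <= 0 or self.education_sd <= 0:
            raise ValueError("covariate SDs must be positive")
        if not 0 <= self.p_female <= 1:
            raise ValueError("p_female must be a probability")


MDD_COVARIATES = CovariateSpec(
    age_mean=52.0, age_sd=15.1, age_range=(22.0, 73.0),
    education_mean=13.4, education_sd=2.5, p_female=44 / 77,
)
HS_COVARIATES = CovariateSpec(
    age_mean=38.9, age_sd=10.2, age_range=(20.0, 65.0),
    education_mean=16.7, education_sd=3.0, p_female=34 / 79,
)


@dataclass
class SyntheticConfig:
    """Study-scale defaults: 77 MDD + 79 HS subjects, a ~3 cc bilateral ROI on
    a 0.9 mm grid, seven planted sources of which two carry opposite-signed
    0.6 SD group shifts in their loadings, and i.i.d. voxel noise."""

    grid_shape: tuple[int, int, int] = (44, 52, 36)
    voxel_size_mm: float = 0.9
    total_volume_cc: float = 3.0
    n_subjects_per_group: tuple[int, int] = (77, 79)  # (MDD, HS)
    k_sources: int = 7
    blob_spec: list[Blob] | None = None
    group_effect: tuple[float, ...] = (0.6, -0.6, 0.0, 0.0, 0.0, 0.0, 0.0)
    noise_sd: float = 0.25
    noise_fwhm_mm: float = 0.0  # >0 smooths the noise field (spatially correlated noise)
    covariate_spec: dict[str, CovariateSpec] = field(
        default_factory=lambda: {"MDD": MDD_COVARIATES, "HS": HS_COVARIATES}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_sources < 1:
            raise ValueError("k_sources must be >= 1")
        if len(self.group_effect) != self.k_sources:
            raise ValueError("group_effect must have one entry per source")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")
        if any(n < 2 for n in self.n_subjects_per_group):
            raise ValueError("need at least 2 subjects per group")

    @property
    def affected_components(self) -> list[int]:
        return [k for k, g in enumerate(self.group_effect) if g != 0.0]


@dataclass
class GroundTruth:
    """Planted sources and loadings for recovery scoring."""

    S_true: np.ndarray  # k_sources x V, standardized over in-mask voxels
    A_true: np.ndarray  # N x k_sources
    affected_components: list[int]


@dataclass
class SyntheticDataset:
    mask: ROIMask
    volumes: list[VolumeGrid]
    table: pd.DataFrame
    truth: GroundTruth
    config: SyntheticConfig


# --------------------------------------------------------------------------
# ROI mask: two mirror-symmetric curved lobes
# --------------------------------------------------------------------------

def _left_lobe_curve(
    grid_shape: Sequence[int], voxel_size_mm: float, rng: np.random.Generator | None = None,
    n_points: int = 160,
) -> np.ndarray:
    """Sampled centreline of the left lobe in mm, a gently curved arc running
    along the grid's y axis (the long, 'longitudinal' axis of the structure)."""
    nx, ny, nz = grid_shape
    Lx, Ly, Lz = ((n - 1) * voxel_size_mm for n in grid_shape)
    jx = jz = 0.0
    if rng is not None:
        jx, jz = rng.uniform(-0.01, 0.01, size=2)
    t = np.linspace(0.0, 1.0, n_points)
    x = (0.26 + jx) * Lx + 0.055 * Lx * np.sin(np.pi * t)
    y = 0.16 * Ly + 0.68 * Ly * t
    z = (0.34 + jz) * Lz + 0.22 * Lz * t
    return np.column_stack([x, y, z])


def _lobe_radius_profile(t: np.ndarray, r0: float) -> np.ndarray:
    # anterior (t=0) pole fatter than the tail, like a hippocampal body
    return r0 * (1.25 - 0.45 * t)


def _lobe_distance_field(
    grid_shape: Sequence[int], voxel_size_mm: float, curve: np.ndarray
) -> np.ndarray:
    """Per-voxel min over curve points of squared distance divided by the
    squared (unit) radius profile; the lobe is {Q <= r0^2} for base radius
    r0, so the in-lobe count is a quantile of Q."""
    nx, ny, nz = grid_shape
    ax = np.arange(nx) * voxel_size_mm
    ay = np.arange(ny) * voxel_size_mm
    az = np.arange(nz) * voxel_size_mm
    t = np.linspace(0.0, 1.0, len(curve))
    prof2 = _lobe_radius_profile(t, 1.0) ** 2
    dx2 = (ax[:, None] - curve[:, 0][None, :]) ** 2  # nx x M
    dy2 = (ay[:, None] - curve[:, 1][None, :]) ** 2
    dz2 = (az[:, None] - curve[:, 2][None, :]) ** 2
    Q = np.full(grid_shape, np.inf)
    for m in range(len(curve)):
        d2 = dx2[:, m][:, None, None] + dy2[:, m][None, :, None] + dz2[:, m][None, None, :]
        np.minimum(Q, d2 / prof2[m], out=Q)
    return Q


def make_roi_mask(
    grid_shape: Sequence[int] = (44, 52, 36),
    voxel_size_mm: float = 0.9,
    seed: int | None = None,
    total_volume_cc: float = 3.0,
) -> ROIMask:
    """Build a bilateral ROI of two mirror-symmetric curved lobes.

    The total in-mask volume is calibrated (by bisection on the lobe radius)
    to ``total_volume_cc``; at the default 3 cc and 0.9 mm isotropic voxels
    the mask holds ~4115 voxels. The mask is exactly mirror-symmetric across
    the mid-sagittal plane by construction, and its left-lobe centreline is
    kept on the object for downstream source placement.
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    if min(grid_shape) < 8:
        raise SizingError(f"grid {grid_shape} too small to hold two lobes")
    rng = None if seed is None else np.random.default_rng(seed)
    curve = _left_lobe_curve(grid_shape, voxel_size_mm, rng)

    target_total = total_volume_cc * 1000.0 / voxel_size_mm**3
    n_lobe = int(round(target_total / 2.0))
    Q = _lobe_distance_field(grid_shape, voxel_size_mm, curve)
    if n_lobe >= Q.size:
        raise SizingError(f"grid {grid_shape} too small for a {total_volume_cc} cc ROI")
    # the n_lobe-th smallest normalized distance sets the lobe radius exactly
    thresh = np.partition(Q.ravel(), n_lobe - 1)[n_lobe - 1]
    left = Q <= thresh
    n_lobe = int(left.sum())  # ties can add a voxel or two
    if abs(2 * n_lobe - target_total) / target_total > 0.008:
        raise SizingError(
            f"could not calibrate ROI to {total_volume_cc} cc on grid {grid_shape} "
            f"(best: {2 * n_lobe} voxels vs target {target_total:.0f})"
        )
    right = left[::-1, :, :]
    if (left & right).any():
        raise SizingError("lobes overlap across the midline; grid too narrow")
    values = left | right
    # lobes must sit clear of the grid faces (room for smoothing support)
    if (
        values[0].any() or values[-1].any()
        or values[:, 0].any() or values[:, -1].any()
        or values[:, :, 0].any() or values[:, :, -1].any()
    ):
        raise SizingError("ROI touches the grid boundary; enlarge the grid")
    return ROIMask(
        values=values,
        voxel_size_mm=(voxel_size_mm,) * 3,
        origin_mm=(0.0, 0.0, 0.0),
        lobe_axis_mm=curve,
    )


def _mirror_mm(center: np.ndarray, grid_shape: Sequence[int], voxel_size_mm: float) -> np.ndarray:
    out = np.array(center, dtype=float)
    out[0] = (grid_shape[0] - 1) * voxel_size_mm - out[0]
    return out


# --------------------------------------------------------------------------
# Sources
# --------------------------------------------------------------------------

def default_blob_spec(mask: ROIMask, k_sources: int = 7, radius_mm: float = 2.2) -> list[Blob]:
    """Blob layout for up to 7 sources: four homotopic bilateral bumps spread
    head-to-tail plus three alternating-sign chains along one lobe's long axis
    (mirroring the bilateral / longitudinal-axis network taxonomy). Bilateral
    bumps sit dorsal and axial chains ventral of the centreline so the two
    families stay approximately uncorrelated."""
    if mask.lobe_axis_mm is None:
        raise ValueError("mask has no stored lobe axis; supply blob_spec explicitly")
    curve = mask.lobe_axis_mm
    M = len(curve)

    def at(tpos: float, dz: float) -> tuple[float, float, float]:
        p = curve[int(round(tpos * (M - 1)))].copy()
        p[2] += dz
        return tuple(p)

    vx = mask.voxel_size_mm[0]
    layout: list[Blob] = [
        Blob(at(0.10, +1.8), radius_mm, "bilateral"),
        Blob(at(0.38, +1.8), radius_mm, "bilateral"),
        Blob(at(0.64, +1.8), radius_mm, "bilateral"),
        Blob(at(0.90, +1.8), radius_mm, "bilateral"),
        Blob(at(0.26, -2.2), radius_mm, "longitudinal"),
        Blob(
            tuple(_mirror_mm(np.array(at(0.52, -2.2)), mask.shape, vx)),
            radius_mm,
            "longitudinal",
        ),
        Blob(at(0.78, -2.2), radius_mm, "longitudinal"),
    ]
    if k_sources > len(layout):
        raise ValueError(f"default layout supports up to {len(layout)} sources")
    return layout[:k_sources]


def _bump_centers(
    blob: Blob, mask: ROIMask
) -> list[tuple[np.ndarray, float]]:
    """Expand a blob into (center_mm, amplitude) bumps by laterality."""
    vx = mask.voxel_size_mm[0]
    c = np.array(blob.center_mm, dtype=float)
    if blob.laterality == "left":
        return [(c, 1.0)]
    if blob.laterality == "right":
        return [(_mirror_mm(c, mask.shape, vx), 1.0)]
    if blob.laterality == "bilateral":
        return [(c, 1.0), (_mirror_mm(c, mask.shape, vx), 1.0)]
    # longitudinal: >=2 bumps along the lobe's long axis, alternating sign so
    # the source expresses anterior-posterior differentiation
    curve = mask.lobe_axis_mm
    midline = 0.5 * (mask.shape[0] - 1) * vx
    on_right = c[0] > midline
    c_left = _mirror_mm(c, mask.shape, vx) if on_right else c
    if curve is None:
        offsets = np.array([[0.0, -5.0, 0.0], [0.0, 0.0, 0.0], [0.0, 5.0, 0.0]])
        pts = [c_left + o for o in offsets]
    else:
        i0 = int(np.argmin(np.sum((curve - c_left) ** 2, axis=1)))
        off = c_left - curve[i0]  # keep any deliberate offset from the centreline
        step = max(1, int(round(0.18 * (len(curve) - 1))))
        idx = np.clip([i0 - step, i0, i0 + step], 0, len(curve) - 1)
        pts = [curve[i] + off for i in idx]
    if on_right:
        pts = [_mirror_mm(p, mask.shape, vx) for p in pts]
    amps = [1.0, -1.0, 1.0][: len(pts)]
    return list(zip(pts, amps))


def make_sources(
    mask: ROIMask, blob_spec: Sequence[Blob], seed: int | None = None
) -> np.ndarray:
    """Build the k x V matrix of planted sources.

    Each source is a sum of isotropic Gaussian bumps restricted to the mask,
    standardized to mean 0 / SD 1 over in-mask voxels. The seed applies a
    small (+/-5%) per-bump amplitude jitter so repeated draws are not
    byte-identical shapes while the layout stays fixed.
    """
    rng = np.random.default_rng(seed)
    coords_vox = mask.voxel_index_map().astype(float)
    coords_mm = coords_vox * np.asarray(mask.voxel_size_mm)[None, :]
    V = coords_mm.shape[0]
    S = np.empty((len(blob_spec), V), dtype=float)
    for k, blob in enumerate(blob_spec):
        f = np.zeros(V)
        peak_scale = 0.0
        for center, amp in _bump_centers(blob, mask):
            jit = 1.0 + rng.uniform(-0.05, 0.05)
            d2 = np.sum((coords_mm - center[None, :]) ** 2, axis=1)
            f += amp * jit * np.exp(-d2 / (2.0 * blob.radius_mm**2))
            peak_scale = max(peak_scale, abs(amp) * jit)
        if np.max(np.abs(f)) < peak_scale * np.exp(-4.5):
            raise PlacementError(
                f"blob {k} at {blob.center_mm} lies outside the mask (no support within 3 sigma)"
            )
        S[k] = (f - f.mean()) / f.std()
    return S


# --------------------------------------------------------------------------
# Subjects and loadings
# --------------------------------------------------------------------------

def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def make_subjects_and_loadings(config: SyntheticConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw the subject table and the N x K ground-truth loading matrix.

    Loading columns are standard normal across subjects; the configured group
    effect (in SD units) is then added to the MDD rows of affected
    components. Covariates are drawn per group from the configured
    distributions, confounded by default (patients older, less educated).
    """
    rng = np.random.default_rng(config.seed)
    n_mdd, n_hs = config.n_subjects_per_group
    rows = []
    for group, n in (("MDD", n_mdd), ("HS", n_hs)):
        spec = config.covariate_spec[group]
        age = _truncated_normal(rng, spec.age_mean, spec.age_sd, *spec.age_range, n=n)
        edu = np.clip(rng.normal(spec.education_mean, spec.education_sd, size=n), 6.0, None)
        female = rng.random(n) < spec.p_female
        for i in range(n):
            rows.append(
                {
                    "group": group,
                    "age": float(age[i]),
                    "sex": "F" if female[i] else "M",
                    "education_years": float(edu[i]),
                }
            )
    table = pd.DataFrame(rows)
    table.insert(0, "subject_id", [f"s{i + 1:03d}" for i in range(len(table))])

    N = n_mdd + n_hs
    A = rng.standard_normal((N, config.k_sources))
    is_mdd = (table["group"] == "MDD").to_numpy()
    for k, g in enumerate(config.group_effect):
        if g != 0.0:
            A[is_mdd, k] += g
    return table, A


# --------------------------------------------------------------------------
# Volumes
# --------------------------------------------------------------------------

def synthesize_volumes(
    A_true: np.ndarray,
    S_true: np.ndarray,
    mask: ROIMask,
    noise_sd: float = 0.25,
    seed: int | None = None,
    noise_fwhm_mm: float = 0.0,
) -> list[VolumeGrid]:
    """Render per-subject volumes: in-mask voxels are sum_k A[i,k] S[k,:]
    plus Gaussian noise; out-of-mask voxels are zero.

    With ``noise_fwhm_mm > 0`` the noise field is smoothed on the full grid
    and rescaled to SD ``noise_sd`` in-mask, giving spatially correlated
    noise like real modulated GM maps.
    """
    A_true = np.asarray(A_true, dtype=float)
    S_true = np.asarray(S_true, dtype=float)
    if A_true.shape[1] != S_true.shape[0]:
        raise ValueError(
            f"loading columns ({A_true.shape[1]}) must match source rows ({S_true.shape[0]})"
        )
    if S_true.shape[1] != mask.n_voxels:
        raise ValueError("source voxel count does not match mask")
    rng = np.random.default_rng(seed)
    Y = A_true @ S_true
    if noise_sd > 0:
        if noise_fwhm_mm > 0:
            from .volume_io import gaussian_smooth

            flat = mask.flat_index()
            noise_rows = []
            for _ in range(Y.shape[0]):
                grid = rng.standard_normal(mask.shape)
                vol = VolumeGrid(grid, mask.voxel_size_mm, mask.origin_mm)
                sm = gaussian_smooth(vol, noise_fwhm_mm).values.ravel(order="F")[flat]
                noise_rows.append(sm / sm.std())
            Y = Y + noise_sd * np.vstack(noise_rows)
        else:
            Y = Y + noise_sd * rng.standard_normal(Y.shape)
    return [scatter_to_volume(Y[i], mask) for i in range(Y.shape[0])]


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """One-call generator: mask, sources, subjects, volumes, ground truth.

    Stage seeds are derived from ``config.seed`` via a seed sequence so the
    whole dataset is a pure function of the config.
    """
    config = config if config is not None else SyntheticConfig()
    ss = np.random.SeedSequence(config.seed)
    s_mask, s_src, s_vol = (int(s) for s in ss.generate_state(3) % (2**31))
    mask = make_roi_mask(
        config.grid_shape, config.voxel_size_mm, seed=s_mask, total_volume_cc=config.total_volume_cc
    )
    blob_spec = config.blob_spec
    if blob_spec is None:
        blob_spec = default_blob_spec(mask, config.k_sources)
    S_true = make_sources(mask, blob_spec, seed=s_src)
    table, A_true = make_subjects_and_loadings(config)
    volumes = synthesize_volumes(
        A_true, S_true, mask, config.noise_sd, seed=s_vol, noise_fwhm_mm=config.noise_fwhm_mm
    )
    truth = GroundTruth(S_true=S_true, A_true=A_true, affected_components=config.affected_components)
    return SyntheticDataset(mask=mask, volumes=volumes, table=table, truth=truth, config=config)


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    """Persist volumes/mask as NIfTI-1 (.nii.gz), the subject table as TSV,
    and the ground truth as compressed matrices plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_mask(dataset.mask, out / "roi_mask.nii.gz")
    for sid, vol in zip(dataset.table["subject_id"], dataset.volumes):
        write_volume(vol, out / f"{sid}_gm.nii.gz")
    dataset.table.to_csv(out / "subjects.tsv", sep="\t", index=False)
    np.savez_compressed(
        out / "ground_truth.npz", S_true=dataset.truth.S_true, A_true=dataset.truth.A_true
    )
    manifest = {
        "affected_components": dataset.truth.affected_components,
        "k_sources": dataset.config.k_sources,
        "noise_sd": dataset.config.noise_sd,
        "seed": dataset.config.seed,
        "grid_shape": list(dataset.config.grid_shape),
        "voxel_size_mm": dataset.config.voxel_size_mm,
    }
    (out / "ground_truth.json").write_text(json.dumps(manifest, indent=2))
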