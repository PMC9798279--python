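# Methods

## Model

The analysis decomposes a subjects-by-voxels matrix **X** (N subjects,
V in-ROI voxels of smoothed, modulated grey-matter density) as
**X** ≈ **A S**: K spatial sources **S** (K×V) and loading coefficients
**A** (N×K). Voxel (column) means are removed before decomposition; row
means are kept, so the N×N subject-space covariance
C = X_c X_cᵀ / V retains between-subject structure. Note that column
centring makes the rows of X_c sum to zero, so C always has one zero
eigenvalue and the usable rank is N − 1.

**Order selection.** The classic Wax–Kailath MDL criterion on the
eigenvalues λ₁ ≥ … ≥ λ_N of C:

MDL(k) = −V (N−k) log(g_k / a_k) + ½ k (2N−k) log V,

with g_k, a_k the geometric/arithmetic means of λ_{k+1..N}; the zero
eigenvalue from centring is excluded and N taken as the positive-spectrum
size. The criterion assumes i.i.d. samples across voxels. That assumption
is reasonable for unsmoothed data (where the implementation recovers
planted ranks reliably, see the tests), but 3 mm FWHM smoothing of a
~4100-voxel ROI leaves on the order of 10² effectively independent spatial
samples — fewer than N = 156 — and the uncorrected criterion then saturates
at k_max. A data-driven effective-sample correction is no help here because
in a small ROI the *signal*, not the noise, dominates neighbour
correlations. The pipeline therefore computes and records the MDL count on
every run but defaults to a fixed K = 7 for the synthetic study; both
numbers appear in the run manifest, and `k_policy="mdl"` switches the
pipeline to the data-determined order.

**Whitening.** PCA to the top K subject-space axes;
Z = D^{-1/2} Eᵀ X_c is K×V with Z Zᵀ/V = I; the dewhitening matrix
E D^{1/2} maps back.

**Infomax ICA.** Plain (non-extended) Infomax with the logistic
nonlinearity y = 1/(1+e^{−u}): natural-gradient updates
ΔW = η (I + (1−2y) uᵀ / B) W over random mini-batches of B ≈ √(V/3)
voxels. The logistic score separates super-Gaussian sources, which is the
right regime for sparse spatial maps (it provably cannot separate
sub-Gaussian sources such as uniform noise — the recovery tests use
Laplace sources for exactly this reason). Defaults: η₀ = 0.01/log K,
halved whenever successive full-pass updates turn by more than 60°
(oscillation), stop when ‖ΔW‖_F < 10⁻⁵ or after 512 passes
(non-convergence is recorded, not raised), and up to 3 restarts with a
halved η₀ if W diverges. With a fixed seed the run is bit-reproducible.

**Back-reconstruction.** A = dewhitening · W⁻¹, so X_topK = A S. Each
source row is standardized to unit SD (scale absorbed into A) and
sign-fixed so its largest-magnitude voxel is positive — the permutation
and sign ambiguities of ICA are thereby pinned to a reproducible
convention, and recovery scoring always matches estimated to planted
components by Hungarian assignment on |corr|, which is label- and
sign-free.

**ICASSO stability.** ICA is repeated n_runs = 20 times (RandInit: new
random W₀, same data; bootstrap resampling is out of scope). All R·K
run-components are compared by σ_ij = |corr| over voxels;
average-linkage agglomerative clustering of 1 − σ is cut at K clusters.
Per cluster: Iq = mean intra-cluster σ − mean σ to all non-members
(1 for a tight, isolated cluster; invariant to sign flips); the
centrotype is the member with the largest summed intra-cluster σ. A
perfectly stable component recurs once per run, so cluster sizes outside
[16, 20] (i.e. missing from >4 of 20 runs, or absorbing components from
several clusters) are flagged, as are clusters with Iq below 0.8; flags
are advisory — components are excluded from inference only when the
pipeline is configured to do so. Final loadings are re-estimated against
the standardized centrotype sources by least squares on X_c.

**Component maps.** Sources are z-scaled over in-mask voxels and
thresholded at |z| > 3.0; positive and negative excursions are labelled
separately with 26-connectivity; clusters below 0.1 cc are omitted from
reports; side is the peak's x relative to the grid's mid-sagittal plane.
The artifact heuristic flags a component when more than half of its
suprathreshold voxels lie on the one-voxel boundary shell of the ROI (the
footprint of edge/registration artifacts); it replaces, imperfectly, the
expert visual review used for real data.

**Group inference.** Demographics: Welch t (age, education) and Pearson
χ² without continuity correction (sex). Loadings: per component, OLS of
loading ~ intercept + group + age + sex(F=1) + education; F for the group
term with (1, N−5) df, partial η² = SS_group/(SS_group+SS_err); the
omnibus Wilks' Λ for the group term across all components is reported
alongside (with one hypothesis df Rao's F is exact; cross-checked against
statsmodels' MANOVA). Significance uses Bonferroni α = 0.05/K (0.05/7
displays as 0.007). Prediction: maximum-likelihood binomial logistic
regression of diagnosis on the K loadings only (unstandardized, no
demographic predictors, no regularization); Wald 95% CIs on the odds-ratio
scale; perfect separation raises an error rather than returning divergent
estimates. ROC: AUC by the Mann–Whitney rank statistic with ties counted
½ (equal to trapezoidal integration of the empirical curve); confusion
metrics at probability cutoff 0.5, ties classified positive, reported as
percentages with MDD positive. All classification metrics are apparent
(in-sample) — there is no train/test split, matching how such figures are
usually reported in small clinical samples; treat them as upper bounds.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not MRI physics:

- **ROI**: two mirror-symmetric curved lobes (a banana-shaped tube around
  a parametric centreline, radius tapering tail-ward), calibrated by a
  distance-field quantile so the total volume hits 3 cc exactly up to
  voxel ties — 4116 voxels at 0.9 mm, 3000 at 1 mm. Exactly
  mirror-symmetric by construction.
- **Sources**: isotropic Gaussian bumps (σ = 2.2 mm default) restricted
  to the mask and standardized over in-mask voxels. The default 7-source
  layout mirrors the two network families seen in hippocampal SBM: four
  homotopic bilateral pairs spread head-to-tail, and three alternating-sign
  chains along one lobe's long axis. Bilateral bumps sit slightly dorsal
  and axial chains ventral of the centreline, keeping pairwise |corr|
  below 0.3 (typically < 0.2). Exact ICA recovery is only possible up to
  this residual correlation; the exact-recovery tests use disjoint blobs.
- **Subjects**: 77 MDD / 79 HS. Covariates are confounded by default as
  in a first-episode drug-naive cohort: age ~ N(52.0, 15.1²) truncated to
  [22, 73] for MDD vs N(38.9, 10.2²) on [20, 65] for HS; education
  13.4(2.5) vs 16.7(3.0) years; P(female) 44/77 vs 34/79 — so the
  covariate adjustment in the group tests is actually exercised.
- **Loadings**: columns ~ N(0, 1); the MDD rows of affected components are
  shifted by the configured effect. Default: components 0 and 1 at
  +0.6/−0.6 SD — two affected networks with opposite directions, the
  pattern seen in the motivating logistic results (one odds ratio above,
  one below 1). The magnitude is a recoverability choice; nothing in a
  real dataset pins it.
- **Noise**: i.i.d. N(0, 0.25²) per in-mask voxel by default; an optional
  smoothed-noise mode generates spatially correlated noise fields.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: registration/segmentation error, spatially
structured (non-stationary) noise, anatomical covariance gradients, and
heavy-tailed source maps. The last one matters for the cluster reports:
a unit-SD-scaled compact bump in a ~4100-voxel ROI cannot place more than
roughly 0.07 cc above |z| = 3 (larger coverage lowers the relative peak,
and smoothing erodes the supra region), so synthetic cluster tables at
the real-data 0.1 cc floor are nearly empty; the map driver reports at
0.03 cc for illustration. Real hippocampal maps are much heavier-tailed
(peak z up to ~9) and do produce 0.1–0.8 cc clusters.

## Numerical choices and degenerate inputs

- Voxel order is x-fastest (Fortran raster); fixed for reproducibility.
- Smoothing uses nearest (constant) boundary extension to avoid edge
  dimming in a small ROI; σ = FWHM/(2√(2 ln 2)) per axis in voxel units.
- `voxel_count` floors (3000/0.729 → 4115).
- A loading explained exactly by the covariates yields zero residual in
  both nested models; the group F is defined as 0 (p = 1) there.
- Constant logistic predictors are excluded from the likelihood and
  reported with coefficient 0 (odds ratio 1, undefined CI).
- Zero-variance sources raise degenerate-source errors in z-scaling;
  singular unmixing matrices raise numeric errors.
- One master seed drives every stochastic stage through spawned seed
  sequences (generator, per-run ICA initializations); reruns are
  byte-identical.

## Problem sizes

The test suite and the acceptance script run the full study scale
(N = 156, V ≈ 4100, K = 7, 20 ICASSO runs) wherever a claim depends on
it — recovery, stability, and end-to-end detection sweep 10 seeds each —
and reduced scales (smaller grids, 62 subjects, 4–6 ICASSO runs) for
contract and invariance checks where scale is irrelevant.

## Known limitations

- The detection power of the default study is modest by design: with a
  0.6 SD loading shift and n = 77/79, the realized group difference has
  SE ≈ 0.16 and the per-component probability of clearing the 0.007
  Bonferroni bar is ≈ 0.75; detecting *both* planted components in one
  run happens in roughly half of seeds. The evaluation reports this
  honestly rather than inflating the planted effect.
- Subject-space MDL is unreliable for small, smooth ROIs (see above); the
  component count on real data should be treated as an analyst decision
  informed by, not dictated by, the criterion.
- The artifact flag is a coarse geometric proxy for expert review.
- Apparent (in-sample) classification metrics; optional cross-validation
  is deliberately out of scope here.
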