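# hipposbm

Source-based morphometry (SBM) of the hippocampus: structural-covariance
networks from conventional T1 grey-matter maps, and their use to detect and
predict major depressive disorder (MDD).

## The problem

The hippocampus is small (~3 cc): at the 0.9 mm isotropic resolution of
structural imaging it holds ~4115 voxels, versus ~375 at the 2 mm of
high-resolution fMRI/DTI — so structural imaging is the only conventional
modality fine enough to resolve *intra*-hippocampal networks. SBM treats the
N×V matrix **X** of N subjects' modulated grey-matter values over V ROI
voxels as a linear mixture

```
X ≈ A · S
```

where the K rows of **S** are spatial sources (structural covariance
networks, voxels whose volumes co-vary across subjects) and **A** holds each
subject's loading coefficients — the per-subject expression of each network.
The decomposition is estimated by Infomax independent component analysis
(natural-gradient entropy maximization with a logistic nonlinearity) after
PCA whitening, with the model order chosen by the minimum description length
(MDL) criterion on the subject-space eigenspectrum, and stabilized by
ICASSO: ICA is repeated 20 times from random initializations, components are
clustered across runs by absolute spatial correlation, and each cluster's
centrotype becomes the canonical component, with a quality index Iq and the
cluster-size band [16, 20] flagging unreliable components. Sources are
displayed as z-maps thresholded at |z| > 3; loadings are tested per
component by covariate-adjusted (age, sex, education) group F-tests with
Bonferroni control (0.05/7 ≈ 0.007), and diagnosis is predicted from the
loadings alone by binomial logistic regression with ROC evaluation.

Because the study's MRI data are not deposited, the package ships a seeded
synthetic-data module that generates a mirror-symmetric two-lobe ROI
(calibrated to 3 cc ≈ 4115 voxels at 0.9 mm), planted bilateral and
longitudinal-axis sources, Table-1-style confounded covariates, and group
mean-shifts on selected loadings — so the whole analysis runs, and can be
scored against ground truth, with no download.

## Worked example

The numbered drivers under `analysis/` run the study end to end on the
synthetic cohort (77 MDD / 79 HS):

```bash
python analysis/01_simulate.py          # volumes + mask + truth -> scratch/
python analysis/02_decompose.py         # smoothing, ICASSO Infomax ICA
python analysis/03_component_maps.py    # thresholded z-map cluster table
python analysis/04_group_inference.py   # demographics, MANCOVA, logistic/ROC
python analysis/05_evaluate_recovery.py # score against ground truth
```

With the default seed, `02_decompose.py` reports

```
data matrix: 156 subjects x 4116 voxels
ICASSO: cluster sizes [20, 20, 20, 20, 20, 20, 20],
        Iq [0.987, 0.986, 0.985, 0.984, 0.979, 0.979, 0.976]
```

— every component recurred in all 20 runs with near-perfect run-to-run
similarity, i.e. all seven networks are stable. `04_group_inference.py` then
prints (abridged)

```
per-component group tests (Bonferroni alpha 0.0071):
 component        F        p  partial_eta_sq  significant
         1 9.288426 0.002723        0.057948         True
         4 4.856016 0.029064        0.031157        False
AUC 0.715; at cutoff 0.5: sensitivity 63.6%, specificity 64.6%, accuracy 64.1%
```

Component 1 here is one of the two planted affected networks (F = 9.29,
partial η² = 0.06, surviving the 0.007 threshold); the second planted shift
(component 4, p = 0.029) misses the Bonferroni bar on this draw — with a
0.6 SD shift and n = 156 that is expected behaviour, not a bug (the
realized group difference itself fluctuates with SE ≈ 0.16).
`05_evaluate_recovery.py` confirms the decomposition: mean matched spatial
correlation 0.972 against the planted sources, and the achieved AUC (0.715)
equals the AUC of a model given the true loadings (0.715) — the classifier
extracts essentially all the information the simulation put in.

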