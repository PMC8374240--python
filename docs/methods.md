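# Methods

`msrad` implements a radiomic classification workflow for distinguishing
multiple-sclerosis patients (MSP) from healthy controls (HCS) on brain MRI,
using first-order and texture features extracted from white matter (WM),
normal-appearing white matter (NAWM) and gray matter (GM) on one
conventional channel (T1w, arbitrary units) and four quantitative maps (PD,
MT, R1, R2\*, physical units). Because the clinical cohorts such a study
rests on cannot be redistributed, the package ships a synthetic cohort
generator that reproduces the *statistical* structure the analysis assumes;
all tests and the acceptance script run on generated data only.

## Synthetic cohorts

A subject is a nested-ellipsoid phantom (background → CSF shell → GM shell →
WM core; semi-axis fractions 0.47/0.38/0.28 of the grid). Tissue probability
maps are Gaussian-smoothed one-hot indicators (σ = 0.8 voxels), so voxelwise
sums stay ≤ 1 and the 0.9 mask threshold meets genuine partial-volume
boundaries. Channel intensities are probability-weighted mixtures of tissue
means plus three stochastic layers:

* **between-subject variability** — each subject's tissue mean is drawn
  around the population mean with SD = 3% of that mean
  (`REL_BETWEEN_SUBJECT_SD`); this is what keeps per-subject ROI means from
  being trivially separable and defines the "pooled SD" scale on which
  planted effects are specified;
* **spatially correlated texture** — Gaussian-smoothed white noise per
  tissue, correlation length 2 mm by default, amplitude equal to the channel
  noise SD;
* **i.i.d. voxel noise** — per-channel SDs of roughly 3–4% of the WM mean.

MSP subjects additionally receive 2–5 spherical focal lesions (radius
1.5–3 mm, i.e. 3–6 mm diameter, the typical size of MS plaques), placed
fully inside the WM core and pairwise disjoint so that the lesion count is
recoverable as 26-connected components. Lesions are hypo-intense on T1w
(×0.70) and MT (×0.60), hyper-intense on PD (×1.15) and isointense on
R1/R2\*; this gives the WM-versus-NAWM contrast that the headline WM models
exploit. Diffuse disease effects are planted through `EffectSpec`: additive
tissue-mean shifts and texture-correlation-length shifts per (channel, ROI).
The default effect lowers MT/R1, raises PD and slightly lowers R2\* in NAWM
and GM by about one between-subject SD, with no diffuse T1w shift.
A multiplicative low-frequency bias field (default amplitude 20%) is applied
to T1w only.

`null_effect=True` zeroes **every** planted class difference, including the
lesions — lesions are themselves a class-dependent feature, and leaving them
in place would leak outcome information into a nominally null cohort. Under
the null, two-sample t statistics of per-subject tissue means are calibrated
(≈5% rejections at α = 0.05 over seeds), which the test suite checks.

What the generator does **not** emulate: anatomy (gyri, ventricles, deep GM
nuclei), MRI physics (k-space sampling, relaxometry fitting, coil
sensitivities), scanner-specific intensity distributions, or lesion shapes
beyond spheres. Passing tests therefore demonstrate that the *pipeline*
behaves correctly under the assumed statistical structure — they say nothing
about classification performance on real patients.

## Preprocessing

Fixed order: resample → threshold probability maps → bias-correct (T1w) →
z-normalize (T1w).

* **Resampling** uses cubic-spline interpolation (`scipy.ndimage`,
  voxel-center convention); splines reproduce polynomials up to degree 3
  exactly away from the boundary.
* **Mask thresholding** keeps voxels with tissue probability ≥ 0.9
  (boundary inclusive). A voxel supra-threshold for several tissues goes to
  the most probable one; exact ties resolve lesion > NAWM > GM > CSF. WM is
  the voxelwise union NAWM ∪ lesion; TIV is the union of all four tissues.
  No morphological cleanup is applied after thresholding.
* **Bias correction** (T1w only, within TIV) removes a smooth multiplicative
  field. A naive smooth-field fit — polynomial or B-spline — applied directly
  to log intensities absorbs genuine anatomy, because the tissue layout of a
  brain is itself low-frequency; measured on the phantom, a plain degree-3
  log-polynomial fit changes a bias-free image by ~50% on average. The
  estimator here therefore alternates (five rounds) between a deterministic
  1-D k-means decomposition of the corrected log intensities into 7 classes
  (tissues plus partial-volume/noise strata) and a degree-3 polynomial
  least-squares fit to the *residual* log intensity after subtracting each
  voxel's class mean — the same separation-of-anatomy-and-field idea used by
  the classic histogram-based correctors. On the phantom this changes a
  bias-free image by 1.6% (mean relative, within TIV) and recovers a planted
  20%-amplitude smooth field to within 1.7%. The TIV mean intensity is
  preserved. An N4 backend (SimpleITK) is available via `method="n4"`.
* **Normalization** (T1w only): subtract the TIV mean and divide by the TIV
  *population* SD; all voxels are transformed but only TIV voxels enter the
  statistics. Quantitative maps are deliberately never rescaled — their
  voxel values are physical quantities and rescaling would destroy exactly
  the cross-subject comparability that motivates using them.

Re-running the chain on its own output is a no-op: resampling at the same
spacing and thresholding the unchanged probability maps are identities, and
`preprocess_subject` recognizes an already z-normalized T1w volume (TIV mean
0, SD 1 to 1e-9) and skips the bias/normalize steps, whose composition is
not otherwise exactly idempotent (the bias estimator needs positive inputs).

## Feature extraction

93 features per (channel, ROI): 18 first-order, 24 GLCM, 16 GLRLM, 16 GLSZM,
5 NGTDM, 14 GLDM — the standard original-image set, named
`<family>_<FeatureName>`. Shape features are deliberately absent. With five
channels and three ROIs this is 1,395 feature columns per subject.

Intensities are discretized with a fixed bin number (N_bins = 50):
`level = min(N, floor(N·(x−min)/(max−min)) + 1)` using the ROI min/max, so
all texture features are invariant to monotone affine intensity transforms.
The ROI is cropped to its bounding box with a 5-voxel pad before any matrix
is built. Matrix conventions:

* GLCM — symmetric, distance 1, 13 unique 3-D directions, normalized per
  direction; features averaged over directions. Gray values are the bin
  indices 1..max-observed-level.
* GLRLM — runs per direction (13, averaged); out-of-ROI voxels break runs.
* GLSZM — zones are 26-connected equal-level components (direction-free).
* NGTDM — 26-neighborhood mean differences at distance 1; voxels with no
  in-ROI neighbor are excluded from the occupancy counts.
* GLDM — dependence at Chebyshev distance 1 with similarity tolerance
  α = 0; the dependence size counts the center voxel plus its equal-level
  in-ROI neighbors, so matrix mass equals the ROI voxel count.

Degenerate conventions (all asserted in tests): zero-variance GLCM
correlation → 1, MCC of a single level → 1, skewness/kurtosis of a constant
ROI → 0, single-level entropy → 0 and uniformity → 1, NGTDM coarseness of a
uniform region → capped at 1e6, busyness/strength with empty denominators
→ 0. First-order intensity statistics use the raw values; entropy and
uniformity use the discretized levels; moments are population moments.

Every matrix family is verified against an independent brute-force
enumeration (pair counting, line walking, flood fill, neighbor loops) on 100
random 5³ grids, along with the mass-conservation identities.

## Univariate exploration

Per feature: two-sided Mann–Whitney U between classes (exact null
distribution when n₁·n₂ ≤ 400 and there are no ties, tie-corrected normal
approximation otherwise) with Bonferroni correction over the features
actually tested; point-biserial correlation with the outcome (t-test
p-value; flagged at |r| ≥ 0.85 and p ≤ 0.05); Spearman correlations with age
and with the feature's own ROI volume (flagged at |r| > 0.85); and the
univariate AUC, folded to max(AUC, 1−AUC) and reported with the identity
AUC = U/(n₁·n₂). Constant features get p = 1 and zero correlations by
convention. Exploration describes the data and never feeds model building.

## Feature selection

Per (channel, ROI), repeated 100 times on balanced bootstrap cohorts of 100
subjects (50 per class, drawn with replacement from the training subset):

1. **Low-variance filter** — drop a feature iff its fraction of distinct
   values is < 10% *and* the ratio of its two most frequent value counts
   exceeds 95/5 ("ratio of most frequent values" is read as the standard
   top-1/top-2 frequency ratio); constants always drop.
2. **De-correlation** — while any pair has |Spearman ρ| > 0.85, drop from
   the worst pair the feature with the larger mean |ρ| against all other
   kept features (ties drop the lexicographically later name).
3. **RF-RFE** — recursive feature elimination with a 100-tree random forest
   (√k split candidates, k shrinking as elimination proceeds), removing one
   feature per step down to N_features.

N_features = max(1, round(n_minor/10)), where n_minor is the minor-class
count of the training subset. The `round` (rather than `int`) reading is
deliberate: a 36/36 cohort split 80/20 leaves a 28-to-29-sample minor class,
and the signature size the procedure is meant to produce there is three —
`int(28/10) = 2` cannot produce it, `round(2.8) = 3` does.

Features are ranked by selection frequency across the 100 iterations; ties
break by mean RFE rank, then by name, so a fixed seed reproduces the
signature exactly.

## Models and evaluation

Three classifiers per (ROI, image type) signature, hyperparameters fixed
with no tuning loop: random forest (100 trees, √k split candidates), RBF
SVM (C = 1.0, γ = 1/(k·Var(X)) — sklearn's `gamma="scale"`), and logistic
regression (L2, C = 1.0, liblinear, dual formulation). SVM and LR inputs are
standardized with training-slice statistics frozen into the model; RF is
scale-free. The image types are T1w, PD, MT, R1, R2\* and `qMRIcomb`, whose
feature pool is the four quantitative channels' features pooled before
selection. MSP is the positive class throughout. AUC scores use predicted
probability (LR), decision value (SVM) and vote fraction (RF).

Evaluation draws 100 balanced bootstrap cohorts of 100 (50 per class, with
replacement) from the held-out test subset and reports the median and 90% CI
(empirical 5th/95th percentiles) of accuracy, AUC, sensitivity and
specificity. Train/test subject disjointness is asserted at call time.
Model types are compared with the paired DeLong test on the raw (un-
bootstrapped) test-subset scores, Bonferroni-corrected over pairs; a model
type is admissible in a combination only with median AUC ≥ 0.7, and the
type winning the most combinations is selected (ties to the fewest
parameters: LR > SVM > RF).

The permutation audit permutes labels within the training and test subsets
separately (class counts preserved) and reruns the unchanged
selection + training + evaluation closure; the AUC drop is tested with a
one-sided Mann–Whitney U between the 100 original and 100 permuted
bootstrap AUCs (significant at p ≤ 0.01).

External validation applies a frozen model — coefficients and
standardization constants untouched — to an unbalanced validation cohort
(many controls, few patients, disjoint scanner labels), with the same
balanced-bootstrap reporting; when the table carries a `source` column, raw
per-source accuracies are reported (an all-negative source's accuracy equals
overall specificity, an all-positive source's equals sensitivity).

A known property of this design worth stating: with a handful of held-out
subjects, stability selection can hand the model a feature that happens to
separate the test subjects by chance, so under the null the *per-run* 90%
bootstrap AUC interval occasionally misses 0.5. The calibration contract is
therefore stated over seeds: pooled across ≥ 10 independent null cohorts,
the 90% interval of the bootstrap AUC distribution contains 0.5.

## Saliency maps

For a selected feature, each ROI voxel's value is the feature computed on
its 3×3×3 neighborhood intersected with the ROI (truncated at borders;
voxels with fewer than two in-patch ROI voxels get 0). Patches reuse the
*global* ROI bin edges — per-patch rediscretization would make neighboring
values incomparable. The map is min–max normalized over the ROI; a constant
raw map collapses to zeros. The first-order-mean map equals a masked
26-neighborhood mean filter to 1e-9, which is tested by direct convolution.

## Orchestration, seeds and problem sizes

`run_study` wires the stages from one `StudyConfig` and writes features,
screening tables, selection JSONs, evaluation JSONs, Table-style CSVs,
saliency maps and a manifest with SHA-256 hashes of every CSV/JSON output.
Every random draw derives from `global_seed` through SHA-256 stage-name
hashing (`stage_seed`), so inserting a stage never shifts another stage's
stream and two runs of one config are bitwise-identical — the manifest
comparison in the test suite checks exactly this.

Default problem sizes are chosen so the whole suite runs on a single CPU in
minutes: the planted-effect recovery and permutation audit use a 40-subject,
48³-voxel MT-only cohort with the full 100 selection iterations; the
ten-seed null-calibration loop uses 5 selection iterations per seed (under
the null the signature content is immaterial — only the held-out AUC
distribution is of interest); the end-to-end smoke study uses 16 subjects at
32³ with 2 selection iterations and 25-cohort bootstraps. The statistical
contracts being checked do not depend on these sizes; they are stated in the
test docstrings where they bite.

## Known limitations

* Phantom geometry is deliberately crude; features sensitive to cortical
  folding or lesion morphology are exercised only through generic texture.
* The bias-field estimator assumes the field is well approximated by a
  degree-3 polynomial; strongly localized coil artifacts are out of scope.
* The 93-name registry reconstructs the conventional original-image feature
  set from the family cardinalities; it is the package's normative list and
  is asserted in tests, but it is a reconstruction, not a copy of any
  external tool's output.
* DeLong comparisons use the asymptotic normal approximation; with very few
  test subjects the p-values are approximate.
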