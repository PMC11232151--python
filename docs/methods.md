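# Methods

This note documents the models, the synthetic data they are exercised on,
the numerical choices, and the known limitations. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Problem setting

After neoadjuvant chemotherapy (NAC), breast tumours either disappear
(pathological complete response, pCR), shrink concentrically (CS — the
lesion collapses toward its centre preserving shape; pCR is the extreme
subtype of CS), or regress non-concentrically (diffuse decrease,
enlargement, intensity decrease, no change). The pipeline predicts p(CS)
and p(pCR) jointly from longitudinal DCE-MRI radiomics, stratifies
patients into three response groups (1 = non-pCR ∧ non-CS, 2 = non-pCR ∧
CS, 3 = pCR), validates the stratification against survival, and
interprets it against gene expression.

## Imaging preprocessing

* **Resampling.** All series are resampled to an isotropic grid
  (default 0.8 mm) with trilinear interpolation; masks use
  nearest-neighbour. Trilinear rather than spline: monotone, no ringing,
  so downstream texture statistics are not contaminated by overshoot.
* **Normalization.** Each sequence is divided by the mean of the
  intensities lying inside its inter-quartile range. The operation is
  scale-invariant and idempotent (the IQR-mean of the output is exactly 1),
  which the tests assert. Normalization is computed over the whole volume,
  not the tumour ROI, so segmentation cannot feed back into normalization.
* **Order of operations.** Subtraction (SM0 = SM − S0) happens on the raw
  co-registered grids; each derived sequence is then normalized
  independently. SM0 retains a positive IQR-mean because parenchyma itself
  enhances moderately after contrast — a property the synthetic generator
  reproduces deliberately.
* **Segmentation.** Two-cluster fuzzy C-means on SM0 with fuzzifier m = 2
  and Chuang-style spatial regularization: the intensity-based membership
  is multiplied by the mean membership of the voxel's 26-neighbourhood
  raised to the spatial weight (default 1; weight 0 recovers plain FCM,
  which the tests check against 2-means centres). Cluster centres
  initialize at intensity quantiles for determinism. The tumour is the
  brighter cluster's membership > 0.5, reduced to its largest 26-connected
  component (single-lesion assumption; diffuse tumours are outside scope).
  An empty result raises a distinct `SegmentationFailure`.
* **Parenchymal ring.** Exact Euclidean distance transform of the tumour
  complement (anisotropy honoured), thresholded at the ring width
  (default 20 mm); disjoint from the tumour by construction, clipped at
  volume borders.

## Feature catalogue

102 features per (sequence × region): shape 14, first-order 18, GLCM 24,
GLRLM 16, GLSZM 16, GLDM 14; NGTDM busyness is emitted as an *extra*
outside the 102 because the catalogue's texture arithmetic
(24+16+16+14 = 70) has no NGTDM family. Conventions:

* Discretization: fixed bin count 32 by default (bin count rather than
  width because normalization already rescaled intensities).
* GLCM: distance 1, all 13 unique 3D directions, symmetric, normalized per
  direction then averaged.
* GLRLM: run counts averaged over the 13 directions (entries may be
  fractional). GLSZM: 26-connected zones. GLDM: dependence = 1 + number of
  26-neighbours with identical level (α = 0).
* Shape: volume and surface area from the marching-cubes mesh so
  sphericity is stable under resampling. The mask is mildly
  Gaussian-smoothed (σ = 1 voxel) before meshing; meshing the raw binary
  staircase inflates surface area by ~8 % and would bias sphericity low for
  every shape. Masks thin enough to vanish under smoothing fall back to
  the raw surface. Axis lengths are 4·√λ of the voxel-cloud covariance
  eigenvalues; flatness = √(λ₃/λ₁).
* Undefined features (e.g. busyness on a single-level region) are flagged
  and carried as NaN, never silently dropped; imputation (training median)
  happens only at model entry.

Every texture feature is verified against an independent plain-Python
enumeration oracle on randomized arrays ≤ 5×5×5 to 1e−10.

## Multitask random forest

Split score = unweighted mean over tasks of the per-task Gini impurity
decrease. This is symmetric in the tasks and reduces *exactly* to the
standard criterion when the tasks coincide — with the same seed, the
multitask forest and a single-task forest are bit-identical (asserted).
Trees are grown on bootstrap samples with mtry = ⌈√p⌉ candidate features
per node (defaults: 100 trees, depth ≤ 6, min leaf 3); leaves store
per-task positive-class frequencies; prediction averages leaves over
trees; OOB predictions average only trees whose bootstrap excluded the
patient. Joint importance accumulates (node sample fraction × multitask
score) per feature, averaged over trees, ties broken lexicographically.

Signature selection refits the top-k of the ranking under leave-one-out
cross-validation for each k in a grid, scoring mean AUC across tasks;
ties go to the smallest k. Selection runs inside the 66 % training split
only (to avoid leakage into the inner validation third); the split is
jointly stratified on (CS, pCR) with largest-remainder allocation so the
train arm has exactly round(0.66·n) patients and every stratum's
prevalence is preserved within one patient. The collinearity filter
removes zero-variance columns, then greedily visits pairs with |r| > 0.9
in descending |r|, dropping the member with the higher mean absolute
correlation to the remaining features.

AUC is the Mann–Whitney statistic with half credit for ties (equal to
exhaustive pair counting, asserted); CIs are stratified percentile
bootstraps (default 2000); operating points use Youden's J; model
comparison uses a paired patient-level bootstrap of ΔAUC with a ±1/B
continuity guard.

## Survival

Kaplan–Meier is the product-limit estimator with simultaneous-death ties;
the log-rank test accumulates observed−expected with the hypergeometric
covariance (both cross-checked against lifelines). The optimal cutoff
scans observed score values between the 10th and 90th percentiles and
returns the threshold minimizing the two-group log-rank p together with
the full trace — the minimal p is selection-biased by construction and is
never interpreted as a calibrated significance level. Cox models are
lifelines fits; the exposure's prognostic value is additionally assessed
by a likelihood-ratio test against the nested model without the exposure.
Administrative censoring truncates all times beyond 120 months to 120
with event = 0 (events recorded after the horizon are unobservable within
the follow-up window). Thresholding uses ≥ (boundary goes to the
responding group). Pairwise log-rank p-values are reported raw and
BH-adjusted.

## Genomics

"Expressed" means non-missing and above the platform floor (default: the
10th percentile of all finite matrix values; configurable). Genes
expressed in ≤ 20 % of patients are dropped, then genes with any remaining
missing values, then all but the top-2000 by variance. Association is
per-gene least-squares regression of expression on the ordinal group code
(positive slope = rising toward pCR), two-sided t test on the slope;
ANOVA is the classical one-way F across groups. Enrichment is
over-representation (hypergeometric upper tail of the overlap between the
significant set and each pathway restricted to the universe = post-filter
genes ∩ pathway genes) with BH correction — the output shape (per-pathway
corrected p + overlapping gene markers) matches how such results are
reported; rank-permutation GSEA is deliberately out of scope.

## Synthetic cohort: what it emulates, what it does not

The generator defines the study conditions: CS prevalence 0.773, pCR
prevalence 0.267 with pCR ⊂ CS (conditional CS probability restores the
marginal); monthly exponential hazards (0.012, 0.005, 0.002) for groups
1/2/3 — ten-year survival ≈ 0.24/0.55/0.79 — with recurrence hazard
1.5× death hazard and RFS = min(recurrence, death) so RFS ≤ OS; 120-month
administrative censoring; clinical covariates drawn with the prevalences
typical of such cohorts (age 48.9 ± 10.4, ER 58 %, PR 46 %, HER2 44 %).
Tumours are axis-aligned ellipsoids (6–9 mm base radius, axis ratios
1 : 0.6–0.9 : 0.4–0.7) with 2–4 surface lobes; pCR leaves a 2.5–4 mm
near-spherical residual, CS scales the whole composite shape by 0.5–0.8
about its centre (axis ratios preserved), and non-CS draws one of the
four non-concentric subtypes. Contrast enhancement is 80 (tumour) over 20
(parenchyma) with Gaussian-smoothed noise textures whose correlation
length differs by group, so texture as well as shape is informative. The
tabular fast path plants features with a standardized step of the
configured effect size between adjacent group codes on an equicorrelated
(ρ = 0.2) Gaussian background. Expression is N(6,1) per gene with planted
alternating-sign trends on the group code, plus low-expression and
missing-value gene subpopulations to exercise the filters.

What it does **not** emulate: MRI acquisition physics, bias fields,
registration error between timepoints, multi-lesion disease, realistic
breast anatomy, non-proportional hazards, or realistic gene–gene
correlation structure. Passing tests therefore demonstrate correctness of
the algorithms under known ground truth, not clinical performance.

## Problem sizes and determinism

The demonstration configuration runs 120 patients with 36×36×24 volumes
at (1, 1, 2) mm, processed on a 1.5 mm working grid — small enough that
the full chain completes in about a minute on one CPU while every stage
still does real work. The heavier learner studies use n = 300 with 5
planted + 50 noise features and 12–15-tree LOOCV forests over a small
k-grid; the multitask-vs-single-task comparison averages 50 seeded
replicates. All randomness flows from a single seed through named
substreams (one per stage, one per patient for images), so adding or
re-running a stage never perturbs another, and identical config + seed
reproduces every artifact digest bit-identically.

## Known limitations

* FCM segmentation of 1–2-voxel-thick early-NAC residuals (pCR cases) is
  partial-volume limited; Dice can drop to ≈ 0.75 there, while
  pre-treatment lesions segment at Dice ≥ 0.9 under default noise. The
  pipeline counts reference-mask fallbacks in its log.
* OOB AUC under a label-permutation null is slightly pessimistic (a known
  out-of-bag artifact); null-calibration checks therefore average a few
  shuffle replicates.
* The forest supports > 2 tasks by construction but is only exercised
  with two.
* Probability calibration of the forest outputs is out of scope; the
  survival stage consumes ranks/thresholds, not calibrated probabilities.
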