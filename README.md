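# radioshrink

Multitask radiomic modelling of breast-tumour response to neoadjuvant
chemotherapy (NAC).

Breast tumours regress under NAC in qualitatively different ways. Two
outcomes matter clinically: whether the patient reaches a pathological
complete response (pCR), and whether a residual tumour shrinks
*concentrically* (CS) — collapsing toward its centre while preserving shape —
rather than fragmenting, diffusing, or enlarging. Both outcomes carry
prognostic information, and both can be read early from longitudinal
dynamic contrast-enhanced MRI (DCE-MRI). `radioshrink` implements the full
analysis chain for this problem, aimed at imaging scientists and
biostatisticians who want a tested, reproducible reference pipeline:

1. **Preprocessing** — resampling to an isotropic grid (0.8 mm default),
   intensity normalization by the mean of the inter-quartile range,
   subtraction imaging (SM0 = SM − S0), tumour segmentation with a
   spatially regularized fuzzy C-means, and a 20 mm parenchymal ring.
2. **Feature extraction** — a native 102-feature radiomic catalogue per
   sequence and region: 14 shape, 18 first-order, and 70 texture features
   (GLCM 24, GLRLM 16, GLSZM 16, GLDM 14), plus NGTDM busyness as an extra.
   Every texture feature is oracle-tested against brute-force enumeration.
3. **Multitask learning** — a random forest whose split criterion is the
   unweighted mean of the per-task Gini impurity decreases, so one model
   jointly predicts p(CS) and p(pCR). Joint feature importance, LOOCV
   top-k signature selection, collinearity filtering at |r| > 0.9, and
   bootstrap AUC machinery are included.
4. **Survival stratification** — patients map to three groups
   (1 = non-pCR ∧ non-CS, 2 = non-pCR ∧ CS, 3 = pCR) through probability
   thresholds found by a minimum-log-rank-p cutoff search; Kaplan–Meier,
   log-rank, and adjusted Cox proportional-hazards models quantify the
   prognostic value, with administrative censoring at 120 months.
5. **Genomic interpretation** — expression filtering (expressed fraction,
   missingness, top-variance), per-gene ordinal regression across the three
   response groups, one-way ANOVA, and hypergeometric pathway
   over-representation with Benjamini–Hochberg correction.

Because the corresponding clinical cohorts are not redistributable, the
package ships a **synthetic cohort generator** with known ground truth:
paired pre-treatment / early-NAC tumour phantoms following the shrinkage
taxonomy, correlated binary outcomes (CS prevalence 77.3 %, pCR 26.7 %,
pCR ⊂ CS), exponential survival with hazard ordering
pCR < CS∧non-pCR < non-CS∧non-pCR, and gene expression with planted
monotone trends. Every downstream claim is tested against this planted
truth.

## The model at the core

At a node with samples S and tasks t = 1…T with binary labels, a candidate
split S → (S_L, S_R) is scored

    score = (1/T) Σ_t [ G_t(S) − (|S_L| G_t(S_L) + |S_R| G_t(S_R)) / |S| ],

with G_t the Gini impurity 2p_t(1−p_t) under task t. Leaves store one
positive-class frequency per task; per-task probabilities are leaf
frequencies averaged over trees. When all tasks coincide the criterion
reduces *exactly* to a standard single-task forest (asserted bit-for-bit in
the tests). Joint importance accumulates (node fraction × score) per
feature, and the signature is the top-k of that ranking with k chosen by
LOOCV mean AUC across tasks.

## Worked example

```bash
radioshrink run-all --seed 1 --out-dir demo_out   # ~1–2 min, 120 patients
radioshrink report --out-dir demo_out
```

prints (abridged):

```
validation performance (inner validation split)
task  AUC (95% CI)               Sens   Spec   Prec     F1
cs    0.931 (0.828-1.000)       0.968  0.800  0.938  0.952
pcr   0.961 (0.900-1.000)       1.000  0.867  0.733  0.846

Cox models (adjusted for age, PR, HER2, diameter)
  OS   predicted_cs   HR 0.371 (0.204-0.675) p=0.001159 LR p=0.001979
  OS   predicted_pcr  HR 0.299 (0.146-0.613) p=0.0009883 LR p=0.0001952
  RFS  predicted_cs   HR 0.356 (0.209-0.608) p=0.0001532 LR p=0.0003494
  RFS  predicted_pcr  HR 0.384 (0.229-0.643) p=0.0002747 LR p=8.782e-05
  overall 3-group log-rank p (OS): 0.0001387

top enriched pathways
  PLANTED_RESPONSE_PATHWAY     p=8.52e-18 corrected=1.7e-16 markers=GENE0000|...
```

Reading: on the held-out third of the synthetic development cohort the
joint model discriminates both outcomes (AUCs 0.93 / 0.96 — the synthetic
signal is deliberately strong); patients predicted CS or pCR have hazard
ratios well below 1 after adjusting for clinical covariates; the three
predicted response groups separate in survival (log-rank p ≈ 1.4e-4); and
the pathway seeded with the planted trend genes tops the corrected-p
ranking. Identical config + seed reproduces every artifact digest
bit-identically (`manifest.json` records them).

The same chain is scriptable: `radioshrink simulate|preprocess|train|
predict|stratify|survive|genomics` re-run individual stages, and
`--config config.yaml` overrides any nested parameter (unknown keys are
rejected).

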