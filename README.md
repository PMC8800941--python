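# radsig — co-clinical FDG-PET radiomics for response-to-therapy prediction

`radsig` implements an end-to-end FDG-PET radiomics pipeline for
co-clinical imaging studies of triple-negative breast cancer (TNBC), in
which patient-derived xenografts (PDX) imaged on small-animal PET/CT are
used to optimize image features that are then applied to the matched
clinical PET/MR arm. It is aimed at quantitative-imaging researchers who
need a tested, reproducible implementation of the full chain: SUV
quantification, IBSI-style feature extraction, robustness triage, signature
selection, and machine-learning evaluation — together with a synthetic
phantom generator so every stage can be exercised and validated without
any imaging data.

## What it computes

**SUV quantification.** Voxel activity is normalized to the standardized
uptake value, SUV = activity (Bq/mL) × body weight (g) / injected dose
(Bq). The panel includes SUV_mean, SUV_max, SUV_peak (maximal mean over a
~1 mL sphere), SUL_peak (peak normalized to Janmahasatian lean body mass,
per PERCIST), SUL_mean, SUV_min, SUV_sd, SUV_median, total lesion
glycolysis (TLG = SUV_mean × MTV), tumor volume, and metabolic tumor
volume (default 40 % of SUV_max). Preclinical caliper volume uses
V = 1/6·L·W².

**Feature panel (131).** 37 first-order features (18 intensity statistics
on the raw SUV grid + 19 statistics of the Ng = 64 equal-probability
intensity histogram) and 83 higher-order texture features — GLCM (25),
GLRLM (16), GLSZM (16), GLDZM (16), NGTDM (5), GLDM (5) — computed per
IBSI definitions on the isotropically resampled, equal-probability
quantized (Ng = 64) grid, with co-occurrence and run-length features
averaged over the 13 unique 3D directions; plus the two volumes and nine
SUV metrics.

**Robustness triage.** A feature is *robust* when it passes three screens:

1. *Reproducibility*: Lin's concordance correlation coefficient over paired
   test–retest acquisitions, LCC = 2·cov(x,y) / (σ²_x + σ²_y + (μ_x −
   μ_y)²) ≥ 0.7;
2. *Non-redundancy*: no retained pair with Spearman ρ ≥ 0.9 at P < 0.001
   (the lower-LCC member of an offending pair is dropped);
3. *Volume independence*: Spearman ρ vs tumor volume ≤ 0.9 or
   nonsignificant; volume-coupled features are additionally fit with
   linear / logarithmic / power / exponential forms, the best selected by
   minimum AIC.

**RadSig.** Robust features are ranked by multi-class ReliefF (full
deterministic pass, k = 10 neighbours, Manhattan distance on min–max
scaled features, Kononenko prior-weighted misses); features with weight
above τ = 0.05 form the shortlist and the top 4 per task make up the
radiomic signature. *Prediction* uses baseline features; *assessment* uses
on-treatment − baseline differences.

**Models.** CART (Gini binary splits), SVM with RBF kernel and L2
regularization, and Gaussian Naive Bayes under stratified 10-fold
cross-validation (fold-internal standardization, pooled out-of-fold
confusion matrix), reporting accuracy, F-score, sensitivity, specificity,
precision, and NPV, and the percent improvement of RadSig over the
single-metric SUV_mean / SUV_max / SUL_peak comparators.

**Clinical cohort.** The packaged 20-patient (25-lesion) TNBC interim
cohort with pathological complete response (pCR) labels and percent
changes in SUV metrics between on-treatment and baseline.

## Worked example

```python
from radsig import (PhantomConfig, generate_longitudinal_cohort,
                    extract_table, select_radsig, cross_validate, ModelSpec)
from radsig.relieff import delta_table

cfg = PhantomConfig(n_subjects=24, seed=1, effect_size=2.0)
cohort = generate_longitudinal_cohort(cfg)          # BL + on-treatment scans
bl = extract_table(cohort.at("BL"))                 # 24 x 131 features
bl.index = bl.index.get_level_values("subject_id")
sig = select_radsig(bl, cohort.labels, "prediction")
print(sig.features)
rep = cross_validate(bl[sig.features], cohort.labels, ModelSpec(), folds=10, seed=1)
print(f"NB accuracy {rep.accuracy:.1f}%")
```

prints (responders carry a planted baseline heterogeneity shift):

```
['fo_minimum', 'suv_min', 'fo_coefficient_of_variation', 'glrlm_low_gray_level_run_emphasis']
NB accuracy 66.7%
```

The selected features are exactly the intensity-spread family the planted
responder effect perturbs, and the 10-fold accuracy sits well above the
three-class chance level (~50 % with 12 responders of 24).

The packaged clinical statistics:

```sh
$ radsig cohort-stats
{
 "pCR.d_suv_mean":  {"mean": -57.70, "sd": 14.83},
 "non_pCR.d_suv_mean": {"mean": -46.94, "sd": 21.56},
 ...
 "pcr_patient_count": 10
}
```

## Analysis scripts

`analysis/01_simulate_cohorts.py` … `07_clinical_cohort.py` run the whole
study in order on synthetic cohorts at the co-clinical sizes (40
test–retest pairs, 29 therapy subjects, 20 clinical subjects): simulation,
SUV metrics, feature extraction, robustness screen, RadSig selection,
model evaluation, and the clinical group statistics. Images land under
`scratch/`, tables under `results/`. The same stages are available as CLI
subcommands (`radsig simulate|metrics|extract|screen|select|train|
cohort-stats|report`).

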