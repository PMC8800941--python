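# Methods

This note documents the models, conventions, and numerical choices behind
`radsig`, and what the synthetic phantoms do and do not establish.

## SUV quantification

Voxel activity A (Bq/mL) is normalized as SUV = A · W / D with body weight
W in grams and injected dose D in Bq; the transform is linear, so every
order statistic commutes with it. SUV_peak is the maximal mean over a
1.0 mL sphere realized on the voxel grid, centred at each in-mask voxel in
lexicographic order (first maximum wins); when the VOI holds less than
1 mL the whole-VOI mean is substituted and flagged. SUL_peak multiplies
SUV_peak by LBM/W using the Janmahasatian lean-body-mass formulation
(sex- and BMI-dependent); for mice SUL ≡ SUV, since no accepted rodent LBM
model exists. Metabolic tumor volume uses a threshold of 40 % of SUV_max
(configurable); TLG = SUV_mean · MTV. Caliper volume is 1/6·L·W² exactly
as written in the preclinical protocol; the π/6·L·W² ellipsoid variant is
available behind a flag because both conventions circulate.

The nine-metric SUV panel (SUV_mean, SUV_max, SUV_peak, SUL_peak,
SUL_mean, SUV_min, SUV_sd, SUV_median, TLG) is a design choice: it covers
the PERCIST quantities and common practice and keeps the panel total at
131. The manifest is versioned so the composition can be swapped without
touching the extraction code.

## Feature panel

131 features = 37 first-order + 25 GLCM + 16 GLRLM + 16 GLSZM + 16 GLDZM
+ 5 NGTDM + 5 GLDM + tumor volume + MTV + 9 SUV metrics.

First-order features are computed on the raw (native-spacing) SUV grid:
18 intensity statistics, and 19 statistics of the Ng = 64
equal-probability histogram of the in-mask intensities. Equal-probability
quantization maps each in-mask value through the empirical CDF,
level = ⌈F(v)·Ng⌉ clipped to [1, Ng]; occupancies are as uniform as ties
permit and the mapping is invariant to any strictly monotone intensity
transform. A consequence worth knowing: on continuous data the quantized
histogram is near-uniform by construction, so the histogram-shape features
(entropy, uniformity) are nearly constant and typically fail the
test–retest variance requirement — they are carried for completeness and
removed by the screens.

Texture families operate on the isotropically resampled (trilinear image /
nearest-neighbour mask; target = native arm spacing, 0.8 mm preclinical,
2.0 mm clinical), equal-probability quantized grid, identically for both
arms. Co-occurrence matrices are symmetric, distance-1, one per the 13
unique 3D directions; features are computed per direction matrix and
averaged (the IBSI 3D "averaged" aggregation), likewise run-length
features. Zone (26-connected), distance-zone (taxicab distance to the
nearest out-of-ROI voxel, with the region beyond the image edge counting
as outside), tone-difference, and dependence (26-neighbourhood, same-level
neighbours, α = 0) features are direction-free. All matrices are
normalized before feature computation; degenerate cases are pinned
(constant grid: joint entropy 0, ASM 1, correlation 1; single-voxel mask:
co-occurrence undefined, error).

Every texture feature is verified, exactly, against an independent
brute-force implementation (explicit loops over voxel pairs, runs, zones,
neighbourhoods) on ≤ 5×5×5 grids with ragged masks.

## Robustness screening

Screens run on 129 features — everything except the two volumes, which the
volume screen regresses against. Order: reproducibility → redundancy →
volume (configurable).

*Reproducibility.* Lin's concordance correlation coefficient with
population (1/n) moments; threshold 0.7. Both-constant pairs are
undefined and fail.

*Redundancy.* For every pair with Spearman |ρ| ≥ 0.9 and P < 0.001 (raw
threshold, no multiplicity correction), the member with the lower
test–retest LCC is dropped — reproducibility is the pipeline's first
criterion, so it arbitrates; ties drop the later feature in manifest
order. The rule is a single pairwise pass, hence order-insensitive for
distinct LCCs. Hierarchical clustering of the correlation heatmap
(average linkage on 1 − |ρ|, default cut 0.5) is reported for inspection
only and does not gate features.

*Volume dependency.* A feature is flagged when Spearman |ρ| vs tumor
volume exceeds 0.9 at P < 0.001 — the raw correlation decides, not a
fit statistic. Four candidate forms a+bV, a+b·log V, a·V^b, a·e^{bV} are
fit by least squares (log-linearized initializations, then nonlinear
refinement for the power/exponential forms) and ranked by AIC with
k = 3 (two coefficients + noise scale) under Gaussian residuals; BIC is
reported and disagreement flagged. Residual sums of squares are floored
at 1e−300 so noiseless fits stay finite.

The robust set is the intersection: reproducible ∧ non-redundant ∧
volume-independent.

## ReliefF and RadSig

Standard multi-class ReliefF with a full deterministic pass over all
instances (no sampling noise), k = 10 nearest hits/misses (reduced with a
warning when a class is smaller), Manhattan distance on min–max scaled
features, and Kononenko's prior-weighted miss contributions,
W[f] ← W[f] − Σ|x_f − hit_f|/(m·k) + Σ_c P(c)/(1−P(class(x)))·|x_f −
miss_f|/(m·k). Weights lie in [−1, 1] and are invariant to instance
order. Features with weight > τ = 0.05 (absolute weight, the usual
relevance-threshold reading), sorted descending, truncated at 15, form
the shortlist; the top 4 are the RadSig for the task. Prediction ranks
baseline features; assessment ranks on-treatment − baseline differences.
The implementation is verified exactly against an exhaustive loop-based
ReliefF on ≤ 30-instance problems.

## Classifiers and evaluation

CART (Gini, binary splits, unlimited depth), SVM-RBF (C = 1,
gamma = "scale"; the protocol describes no inner tuning loop, so none is
run), Gaussian NB (variance smoothing 1e−9). Stratified k-fold (default
10; reduced with a warning when the smallest class is smaller than k),
features standardized inside each training fold only. Out-of-fold
predictions are pooled into a single confusion matrix per model/task —
stable at n ≈ 20–30, where per-fold averaging is dominated by 2–3-sample
test folds. Binary tasks report positive-class sensitivity/specificity/
precision/NPV/F (positive = pCR/response); the 3-class preclinical task
macro-averages one-vs-rest; accuracy is always overall. RadSig is
compared against single-feature SUV_mean / SUV_max / SUL_peak predictors
under the same model, folds, and seed; improvement = 100·(m_RadSig −
m_SUV)/m_SUV per metric.

## Synthetic phantoms

The generator emulates the co-clinical acquisition geometry, not PET
physics: no sinograms, scatter, attenuation, or reconstruction.

A tumor is an ellipsoid (semi-axes jittered ±20 % around a radius drawn
from 3–7 mm preclinical, volume-preserving) filled with
SUV_tumor·(1 + a·G) where G is a correlated Gaussian random field —
white noise smoothed with a kernel of width equal to the texture
correlation length (default 1.6 mm) and renormalized to unit variance —
so one knob (the amplitude a, default 0.30) controls heterogeneity and
hence the texture features. Background SUV 0.4, white voxel noise
SD 0.05 SUV, intensities clipped at 0. Preclinical arm: 0.8 mm isotropic
voxels, ~25 g animals, 6.66–8.14 MBq doses; clinical arm differs only in
spacing (2.0 mm), tumor sizes, and dose/weight/height metadata (~10 mCi,
~70 kg, female). Images are stored as activity so SUV normalization is
exercised end to end.

Test–retest day 2 reuses the day-1 tumor and texture field and applies a
jitter j (default 0.05) three ways: the voxel noise is redrawn, the
global intensity scale is perturbed by exp(N(0, j)), and the tumor centre
shifts by N(0, j)·spacing per axis (a sub-voxel boundary shift). j = 0
returns bit-identical scans. These reproduce the two observed
repeatability failure modes: noise-sensitive features lose concordance as
noise grows, and border-sensitive zone/distance features lose concordance
as the boundary moves.

Longitudinal cohorts plant a latent class: responders (default fraction
0.5) carry a baseline texture amplitude elevated by the effect size
(default 1.0, i.e. a doubled amplitude) that relaxes to nominal on
treatment, and shrink to 40–75 % of baseline volume; non-responders grow
to 125–170 %; partials stay within 85–115 %. Labels are derived from the
caliper-volume trichotomy (> 20 % shrinkage / within ±20 % / > 20 %
growth) and coincide with the latent class by construction. The binary
mode (responder → pCR) emulates the clinical dichotomy. Note the baseline
signal separates responders from the rest only — partial and no-response
tumors are identical at baseline — so baseline-task accuracy has a
ceiling below 100 % by design, while the assessment task additionally
sees the volume trajectory.

A tabular companion generator plants exactly `n_signal` discriminative
features (class-mean shift, default 1.6 SD per feature) among N(0,1)
decoys. The 1.6 SD default makes the planted quartet individually
moderate but jointly strong: the regime in which ReliefF ranks all four
above every decoy in ≳ 90 % of seeds *and* cross-validated accuracy
saturates near four features rather than at one dominant predictor.

What passing phantom tests shows — and does not. The pipeline recovers
planted heterogeneity signals, screens behave correctly on constructed
couplings, and every numeric stage matches independent oracles. The
phantoms do not model PDX morphology statistics, partial-volume effects,
scanner-specific noise texture, or inter-subject biological variability,
so screen pass-counts and model accuracies on synthetic cohorts are
qualitative analogues, not estimates of the values a real co-clinical
dataset would give.

## Clinical cohort fixture

The packaged 25-lesion/20-patient table ships as CSV with a SHA-256
checksum verified at load. Continuation rows without stage/grade are
additional lesions of the preceding patient (adjacency convention); one
patient's grade is recorded missing. Group statistics treat lesion rows
as observations, exclude the four rows with missing percent changes, and
use the sample (n−1) SD — the unique convention that reproduces the
published group means and SDs to two decimals, locked by test.

## Problem sizes and determinism

Analysis scripts and the acceptance script run the study at the
co-clinical sizes (40 test–retest pairs, 29 therapy subjects, 20 clinical
subjects); unit and property tests use 8–24-subject cohorts and ≤ 5×5×5
oracle grids. All randomness flows from explicit seeds through
`numpy.random.default_rng`; identical config + seed reproduces every
artifact bit-for-bit.

## Known limitations

- No orientation-matrix support: world coordinates come from voxel
  spacing only (axis-aligned volumes).
- No partial-volume correction, kinetic modelling, wavelet/filtered
  feature maps, or shape features beyond the two volumes.
- Clinical multi-lesion handling broadcasts the patient label to lesions
  with patient-level stratification; the packaged cohort is used for
  group statistics, not for training (baseline-only SUV triples with 10
  pCR labels would not support a stable 10-fold model).
- The equal-probability histogram features are near-degenerate by
  construction (see above) and survive mainly to keep the panel
  composition faithful.
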