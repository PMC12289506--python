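# Methods

`habitatpipe` implements a habitat-imaging analysis for predicting
response to neoadjuvant chemoradiotherapy (nCRT) in locally advanced
rectal cancer (LARC): each tumor, observed on co-registered T2-weighted
and ADC volumes with a binary mask, is decomposed voxel-wise into
intensity habitats; habitat-level and whole-tumor radiomics feed a
LASSO signature (Radscore) and clinical logistic models; five models
are compared with DeLong inference, Youden-threshold metrics and
decision-curve analysis. Because no imaging cohort is distributed with
the package, every stage is exercised on synthetic multiparametric
phantoms with known ground truth.

## Synthetic phantom cohort

Each phantom is an ellipsoidal tumor (randomized semi-axes of 8–20
voxels) on a 64³ grid at 1 mm isotropic spacing. The tumor interior is
partitioned into three spatially contiguous habitats by seeded
competitive region growth: habitat volume fractions are drawn from a
Dirichlet(2, 2, 2); each habitat grows from a random interior seed,
claiming unassigned 6-connected voxels, with the habitat that is
furthest below its target fraction growing next. Region growth (rather
than thresholding a smoothed random field) guarantees exact contiguity
and directly controllable fractions.

Voxel intensities are drawn per habitat from independent normals in the
two channels. Defaults (arbitrary T2 units; ADC in 10⁻³ mm²/s):

| habitat | semantics          | T2 mean (SD) | ADC mean (SD) |
|--------:|--------------------|--------------|---------------|
| 1       | high T2            | 180 (15)     | 1.1 (0.15)    |
| 2       | low T2 / high ADC  | 80 (15)      | 1.8 (0.15)    |
| 3       | low T2 / low ADC   | 90 (15)      | 0.8 (0.15)    |

Background: T2 40 (10), ADC 0.4 (0.1). The scale is deliberately
arbitrary — all downstream steps are invariant to increasing affine
transforms of either channel — and the separations (~6 within-habitat
SDs between the discriminating channels) give a mean adjusted Rand
index against truth above 0.95 at default noise, emulating clearly
delineable subregions rather than scanner physics. No acquisition
effects (bias fields, partial volume, motion, Rician noise, b-value
dependence) are simulated, so passing tests demonstrate correctness of
the pipeline's computations and recovery behaviour, not robustness to
real MRI artifacts.

Response labels are Bernoulli draws from a logistic model on the true
habitat fractions and clinical covariates. The default coefficients are
+3.0 (high-T2 fraction), −3.0 (low-T2/high-ADC fraction), +2.0
(low-T2/low-ADC fraction), −0.02/mm (tumor length, centered at 51 mm),
−0.8 (MRF involvement), −0.6 (CEA positivity), +0.5 (radiation
therapy), −0.5 (N2 stage). Signs encode the clinical reading that
necrotic low-cellularity tissue (high ADC) resists chemoradiation while
densely cellular and well-perfused tissue responds; the magnitudes are
chosen for testability (learnable at n≈180) since no quantitative
effect sizes are established. The intercept is calibrated by bisection
so the expected prevalence of good responders hits the 0.33 target of
the emulated cohort (181 patients, ~60 good responders). Clinical
covariates are sampled from marginals typical of a LARC cohort (age
N(60, 10); 66% male; 62% EMVI-positive; length N(51, 18) mm; ...) and
are independent of the habitats except through the label model, keeping
planted effects identifiable.

Seeding is two-level: a cohort seed expands to per-case seeds through a
counter, so any single case is reproducible in isolation; identical
(config, seed) yields byte-identical cohorts.

## Preprocessing

The fixed order is: whole-image Z-score normalization of T2 (population
SD); joint 3-sigma re-segmentation over the mask (per modality, μ and σ
over the original ROI; a voxel survives only if it is within μ±3σ in
*every* modality; σ=0 degenerates to keeping everything); fixed-bin-count
discretization into 16 equal-width bins over the retained ROI range
(half-open bins, last bin closed, so interior-edge values go up and the
maximum maps to bin 16; a constant ROI collapses to bin 1 with a
warning). ADC stays in native units for feature extraction because it
is already quantitative; both channels are z-scored *within the ROI*
for clustering only. Bin edges are per-case; cohort-pooled edges were
considered and rejected as the default because per-case edges make
texture features invariant to per-case affine intensity transforms.

## Radiomics features

Per modality: 18 first-order statistics (IBSI definitions; population
variance; non-excess kurtosis; entropy/uniformity on the 16-level
histogram, entropy in bits), tumor volume, 75 texture features, and
8×18 wavelet first-order features — 238 per modality, 476 per case. A
19th first-order statistic (standard deviation) is computed but not in
the default set, being the square root of variance.

Texture uses the 2.5-D merge strategy: per axial slice, GLCM
(distance 1, 4 in-plane directions, symmetrized) and GLRLM (4
directions) matrices, and GLSZM/GLDM/NGTDM with 8-connected in-plane
neighbourhoods, are computed and **merged by summation across slices
and directions before feature computation**, yielding one value per
family statistic (24 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM).
Degenerate conventions: NGTDM coarseness is capped at 10⁶ when the
denominator vanishes; GLCM correlation is 1 for zero marginal variance;
run percentage divides by voxel count × direction count.

Wavelet features come from a single-level 3-D stationary (undecimated)
coif1 decomposition of the ROI bounding box (margin 4, reflect-padded
to ≥8 per axis), restricted to retained ROI voxels; the 8 subbands are
named LLL…HHH by axis order. The transform is periodized and
unnormalized (lowpass gain √2 per axis).

Inter-rater stability is emulated by re-extracting all features after a
random one-voxel erosion or dilation of each mask on a reproducibility
subset (default 30 training cases, mirroring a two-reader re-segmentation
protocol); per-feature ICC(2,1) (two-way random effects, absolute
agreement, single rater) below 0.75 excludes a feature. ICC = 1 is
defined for zero total variance.

## Habitat decomposition

Clustering is **per patient**: each tumor's retained ROI voxels, rows
of a (z-scored T2, z-scored ADC) matrix, are clustered with K-means
(Lloyd, k-means++, 10 restarts, seeded). K is selected **globally** as
the argmax over K ∈ {2,…,6} of the mean per-case Calinski–Harabasz
score CH = [B/(K−1)]/[W/(n−K)] across training cases only; scores
within 10⁻⁹ relative of the maximum tie and resolve to the smaller K;
W = 0 reports +∞ with a warning; a flat profile (max/median < 1.2)
logs a low-confidence warning. Test cases are clustered on their own
voxels at the selected K (no centroid transfer; a transfer variant is a
flagged alternative for sensitivity analysis).

Cross-patient comparability comes from canonical centroid labeling:
part 1 is the centroid with the highest T2; of the remaining two,
part 2 has the higher ADC (necrosis-like) and part 3 the lower
(dense-cellularity-like). K ≠ 3 falls back to lexicographic (−T2, −ADC)
ordering and is flagged. Per habitat and modality the features are
volume, volume ratio (ratios over parts sum to 1 exactly), and the 18
first-order statistics; an empty part yields zeros plus an
`empty_habitat` flag.

## Model building

All selection and fitting consume training rows only; feature z-scoring
parameters, ICC decisions, pruning order, λ, stepwise selection and
classification thresholds are frozen on the training cohort and applied
unchanged to the test cohort (verified by a test that poisons held-out
rows and checks bit-identical fits).

After the ICC filter, features are z-scored on training statistics and
greedily decorrelated: while any pair exceeds |r| > 0.9, the member of
the worst pair with the larger mean absolute correlation to the
remaining features is dropped (ties: later name alphabetically). The
LASSO logistic signature uses a 40-point geometric λ path from
λ_max = max|Xᵀ(y−ȳ)|/n down by 10⁻³, 10-fold stratified CV on binomial
deviance, and the **1-SE rule** (largest λ within one standard error of
the deviance minimum). The plain minimizer is available
(`rule="min"`), but measured on planted-support simulations (3
informative + 47 noise features, n = 400) it admits 10–20 noise
features per fit whereas the 1-SE rule keeps false positives ≤5 while
retaining all informative features in 9/10 seeds — selection
consistency drove the default. Radscore = β + Σωᵢχᵢ is the penalized
fit's own linear predictor; model probabilities are its logistic
transform. If nothing survives, the signature degenerates to
logit(prevalence), flagged. The underlying solver leaves the intercept
effectively unpenalized (glmnet convention).

The clinical model is a bidirectional stepwise logistic regression from
the full covariate design (treatment-coded dummies), minimizing
AIC = 2k − 2lnL; ties prefer drops, then alphabetical order. The two
combined models are plain logistic fits on the clinical model's
*selected* variables plus the corresponding signature score, with **no
second selection** — deliberately, so that overfitting of a rich
signature shows up in the train/test gap rather than being masked.
Class imbalance is left unweighted.

Every model carries the training-cohort Youden threshold: the observed
cut-point maximizing sensitivity + specificity − 1 (ties: higher
specificity, then lower cut), returned as the midpoint of the gap below
the winning cut-point; classification is "probability ≥ threshold".

## Evaluation

AUC is the Mann–Whitney statistic with ties counted ½ (tested against
exhaustive pair counting to 10⁻¹²). Variances, 95% CIs (normal
approximation on the AUC scale, truncated to [0,1]) and paired tests
use DeLong placement values; identical score vectors give p = 1, and a
zero-variance contrast with unequal AUCs is an error (recorded as NaN
in the pairwise report matrix). Confusion metrics come from raw counts
with zero-denominator ratios reported as 0 and flagged. Decision curves
report NB(p_t) = TP/n − (FP/n)·p_t/(1−p_t) on a 0.01–0.99 grid against
treat-all (π − (1−π)p_t/(1−p_t)) and treat-none (0); model input is the
fitted model's probability scale. F1 is computed from counts.

Null calibration of the DeLong test (two independent noise scores,
n = 1000, 500 replicates) keeps the type-I error within [0.03, 0.07] at
α = 0.05, and CI coverage at true AUC 0.75 (binormal, n = 100, 500
replicates) lies within [0.92, 0.98]; both are asserted in the test
suite.

## Problem sizes and determinism

The acceptance script runs the full pipeline at the emulated study
scale (181 cases, 64³ grids, ~5–15 k ROI voxels per tumor, 7:3
stratified split reproducing 127/54 with 42/18 good responders). The
test suite uses the same study conditions for noise and effect sizes
but smaller cohorts/grids where only contracts are exercised (e.g.
36-case, 40³ mini-pipelines for determinism; 30 default phantoms for
habitat recovery) — sizes chosen as the smallest that leave the checked
statistics stable. Full-pipeline reruns under a fixed config produce
byte-identical CSV/JSON artifacts (SHA-256-verified).

## Known limitations

* Phantom geometry is ellipsoidal with normal within-habitat noise; no
  infiltrative margins, no spatial intensity gradients, no inter-scanner
  harmonization problem.
* The second-rater surrogate perturbs masks morphologically, which
  under-represents the structured disagreement of human readers; ICC
  values on phantoms are optimistic.
* The per-patient clustering + canonical labeling strategy assumes the
  same three habitat archetypes exist in every tumor; tumors genuinely
  lacking a habitat receive a small spurious part rather than an empty
  one (K is global, not per-case).
* Real-cohort discrimination values are not reproducible from synthetic
  data; synthetic AUCs quantify recoverability of the planted effect
  under the default conditions, nothing more.
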