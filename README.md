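# habitatpipe

Tumor **habitat imaging** pipeline for predicting response to
neoadjuvant chemoradiotherapy (nCRT) in locally advanced rectal cancer
(LARC), built for methodologists who want every stage — subregion
clustering, radiomics, signature modeling, evaluation — as tested,
reusable code that runs end to end on synthetic phantoms with known
ground truth.

## The analysis

A tumor observed on co-registered T2-weighted and ADC volumes is rarely
homogeneous: necrotic pockets (low T2, high ADC), densely cellular
regions (low ADC) and well-perfused tissue (high T2) respond
differently to chemoradiation. The pipeline quantifies this spatial
heterogeneity and turns it into a response model:

1. **Preprocess** — Z-score the T2 image, apply a joint 3σ
   re-segmentation inside the tumor mask, discretize to 16 gray levels.
2. **Habitats** — cluster each tumor's voxels in joint z-scored
   (T2, ADC) space with K-means; pick K by the mean Calinski–Harabasz
   score CH = [B/(K−1)]/[W/(n−K)] over training cases; label parts
   canonically (1 high-T2, 2 low-T2/high-ADC, 3 low-T2/low-ADC).
3. **Features** — per habitat: volume, volume ratio and 18 first-order
   statistics per modality; whole-tumor: first-order + volume + 75
   2.5-D-merged texture features (GLCM/GLRLM/GLSZM/GLDM/NGTDM) + coif1
   stationary-wavelet first-order features (476 per case).
4. **Models** — ICC(2,1) ≥ 0.75 stability filter, |r| > 0.9 Pearson
   pruning, then a LASSO logistic signature with 10-fold CV whose
   linear predictor is the radiomics score

   Radscore = β + Σᵢ ωᵢ χᵢ

   Five models are fitted: Clinic (stepwise-AIC logistic on clinical
   covariates), Radiomics, Habitat (signatures), and Clinic+Radiomics /
   Clinic+Habitat (clinical selected terms + score, no re-selection).
5. **Evaluation** — AUC with DeLong 95% CIs and paired DeLong tests,
   confusion metrics at the training-cohort Youden threshold, and
   decision-curve net benefit NB(pₜ) = TP/n − (FP/n)·pₜ/(1−pₜ) against
   treat-all/treat-none.

Because no patient imaging ships with the package, a first-class
synthetic module generates cohorts of ellipsoidal phantoms whose tumors
contain three spatially contiguous planted habitats, with clinical
covariates and labels from a calibrated logistic model (~181 patients,
~33% good responders). Ground truth is retained, so recovery of the
planted structure is testable. See `docs/methods.md` for every modeling
choice and its rationale.

## Worked example

```python
from habitatpipe import PipelineConfig, run_all

cfg = PipelineConfig(n_cases=181, seed=1, outdir="results/pipeline")
res = run_all(cfg)
print("selected K =", res.ch_result.selected_k)
print(res.report["table"][["model", "split", "auc", "accuracy",
                           "sensitivity", "specificity"]].to_string(index=False))
```

prints (about 2.5 minutes on one CPU):

```
selected K = 3
           model split      auc  accuracy  sensitivity  specificity
          Clinic train 0.743881  0.677165     0.897436     0.579545
          Clinic  test 0.550079  0.537037     0.588235     0.513514
       Radiomics train 0.763986  0.732283     0.666667     0.761364
       Radiomics  test 0.713831  0.666667     0.647059     0.675676
         Habitat train 0.740385  0.755906     0.512821     0.863636
         Habitat  test 0.748808  0.740741     0.529412     0.837838
Clinic+Radiomics train 0.850816  0.700787     1.000000     0.568182
Clinic+Radiomics  test 0.689984  0.592593     0.705882     0.540541
  Clinic+Habitat train 0.828380  0.740157     0.923077     0.659091
  Clinic+Habitat  test 0.726550  0.666667     0.647059     0.675676
```

Reading it: the CH criterion recovers the three planted habitats
(K = 3); the habitat-based models carry the planted effect to held-out
cases (Habitat test AUC ≈ 0.75) while the clinical covariates alone are
weak (test AUC ≈ 0.55); the combined clinical+radiomics model shows the
classic train/test overfitting gap that motivates comparing all five
models. Test-set metrics always use the training Youden threshold.
Artifacts (feature tables, `models.json`, `report.csv`, DCA curves,
DeLong matrices, habitat label volumes) land in `results/pipeline/`.

The same flow is available as numbered drivers —
`analysis/01_simulate_cohort.py` … `analysis/04_fit_and_evaluate.py` —
and as a CLI (`habitatpipe simulate|features|split|run-all`).

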