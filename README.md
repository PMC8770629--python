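# temporalis

Deep-learning segmentation and quantification of the temporalis muscle on
axial head MRI, with downstream survival analysis of the resulting
cross-sectional-area (CSA) biomarker — packaged so the entire pipeline can
be exercised, tested and benchmarked on synthetic head phantoms and
simulated patient cohorts, with no imaging data download.

## Why

Sarcopenia (loss of skeletal muscle mass) predicts worse outcomes in many
cancers. Patients with brain tumours get routine head MRI rather than body
CT, and the temporalis muscle's cross-section on an axial slice is a
practical surrogate for total skeletal muscle mass. Measuring it by hand is
slow and rater-dependent; this package automates the measurement with a 2D
U-Net and then asks the clinical question: do patients with larger
temporalis CSA live longer?

## What is inside

- **`phantom`** — seedable generators for (a) head-like 2D slices with two
  bilateral crescent "muscles" and exact ground-truth masks, and (b) patient
  cohorts with sex-specific CSA ~ N(μ_sex, σ_sex²) and survival times from
  an exponential proportional-hazards model with a high-vs-low CSA group
  effect and independent censoring.
- **`imaging_io`** — NIfTI I/O (via nibabel), axial slice extraction, and
  the preprocessing chain: polynomial bias-field correction, Z-score
  normalisation ((x − μ)/σ over the slice), resampling to 1×1 mm and
  centre crop/pad to 256².
- **`unet`** — the 2D U-Net: 4 down/up-sampling stages, two 3×3 conv +
  batch-norm + ReLU per stage, 2×2 max pooling, 2×2 transposed-conv
  upsampling with skip concatenation, dropout 0.5 at the two deepest
  stages, and a 1×1 conv + sigmoid head binarised at p ≥ 0.5. At the
  default 256 px input the bottleneck is a 16×16×1024 representation.
  Implemented in NumPy with hand-written backpropagation.
- **`losses`** — the three loss families compared for this task:
  binary cross-entropy −(1/N) Σᵢ [gᵢ log pᵢ + (1−gᵢ) log(1−pᵢ)],
  Dice loss 1 − 2Σpᵢgᵢ/(Σpᵢ+Σgᵢ), and the differentiable
  weighted-Hausdorff surrogate (generalized-mean soft-min, α = −9).
- **`trainer`** — Adam, mini-batch 2, learning-rate grid
  {1e-4, 5e-4, 7.5e-4, 1e-3, 1e-2} selected on validation loss, early
  stopping with patience 3, best-epoch checkpointing.
- **`metrics`** — DSC, Jaccard, precision, recall, Hausdorff distance in
  mm, CSA error %, and Pearson + Bland–Altman agreement of areas.
- **`quantify`** — connected-component split into left/right muscles and
  CSA = pixel count × pixel area, averaged over sides per patient.
- **`survival`** — median dichotomisation, Kaplan–Meier with log-rank,
  univariate and age/sex-adjusted Cox models (HR = exp β, Wald 95% CI;
  lifelines, Efron ties).

## Worked example

`python examples/04_train_and_evaluate.py` trains the reduced-scale network
(64 px phantoms, 16 base channels, Dice loss) on 30 phantoms and evaluates
10 held-out ones:

```
trained 12 epochs; best epoch 12 (val dice loss 0.2249)
           dsc: 0.9880 ± 0.0040
            ji: 0.9764 ± 0.0079
     precision: 0.9896 ± 0.0058
        recall: 0.9865 ± 0.0065
         hd_mm: 2.1657 ± 0.3493
 csa_error_pct: 0.7856 ± 0.5525
```

A mean DSC of 0.988 means the predicted muscles overlap the ground truth
almost pixel-for-pixel; the Hausdorff distance of ≈2 mm (one 2 mm pixel)
and sub-percent CSA error say boundaries and areas are equally tight.

`python examples/06_survival_analysis.py` runs the clinical half on a
simulated 200-patient cohort (true group effect HR 0.464):

```
median CSA 568 mm² -> 100 low / 100 high
  low: n=100, events=85, median survival 23.5 mo
  high: n=100, events=74, median survival 41.9 mo
log-rank p = 0.0000
univariate HR 0.434 (95% CI 0.310-0.608)
adjusted   HR 0.431 (95% CI 0.300-0.619)
male CSA 610 ± 99 vs female 471 ± 101 mm² (t-test p=8e-14)
```

The fitted hazard ratios bracket the simulated truth: high muscle mass is
protective, and the effect survives adjustment for age and sex.

The other examples cover phantom/cohort generation, preprocessing, the
loss comparison and CSA quantification. A thin CLI mirrors the API:
`temporalis simulate phantoms|cohort`, `temporalis train`,
`temporalis evaluate`, `temporalis quantify`, `temporalis survive`.

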