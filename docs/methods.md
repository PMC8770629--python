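# Methods

This note documents the models, numerical choices and deliberate
assumptions behind the package, in the order data flows through it.

## Synthetic phantoms

Real temporalis segmentation is trained on axial T1 head MRI. The phantom
generator emulates the features of that task that drive the pipeline —
bilateral, crescent-shaped targets of controlled physical area embedded in
higher- and lower-intensity structures, with additive noise and smooth
multiplicative bias — and nothing else. Each phantom is built from:

- an elliptical skull ring (intensity 0.85) around an elliptical "brain"
  (0.40) on a zero background;
- per side, a crescent formed as the set difference of two equal-radius
  discs, the inner one shifted medially by a factor ~U(0.9, 1.1) of the
  radius; the radius is solved from the closed-form crescent area and then
  adjusted multiplicatively (≤ 60 iterations) until the *pixelated* area
  times spacing² lies inside the requested range, so the recorded truth is
  an exact pixel count. Placement jitter defaults to ±2 px;
- muscle intensity = brain + `muscle_contrast` (default 0.30), applied
  before corruption;
- optional multiplicative bias: an exponentiated random degree-2
  polynomial rescaled so its peak-to-trough ratio equals
  `bias_amplitude`; optional additive Gaussian noise (default σ = 0.05,
  i.e. 1/6 of the muscle contrast).

The generator guarantees (and the suite fuzzes) the bilateral invariant:
exactly two 8-connected foreground components, one centroid on each side
of the vertical midline, each within the area range. Unsatisfiable
requests (a crescent that cannot fit the image) raise at spec construction.

What the phantoms do *not* model: anatomical texture, partial-volume
boundaries, neighbouring muscles of similar intensity, pathology, or 3D
context. Passing the phantom benchmark therefore demonstrates that the
architecture, losses, trainer, metrics and quantification are implemented
correctly and can learn a bilateral segmentation task end to end — not
that the trained weights transfer to clinical MRI.

Randomness: numpy PCG64; each sample's stream is
`SeedSequence(seed, spawn_key=(index,))`, so generation is bit-reproducible
across runs and platforms and safe to parallelise.

## Cohort simulator

Patients are drawn as: sex ~ Bernoulli(male_fraction); CSA ~ N(μ_sex,
σ_sex²); age ~ N(55, 10²) (age is a covariate, independent of CSA in the
simulator); group = high iff CSA ≥ within-cohort median; event time ~
Exp(h), h = h₀·exp(β·1[high]); censoring time ~ Exp(c); the observed time
is the minimum and the event flag marks which came first. Defaults are
calibrated once to a glioblastoma cohort: n = 45, 75.6% male, male/female
CSA 607 ± 100 / 472 ± 109 mm², h₀ = ln2/18.3 per month (median overall
survival 18.3 months), β = ln 0.464 (protective high-CSA effect), c =
0.005/month (≈ 11% censored). The exponential baseline makes the
proportional-hazards assumption exact, which is what the Cox
parameter-recovery checks need.

## Preprocessing

Order: bias correction → Z-score → resample → crop/pad.

- **Bias correction** divides out exp(P̂), where P̂ is a least-squares
  polynomial fit (default degree 2) to log-intensities on the
  dominant-tissue band — non-background pixels within [0.6, 1.4]× the
  median intensity, in the spirit of white-stripe-style normalisation.
  Restricting the fit to one tissue band keeps genuine anatomical contrast
  (the bright skull rim is itself a smooth radial pattern) out of the
  estimated field. `bias_degree=0` disables the step, so images corrected
  upstream by a dedicated tool (e.g. N4) pass through unchanged; this
  module intentionally does not re-implement N4.
- **Z-score** uses whole-slice statistics (no brain mask): deterministic
  and mask-free, at the cost of background pixels influencing μ and σ.
  Constant slices raise, naming the slice.
- **Resampling** is linear interpolation to the target spacing (nearest
  neighbour for masks, which must stay binary), followed by centre
  crop/zero-pad to the fixed grid — not an anisotropic stretch, so pixel
  area keeps its physical meaning for CSA. Resizing perturbs the
  post-Z-score moments slightly; that is expected and documented rather
  than re-normalised away.

Conventions: row 0 is the top of the image; slice index 0 is the
inferior-most axial slice; `extract_axial_slice(volume, f)` takes index
`round(f·(n−1))`. Left/right of the *image* is assigned by centroid versus
the central column; the patient-side reading under radiological display is
a display convention, not a computation.

## Network

A standard 2D U-Net (depth 4, base 64 channels by default; 16×16×1024
bottleneck at 256 px input). Choices the architecture description leaves
open, fixed here: activation ReLU; conv → batch-norm → ReLU ordering; the
two dropout layers (rate 0.5) sit after the deepest encoder stage and
after the bottleneck, the common placement; upsampling is a learned 2×2
stride-2 transposed convolution. Inference uses batch-norm running
statistics with dropout off, so prediction is deterministic; the 0.5
binarisation threshold sends ties to muscle.

The layers are implemented directly in NumPy (im2col convolutions backed
by BLAS GEMM, float32 throughout) with hand-written backward passes and an
Adam optimiser. Backpropagation was verified against central finite
differences: the directional derivative over the full parameter vector
converges to the analytic value as ε → 0 (0.1% at ε = 1e-5), and
per-parameter checks agree except at the expected ReLU/max-pool kink
noise. He-normal initialisation, seeded per layer from a single model
seed.

## Losses

- BCE with predictions clipped to [1e-7, 1 − 1e-7]: the bare formula is
  −∞ at saturated pixels; clipping is the standard remedy and bounds the
  worst case at −log ε.
- Dice loss with smoothing s = 1e-6 in numerator and denominator: the
  bare ratio is 0/0 when both maps are empty; smoothing defines that case
  as loss 0 and matches common library implementations. For binary
  predictions 1 − loss equals the DSC metric to within s.
- Weighted-Hausdorff surrogate: term 1 averages distance-to-truth over
  predicted mass, (Σ p·d(x,Y))/(Σp + ε); term 2 is the mean over
  ground-truth pixels of the generalized power mean M_α over pixels of
  p·d + (1−p)·d_max, with α = −9 (a soft minimum), ε = 1e-6 stabiliser,
  distances in pixel units, d_max the image diagonal. Undefined (raises)
  for an empty ground truth. The implementation is evaluated in chunks
  over ground-truth points to bound the pairwise-distance matrix; its
  gradient is analytic and finite-difference-checked.

## Training protocol

Adam on mini-batches of 2 (seeded reshuffle each epoch); validation loss
is the same loss as training, computed per-image in inference mode;
"improvement" is a strict decrease below the running best (no min-delta);
stopping occurs after `patience` = 3 consecutive non-improving epochs; the
returned weights are the best epoch's, not the last. The learning-rate
grid search trains one fresh seeded model per candidate
({1e-4, 5e-4, 7.5e-4, 1e-3, 1e-2} by default) and breaks ties toward the
smaller rate. No data augmentation (an extension point, deliberately
unused).

Problem sizes: the suite and the acceptance script train at 64 px /
2 mm / 16 base channels (≈ 50 s per run), the package's chosen desk-scale
configuration; the 256 px / 64-channel default remains the intended
real-data configuration.

## Metrics

Overlap metrics from TP/FP/FN pixel counts with explicit degenerate
conventions: both masks empty → all four metrics 1; exactly one empty →
DSC = JI = 0 and the undefined ratio reported as 0. Hausdorff distance is
the full (100th percentile) symmetric distance between foreground
pixel-center point sets in physical mm — over all foreground pixels, not
boundaries, which is equivalent for filled shapes and trivial to verify by
brute force. CSA error is |CSA_pred − CSA_gt|/CSA_gt × 100. Summaries are
per-image mean ± SD, not pooled-pixel statistics. Area agreement uses
Pearson r (two-sided) and Bland–Altman mean difference ± 1.96 SD.

## Quantification

CSA = foreground pixel count × (row spacing × col spacing). Pixel-count
area, not polygonal contour area: it is deterministic, exactly matches the
generator's bookkeeping, and is unbiased for filled regions; contour-based
areas differ by a sub-percent boundary term and are out of scope.
Components under 10 mm² (configurable) are discarded as specks; the two
largest survivors are assigned left/right by centroid column versus the
image midline. Degenerate cases — a single component, or both components
on one side — are quantified anyway and *flagged*, so e.g. surgically
disrupted muscles surface in the output instead of being silently averaged.

## Survival analysis

Median dichotomisation is computed per cohort (never pooled), with the tie
rule `csa ≥ median → high` by default. For odd cohorts of distinct values
this puts the median patient in the high group (a 45-patient cohort splits
22/23); published cohorts exist under both conventions, so the rule is
configurable. Kaplan–Meier median survival is the first time S(t) ≤ 0.5,
reported as not-reached (inf) otherwise; the log-rank test is two-sided.
Cox models use the partial likelihood with Efron tie handling (lifelines),
coding group high = 1 and sex male = 1; hazard ratios are exp(β) with Wald
95% CIs. Models refuse to fit with zero events or constant covariates, and
an independent grid-search maximisation of the partial likelihood guards
the fit on a tie-free toy table in the tests. The cohort characteristics
table uses Pearson correlation (CSA vs age) and a Welch t-test (CSA by
sex), skipping with a notice when degenerate.

## Known limitations

- Phantoms are piecewise-constant cartoons; clinical performance is out of
  reach of this repository by construction (no patient data ships with it).
- The bias-correction stand-in assumes a dominant tissue class; strongly
  trimodal images would need the band widened or a dedicated tool upstream.
- The NumPy network trains on CPU at desk scale only; there is no GPU path,
  augmentation, or mixed precision.
- Whole-image Z-score ties normalisation to field-of-view composition.
- The weighted-Hausdorff loss is not guaranteed monotone along a linear
  homotopy toward the truth at every step; the suite asserts overall
  decrease only.
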