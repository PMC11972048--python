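# Methods

This package implements joint early pre-spatial (JEPS) fusion — injecting a
tabular-data embedding into a volumetric CNN *before* most of its spatial
processing — together with the complete harness needed to compare it fairly
against the common alternatives: single-modality baselines, early fusion via
radiomics, late (prediction-averaging) fusion, and joint late (post-flatten)
fusion. Because no patient cohort is distributed with the package, every
claim the test suite makes is grounded in synthetic phantom cohorts with a
known generating model, plus exact regressions of the published
cross-validation summary statistics and architecture parameter totals.

## Model designs

All volumetric designs share one backbone, a 3-D CNN in the ResNet-18
pattern operating on a `(depth, height, width, 3)` input with channels
(CT, dose, PTV mask), each normalized to [0, 1]:

* **Stem** — 5×5×5 convolution, stride 2, 16 filters (bias), batch
  normalization, ReLU, then 3×3×3 max-pooling with stride 2. Together the
  stem reduces every spatial axis by 4× (ceil division), so a
  90×128×128 input yields a 23×32×32×16 activation.
* **Stages** — four stages of two post-activation basic blocks
  (3×3×3 conv + BN + ReLU, twice, plus the residual shortcut) with
  16/32/64/128 filters; stages 2–4 downsample by stride 2 in their first
  block. Shortcuts that change resolution or channel count are 1×1×1
  convolutions with bias and no normalization.
* **Head** — global average pooling, then dense layers 72 → 60 → 16. The
  final 16-wide layer is the *volume embedding*; a sigmoid unit on top of it
  produces the survival probability.

The clinical branch used by both joint designs is a dense network with
incremental size reductions, 78 → 32 → 16, dropout-interleaved (rate 0.3),
ending in a 16-wide *clinical embedding*.

* **Joint late fusion** concatenates the two embeddings (width 32) after all
  spatial processing and predicts through dense 32 → 16 → 1.
* **JEPS** passes the clinical embedding through an upsampler — one more
  dense 16 → 16 layer, reshape to 1×1×1×16, and spatial repetition to the
  post-stem grid — and concatenates it on the channels axis (16 + 16 = 32)
  before stage 1, whose first block therefore consumes 32 channels and gains
  a projection shortcut. Every subsequent convolution sees both modalities,
  so clinical information can steer spatial feature extraction directly
  rather than only through backpropagated loss signals.

### Calibration to the published parameter totals

The published description of the backbone fixes its topology but not every
layer-level convention (kernel sizes, bias usage, normalization placement,
exact head widths). We resolved these frozen degrees of freedom by integer
search against the three published totals — 2 094 341 (volume-only),
2 104 243 (joint late), 2 111 427 (JEPS) — requiring one configuration to
reproduce all three simultaneously. The configuration above is the unique
solution found with canonical doubling stage widths; notable consequences
are the 5×5×5 stem (a 7×7×7 stem admits no exact solution under any
combination of bias/normalization/head conventions we enumerated), the
two extra head layers (72, 60) above the 16-wide embedding, biased
un-normalized projection shortcuts, and the extra dense layer inside the
JEPS upsampler which accounts for the "additional upsampling" parameter
excess (27·16·16 = 6 912 for the widened stage-1 convolution, 528 for the
new projection, 272 for the upsampler dense layer, −528 for the narrower
single head). Totals count trainable parameters; batch-normalization
running moments are buffers. `count_parameters` reproduces all three
totals exactly and the test suite regresses them.

## Neural-network engine

No deep-learning framework is part of the package's dependency set; the
layers above are implemented in a small numpy engine
(`jeps.nn`) with explicit backpropagation: im2col-based 3-D convolution
("same" padding, TensorFlow stride semantics), batch normalization with
running statistics, inverted dropout, max/global-average pooling, Adam, and
a class-weighted binary cross-entropy whose gradient is fused with the
output sigmoid for numerical stability. All computation is float32 and
single-threaded-BLAS friendly; every gradient is validated against central
finite differences in the test suite. Biases of convolutions that feed a
batch-normalization layer are mathematically inert (the normalization
cancels any constant offset); they are retained because the parameter
totals include them.

## Training protocol

Stratified k-fold cross-validation (default 10; the phantom experiments use
5) with seeded shuffles; per fold, 10% of the training rows (stratified)
are held out for validation. All preprocessing that learns from data — the
clinical encoder's min-max ranges and one-hot vocabularies, the radiomics
min-max scaling and variance filter — is fitted on that fold's training
rows only; a mutation test asserts that altering test rows cannot change
any fitted parameter. Networks train with Adam on weighted BCE (positives
2:1), batch size 25, learning-rate halving on a validation plateau, early
stopping, and best-weight restoration (restoration is our choice; common
practice). Volume inputs receive on-line augmentation with probability 2/3
per volume per epoch — exactly one of: 3-D zoom 0.8–1.2, in-plane rotation
±15°, or in-plane shift up to 20% of the axis extent (never axial); CT and
dose interpolate linearly, the mask nearest-neighbor so it stays binary.
Clinical-only models are never augmented. The late-average design reuses
the fold's trained clinical MLP and volume ResNet and averages their
predicted probabilities.

The Cox proportional-hazards baselines are ridge-penalized fits (lifelines,
penalizer 0.1, escalated tenfold on ill-conditioned designs) on genuine
(time, event) pairs; their risk score is the partial hazard, evaluated by
AUC against the 2-year label like every other design.

## Phantom cohorts

Each phantom patient has: a pseudo-CT (air/soft-tissue/bone-shell head
ellipsoid with noise), an ellipsoidal tumor of randomized size and position
offset to a randomly drawn ipsilateral side, both parotid glands (the
axial-centering reference), a smooth peaked dose field whose center is
deliberately jittered off the tumor and whose maximum is scaled to at most
the 70 Gy prescription, and a clinical record (2 numeric + 6 categorical
fields) noisily reflecting a latent tabular risk score `z_tab`. The
spatial risk feature `z_vol` is the *cold-margin fraction* — the fraction
of tumor voxels receiving < 90% of the prescription — standardized over
the cohort. It was chosen because tabular models cannot see it and
intensity-only radiomics destroys it unless the dose channel is included.
Outcomes follow

    logit(p) = b0 + bt·z_tab + bs·z_vol + bi·z_tab·z_vol + e,

with defaults bt = bs = 1.5, bi = 1.0, e ~ N(0, 0.5²); `b0` is solved by
root-finding so the cohort's expected 2-year death prevalence matches the
configured 63/222 ≈ 0.284. Survival times are exponential with the rate
tied to p (P(T ≤ 24 mo) = p) and follow-up always exceeds 24 months, so
labels are never censored before the endpoint and Cox baselines receive
real time/event data. Each patient draws from an independent stream spawned
from the cohort seed, so cohorts are bitwise reproducible.

What the phantom does *not* emulate: realistic anatomy and beam physics,
multi-lesion disease, censoring before 2 years, missing data, and any
claim about real head-and-neck biology — the generating model is a stand-in
that makes recovery measurable, not an epidemiological statement. Passing
the recovery tests shows the pipeline can find a planted cross-modal
signal at the stated sizes; it does not predict clinical performance.

## Problem sizes and the micro profile

The package supports the full-scale geometry (2 × 2 × 2.5 mm voxels,
90×128×128×3 crops), and all shape/parameter contracts are tested at that
scale. The *experiments* that actually train networks run on a micro
profile chosen so a complete cross-validated comparison finishes in
minutes on one CPU core: grid 12×16×16 at ~1 cm voxels, n = 200 patients,
5 folds, 32 training epochs with initial learning rate 3·10⁻³ (the larger
rate compensates the much shorter schedule; plateau halving still applies).
The fusion-point semantics are unaffected because the profile scales the
volume, not the architecture topology. Under this profile the recovery
experiments ask for direction, not magnitude: the generating-model oracle
AUC bounds every model, JEPS beats the volume-only baseline on average,
and JEPS's Shapley modality balance is closer to parity than joint-late's.

## Evaluation and attribution

AUC is the midrank Mann–Whitney statistic (ties credit ½), checked against
brute-force pair counting. Cross-validation summaries are mean ± the 95%
Student-t half-width over fold AUCs; design pairs are compared with paired
two-tailed t-tests on the fold-wise differences at α = 0.05, uncorrected
by default (a Bonferroni flag exists). Zero-variance difference vectors
report p = 1 with a warning rather than an error.

Shapley attributions use permutation sampling: players are clinical
features plus cubic volume blocks (all channels toggling together; default
edge 4, per-voxel for tiny grids), the baseline is the per-position
training-set mean, and the attribution target is the predicted
probability. The estimator is unbiased for the block-grouped game,
satisfies efficiency exactly per sampled permutation, and is validated
against full subset enumeration on ≤ 12-player games. Per-modality
influence is the sum of absolute attributions; balance is reported as
log10(volume/clinical). Heatmaps are voxel-block means over patients with
three axis-flattened views, each independently scaled for display.

## Numerical choices and edge cases

* Resampling: cubic splines for CT and dose (exact on cubics; the ramp
  test pins this), nearest-slice assignment and polygon filling for masks
  so binarity is never interpolated away. Aligned dose is floored at 0 Gy
  because cubic splines can undershoot on non-negative fields.
* Rasterization boundary rule: a voxel belongs to a contour if its center
  is inside *or on* the snapped polygon (shapely point-in-polygon;
  verified against an independent ray-casting oracle). Degenerate snapped
  polygons fall back to marking their vertex cells.
* Parotid centering uses the midpoint of the min/max axial positions over
  the union of both glands; in-plane crops center on the grid center;
  out-of-window regions are zero-filled (the post-normalization floor).
* Clinical encoding: out-of-range test numerics pass through the affine
  map unclamped (ordering information preserved); unseen categories encode
  as all-zero blocks; constant training numerics encode as 0 with a
  warning; records with missing values are rejected rather than imputed.
* Variance filter: population variance of min-max-scaled training values,
  strict `< 0.05` rejection.
* Fold assignment round-robins a single cursor across classes so remainder
  patients spread over folds (fold sizes differ by at most 1).
* Seed fan-out: every stage derives its seed from the global seed and a
  stage tag via CRC32, so stages are independently reproducible.

## Known limitations

Training 2-million-parameter 3-D CNNs in a numpy engine is CPU-bound; the
micro profile trades resolution and epochs for runtime, which caps
achievable AUCs well below the generating-model oracle and leaves the
JEPS-vs-joint-late ordering noisy at small effect sizes — on this phantom
the planted interaction acts at the outcome level, which a post-flatten
joint head can also represent, so JEPS's structural advantage (clinical
information steering feature extraction) is not strictly required to fit
the signal. The radiomics suite is deliberately compact (27 features; no
wavelet classes) and pluggable. DICOM support covers the axial,
identity-orientation geometry the fixtures generate, not the full breadth
of clinical exports.
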