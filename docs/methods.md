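# Methods

This note documents the models, parameters, numerical choices and known
limitations of the package. It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## Conventions

Arrays are (z, y, x); voxel spacing is isotropic in mm; the anatomical
left–right axis is x with "left" = lower x index. Labels: 0 background,
1 AL (antennal lobes), 2 MB (mushroom bodies), 3 CX (central complex),
4 ME (medullae), 5 LO (lobulae), 6 OTH (remaining neuropils). The optic
lobes OL are always derived as ME + LO and never stored as a voxel label.
Reported relative volumes are percentages of the total over the five groups
{AL, MB, OL, CX, OTH}, which sum to 100 by construction.

## Synthetic phantom generator

The generator emulates the statistical structure of a stained micro-CT bee
cohort, not its anatomy.

**Cohort draws.**  Per specimen and neuropil, the absolute volume is drawn
lognormally with the preset arithmetic mean and coefficient of variation
(lognormal because volumes are positive and right-skewed; the distributional
family of real inter-individual variation is not established, which is an
assumption of this generator).  A lognormal hive-level multiplier (CV
`hive_cv`, default 0.03; bumblebee 0.045) is shared by all specimens of a
hive and creates colony effects.  Paired neuropils split into sides via
ln(L/R) = ln(1−δ) + ε, ε ~ N(0, `lateral_noise_cv`); δ = 0 and
`lateral_noise_cv` = 0.02 by default, so cohorts are unlateralized with a
small per-specimen fluctuation.  Mushroom bodies touch across the midline
with probability `p_merge_mb` (honey-bee preset 0.46 and bumblebee 0.53 —
the observed fractions of merged-MB segmentations, 51/110 and 41/77).

**Presets.**  The honey-bee preset uses the forager cohort scale: means
(mm³) AL 0.0284, MB 0.134, CX 0.0033, ME 0.146, LO 0.045, OTH 0.166 with
the matching CVs (s.d./mean, e.g. AL 0.0033/0.0284).  The bumblebee preset
keeps the means and multiplies all CVs by 1.6, reflecting the roughly
1.5–1.7× wider ranges reported for bumblebee cohorts.  All values are
overridable.

**Rendering.**  Each neuropil is rasterized as an ellipsoid (per-structure
axis ratios, anatomically inspired placement: paired AL anterior, MB dorsal
flanking the midline, CX small and central, ME/LO lateral, OTH a posterior
mass).  Because a desk grid cannot hold a 0.52 mm³ brain at 5.4 µm voxels,
volumes are rescaled so that the mean brain fills `fill_fraction` (default
0.10) of the grid; relative proportions are preserved.  The label volume is
the exact rasterization; achieved voxel-true volumes (count × spacing³) are
recorded back into the cohort table since rasterization quantizes targets.
The image is a per-tissue grayscale lookup (distinct tissues separated by
more than 2× the noise s.d.), Gaussian-blurred (σ 0.7 voxels) with additive
Gaussian noise (s.d. 0.05) — a high-contrast caricature of phosphotungstic-
acid-stained micro-CT.  Structures are disjoint by construction except
deliberate MB merges; a collision or grid overflow raises a render error
naming the structure.

**What passing tests show — and do not.**  Phantoms share one layout and
differ only in structure sizes, side ratios, gray draws and noise, so
segmentation results on phantoms demonstrate that the training/inference
machinery works, not that the network handles real anatomical variability,
staining gradients or scanner artefacts.  Statistical results (type-I
error, power, df) transfer, since they depend only on the cohort model.

## Preprocessing

The denoiser is the arithmetic mean filter with a 3×3×3 mask.  Borders are
reflect-padded (a choice; the underlying description is silent), and the
brute-force oracle in the tests uses the same policy.  Intensity
standardisation is the affine map to zero mean, unit variance; constant
volumes are rejected.  z-flip is an involution and records its flag.

Automatic cropping trains one small 2D CNN per axis (conv 1→4→8 with batch
norm, global average pooling, dropout 0.3, sigmoid head) to classify
whether a slice contains any foreground, in two phases: head-only (Adam,
lr 10⁻³) then full fine-tuning — the full-scale schedule fine-tunes at
10⁻⁵ per the original transfer-learning recipe, while the desk preset uses
10⁻³ because a from-scratch backbone needs a real second-phase rate.  The
crop box is the first-to-last present slice per axis expanded by a buffer
of 25 slices for 256-voxel axes, scaled as round(25·len/256) with a floor
of 2 for small grids, and clamped.  Slice ground truth is "any
non-background label voxel in the slice", so a 1–2-voxel blob tail makes a
slice positive; this intrinsic label noise caps attainable slice accuracy
at roughly 0.95 on 48³ phantoms.

## Segmentation network

Architecture and optimiser follow the standard 3D U-Net configuration
described above (README).  Implementation notes:

* Convolutions are stride-1 same-padding cross-correlations evaluated as
  one BLAS matmul per kernel offset with scatter accumulation; the input
  gradient is the convolution with the flipped, channel-transposed kernel.
  All gradients (conv, batch norm, pooling via argmax scatter, nearest
  upsampling via sum pooling) are checked against central finite
  differences to < 10⁻⁵ relative error in the test suite.
* Loss is voxel-wise categorical cross-entropy (the loss is not otherwise
  specified; cross-entropy is consistent with monitoring standard
  accuracy).  Overlap fusion averages pre-argmax class scores; majority
  voting is available by flag.  Padding to stride multiples uses zeros on
  standardized images and background on labels, and is cropped after
  stitching.
* Batch-norm running statistics are part of the serialized model state;
  best-epoch selection stores them with the weights.  "Best" = highest
  stitched full-volume validation Dice (cadence configurable, default
  every epoch), never patch accuracy.
* Encoder-only fine-tuning freezes all decoder blocks and the final 1×1×1
  conv; the bottleneck block is counted as encoder.  Frozen weights are
  bit-identical after fine-tuning (batch-norm running statistics, which
  are buffers rather than weights, still track the new data).

**Profiles.**  `NetConfig.full()` is the full-scale configuration (scale
to 256³, patch 64/stride 32, channels 32→1024, 200 epochs, batch 24, SGD
lr 0.01) — GPU-scale, provided for completeness.  `NetConfig.desk()` (96³,
channels 8→128, 40 epochs, batch 4) and `NetConfig.mini()` (32³, patch 32,
channels 8→64, 60 epochs, batch 4, lr 0.1) are the package's reduced
profiles.  Two mini-profile choices deserve explanation:

* *Learning rate 0.1.*  The full-scale rate 0.01 is calibrated for tens of
  thousands of gradient steps per training; the mini schedule takes ~10²
  steps, where 0.01 demonstrably undertrains (loss still descending after
  the full budget).  0.1 with batch norm converges reliably at this scale.
* *Native 32³ phantoms.*  Nearest-neighbour label rescaling 48→32→48 alone
  caps Dice near 0.91, so the mini profile renders phantoms directly at
  the network grid; the desk profile keeps the scale-then-predict path and
  the rescaling round trip is covered by its own invariant test
  (96→64→96 Dice > 0.9).

**Learning-curve experiment.**  Training runs on the first k pool volumes
for k ∈ {2, 4, 8} with a *fixed* epoch count for every k, matching the
original protocol in which each training-set size gets the same number of
epochs (so larger k also means more gradient steps per epoch).  The test
asserts the resulting test Dice is non-decreasing in k for at least 4 of 5
training seeds (at 24³, 30 epochs, batch 2).  Equal-step schedules are
available via `epochs_per_k` for users who want the pure data effect.

## Postprocessing

Island removal: per label, 26-connected components; any component smaller
than `threshold` × the label's largest component is relabelled background.
The threshold semantics (fraction of the label's largest component) are
chosen to make the low default 0.1 coherent: paired neuropils have two
near-equal bodies (ratio ≈ 1), so a high threshold would delete the smaller
body, while 0.1 removes only genuine outliers.  CX is excluded.  The
operation is idempotent and never increases a label's count.

Left/right splitting: the midline is the x-centroid of all paired-label
voxels (robust to off-centre crops, unlike the grid centre); each
26-connected component goes to the side containing its centroid; a
component with > 5% of voxels on each side marks its label non-separable
(counts withheld) — the midline-merged MB case.  The 5% bilateral-span
threshold is an implementation choice, exposed in the API.  Centroid
exactly on the plane: majority voxel side, then left, with a logged warning.

## Evaluation metrics

Dice and ASSD implement the formulas quoted in the README.  |X| in the
total Dice is the total *non-background* voxel count: including background
would inflate scores toward 1 and is inconsistent with per-label correction
burdens; the convention is applied consistently so internal comparisons are
unaffected.  Surfaces are 6-connectivity boundary voxels, with the array
border counting as outside.  A label empty on both sides scores Dice 1 /
ASSD 0 (logged); empty on exactly one side leaves ASSD undefined (NaN,
excluded from the total, logged).  Both metrics are validated against
brute-force oracles (set enumeration for Dice, O(n²) all-pairs distances
for ASSD) on 100 random ≤ 12³ volumes: Dice exact, ASSD within 10⁻⁹.

## Cohort statistics

* Percent variation: (Max − Min) × 100 / Max; scale-invariant, in [0, 100).
* Pearson r with two-sided p from t with n − 2 df; pairwise-complete rows.
* Allometric slope: OLS of log(part) on log(total); isometric when the 95%
  CI contains 1.
* Colony effect: linear mixed model, hive fixed categorical, population
  random intercept, Wald F for the hive term; denominator df follows the
  between/within (containment) convention n − k, so the 110-specimen,
  9-hive design yields F(8, 101).  A single population reduces to one-way
  ANOVA with identical df; singular mixed fits fall back to ANOVA with a
  logged warning.
* Lateralization: Student's paired two-sided t-test on (left − right),
  plus the percentage of specimens with strictly smaller left side; ties
  reported separately (exact equality is common on phantoms, measure-zero
  on real data).  Rows with missing sides (merged MB) are excluded and
  counted, so MB analyses automatically run on the separable subset.
* Asymmetry quadrants: sign of (right − left) for two pairs, strict
  inequalities, ties excluded and reported; percentages over classified
  rows sum to 100.
* Operating characteristics: repeated cohort draws (no rendering) through
  the full table path; with the default 2% side-ratio noise and δ = 0 the
  paired test's type-I rate is ~0.05, and at δ = 0.05, noise 0.03, n = 77
  the power exceeds 0.9 (the per-specimen effect/sd ratio is ≈ 1.7).

## Problem sizes

Test and acceptance runs use the mini profile: 14 phantoms at 32³ (8
train / 2 val / 4 test) for segmentation, 13 phantoms at 24³ for the
learning curve (5 seeds × k ∈ {2, 4, 8}), 200 Monte-Carlo replicates per
operating-characteristic rate, and study-design cohort tables (110 and 77
specimens).  These sizes were chosen so the whole study runs in minutes on
a single CPU while every stage still operates in its intended regime.

## Known limitations

* Phantom geometry is schematic; no CT physics (beam hardening, rings),
  no staining gradients, no anatomical shape variation.
* The pure-numpy network is practical at desk scale only; the full-scale
  profile is provided but not intended for CPU runs.
* The mixed-model F uses the containment-df Wald statistic, not
  Satterthwaite/Kenward–Roger approximations.
* CX at 24–32³ occupies ~10–20 voxels and is frequently missed by the mini
  networks; total Dice is voxel-weighted, so headline scores remain high
  while per-label CX Dice can be 0 at these scales.
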