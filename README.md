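# beemorph

Volumetric morphometry of bee brains from micro-CT imagery: a tested,
reusable implementation of the full analysis chain — denoising, cropping,
patch-based 3D U-Net segmentation of six neuropils, island cleanup,
left/right splitting, voxel-count volumetry, and the cohort statistics used
in comparative studies of honey bees (*Apis mellifera*) and bumblebees
(*Bombus terrestris*).  A synthetic phantom generator stands in for the
micro-CT scans, so every stage is testable without external data.

## Who this is for

Researchers doing large-scale comparative neuroanatomy of insects who want
the segmentation-to-statistics pipeline as importable, testable Python
rather than a chain of GUI tools, and anyone who needs trustworthy
reference implementations of the Dice / average-symmetric-surface-distance
metrics, connected-component island cleanup, or paired left/right
lateralization statistics for labelled 3D volumes.

## The model in brief

**Segmentation.** Volumes are rescaled to a common grid, standardized to
zero mean and unit variance, and cut into overlapping 64³ patches (stride
32).  A 3D U-Net — repeated [3×3×3 conv + batch norm + ReLU] ×2 blocks with
2×2×2 max pooling, channels doubling 32 → 1024, mirrored decoder with skip
concatenations, final 1×1×1 conv — is trained with voxel-wise categorical
cross-entropy under SGD (lr 0.01, decay 10⁻⁶, momentum 0.9, Nesterov).
Validation Dice is computed on stitched full volumes after each epoch and
only the best-performing weights are kept.  Per-patch class scores are
averaged over overlaps at inference.  The network and its training loop are
implemented in numpy with hand-derived backpropagation (verified against
finite differences in the test suite), so the package has no deep-learning
framework dependency; reduced "desk" and "mini" profiles make CPU training
practical.

**Evaluation.**  For segmentations X, X′ with labels i = 1..n,

    Dice = 2 Σᵢ |Xᵢ ∩ X′ᵢ| / (|X| + |X′|),

with |X| the non-background voxel count, and ASSD is the symmetric mean of
Euclidean nearest-surface distances between the label surfaces (6-connected
boundary voxels).  An error percentage (1 − Dice)×100 triages results into
negligible (< 0.01%), slight (0.01–4%) and flawed (> 4%) correction classes.

**Morphometry and statistics.**  After 26-connected island removal
(threshold 0.1 of the label's largest component, CX excluded) and midline
splitting of paired neuropils (AL, MB, ME, LO; merged mushroom bodies are
flagged non-separable), volume = voxel count × spacing³.  The statistics
layer provides percent variation ((Max−Min)×100/Max), Pearson correlations,
log–log allometric slopes (isometry = slope 1), mixed-model colony-effect
F-tests (hive fixed, population random; df = (k−1, n−k)), paired left/right
t-tests with smaller-left percentages, asymmetry quadrants, and Monte-Carlo
operating characteristics of those tests against the generator.

## Worked example

```python
import numpy as np
from beemorph import (PhantomParams, sample_cohort, render_cohort,
                      NetConfig, train_unet, predict_volume, evaluate,
                      remove_islands, split_left_right, measure_volumes)

params = PhantomParams(grid_shape=(32, 32, 32), seed=11, p_merge_mb=0.4)
cohort = sample_cohort(params, 14, {"H1": 7, "H2": 7})
phantoms, cohort = render_cohort(cohort, params)

model = train_unet(phantoms[:8], phantoms[8:10], NetConfig.mini(seed=0))
print(f"best validation Dice {model.best_val_dice:.3f} "
      f"at epoch {model.best_epoch}")

vol, truth = phantoms[10]
pred = remove_islands(predict_volume(model, vol))
ev = evaluate(pred, truth)
print(f"test Dice {ev.total_dice:.3f}, ASSD {ev.total_assd_vox:.2f} vox, "
      f"category: {ev.category}")

rec = measure_volumes(pred, split_left_right(pred))
print(f"total {rec.volumes_mm3['total']*1e6:.1f} x 10^-6 mm^3, "
      f"relative MB {rec.relative_pct['MB']:.1f}%")
```

Output from this exact run:

```
best validation Dice 0.949 at epoch 59
test Dice 0.954, ASSD 0.25 vox, category: flawed
total 510.2 x 10^-6 mm^3, relative MB 24.5%
```

Reading the numbers: the mini-profile network segments held-out phantoms at
Dice ≈ 0.95 with surfaces a quarter-voxel off on average (the triage
category is "flawed" only because the 4% error band is calibrated for
full-resolution scans, and a 32³ grid quantizes the small structures); the
measured relative mushroom-body volume (≈ 25%) recovers the generator's
honey-bee preset (25.7%), and absolute volumes are small because desk
phantoms rescale the brain to fit a 32³ grid at 5.4 µm voxels.

A command-line interface mirrors the library
(`beemorph simulate|preprocess|train|predict|evaluate|morphometry|stats|`
`learning-curve|oc-sim|run`), e.g.:

```bash
beemorph run --profile mini --seed 1 --out run1
beemorph oc-sim --n 77 --reps 200 --delta 0.05
```

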