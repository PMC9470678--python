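# Methods note

This note describes the models and procedures implemented in `fibroquant`,
the parameters they expose, and the numerical choices behind them. It makes
no empirical claims beyond what the test suite and `scripts/acceptance.py`
compute.

## Rule-based five-class labeling

Each axial CT slice (calibrated Hounsfield units) is labeled pixel-wise as
air, muscle/water, fat, skin, or fibrosis:

1. **Body mask.** Pixels > `body_threshold` (default **−200 HU**) are
   candidate body. −200 HU sits well above air (−1000 HU) and well below
   subcutaneous fat (≈ −80 HU), so the split is insensitive to the exact
   value over a wide range. The largest connected component is kept
   separately in each vertical image half (one per limb) and holes are
   filled, removing couch/clothing artifacts and internal air.
2. **Skin.** The body mask minus its binary erosion by a disk of radius
   `skin_erosion_radius` (default **2 px**): a fixed-thickness peel whose
   width should match the imaged skin thickness at the acquisition's pixel
   spacing.
3. **Muscle/water.** Interior pixels with HU in `[mw_low, mw_high]`
   (default **[−34, 26]**, both ends inclusive). The window brackets water
   (0 HU) and lean muscle while excluding fat; inclusivity at the ends is
   part of the contract and is what makes integer-HU phantoms reproducible.
   An optional `bone_threshold` folds dense pixels into this class.
4. **Fat vs fibrosis.** The remaining subcutaneous "donut" is split by
   two-cluster k-means on the 1-D HU values; the lower-mean cluster is fat.
   Rather than Lloyd iterations, the split is computed *exactly*: values are
   sorted, and prefix sums score every contiguous two-way partition; the
   partition minimizing within-cluster SSE is a Lloyd fixed point and the
   global optimum, so the result is deterministic and initialization-free.
   Tie-breaks: the decision threshold is the midpoint of the two centroids,
   values equal to it go to the lower cluster, and among equal-cost
   partitions the larger low cluster is chosen. A constant donut is labeled
   all fat (no evidence of two tissues).

## Segmentation network

`seg_model` provides a compact NumPy encoder–decoder: three encoder stages
(3×3 convolution → ReLU → 2×2 max-pool with remembered argmax indices),
a mirrored decoder that unpools with those indices (SegNet-style), and a 1×1
five-class head. Convolutions use im2col; gradients are hand-written and
verified against finite differences in the tests. Inputs are normalized as
(HU + 1000)/1000, mapping air to 0 and water to 1.

`TrainConfig` defaults to the published training recipe: encoder depth 3,
**55 epochs**, Adam with learning rate **2·10⁻³**, minibatch 16, per-epoch
shuffling, 256×256 inputs. `TrainConfig.desk_scale()` is this package's own
CPU-budget preset — 64×64 inputs, 8 base channels, 120 epochs — sized so
that training on a few dozen phantom slices converges in about a minute on
one core (fewer epochs demonstrably underfit at this scale).

Supporting utilities: patient-grouped train/val/test splitting (greedy
largest-group-first to the most-deficient split; default fractions
0.65/0.15/0.20), and the augmentation enumeration of 7×7 pixel shifts
({−3..3}²) × (61 rotations in −30°..30° at 1° steps + 1 horizontal
reflection) = 3 038 variants per image.

## Metrics

Per-class accuracy (row-normalized recall), IoU and Dice (DSC) are computed
from an accumulated 5×5 confusion matrix; DSC = 2·IoU/(1+IoU) holds exactly
and is asserted in the tests. Boundary-F1 matches inner-boundary pixels
within a distance tolerance defaulting to **0.75 % of the image diagonal**
(at least 1 px), computed via Euclidean distance transforms; a class absent
from both maps yields NaN and is excluded from means.

`fibroquant.reference` ships the confusion matrix of the original clinically
trained model on its test set, so the metric implementations can be checked
against the published per-class figures without any clinical data. The
published muscle/water row is not reconcilable with that matrix under any
reading and is deliberately excluded from the reference scores.

## Fibrosis indices

Four affected/unaffected indices (see the package README) with 19
patient-level subindices. Zero denominators yield NaN with a warning;
patient-level Means skip NaN slices while Sums count them as zero, so a
single degenerate slice cannot poison a patient. Limb halves are taken at
the vertical midline under the radiological convention (image-left =
patient's right limb); a body component straddling the midline raises.

## Clinical statistics

Reference measures are the bioimpedance ratio BEI = (unaffected −
affected)/unaffected and the circumference-difference ratio SCDR =
(affected − unaffected)/unaffected. Each variable is tested for normality
by a Kolmogorov–Smirnov test against a normal with the sample's own mean
and (ddof = 1) SD, at p ≥ 0.05; non-normal variables are log-transformed
with a safe offset (|min| + 10⁻⁶ × range when the minimum is ≤ 0, keeping
the transform monotone and finite without distorting all-positive data).
Partial correlation is computed by least-squares residualization of both
variables on an intercept plus the covariates, Pearson correlation of the
residuals, and a t-test with n − k − 2 degrees of freedom (k covariates).
By default each subindex is correlated with BEI controlling mean SCDR, and
with each SCDR controlling BEI. Stars: * for 0.01 < p < 0.05, ** for
0.001 < p < 0.01, *** for p < 0.001; boundary values take the weaker label.

## Phantom generator

The phantom emulates the *geometry and contrast structure* the pipeline
depends on: two circular limbs (skin annulus, subcutaneous fat annulus,
muscle/water core) on an air background, with fibrosis planted in the
affected limb's fat annulus as a reticular pattern (distance to three
oblique line families, period `reticulation_period`). The planted fraction
is exact by construction — the `round(f × annulus area)` pixels with the
smallest pattern value are fibrosis, via a stable argsort — which makes the
planted burden strictly monotone in `f` and exactly countable. Class HU
means default to air −1000, muscle/water 0, fat −80, skin 20, fibrosis 40,
with additive Gaussian noise (default SD 5 HU).

Cohort generation draws per-patient burdens from U(0.05, 0.45) and links
BEI and SCDR to burden linearly plus Gaussian noise;
`noise_sd_for_target_correlation` inverts the linear-model correlation
r = 1/√(1 + σ²/(β²σ_x²)) so cohorts with a planted correlation can be
synthesized and the full rendered pipeline checked for recovery.

The phantom does **not** emulate: realistic limb contours or bone, partial
volume effects, beam hardening or other CT artifacts, anatomically
realistic fibrosis morphology, or inter-slice anatomical continuity beyond
a smooth radius scaling. It validates the measurement chain's correctness,
not its clinical accuracy.

## Limitations

- The published muscle/water metrics cannot be verified against the shipped
  reference confusion matrix (internally inconsistent source table).
- The NumPy network is a faithful but small-scale stand-in for a GPU
  implementation; the desk-scale preset demonstrates learnability on
  phantoms, not clinical-grade segmentation.
- Indices assume one limb per image half; slices where the limbs touch the
  midline are rejected rather than resolved.
- The clinical statistics assume independent patients and linear
  (partial-correlation) associations.
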