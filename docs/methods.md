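# Methods

## Problem

Classify individual chromatid images into 24 karyotype classes (0 = Y,
1–22 = autosomes, 23 = X) when the imagery is low-resolution and the class
distribution is imbalanced (autosomes outnumber sex chromosomes roughly
5:1 for Y). The pipeline combines super-resolution restoration, size
standardisation, minority oversampling, rotation augmentation and a CNN
classifier, evaluated with per-class one-vs-rest metrics.

## Synthetic data generator

Real banded-chromosome datasets cannot be shipped with the package, so a
seeded generator renders class-conditional chromosome images:

- each class has a fixed relative length and centromere position (all 24
  lengths distinct; X similar to the 6–12 group, Y the shortest) and a
  per-class band pattern drawn once from a class-keyed RNG;
- the shape is an analytically rotated capsule with a tapered width
  profile and a centromeric constriction; band intensities modulate the
  interior; background is exactly 0 (IAM's content definition);
- per-image jitter: length (σ = 3%), rotation (≤ 5°), band noise, pixel
  noise, random margins;
- a paired low-resolution degradation (gaussian blur, block-mean
  downsampling by the scale factor, noise) produces (LR, HR) pairs for
  super-resolution training.

The generator emulates what the pipeline needs — class-separable banded
shapes with realistic nuisances — not cytogenetic realism: no touching or
overlapping chromosomes, no stain or illumination artefacts, no
chromosome bending.

## SRAFBN super-resolution

- Shallow features: `L0 = conv1x1(relu(conv3x3(LR)))`.
- Feedback block (weights shared across iterations): inputs
  `[FB_{t-1}, L0]` fused by a 1×1 conv; `n_groups` encode/decode pairs with
  dense skips (encoder *i* sees the fused input plus all previous decoder
  outputs through a 1×1 reduction; decoder *i* sees all encoder outputs);
  a final 1×1 over all decoder outputs. `FB_0 := L0`.
- Reconstruction per iteration: transposed convolution (zero-stuffing by
  the scale factor followed by a learned kernel, 3×3 for scale ≤ 3, 5×5
  for scale 4), two conv layers, and a zero-initialised 1×1 head producing
  a residual added to the bicubic upsample of the input. Zero
  initialisation makes the untrained network exactly bicubic and the
  residual path a pure correction.
- Loss: `Σ_t w_t ‖SR_t − HR‖` (L1 default) with `w = softmax(z)` and
  learnable logits `z`; the logits receive gradient
  `∂L/∂z_j = w_j (loss_j − L)`. The published loss formula compares `SR_t`
  with the low-resolution input, which is dimensionally inconsistent
  (the two differ by the scale factor); the implementation compares with
  the ground-truth high-resolution target.
- Training: Adam, per-epoch shuffling, best-epoch parameter restore.
  Backpropagation runs through the shared weights of all iterations
  (backpropagation through time), implemented with functional
  forward/backward caches in the in-repo numpy layer library.
- "Double triple interpolation" of the upsampling path is read as bicubic
  interpolation (PIL's BICUBIC on a float image).

Parameter count is independent of the iteration count except for the
attention logits (one scalar per iteration).

## IAM size standardisation

Content bounds are the true min/max nonzero row/column indices
(`U/D/L/R`); an alternative published pseudocode with first-gap early
exits conflicts with those definitions and would truncate chromosomes with
internal zero rows, so the min/max semantics are implemented. The crop is
rescaled only when its longest side exceeds the canvas (factor
`canvas/max(H, W)`, aspect preserved, bilinear, floor-rounded dims with a
1 px minimum), re-tightened (bilinear downscaling can zero out boundary
rows, which would break idempotence), and pasted centred (or top-left)
onto a zero canvas, 224×224 by default. The operation is bit-exact
idempotent.

## SMOTE balancing

Applied only to the training split and only to the sex-chromosome classes
in the full pipeline. For each minority sample, `η` neighbours are drawn
without replacement from its `K = 5` nearest minority neighbours
(Euclidean distance in flattened post-IAM pixel space, ties broken by
lower index; with-replacement fallback with a warning when `η > K`) and
synthesised as `x_i + u (x_k − x_i)`, `u ~ U(0,1)`. The sampling
magnification is `η = round((|S_max| − |S_min|)/|S_min|)` (half-even; 4
for 238 vs 45). `balance_dataset` clamps `η` so the class does not
overshoot the majority count and tops up to exact equality.

## Classifier and augmentation

Every training image yields 24 copies rotated by multiples of 15°
(bilinear, zero-filled corners, dims preserved); the upright original is
kept because orientation carries the polarisation convention. The working
backbone is a small CNN (3×3 conv / ReLU / 2×2 max-pool blocks, global
average pooling, dense 24-way softmax head) trained with cross-entropy and
Adam. Protocol defaults: batch 40, max 100 epochs, early stopping on
validation accuracy with patience 21, learning rate 5e-4. The named
ImageNet-era backbones would need a deep-learning framework and pretrained
weights that the package does not ship; selecting them raises
`NotImplementedError`.

## Metrics

Per class *i*, one-vs-rest counts from the confusion matrix (rows = true)
give accuracy, precision, recall and F1, printed as percentages with two
decimals (round-half-even, numpy semantics). Two overall accuracies are
reported: the one-vs-rest aggregate (equals the mean of per-class
one-vs-rest accuracies and is inflated by true negatives) and standard
top-1 accuracy (trace/total); the headline figure is the standard one.

`f1_from_pr_counts` recovers the smallest integer (TP, FP, FN) consistent
with precision/recall printed at two decimals and computes F1 from the
counts. This matters because published tables compute F1 before rounding
P and R: the harmonic mean of the printed values can differ in the last
digit (e.g. P = 93.75, R = 95.74 gives 94.73 directly but 94.74 from
counts).

## Pipeline

Stage order: simulate → SR train/apply → IAM → SMOTE → augment → train →
evaluate. The working images handed downstream are the degraded LR copies
(`classify_from_lr`, default on), so ablating SR measures exactly the
value of the restoration. SR runs before IAM by default (its output is
larger, so canvas fitting must follow); the order is switchable, in which
case IAM is re-applied after SR. Images smaller than the network's 8 px
minimum are zero-padded before SR and cropped back afterwards.

All stage seeds derive from one root seed via
`numpy.random.SeedSequence`, reduced modulo 2³¹. A provenance log records
the config hash and per-stage timings/output counts; a failure names the
stage.

Mirroring the study protocol, the held-out fifth doubles as both the
early-stopping validation set and the test set. This is leakage-prone
(early stopping selects for the reported split); a three-way split is the
rigorous alternative and is easy to add, but the default reproduces the
protocol.

## Parameter defaults and rationale

| Parameter | Default | Rationale |
| --- | --- | --- |
| IAM canvas | 224 px | standard CNN input size; tests/desk runs use 32 px |
| SMOTE K | 5 | conventional neighbourhood size |
| rotations | 24 × 15° | full circle; chromosomes appear at any orientation |
| batch size | 40 | study protocol |
| max epochs / patience | 100 / 21 | study protocol |
| learning rate | 5e-4 | study protocol; desk-scale runs use 3e-3 because the small CNN on 32 px images underfits at 5e-4 within a few dozen epochs |
| SR scale | 2 (of 2/3/4) | matches the paired degradation default |
| SR iterations / groups / channels | 4 / 3 / 32 | protocol-sized; desk-scale runs use 2 / 1 / 8 |

## Limitations

- Headline published results (97.55% overall on a real banded-chromosome
  dataset with GPU-scale backbones) are out of desk-scale reach; the
  package demonstrates the mechanisms on synthetic data and verifies the
  exact quantities that are recomputable from printed numbers.
- The numpy networks are CPU-only and small; no GPU, no distributed
  execution, no hyperparameter search.
- The synthetic generator's class separability is optimistic compared
  with real banding; absolute accuracies on it are not comparable to real
  data.
- Validation-equals-test in the default pipeline (see above).
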