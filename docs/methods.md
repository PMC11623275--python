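# Methods

## Problem and model

Glaucoma screening from fundus photographs hinges on the appearance of the
optic nerve head (ONH): the optic cup enlarges relative to the optic disc,
so the vertical cup-to-disc ratio (CDR) is the key biomarker. `glaucnet`
implements a multi-task convolutional network that takes a square ONH crop
and jointly (i) segments background / disc / cup and (ii) classifies the
eye as normal or glaucomatous, sharing one encoder between both tasks.

### Architecture

The network is V-shaped. The encoder applies an initial 3×3
convolution block and then four downsampling steps; each step is a 2×2
stride-2 convolution followed by a 3×3 convolution block (every block is
convolution → batch normalization → ReLU). Stage *s* ∈ {1..5} has spatial
side `input_size / 2^(s−1)` and `base_channels · 2^(s−1)` channels. The
segmentation decoder mirrors the encoder with four nearest-neighbour
upsampling steps, concatenating the same-resolution encoder feature at
each step (skip connections), and ends in a per-pixel 3-class softmax at
the input resolution. The classification head global-average-pools the
three deepest encoder stages, concatenates the pooled vectors, and applies
two fully connected layers (hidden width 256, dropout 0.5 on the hidden
units) and a 2-way softmax.

Design choices that were genuinely open:

- **Decoder width.** The stage-wise channel doubling constrains the
  encoder only; decoder blocks use a fixed width equal to `base_channels`.
  A narrow decoder is sufficient for the two-ellipse geometry of ONH
  masks and keeps the per-step cost of the full-resolution level low.
- **Fusion stages.** With five encoder resolutions, "the deepest stages"
  is taken as stages 3–5 (configurable via `fusion_stages`).
- **Dimensionality.** All blocks are dimension-parameterized. Fundus
  crops are 2-D, so `spatial_dims=2` is the default (side-3 kernels in
  2-D); 3-D volumes work through `spatial_dims=3`.
- **Dropout realization.** Inverted dropout — kept units scaled by
  1/(1−p) during training, identity at evaluation. This has the same
  expectation as keeping all units and halving their outputs at test
  time, and makes evaluation deterministic.
- **Extra features.** The classifier can accept a pre-computed feature
  vector concatenated before the FC layers (`extra_features_dim`); off by
  default.
- **Initialization.** He-style normal initialization from a fixed seed;
  all training-time randomness (shuffling, augmentation, dropout) flows
  from the run seed, so runs replay bit-identically.

The network, including forward and backward passes, is implemented
directly on numpy: convolutions are lowered to BLAS GEMMs (an im2col
transform in general; 3×3 stride-1 convolutions use a shift-and-accumulate
GEMM formulation that avoids materializing the im2col matrix), and the
batch-normalization passes are fused numba kernels. A finite-difference
check of the complete network gradient (in float64, directional
derivative) agrees with backpropagation to ~1e-9 relative error.

## Loss functions

For a predicted glaucoma probability p̂ and label a ∈ {0,1}, with
m = p̂ if a=1 else 1−p̂ (the probability assigned to the true class):

- **Cross-entropy**: −log m (natural log; probabilities are clipped to
  [1e−7, 1−1e−7] before any logarithm, so exact 0/1 inputs never produce
  infinities).
- **Focal loss**: w · (1−m)^γ · (−log m). The focusing parameter γ ≥ 0
  down-weights easy examples. The class weight w is ϑ for positives and
  1−ϑ for negatives when `class_balanced` is on (the standard α-balanced
  convention, which is what lets ϑ compensate class imbalance); with
  `class_balanced` off, ϑ scales every sample uniformly. Defaults
  γ = 2, ϑ = 0.25 — the canonical focal-loss settings.
- **Correntropy-induced loss (CL)**: 1 − exp(−e²/D) with e = a − p̂ and
  D = β² by default (`kernel_denominator="beta_sq"`), or the standard
  Gaussian-kernel convention D = 2β² as an option. Default β = 1, in
  units of label-probability error. The loss is bounded in [0,1),
  behaves like e²/D for small errors, and saturates for large ones —
  a mislabelled sample whose error cannot shrink contributes a bounded,
  vanishing gradient instead of dominating the fit. Implemented with
  `expm1` so the small-error quadratic regime is computed at full
  precision.
- **FC loss**: the epoch schedule — focal loss for epochs
  `< switch_epoch`, CL loss from `switch_epoch` on (default M/2 of M
  total epochs). The switch is hard, not a blend: focal loss first drives
  learning on the hard minority-class examples; the bounded CL loss then
  finishes the fit while ignoring outliers.

Batch reduction is the arithmetic mean of per-sample losses. During the
correntropy phase no class weighting is applied.

## Training procedure

Datasets are split 0.70 / 0.15 / 0.15 (train/validation/test), stratified
by label with largest-remainder rounding so the split sizes are exact and
per-split class proportions stay within one sample of the global ones.
Each epoch shuffles the training set, applies on-the-fly augmentation
(horizontal/vertical flips, rotation within ±15°, brightness scaling in
[0.9, 1.1]; geometric transforms apply identically to image and mask), and
minimizes

    total = FC-classification loss + λ · soft-Dice segmentation loss

with λ = 1 by default and soft Dice averaged over the three mask classes
(ε = 1e−6 smoothing). The optimizer is Adam (lr 1e−3) by default; SGD
with momentum 0.9 is available. Validation accuracy is recorded every epoch in
evaluation mode; the final test report contains the confusion matrix,
accuracy, sensitivity (glaucoma = positive class), specificity, precision,
F1, the ROC curve with trapezoidal AUC (equal to the tie-aware
concordance probability), and per-class Dice. Ratios with zero
denominators are reported as NaN with a warning, never silently as 0.

## The phantom generator

Synthetic fundus phantoms stand in for clinical datasets so the pipeline is
testable without external data or a GPU. Each phantom is a square crop
containing a textured reddish background, a bright elliptical disc
(vertical radius ≈ 0.29 of the image side, mild eccentricity, center
jitter ≤ 10% of the side — ranges chosen to keep the disc in frame), a
brighter concentric cup whose vertical diameter is CDR × the disc's, a
few dark Bézier vessel strokes, and additive Gaussian noise (σ = 0.05 by
default). Vertical radii are snapped to half-integers about an integer
center row, which makes the mask-measured vertical diameters exact;
`true_cdr` is always measured from the emitted mask and agrees with the
requested CDR within 2/image_size. CDR is measured on the vertical
diameter (the clinical convention), not as an area ratio.

Labels follow the clinical rule `glaucoma = CDR > 0.6`, with normal CDRs
drawn from [0.2, 0.45] and glaucomatous from [0.65, 0.9]. Class imbalance
(`glaucoma_fraction`, default 1/6) and label-flip outliers
(`label_flip_rate`, default 0.05) are first-class generator parameters
because they are precisely the failure modes the FC loss targets. The
standard study conditions used by the acceptance script and the
end-to-end tests are: 600 images at 64 px, 1/6 glaucoma prevalence, 5%
label flips, noise σ = 0.05; training with base_channels = 8 for 30
epochs, loss switch at epoch 15, Adam at 1e−3, batch 16. Image size 64
(rather than the 224 used for real photographs) keeps a full training run
around two minutes on one CPU; the geometry and intensity orderings are
scale-free, so nothing about the task changes qualitatively.

What the phantom does *not* emulate: photographic vignetting and
illumination gradients, vessel-tree topology, peripapillary atrophy,
camera noise correlation, inter-grader label disagreement structure
(flips here are independent), and real CDR measurement ambiguity. Passing
the end-to-end tests therefore shows the pipeline learns the intended
geometry under controlled imbalance and label noise — not that it reaches
clinical performance on real fundus photographs.

## Numerical choices and degenerate inputs

- Probabilities clipped to [1e−7, 1−1e−7] before logarithms.
- Batch statistics in batch normalization accumulate in float64; weights
  and activations are float32.
- Soft-Dice smoothing ε = 1e−6; a class absent from both prediction and
  truth gives Dice 1 in evaluation.
- Ties in ROC scores are handled so the AUC equals the all-pairs
  concordance with ties counted ½.
- Empty batches, mismatched lengths, non-square or indivisible input
  sizes, out-of-range probabilities, and epochs beyond the schedule all
  raise ValueError; a non-finite training loss aborts with the epoch and
  batch in the message.

## Known limitations

- The numpy training loop is single-threaded and tuned for small images;
  224-px training is functional but slow.
- The classifier threshold is fixed at 0.5; no calibration or operating
  point selection is provided.
- Only binary classification is supported; the segmentation classes are
  fixed at {background, disc, cup}.
- The robustness comparison (FC vs cross-entropy) asserts a direction
  over five seeds, not a margin; individual seeds can tie at ceiling.
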