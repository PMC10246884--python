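# Methods

## The prediction problem

A fruit photographed on day *d* is to be rendered as it will look on day
*d + N*, for a user-chosen horizon *N* (days).  Supervision comes from
day-indexed image series of individual fruits: any two frames of the
same fruit, *N* days apart, form a training pair (input, horizon,
target).  No pixel correspondence between input and target is assumed —
the fruit may have moved, the background changed, the apparent size
differ.  That assumption is what the loss design must accommodate.

## Segmentation

A U-Net maps the RGB frame to per-pixel fruit probabilities: encoder
stages of two 3×3 convolutions (optionally instance-normalized) and 2×2
max pooling, a bottleneck, then decoder stages of nearest-neighbor ×2
upsampling, skip concatenation and two 3×3 convolutions, ending in a
1×1 convolution and sigmoid.  Training minimizes the smoothed Dice loss

    1 − (1 + 2 Σ p·g) / (1 + Σ p² + Σ g²),

whose unit smoothing terms keep the ratio defined when both the
prediction and the ground truth are empty.  The checkpoint with the best
validation MIoU is kept.  Binarization is strict (`p > 0.5`), ties going
to background.  MIoU pools confusion counts over the whole evaluation
set and averages the fruit and background IoUs; per-image averaging is
available behind a flag.

Defaults (desk scale): depth 4, base 8 channels doubling per stage,
instance normalization, random horizontal flips during training, Adam at
learning rate 10⁻³ with moment estimates (0.9, 0.99), batch 8, 12
epochs.

## Generator

Encoder: two stride-2 4×4 convolutions (3→32→64), then a stack of
identical 3×3 residual blocks at 64 channels.  Decoder: two resize
convolutions — nearest-neighbor ×2 upsampling followed by a stride-1 4×4
convolution — then a 3×3 output convolution.  Resize convolutions avoid
the checkerboard artifacts of transposed convolutions.  Every
convolution is followed by instance normalization and ReLU except the
output, which uses a scaled tanh, `127.5·(tanh(z)+1)`, bounding pixels
to [0, 255].  A skip connection concatenates the first encoder stage
into the first decoder stage.

**Time conditioning.**  Two trainable embedding tables (one encoder-side,
one decoder-side) map each representable horizon *N* ∈ {1..45} to a
64-vector that multiplies, channel by channel, the 64 feature maps after
the second encoder convolution and after the second decoder stage.
Tables are initialized near 1 (identity gating) so conditioning starts
as a perturbation of a working network.  One weight set thus serves all
horizons; the fixed-interval ablation (`train_fixed_interval_generator`)
drops the tables and needs one weight set per horizon.

**Masked input and background re-fusion.**  The network receives the
*segmented* fruit (background zeroed by the mask), and its output is
composited as `mask ⊙ generated + (1 − mask) ⊙ original`, so background
pixels are bit-equal to the input.  Feeding the segmented fruit rather
than the raw frame matters at small scale: instance normalization makes
every feature map's statistics depend on the whole frame, so background
content otherwise leaks into the generated fruit color — on synthetic
probes an identical fruit rendered over eight different backgrounds
varied by ~6° in predicted hue with raw-frame input, and by 0° with
masked input.  A final concatenation of the masked input into the output
stage gives the output convolution direct access to absolute pixel
colors, which the instance-normalized trunk suppresses.

## Perceptual objective

All losses are computed on a fixed extractor's activations, images
scaled to [0, 1] beforehand.  Two extractors are provided:

* **Identity** — a single "layer" holding the raw pixel array; every
  loss then has a closed form.  With `augment_constant`, a fourth
  all-ones channel is appended, so the mask-normalized Gram matrix
  carries the masked *first* moments (mean color) alongside the raw
  second moments.  Raw 3×3 RGB Grams alone leave the mean color
  underdetermined, which measurably degrades color tracking.
* **VGG19-topology** — five convolution blocks of (2,2,4,4,4) 3×3
  convolutions with ReLU and 2×2 max pooling between blocks, layers
  named `Conv<i>_<j>`, with frozen seeded random weights (a fixed
  random convolutional basis; useful for receptive-field and
  multi-scale behavior, exercised in tests).

The content loss is the per-layer mean squared activation difference to
the **input** (default layers: Conv4_2, Conv5_2 — or the identity
layer).  The local style loss compares **mask-normalized Gram matrices**
to the **target** at the style layers (default Conv1_1…Conv5_1, or the
identity layer): features are multiplied by the mask resized (nearest
neighbor) to the layer's resolution, the Gram matrix `G_mn = Σ_t F^m_t
F^n_t` is accumulated, and the result is divided by the mask sum.  For a
constant-colored region the normalized Gram equals the color's outer
product whatever the region's area — the loss is size-invariant by
construction, and exactly background-invariant.  The total objective is
`content + style` with configurable weights.

**Normalization convention.**  The per-layer style prefactor is exposed
as a convention switch: `as_printed` divides by `(H·W·C)²` (the same
grouping as the unmasked Gatys loss), `channels_only` divides by `C²`.
Because the mask-sum division has already removed the spatial extent,
the `as_printed` grouping makes the style term vanish numerically
against the content term at small image sizes (at 32×32 it is ~10⁻⁸ of
the content term); the desk-scale training configuration therefore uses
`channels_only` with a style weight of 10, set by this scale analysis.
Both conventions rescale rather than reorder pairwise style differences
when layer weights are uniform (tested exactly for a single layer).

**Baselines.**  The classic unmasked Gram loss and its black-background
variant (zero the background, then apply the unmasked loss) are
implemented for comparison; `style_difference_matrix` computes all
pairwise distances among a set of images under any of the three metrics
and can quantize the matrix into 5 equal-width levels for display.  The
test suite demonstrates the motivating argument: background
perturbations and area doubling move both baselines but leave the local
style loss unchanged exactly.

## Training the generator

Adam (lr 10⁻³, betas 0.9/0.99) on the local perceptual loss, no
discriminator.  Per-pair constants — input content features, target
mask-normalized Grams, generated-side layer masks — are precomputed
once.  Pairs whose mask vanishes (at full resolution or after
downscaling to a style layer) are skipped with a warning.  Per epoch,
total loss, PSNR and MLSL are recorded on train and validation sets;
model selection follows a two-stage rule on validation epochs: shortlist
the 10 best by MLSL, keep the 5 best by PSNR among them, restore the
top one.

## Metrics

* **PSNR** `10·log₁₀(255²/MSE)`; identical images report `inf`
  (serialized as the string `"inf"`).  The reference image is the
  *input* frame by default — generated frames share its background
  bit-for-bit, making this well defined without pixel correspondence to
  the target; a flag switches to the ground-truth target.
* **Hunter Lab / CCI** — sRGB → linearization → XYZ (D65) → Hunter Lab
  with Ka = 172.30, Kb = 67.20; the D65 normalization is taken from the
  XYZ of pure white through the same matrix, so neutral grays map to
  a = b = 0 exactly.  An illuminant-C variant (Ka = 175, Kb = 70) is
  selectable.  CCI = 1000·a/(L·b) of the mean masked RGB.  Degenerate
  denominators: achromatic colors (|a| and |b| < 0.05) return CCI 0;
  otherwise a near-zero b is clamped at 10⁻⁶ with a warning and L = 0
  raises.  Real rind colors never approach these guards.
* **MLSL** — the arithmetic mean of the local style loss over an
  evaluation set; the color-accuracy headline.
* **CCI error** — |CCI(prediction) − CCI(target)|.

## Synthetic orchard data

Each sample (fruit) draws a linear hue trajectory from green (~95°) to
orange (30°) at a per-fruit rate (mean 1.5°/day, sd 0.25 — a ~45-day
transformation), with 2° per-frame jitter; frames render the fruit as a
shaded ellipse (multiplicative radial lighting, low-frequency hue
mottling, 1–4 stripe/spot blemishes of ±12°) over a smoothed colored-
noise background that depends only on the scene seed, with a per-fruit
lighting gain in [0.7, 1.3].  Masks are the exact ellipse support.
Frames drop out with probability 0.05, emulating missing acquisition
days.  Everything is bit-deterministic given the seeds.

What this emulates: the nuisance factors the method must tolerate —
fruit size/position, background variation, uneven coloration, missing
frames — and a recoverable one-parameter color signal.  What it does
not: 3-D shape and perspective, specular highlights, occlusion,
weather-driven illumination changes, and the fine texture statistics of
real rinds.  Passing the desk-scale studies therefore demonstrates that
the pipeline learns and extrapolates a color trajectory under these
nuisances; it does not certify field performance on real orchard
imagery.

## Desk-scale study sizes

Chosen so the full pipeline trains in minutes on one CPU:

* Segmentation study: 20 samples × 20 days at 64×64 (≈380 frames),
  3:1:1 sample-disjoint split, 12 epochs.  Typical held-out (test)
  MIoU ≈ 0.93; because the test split holds only four fruits, a single
  green-on-green sample (rind hue overlapping the foliage background)
  can move the pooled value by several points across seeds.
* Generation study: 100 samples × 36 days at 32×32, horizons N ∈ [2, 15],
  420/60/80 train/val/test pairs, 16 epochs.  The 36-day window mirrors
  the multi-week transformation period; much shorter windows leave too
  little hue variance for a meaningful correlation measure (an oracle
  applying the true mean rate tops out near r ≈ 0.89 under the
  generator's own noise).  Typical held-out hue-recovery r ≈ 0.85,
  CCI-vs-horizon Spearman ρ = 1.0.

## Numerical choices and reproducibility

The networks run on a small reverse-mode autodiff engine over NumPy
(float32), with convolution via im2col, pooling-argmax ties broken
toward the first element, and instance normalization ε = 10⁻⁵.  All
randomness flows from explicit `numpy` Generators; training is
bit-reproducible given (data, config, seed).  Checkpoints are `.npz`
archives holding the config, seed and parameter arrays.

## Known limitations

* The feature extractor is not a pretrained classification network; the
  identity extractor's color statistics carry the desk-scale training
  signal, and the VGG-topology extractor uses random features.  Results
  on real imagery would likely benefit from a pretrained backbone.
* Fixed 64-channel gating stages tie the architecture to the embedding
  width.
* The CCI-vs-horizon monotonicity is evaluated on the synthetic
  trajectory family; saturation at full orange bounds extrapolation.
* Environmental covariates (temperature, humidity) are out of scope;
  the embedding mechanism could host them but none are modeled.
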