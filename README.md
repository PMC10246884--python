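# citrusgen

Predicting and visualizing how a citrus fruit's rind color will change
over the coming days, from a single orchard photograph.

During the color transformation period, chlorophyll in the rind degrades
and carotenoids accumulate: hue drifts from green toward orange, and the
standard maturity proxy — the Citrus Color Index,

    CCI = 1000 · a / (L · b)

in Hunter Lab coordinates — rises from negative (green) through zero to
positive (orange).  `citrusgen` implements a mask-guided generative
framework for forecasting this transformation visually:

1. **Segmentation** — a U-Net (3×3 convolutions, 2×2 max pooling, skip
   concatenations, sigmoid head) locates the fruit, trained with a
   smoothed Dice loss `1 − (1 + 2Σpg) / (1 + Σp² + Σg²)`.
2. **Generation** — an encoder–decoder network (stride-2 4×4
   convolutions, 3×3 residual blocks, resize convolutions instead of
   transposed convolutions, scaled tanh onto [0, 255]) synthesizes the
   fruit's appearance after a horizon of *N* days.  Two trainable
   embedding tables map *N* to 64-dimensional vectors that gate,
   channel by channel, the 64 feature maps after the second encoder and
   second decoder convolutions — so a single weight set serves every
   horizon.  The original background is re-fused through the mask, so
   only the fruit is synthesized.
3. **Perceptual objective** — no adversarial discriminator.  The
   training loss is computed on a fixed feature extractor:
   a content term (mean squared feature distance to the *input*) plus a
   **local style loss**: Gram matrices accumulated over mask-weighted
   features and divided by the mask sum,

       L*_style(y, ŷ) = Σ_l W_l · ‖G^l(ŷ⊙M)/ΣM(ŷ) − G^l(y⊙M)/ΣM(y)‖²_F · norm_l ,

   which — unlike the classic unmasked Gram loss or its black-background
   variant — is provably invariant to the background and to the fruit's
   apparent size.  This removes the need for pixel-aligned image pairs.

Evaluation: MIoU for segmentation; PSNR, mean local style loss (MLSL)
and CCI error (L1 distance of predicted vs. true CCI) for generation;
3:1:1 sample-disjoint splits and sample-wise 5-fold cross-validation.

A synthetic orchard generator (shaded ellipse fruit with a seeded
green→orange hue trajectory, uneven coloration, varying backgrounds and
lighting, exact masks, day-indexed manifest) makes the entire pipeline
testable end to end on a desk CPU.

## Worked example

```python
import tempfile
from citrusgen.recipes import generation_study

out = generation_study(tempfile.mkdtemp(), seed=5)
print(f"held-out hue recovery r = {out['hue_pearson_r']:.3f}")
print(f"CCI vs horizon Spearman rho = {out['cci_spearman_rho']:.1f}")
print(f"test PSNR = {out['test_report'].psnr:.2f} dB")
```

prints (seed 5):

```
held-out hue recovery r = 0.845
CCI vs horizon Spearman rho = 1.0
test PSNR = 22.35 dB
```

Interpretation: across 80 held-out (unseen-fruit) pairs, the mean hue of
the generated fruit correlates 0.845 with the true future hue; sweeping
the horizon N over {2, 5, 8, 10} days for a fixed input produces strictly
increasing predicted CCI (the fruit ripens monotonically, ρ = 1.0); and
the generated frames stay close to the input frame structurally
(22.4 dB against the input, whose background they share exactly).

The same pipeline is scriptable from the shell:

```bash
citrusgen synth --seed 7 --out data/
citrusgen train-seg --data data/ --seed 1 --out runs/seg
citrusgen train-gen --data data/ --seed 1 --out runs/gen
citrusgen predict --image data/s000_front_d000.png \
    --checkpoint runs/gen/gen_checkpoint.npz \
    --seg-checkpoint runs/seg/seg_checkpoint.npz \
    --n 5 --n 10 --n 15 --n 20 --out preds/
citrusgen kfold --data data/ --k 5 --seed 1 --out runs/kfold
```

## Layout

| module | contents |
| --- | --- |
| `citrusgen.data` | manifests, image/mask I/O, temporal pairing, sample-wise splits and k-fold |
| `citrusgen.synthetic` | the synthetic orchard renderer |
| `citrusgen.segmentation` | U-Net, Dice loss, MIoU, training |
| `citrusgen.losses` | feature extractors, Gram matrices, content/style/perceptual losses, baselines, comparison harness |
| `citrusgen.generator` | the time-conditioned generator and its training loop |
| `citrusgen.metrics` | PSNR, Hunter Lab, CCI, MLSL, evaluation reports |
| `citrusgen.recipes` | end-to-end desk-scale study protocols |
| `citrusgen.cli` | `citrusgen synth / train-seg / train-gen / predict / eval / kfold` |
| `citrusgen.nn` | NumPy autodiff engine (conv, pooling, instance norm, Adam, …) |

See `docs/methods.md` for the scientific and numerical details.
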