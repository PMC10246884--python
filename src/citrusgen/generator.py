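"""Time-conditioned mask-guided generative network.

Architecture: an encoder of stride-2 4x4 convolutions (3 -> 32 -> 64)
followed by a stack of identical 3x3 residual blocks at 64 channels; a
decoder of resize convolutions (nearest-neighbor x2 upsampling, then a
stride-1 4x4 convolution — no transposed convolutions, avoiding
checkerboard artifacts) and a final 3x3 convolution.  Every convolution
is followed by instance normalization and ReLU except the output, which
uses a scaled tanh onto [0, 255].  The integer horizon N (days) is
encoded by two trainable embedding tables into 64-dimensional vectors
that multiply, channel by channel, the 64 feature maps after the second
encoder convolution and after the second decoder convolution — one set
of weights thereby serves every horizon.  The generated frame is
composited with the fruit mask so background pixels are taken verbatim
from the input (background re-fusion).

Training minimizes the local perceptual loss (content to the input +
mask-normalized Gram style to the target) with Adam; there is no
adversarial discriminator.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .nn import Tensor, concat, Module, Conv2d, InstanceNorm2d, Embedding, Adam
from .losses import StyleConfig, IdentityExtractor, resize_mask_nearest
from . import metrics as _metrics

__all__ = [
    "GeneratorConfig", "GeneratorModel", "build_generator",
    "apply_time_embedding", "composite_background", "predict",
    "train_generator", "train_fixed_interval_generator",
    "select_generator_epoch", "save_checkpoint", "load_checkpoint",
]

EMBED_CHANNELS = 64  # the embedding-gated stages carry exactly 64 maps


@dataclass(frozen=True)
class GeneratorConfig:
    input_size: tuple = (64, 64)          # (H, W), divisible by 4
    stem_channels: tuple = (32, EMBED_CHANNELS)
    n_resblocks: int = 5
    embedding_dim: int = EMBED_CHANNELS
    n_max: int = 45                       # largest representable horizon
    skip_mode: str = "concat"             # "concat" | "add" | "none"
    decoder_mid_channels: int = 32
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 80
    use_embedding: bool = True
    input_skip: bool = True    # concat the (masked) input to the output stage
    mask_input: bool = True    # feed the segmented fruit, not the raw frame

    def __post_init__(self):
        h, w = self.input_size
        if h % 4 or w % 4:
            raise ValueError("input size must be divisible by 4")
        if self.stem_channels[-1] != EMBED_CHANNELS:
            raise ValueError(
                f"second encoder stage must carry {EMBED_CHANNELS} channels"
            )
        if self.skip_mode not in ("concat", "add", "none"):
            raise ValueError(f"unknown skip mode {self.skip_mode!r}")
        if self.n_max < 1:
            raise ValueError("n_max must be >= 1")


class _ResBlock(Module):
    """conv3x3-IN-ReLU-conv3x3-IN + identity, then ReLU."""

    def __init__(self, ch, rng):
        self.c1 = Conv2d(ch, ch, 3, rng=rng)
        self.n1 = InstanceNorm2d(ch)
        self.c2 = Conv2d(ch, ch, 3, rng=rng)
        self.n2 = InstanceNorm2d(ch)

    def __call__(self, x):
        h = self.n1(self.c1(x)).relu()
        h = self.n2(self.c2(h))
        return (h + x).relu()


def apply_time_embedding(features: Tensor, n, table: Embedding,
                         n_max: int) -> Tensor:
    """Gate 64 feature maps by the embedding vector(s) of horizon n.

    ``n`` is an integer or a length-B sequence; channel k of sample i is
    multiplied by table[n_i][k].  Valid horizons are 1..n_max (0 is
    reserved/invalid).
    """
    ns = np.atleast_1d(np.asarray(n, dtype=np.int64))
    if np.any((ns < 1) | (ns > n_max)):
        raise ValueError(f"horizon N must lie in [1, {n_max}], got {n}")
    vec = table(ns)                      # (B, C)
    B, C = vec.shape
    if features.shape[1] != C:
        raise ValueError(
            f"embedding dim {C} does not match {features.shape[1]} channels"
        )
    return features * vec.reshape(B, C, 1, 1)


def composite_background(generated, original, mask):
    """mask * generated + (1 - mask) * original, pixel by pixel.

    Background pixels of the result are bit-equal to the original; the
    operation is idempotent in (generated, mask).
    """
    generated = np.asarray(generated)
    original = np.asarray(original)
    mask = np.asarray(mask)
    if generated.shape != original.shape or mask.shape != generated.shape[:2]:
        raise ValueError("composite_background: shape mismatch")
    m = mask.astype(bool)[..., None]
    return np.where(m, generated, original)


class GeneratorModel(Module):
    def __init__(self, cfg: GeneratorConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        chans = cfg.stem_channels
        self.stem_convs, self.stem_norms = [], []
        in_ch = 3
        for ch in chans:
            self.stem_convs.append(
                Conv2d(in_ch, ch, 4, stride=2, pad=(1, 1, 1, 1), rng=rng))
            self.stem_norms.append(InstanceNorm2d(ch))
            in_ch = ch
        self.resblocks = [_ResBlock(in_ch, rng) for _ in range(cfg.n_resblocks)]
        if cfg.use_embedding:
            self.embed_enc = Embedding(cfg.n_max + 1, cfg.embedding_dim, rng=rng)
            self.embed_dec = Embedding(cfg.n_max + 1, cfg.embedding_dim, rng=rng)
        else:
            self.embed_enc = self.embed_dec = None
        skip_ch = chans[0] if cfg.skip_mode == "concat" else 0
        self.skip_proj = (
            Conv2d(chans[0], in_ch, 1, rng=rng) if cfg.skip_mode == "add" else None
        )
        mid = cfg.decoder_mid_channels
        self.dec1 = Conv2d(in_ch + skip_ch, mid, 4, stride=1, rng=rng)
        self.dn1 = InstanceNorm2d(mid)
        self.dec2 = Conv2d(mid, EMBED_CHANNELS, 4, stride=1, rng=rng)
        self.dn2 = InstanceNorm2d(EMBED_CHANNELS)
        out_in = EMBED_CHANNELS + (3 if cfg.input_skip else 0)
        self.out_conv = Conv2d(out_in, 3, 3, rng=rng)

    def __call__(self, x: Tensor, n) -> Tensor:
        """x: (B, 3, H, W) in [0, 1]; n: int or length-B array of horizons.

        Returns the raw generated batch (B, 3, H, W) on the [0, 255]
        scale (scaled tanh), before background re-fusion.
        """
        x_in = x
        skips = []
        for conv, norm in zip(self.stem_convs, self.stem_norms):
            x = norm(conv(x)).relu()
            skips.append(x)
        if self.embed_enc is not None:
            x = apply_time_embedding(x, n, self.embed_enc, self.cfg.n_max)
        for rb in self.resblocks:
            x = rb(x)
        x = x.upsample_nearest2x()
        if self.cfg.skip_mode == "concat":
            x = concat([x, skips[0]], axis=1)
        elif self.cfg.skip_mode == "add":
            x = x + self.skip_proj(skips[0])
        x = self.dn1(self.dec1(x)).relu()
        x = x.upsample_nearest2x()
        x = self.dn2(self.dec2(x)).relu()
        if self.embed_dec is not None:
            x = apply_time_embedding(x, n, self.embed_dec, self.cfg.n_max)
        if self.cfg.input_skip:
            x = concat([x, x_in], axis=1)
        z = self.out_conv(x)
        return (z.tanh() + 1.0) * 127.5


def build_generator(cfg: GeneratorConfig, seed: int = 0) -> GeneratorModel:
    return GeneratorModel(cfg, seed=seed)


def _image_batch(images) -> Tensor:
    arr = np.stack([np.asarray(im, dtype=np.float32) for im in images])
    return Tensor(arr.transpose(0, 3, 1, 2) / 255.0)


def _forward_composited(model, images, masks, ns) -> Tensor:
    """Batched generate + re-fuse; stays in the autodiff graph."""
    x = _image_batch(images)
    m = np.stack([np.asarray(mk, dtype=np.float32) for mk in masks])[:, None]
    x_net = x * Tensor(m) if model.cfg.mask_input else x
    out = model(x_net, ns)
    return out * Tensor(m) + (x * 255.0) * Tensor(1.0 - m)


def predict(model: GeneratorModel, image, mask, n: int,
            refuse_background: bool = True) -> np.ndarray:
    """Predicted appearance of one frame after n days (uint8 image)."""
    if model.embed_enc is not None:
        n = int(n)
        if not (1 <= n <= model.cfg.n_max):
            raise ValueError(f"horizon N must lie in [1, {model.cfg.n_max}]")
        ns = [n]
    else:
        ns = [1]  # embedding-free ablation: the horizon argument is ignored
    x = _image_batch([image])
    if model.cfg.mask_input:
        x = x * Tensor(np.asarray(mask, dtype=np.float32)[None, None])
    out = model(x, ns)
    gen = out.data[0].transpose(1, 2, 0)
    gen = np.clip(np.round(gen), 0, 255).astype(np.uint8)
    if refuse_background:
        return composite_background(gen, np.asarray(image, dtype=np.uint8), mask)
    return gen


# ---------------------------------------------------------------------------
# training

def _precompute_targets(pairs, extractor, cfg: StyleConfig):
    """Constant per-pair loss inputs: input content features, target
    mask-normalized Grams, and the generated-side layer masks."""
    content_layers = tuple(cfg.content_layers or extractor.default_content_layers)
    style_layers = tuple(cfg.style_layers or extractor.default_style_layers)
    usable, prepared = [], []
    for p in pairs:
        if not np.any(np.asarray(p["y_mask"])) or not np.any(np.asarray(p["x_mask"])):
            warnings.warn(
                f"skipping pair with degenerate mask (sample N={p['n']})",
                stacklevel=3,
            )
            continue
        x4 = _image_batch([p["x"]]) * (extractor.input_scale * 255.0)
        y4 = _image_batch([p["y"]]) * (extractor.input_scale * 255.0)
        xf = {k: v.data[0] for k, v in
              extractor.features(x4, content_layers).items()}
        yf = {k: v.data[0] for k, v in
              extractor.features(y4, style_layers).items()}
        tgt_grams, gen_masks, gen_msums = {}, {}, {}
        for layer in style_layers:
            f = yf[layer]
            my = resize_mask_nearest(np.asarray(p["y_mask"]), f.shape[-2:])
            mx = resize_mask_nearest(np.asarray(p["x_mask"]), f.shape[-2:])
            if my.sum() == 0 or mx.sum() == 0:
                break
            fm = f * my[None]
            flat = fm.reshape(f.shape[0], -1)
            tgt_grams[layer] = (flat @ flat.T) / my.sum()
            gen_masks[layer] = mx.astype(np.float32)
            gen_msums[layer] = float(mx.sum())
        else:
            usable.append(p)
            prepared.append({
                "x_feats": xf, "tgt_grams": tgt_grams,
                "gen_masks": gen_masks, "gen_msums": gen_msums,
            })
            continue
        warnings.warn("skipping pair: mask vanished at a style layer",
                      stacklevel=3)
    return usable, prepared, content_layers, style_layers


def _batched_perceptual_loss(model, batch_pairs, batch_prep, extractor,
                             cfg: StyleConfig, content_layers, style_layers):
    ns = [p["n"] for p in batch_pairs]
    yhat = _forward_composited(
        model, [p["x"] for p in batch_pairs],
        [p["x_mask"] for p in batch_pairs], ns)
    feats = extractor.features(yhat * extractor.input_scale,
                               tuple(set(content_layers) | set(style_layers)))
    B = len(batch_pairs)
    loss = None
    # content term: mean squared difference to the *input's* features
    for layer in content_layers:
        f = feats[layer]
        ref = np.stack([prep["x_feats"][layer] for prep in batch_prep])
        size_per = f.data[0].size
        term = ((f - Tensor(ref)) ** 2.0).sum() * (cfg.content_weight / (size_per * B))
        loss = term if loss is None else loss + term
    # style term: mask-normalized Gram distance to the *target's* Grams
    for layer in style_layers:
        f = feats[layer]
        C = f.shape[1]
        masks = np.stack([prep["gen_masks"][layer] for prep in batch_prep])[:, None]
        msums = np.array([prep["gen_msums"][layer] for prep in batch_prep])
        fm = f * Tensor(masks)
        flat = fm.reshape(B, C, -1)
        grams = (flat @ flat.transpose(0, 2, 1)) * Tensor(
            (1.0 / msums).reshape(B, 1, 1).astype(np.float32))
        tgt = np.stack([prep["tgt_grams"][layer] for prep in batch_prep])
        Hl, Wl = f.shape[2], f.shape[3]
        if cfg.prefactor_convention == "as_printed":
            pref = cfg.weight(layer) / float(Hl * Wl * C) ** 2
        else:
            pref = cfg.weight(layer) / float(C) ** 2
        term = ((grams - Tensor(tgt.astype(np.float32))) ** 2.0).sum() * (
            cfg.style_weight * pref / B)
        loss = term if loss is None else loss + term
    return loss


def _epoch_eval(model, pairs, extractor, cfg, psnr_reference="input"):
    report = _metrics.evaluate_pairs(
        lambda im, mk, n: predict(model, im, mk, n),
        pairs, extractor=extractor, cfg=cfg, psnr_reference=psnr_reference)
    return report.psnr, report.mlsl


def select_generator_epoch(history: pd.DataFrame, n_mlsl: int = 10,
                           n_psnr: int = 5) -> int:
    """Two-stage validation model selection.

    Shortlist the ``n_mlsl`` epochs with the lowest validation MLSL, keep
    the ``n_psnr`` with the highest validation PSNR among them, and
    return the best-PSNR epoch of that shortlist.
    """
    df = history.dropna(subset=["val_mlsl", "val_psnr"])
    if df.empty:
        raise ValueError("history has no validation metrics")
    short = df.nsmallest(min(n_mlsl, len(df)), "val_mlsl")
    short = short.nlargest(min(n_psnr, len(short)), "val_psnr")
    return int(short.iloc[0]["epoch"])


def train_generator(pairs, loss_cfg: StyleConfig, cfg: GeneratorConfig,
                    extractor=None, seed: int = 0, val_pairs=None,
                    verbose: bool = False):
    """Train the generator on paired examples with Adam.

    ``pairs`` (and optional ``val_pairs``) are dicts with keys
    x, x_mask, n, y, y_mask (arrays / ints).  Returns (model, history);
    history holds per-epoch total loss, PSNR and MLSL on train and
    validation.  When validation pairs are given the checkpoint chosen by
    the two-stage (MLSL top-10 -> PSNR top-5) rule is restored.
    Deterministic in (data, configs, seed).
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty training set")
    bad = [p for p in pairs if p["n"] > cfg.n_max]
    if bad:
        raise ValueError(f"{len(bad)} pairs exceed n_max={cfg.n_max}")
    extractor = extractor if extractor is not None else IdentityExtractor()
    model = GeneratorModel(cfg, seed=seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate, betas=(0.9, 0.99))
    rng = np.random.default_rng(seed + 1)

    pairs, prep, content_layers, style_layers = _precompute_targets(
        pairs, extractor, loss_cfg)
    if not pairs:
        raise ValueError("no usable pairs after mask screening")

    rows, snapshots = [], {}
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(pairs))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            loss = _batched_perceptual_loss(
                model, [pairs[i] for i in idx], [prep[i] for i in idx],
                extractor, loss_cfg, content_layers, style_layers)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        row = {"epoch": epoch, "train_loss": float(np.mean(losses)),
               "train_psnr": np.nan, "train_mlsl": np.nan,
               "val_psnr": np.nan, "val_mlsl": np.nan}
        row["train_psnr"], row["train_mlsl"] = _epoch_eval(
            model, pairs[:64], extractor, loss_cfg)
        if val_pairs:
            row["val_psnr"], row["val_mlsl"] = _epoch_eval(
                model, val_pairs, extractor, loss_cfg)
            snapshots[epoch] = copy.deepcopy(model.state_arrays())
        rows.append(row)
        if verbose:
            print(f"[gen] epoch {epoch}: " + " ".join(
                f"{k}={v:.4f}" for k, v in row.items() if k != "epoch"))
    history = pd.DataFrame(rows)
    if snapshots:
        chosen = select_generator_epoch(history)
        model.load_state_arrays(snapshots[chosen])
        history.attrs["selected_epoch"] = chosen
    return model, history


def train_fixed_interval_generator(pairs, loss_cfg: StyleConfig,
                                   cfg: GeneratorConfig, extractor=None,
                                   seed: int = 0, val_pairs=None,
                                   verbose: bool = False):
    """Ablation: one embedding-free model per fixed horizon N.

    All pairs must share a single N; the returned model ignores the N
    argument at inference.  Comparing against the merged model shows the
    storage trade-off: one weight set per horizon here versus a single
    weight set serving all horizons.
    """
    ns = {p["n"] for p in pairs}
    if len(ns) != 1:
        raise ValueError(f"fixed-interval training needs a single N, got {sorted(ns)}")
    cfg = replace(cfg, use_embedding=False)
    return train_generator(pairs, loss_cfg, cfg, extractor=extractor,
                           seed=seed, val_pairs=val_pairs, verbose=verbose)


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(model: GeneratorModel, path, seed: int = 0) -> None:
    cfg = model.cfg
    meta = {}
    for k, v in vars(cfg).items():
        meta[f"cfg_{k}"] = np.asarray(v)
    arrays = {f"p{i:04d}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, seed=np.asarray(seed), **meta, **arrays)


def load_checkpoint(path) -> GeneratorModel:
    with np.load(path, allow_pickle=False) as z:
        cfg = GeneratorConfig(
            input_size=tuple(int(v) for v in z["cfg_input_size"]),
            stem_channels=tuple(int(v) for v in z["cfg_stem_channels"]),
            n_resblocks=int(z["cfg_n_resblocks"]),
            embedding_dim=int(z["cfg_embedding_dim"]),
            n_max=int(z["cfg_n_max"]),
            skip_mode=str(z["cfg_skip_mode"]),
            decoder_mid_channels=int(z["cfg_decoder_mid_channels"]),
            learning_rate=float(z["cfg_learning_rate"]),
            batch_size=int(z["cfg_batch_size"]),
            epochs=int(z["cfg_epochs"]),
            use_embedding=bool(z["cfg_use_embedding"]),
            input_skip=bool(z["cfg_input_skip"]),
            mask_input=bool(z["cfg_mask_input"]),
        )
        model = GeneratorModel(cfg, seed=int(z["seed"]))
        arrays = [z[k] for k in sorted(k for k in z.files if k.startswith("p"))]
    model.load_state_arrays(arrays)
    return model
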