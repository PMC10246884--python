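"""Fruit/background semantic segmentation.

A U-Net-style encoder-decoder (3x3 convolutions, 2x2 max pooling,
nearest-neighbor upsampling with skip concatenations, final sigmoid)
trained with a smoothed Dice loss

    loss = 1 - (1 + 2 sum(p*g)) / (1 + sum(p^2) + sum(g^2)),

whose +1 terms keep the ratio defined when both prediction and ground
truth are empty.  Evaluation is mean intersection-over-union over the two
classes {fruit, background}, pooled over the dataset's confusion counts.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .nn import Tensor, concat, Module, Conv2d, InstanceNorm2d, Adam

__all__ = [
    "SegConfig", "SegmentationModel", "build_segmentation_model", "dice_loss",
    "train_segmentation", "predict_mask", "miou",
    "save_checkpoint", "load_checkpoint",
]


@dataclass(frozen=True)
class SegConfig:
    input_size: tuple = (64, 64)       # (H, W), each divisible by 2**depth
    encoder_depth: int = 3             # number of 2x2 poolings
    base_channels: int = 8             # doubled at each encoder stage
    learning_rate: float = 1e-3        # Adam, betas (0.9, 0.99)
    batch_size: int = 8
    epochs: int = 10
    binarize_threshold: float = 0.5    # strict >, ties go to background
    norm: str = "none"                 # "none" | "instance"
    augment_flips: bool = False        # random horizontal flips while training

    def __post_init__(self):
        h, w = self.input_size
        f = 2 ** self.encoder_depth
        if h % f or w % f:
            raise ValueError(
                f"input size {self.input_size} not divisible by 2^{self.encoder_depth}"
            )
        if not (0.0 < self.binarize_threshold < 1.0):
            raise ValueError("binarize_threshold must lie in (0, 1)")


class _ConvBlock(Module):
    """(conv3x3 -> [IN] -> ReLU) x 2."""

    def __init__(self, in_ch, out_ch, rng, norm):
        self.c1 = Conv2d(in_ch, out_ch, 3, rng=rng)
        self.c2 = Conv2d(out_ch, out_ch, 3, rng=rng)
        self.n1 = InstanceNorm2d(out_ch) if norm == "instance" else None
        self.n2 = InstanceNorm2d(out_ch) if norm == "instance" else None

    def __call__(self, x):
        x = self.c1(x)
        if self.n1 is not None:
            x = self.n1(x)
        x = x.relu()
        x = self.c2(x)
        if self.n2 is not None:
            x = self.n2(x)
        return x.relu()


class SegmentationModel(Module):
    """U-Net over RGB frames; returns per-pixel fruit probabilities."""

    def __init__(self, cfg: SegConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        ch = cfg.base_channels
        self.encoders = []
        in_ch = 3
        for d in range(cfg.encoder_depth):
            self.encoders.append(_ConvBlock(in_ch, ch * 2 ** d, rng, cfg.norm))
            in_ch = ch * 2 ** d
        self.bottleneck = _ConvBlock(in_ch, in_ch * 2, rng, cfg.norm)
        self.decoders = []
        cur = in_ch * 2
        for d in reversed(range(cfg.encoder_depth)):
            skip_ch = ch * 2 ** d
            self.decoders.append(_ConvBlock(cur + skip_ch, skip_ch, rng, cfg.norm))
            cur = skip_ch
        self.head = Conv2d(cur, 1, 1, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        """x: (B, 3, H, W) in [0, 1] -> probabilities (B, H, W)."""
        skips = []
        for enc in self.encoders:
            x = enc(x)
            skips.append(x)
            x = x.maxpool2x2()
        x = self.bottleneck(x)
        for dec, skip in zip(self.decoders, reversed(skips)):
            x = x.upsample_nearest2x()
            x = concat([x, skip], axis=1)
            x = dec(x)
        logits = self.head(x)
        B, _, H, W = logits.shape
        return logits.sigmoid().reshape(B, H, W)


def build_segmentation_model(cfg: SegConfig, seed: int = 0) -> SegmentationModel:
    return SegmentationModel(cfg, seed=seed)


def _to_tensor_batch(images) -> Tensor:
    arr = np.stack([np.asarray(im, dtype=np.float32) for im in images])
    return Tensor(arr.transpose(0, 3, 1, 2) / 255.0)


def dice_loss(pred, truth):
    """Smoothed Dice loss between a probability map and a binary mask.

    Accepts arrays (returns float) or Tensors (returns a scalar Tensor in
    the autodiff graph).  Batched inputs score each item jointly via the
    global sums, matching the single-mask formula when B = 1.
    """
    is_tensor = isinstance(pred, Tensor)
    p = pred if is_tensor else Tensor(np.asarray(pred, dtype=np.float64))
    t = truth if isinstance(truth, Tensor) else Tensor(np.asarray(truth, dtype=np.float64))
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    if not np.isin(t.data, (0.0, 1.0)).all():
        raise ValueError("ground truth mask must be binary")
    inter = (p * t).sum()
    denom = (p * p).sum() + (t * t).sum() + 1.0
    loss = 1.0 - (2.0 * inter + 1.0) / denom
    return loss if is_tensor else loss.item()


def predict_mask(model: SegmentationModel, image: np.ndarray,
                 threshold: float = None) -> np.ndarray:
    """Binarized fruit mask for one RGB frame (strict > threshold)."""
    thr = model.cfg.binarize_threshold if threshold is None else threshold
    prob = model(_to_tensor_batch([image])).data[0]
    return (prob > thr).astype(np.uint8)


def miou(preds: Sequence[np.ndarray], truths: Sequence[np.ndarray],
         per_image: bool = False) -> float:
    """Mean IoU over {fruit, background}.

    Default pools confusion counts over the whole list (dataset-level);
    ``per_image`` averages the two-class mean IoU frame by frame instead.
    An absent class with an empty prediction counts IoU 1 for that class.
    """
    if len(preds) == 0:
        raise ValueError("miou requires at least one mask pair")
    if len(preds) != len(truths):
        raise ValueError("preds and truths must have equal length")

    def pair_counts(p, t):
        p = np.asarray(p).astype(bool)
        t = np.asarray(t).astype(bool)
        if p.shape != t.shape:
            raise ValueError(f"mask shape mismatch {p.shape} vs {t.shape}")
        tp = np.count_nonzero(p & t)
        fp = np.count_nonzero(p & ~t)
        fn = np.count_nonzero(~p & t)
        tn = p.size - tp - fp - fn
        return np.array([tp, fp, fn, tn], dtype=np.int64)

    def mean_iou(c):
        tp, fp, fn, tn = c
        fruit = tp / (tp + fp + fn) if (tp + fp + fn) else 1.0
        background = tn / (tn + fp + fn) if (tn + fp + fn) else 1.0
        return (fruit + background) / 2.0

    if per_image:
        return float(np.mean([mean_iou(pair_counts(p, t))
                              for p, t in zip(preds, truths)]))
    total = sum(pair_counts(p, t) for p, t in zip(preds, truths))
    return float(mean_iou(total))


def _epoch_metrics(model, items, cfg):
    """(dice loss, miou) over a list of (image, mask) without gradients."""
    losses, preds, truths = [], [], []
    for start in range(0, len(items), cfg.batch_size):
        chunk = items[start:start + cfg.batch_size]
        x = _to_tensor_batch([im for im, _ in chunk])
        probs = model(x).data
        for (im, mask), prob in zip(chunk, probs):
            losses.append(dice_loss(prob, np.asarray(mask, dtype=np.float64)))
            preds.append((prob > cfg.binarize_threshold).astype(np.uint8))
            truths.append(mask)
    return float(np.mean(losses)), miou(preds, truths)


def train_segmentation(train_items, cfg: SegConfig, seed: int = 0,
                       val_items=None, verbose: bool = False):
    """Train a U-Net on (image, mask) pairs with Adam on the Dice loss.

    Returns (model, history) where history is a DataFrame with one row
    per epoch (train/val Dice loss and MIoU).  The parameters achieving
    the best validation MIoU are restored into the returned model.
    Deterministic in (data, cfg, seed).
    """
    train_items = list(train_items)
    if not train_items:
        raise ValueError("empty training set")
    model = SegmentationModel(cfg, seed=seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate, betas=(0.9, 0.99))
    rng = np.random.default_rng(seed + 1)
    rows = []
    best = (-1.0, None)
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_items))
        for start in range(0, len(order), cfg.batch_size):
            batch = [train_items[i] for i in order[start:start + cfg.batch_size]]
            ims = [np.asarray(im) for im, _ in batch]
            mks = [np.asarray(m, dtype=np.float32) for _, m in batch]
            if cfg.augment_flips:
                flips = rng.random(len(batch)) < 0.5
                ims = [im[:, ::-1] if f else im for im, f in zip(ims, flips)]
                mks = [mk[:, ::-1] if f else mk for mk, f in zip(mks, flips)]
            x = _to_tensor_batch(ims)
            t = Tensor(np.stack(mks))
            probs = model(x)
            loss = dice_loss(probs, t)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite Dice loss at epoch {epoch}, step {start}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
        tr_loss, tr_miou = _epoch_metrics(model, train_items, cfg)
        row = {"epoch": epoch, "train_loss": tr_loss, "train_miou": tr_miou,
               "val_loss": np.nan, "val_miou": np.nan}
        if val_items:
            row["val_loss"], row["val_miou"] = _epoch_metrics(model, val_items, cfg)
            if row["val_miou"] > best[0]:
                best = (row["val_miou"], copy.deepcopy(model.state_arrays()))
        rows.append(row)
        if verbose:
            print(f"[seg] epoch {epoch}: " + " ".join(
                f"{k}={v:.4f}" for k, v in row.items() if k != "epoch"))
    if best[1] is not None:
        model.load_state_arrays(best[1])
    return model, pd.DataFrame(rows)


def save_checkpoint(model: SegmentationModel, path, seed: int = 0) -> None:
    cfg = model.cfg
    meta = {f"cfg_{k}": np.asarray(v) for k, v in vars(cfg).items()}
    arrays = {f"p{i:04d}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, seed=np.asarray(seed), **meta, **arrays)


def load_checkpoint(path) -> SegmentationModel:
    with np.load(path, allow_pickle=False) as z:
        cfg = SegConfig(
            input_size=tuple(int(v) for v in z["cfg_input_size"]),
            encoder_depth=int(z["cfg_encoder_depth"]),
            base_channels=int(z["cfg_base_channels"]),
            learning_rate=float(z["cfg_learning_rate"]),
            batch_size=int(z["cfg_batch_size"]),
            epochs=int(z["cfg_epochs"]),
            binarize_threshold=float(z["cfg_binarize_threshold"]),
            norm=str(z["cfg_norm"]),
            augment_flips=bool(z["cfg_augment_flips"]),
        )
        model = SegmentationModel(cfg, seed=int(z["seed"]))
        arrays = [z[k] for k in sorted(k for k in z.files if k.startswith("p"))]
    model.load_state_arrays(arrays)
    return model
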