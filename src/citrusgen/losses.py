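"""Loss network and perceptual loss functions.

The generative network is trained without a discriminator; its objective
is computed on activations of a fixed *loss network*:

* content loss — per-layer mean squared activation difference at
  high-level layers (Conv4_2, Conv5_2 in the VGG19 layout),
* local style loss (``L*_style``) — squared Frobenius difference of
  *mask-normalized* Gram matrices at low-level layers.  Features are
  multiplied by the fruit mask (resized to each layer) before Gram
  accumulation and the Gram matrix is divided by the mask sum, which
  removes both the background and the fruit-size dependence that plain
  Gram style losses suffer from,
* local perceptual loss — content(input, generated) + L*_style(target,
  generated).

Two baselines are provided for comparison: the classic unmasked Gram
style loss (Gatys) and the "black background" variant that zeroes the
background before applying it.

Two extractors are available: a VGG19-topology network with frozen,
seeded random weights (untrained random convolutional features are a
standard fixed basis for texture statistics), and an identity extractor
whose single layer is the raw pixel array, which makes every loss exactly
computable by hand and is the default for desk-scale training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from .nn import Tensor, Conv2d

__all__ = [
    "StyleConfig", "IdentityExtractor", "VGGStyleExtractor",
    "extract_features", "resize_mask_nearest", "layer_masks",
    "gram", "masked_normalized_gram", "content_loss", "local_style_loss",
    "local_perceptual_loss", "style_loss_gatys", "style_loss_blackbg",
    "style_difference_matrix", "quantize_levels",
]

VGG19_CONTENT_LAYERS = ("Conv4_2", "Conv5_2")
VGG19_STYLE_LAYERS = ("Conv1_1", "Conv2_1", "Conv3_1", "Conv4_1", "Conv5_1")


@dataclass(frozen=True)
class StyleConfig:
    """Layer selection and normalization conventions for the losses.

    ``content_layers`` / ``style_layers`` of None mean "use the
    extractor's defaults" (the VGG19 layout above, or the identity
    extractor's single ``input`` layer).  ``style_layer_weights`` maps
    layer name -> weight; missing layers weigh 1.

    ``prefactor_convention`` fixes the per-layer normalization of
    ``L*_style``: ``as_printed`` divides by (H_l W_l C_l)^2 like the
    Gatys loss; ``channels_only`` divides by C_l^2 on the grounds that
    the mask-sum division has already normalized spatial extent.
    """

    content_layers: Optional[Sequence[str]] = None
    style_layers: Optional[Sequence[str]] = None
    style_layer_weights: Dict[str, float] = field(default_factory=dict)
    prefactor_convention: str = "as_printed"   # or "channels_only"
    content_weight: float = 1.0
    style_weight: float = 1.0

    def __post_init__(self):
        if self.prefactor_convention not in ("as_printed", "channels_only"):
            raise ValueError(
                f"unknown prefactor convention {self.prefactor_convention!r}"
            )
        if any(w < 0 for w in self.style_layer_weights.values()):
            raise ValueError("style layer weights must be >= 0")

    def weight(self, layer: str) -> float:
        return float(self.style_layer_weights.get(layer, 1.0))


# ---------------------------------------------------------------------------
# extractors

class IdentityExtractor:
    """Single-layer extractor returning the (scaled) raw pixels.

    Its one layer is named ``input`` with downsampling factor 1.  Every
    loss built on it has a closed form, which the unit tests exploit.

    With ``augment_constant`` a fourth, all-ones channel is appended, so
    the mask-normalized Gram additionally carries the first moments (the
    mean color over the mask) next to the raw second moments — the
    configuration the desk-scale generator training uses, since plain
    RGB second moments leave the mean color underdetermined.
    """

    input_scale = 1.0 / 255.0

    def __init__(self, augment_constant: bool = False):
        self.augment_constant = augment_constant

    default_content_layers = ("input",)
    default_style_layers = ("input",)

    def layer_factor(self, layer: str) -> int:
        self._check(layer)
        return 1

    def _check(self, layer):
        if layer != "input":
            raise KeyError(f"identity extractor has no layer {layer!r}")

    def features(self, x: Tensor, layers=("input",)) -> Dict[str, Tensor]:
        for layer in layers:
            self._check(layer)
        if self.augment_constant:
            ones = Tensor(np.ones((x.shape[0], 1) + tuple(x.shape[2:]),
                                  dtype=np.float32))
            x = concat_channels(x, ones)
        return {"input": x}


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    from .nn import concat as _concat
    return _concat([a, b], axis=1)


class VGGStyleExtractor:
    """VGG19-topology feature extractor with frozen seeded random weights.

    Five convolution blocks of (2, 2, 4, 4, 4) 3x3 convolutions with ReLU,
    each block followed by 2x2 max pooling; layers are named Conv<i>_<j>.
    ``width_scale`` shrinks the canonical (64, 128, 256, 512, 512) channel
    widths for desk-scale use.  Weights are orthogonal-free He draws from
    a fixed seed and never trained; gradients still flow through to the
    input image.
    """

    BLOCK_CONVS = (2, 2, 4, 4, 4)
    BLOCK_CHANNELS = (64, 128, 256, 512, 512)
    default_content_layers = VGG19_CONTENT_LAYERS
    default_style_layers = VGG19_STYLE_LAYERS
    input_scale = 1.0 / 255.0

    def __init__(self, seed: int = 0, width_scale: float = 1.0):
        rng = np.random.default_rng(seed)
        self.convs = {}          # name -> Conv2d (frozen)
        self.order = []          # [(name, block_index)]
        in_ch = 3
        for b, (n_convs, width) in enumerate(
                zip(self.BLOCK_CONVS, self.BLOCK_CHANNELS), start=1):
            out_ch = max(2, int(round(width * width_scale)))
            for j in range(1, n_convs + 1):
                name = f"Conv{b}_{j}"
                self.convs[name] = Conv2d(in_ch, out_ch, 3, rng=rng,
                                          trainable=False)
                self.order.append((name, b))
                in_ch = out_ch

    def layer_factor(self, layer: str) -> int:
        """Total spatial downsampling at a layer's output."""
        for name, block in self.order:
            if name == layer:
                return 2 ** (block - 1)
        raise KeyError(f"unknown layer {layer!r}")

    def features(self, x: Tensor, layers) -> Dict[str, Tensor]:
        wanted = set(layers)
        unknown = wanted - set(self.convs)
        if unknown:
            raise KeyError(f"unknown layers {sorted(unknown)!r}")
        out: Dict[str, Tensor] = {}
        prev_block = 1
        for name, block in self.order:
            if block != prev_block:
                x = x.maxpool2x2()
                prev_block = block
            x = self.convs[name](x).relu()
            if name in wanted:
                out[name] = x
            if len(out) == len(wanted):
                break
        return out


def _to_batch_tensor(image) -> Tensor:
    """HxWx3 array in [0,255] -> (1,3,H,W) Tensor (no scaling)."""
    if isinstance(image, Tensor):
        return image if image.ndim == 4 else image.reshape((1,) + image.shape)
    arr = np.asarray(image, dtype=np.float32)
    if arr.ndim == 3 and arr.shape[2] == 3:
        arr = arr.transpose(2, 0, 1)
    return Tensor(arr[None])


def extract_features(image, extractor, layers) -> Dict[str, Tensor]:
    """Per-layer activations for one image.

    ``image`` is an HxWx3 array on the [0, 255] scale (or a CHW/BCHW
    Tensor already in the graph); it is scaled by ``extractor.input_scale``
    before extraction.  Returns {layer: Tensor(C, H_l, W_l)}.
    """
    x = _to_batch_tensor(image) * extractor.input_scale
    feats = extractor.features(x, layers)
    return {k: v.reshape(v.shape[1:]) for k, v in feats.items()}


# ---------------------------------------------------------------------------
# masks at layer resolution

def resize_mask_nearest(mask: np.ndarray, shape) -> np.ndarray:
    """Nearest-neighbor resize preserving binarity."""
    mask = np.asarray(mask)
    h, w = shape
    rows = (np.arange(h) * mask.shape[0] / h).astype(int)
    cols = (np.arange(w) * mask.shape[1] / w).astype(int)
    return mask[np.ix_(rows, cols)]


def layer_masks(mask: np.ndarray, feats: Dict[str, Tensor]) -> Dict[str, np.ndarray]:
    """Resize a full-resolution mask to each layer's feature-map size."""
    return {
        layer: resize_mask_nearest(mask, f.shape[-2:]) for layer, f in feats.items()
    }


# ---------------------------------------------------------------------------
# grams and losses

def _maybe_float(t: Tensor):
    if t.requires_grad:
        return t
    return float(t.data) if t.data.ndim == 0 else t.data


def _as_feature_tensor(feature) -> Tensor:
    f = feature if isinstance(feature, Tensor) else Tensor(np.asarray(feature))
    if f.ndim != 3:
        raise ValueError(f"expected C x H x W feature, got shape {f.shape}")
    return f


def gram(feature):
    """Unnormalized Gram matrix G_mn = sum_t F^m_t F^n_t of a CxHxW map."""
    f = _as_feature_tensor(feature)
    C, H, W = f.shape
    flat = f.reshape(C, H * W)
    g = flat @ flat.transpose(1, 0)
    return _maybe_float(g)


def masked_normalized_gram(feature, mask):
    """Gram of mask-multiplied features, divided by the mask sum.

    For a region of constant per-channel value c the result is the outer
    product c c^T whatever the region's area — the size invariance that
    motivates the local style loss.
    """
    f = _as_feature_tensor(feature)
    mask = np.asarray(mask, dtype=f.data.dtype)
    if mask.shape != f.shape[-2:]:
        raise ValueError(
            f"mask shape {mask.shape} does not match feature {f.shape[-2:]}"
        )
    total = float(mask.sum())
    if total == 0:
        raise ValueError("degenerate mask: sum is zero")
    masked = f * Tensor(mask[None])
    C, H, W = f.shape
    flat = masked.reshape(C, H * W)
    g = (flat @ flat.transpose(1, 0)) * (1.0 / total)
    return _maybe_float(g)


def _resolve(layers, cfg_layers, extractor, which):
    if cfg_layers is not None:
        return tuple(cfg_layers)
    if extractor is not None:
        return tuple(getattr(extractor, f"default_{which}_layers"))
    return tuple(layers)


def content_loss(x_feats: Dict[str, Tensor], yhat_feats: Dict[str, Tensor],
                 layers=None):
    """Sum over layers of the mean squared activation difference."""
    layers = tuple(layers) if layers is not None else tuple(x_feats)
    total = None
    for layer in layers:
        fx, fy = x_feats[layer], yhat_feats[layer]
        fx = fx if isinstance(fx, Tensor) else Tensor(np.asarray(fx))
        fy = fy if isinstance(fy, Tensor) else Tensor(np.asarray(fy))
        if fx.shape != fy.shape:
            raise ValueError(
                f"content layer {layer}: shape {fx.shape} vs {fy.shape}"
            )
        term = ((fx - fy) ** 2.0).sum() * (1.0 / fx.data.size)
        total = term if total is None else total + term
    return _maybe_float(total)


def _style_prefactor(shape, cfg: StyleConfig, layer: str) -> float:
    C, H, W = shape
    if cfg.prefactor_convention == "as_printed":
        return cfg.weight(layer) / float(H * W * C) ** 2
    return cfg.weight(layer) / float(C) ** 2


def local_style_loss(y_feats, yhat_feats, y_masks, yhat_masks,
                     cfg: StyleConfig = StyleConfig(), layers=None):
    """Mask-normalized Gram distance, summed over style layers.

    ``y_masks``/``yhat_masks`` map layer name -> mask at that layer's
    resolution (see :func:`layer_masks`).  Raises on a degenerate (all
    zero) mask, naming the layer.
    """
    layers = tuple(layers) if layers is not None else tuple(y_feats)
    total = None
    for layer in layers:
        fy, fyh = y_feats[layer], yhat_feats[layer]
        fy = _as_feature_tensor(fy)
        fyh = _as_feature_tensor(fyh)
        try:
            gy = masked_normalized_gram(fy, y_masks[layer])
            gyh = masked_normalized_gram(fyh, yhat_masks[layer])
        except ValueError as e:
            raise ValueError(f"style layer {layer}: {e}") from e
        gy = gy if isinstance(gy, Tensor) else Tensor(gy)
        gyh = gyh if isinstance(gyh, Tensor) else Tensor(gyh)
        term = ((gyh - gy) ** 2.0).sum() * _style_prefactor(fy.shape, cfg, layer)
        total = term if total is None else total + term
    return _maybe_float(total)


def local_perceptual_loss(x_feats, y_feats, yhat_feats, y_masks, yhat_masks,
                          cfg: StyleConfig = StyleConfig(),
                          content_layers=None, style_layers=None):
    """content(input, generated) + L*_style(target, generated)."""
    c = content_loss(x_feats, yhat_feats,
                     layers=content_layers or cfg.content_layers)
    s = local_style_loss(y_feats, yhat_feats, y_masks, yhat_masks, cfg,
                         layers=style_layers or cfg.style_layers)
    c = c if isinstance(c, Tensor) else Tensor(np.asarray(c))
    s = s if isinstance(s, Tensor) else Tensor(np.asarray(s))
    return _maybe_float(cfg.content_weight * c + cfg.style_weight * s)


def style_loss_gatys(y_feats, yhat_feats, cfg: StyleConfig = StyleConfig(),
                     layers=None):
    """Classic unmasked Gram style loss: sum_l |G(yhat)-G(y)|_F^2/(HWC)^2."""
    layers = tuple(layers) if layers is not None else tuple(y_feats)
    total = None
    for layer in layers:
        fy = _as_feature_tensor(y_feats[layer])
        fyh = _as_feature_tensor(yhat_feats[layer])
        if fy.shape != fyh.shape:
            raise ValueError(f"style layer {layer}: shape mismatch")
        gy, gyh = gram(fy), gram(fyh)
        gy = gy if isinstance(gy, Tensor) else Tensor(gy)
        gyh = gyh if isinstance(gyh, Tensor) else Tensor(gyh)
        C, H, W = fy.shape
        term = ((gyh - gy) ** 2.0).sum() * (cfg.weight(layer) / float(H * W * C) ** 2)
        total = term if total is None else total + term
    return _maybe_float(total)


def style_loss_blackbg(y, yhat, y_mask, yhat_mask, extractor,
                       cfg: StyleConfig = StyleConfig(), layers=None):
    """Gatys loss on images whose background was zeroed by the masks."""
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y_mask.shape != y.shape[:2] or yhat_mask.shape != yhat.shape[:2]:
        raise ValueError("mask sizes must match their images")
    yb = y * np.asarray(y_mask)[..., None]
    yhb = yhat * np.asarray(yhat_mask)[..., None]
    layers = tuple(layers) if layers is not None else _resolve(
        None, cfg.style_layers, extractor, "style")
    fy = extract_features(yb, extractor, layers)
    fyh = extract_features(yhb, extractor, layers)
    return style_loss_gatys(fy, fyh, cfg, layers=layers)


# ---------------------------------------------------------------------------
# pairwise comparison harness

def quantize_levels(matrix: np.ndarray, levels: int = 5) -> np.ndarray:
    """Bin a difference matrix into 1..levels equal-width bands."""
    m = np.asarray(matrix, dtype=float)
    lo, hi = m.min(), m.max()
    if hi == lo:
        return np.ones_like(m, dtype=int)
    q = np.floor((m - lo) / (hi - lo) * levels).astype(int) + 1
    return np.clip(q, 1, levels)


def style_difference_matrix(images, masks=None, metric: str = "local",
                            extractor=None, cfg: StyleConfig = StyleConfig(),
                            quantize: bool = False) -> np.ndarray:
    """Pairwise style differences under one of the three metrics.

    ``metric`` is "gatys", "blackbg" or "local"; the latter two require
    ``masks``.  Returns a symmetric zero-diagonal matrix, optionally
    quantized into 5 equal-width levels between its min and max.
    """
    if len(images) < 2:
        raise ValueError("need at least 2 images")
    if metric in ("blackbg", "local") and masks is None:
        raise ValueError(f"metric {metric!r} requires masks")
    if extractor is None:
        extractor = IdentityExtractor()
    layers = _resolve(None, cfg.style_layers, extractor, "style")
    n = len(images)
    feats, lmasks = [], []
    for i in range(n):
        f = extract_features(images[i], extractor, layers)
        feats.append(f)
        if masks is not None:
            lmasks.append(layer_masks(np.asarray(masks[i]), f))
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "gatys":
                d = style_loss_gatys(feats[i], feats[j], cfg, layers=layers)
            elif metric == "blackbg":
                d = style_loss_blackbg(images[i], images[j], masks[i], masks[j],
                                       extractor, cfg, layers=layers)
            elif metric == "local":
                d = local_style_loss(feats[i], feats[j], lmasks[i], lmasks[j],
                                     cfg, layers=layers)
            else:
                raise ValueError(f"unknown metric {metric!r}")
            out[i, j] = out[j, i] = float(d)
    return quantize_levels(out) if quantize else out


def plot_difference_matrix(matrix: np.ndarray, path, title: str = "") -> None:
    """5-level heat map of a pairwise style-difference matrix."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    q = quantize_levels(matrix)
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(q, cmap="viridis", vmin=1, vmax=5)
    for (i, j), v in np.ndenumerate(q):
        ax.text(j, i, str(v), ha="center", va="center", color="white")
    ax.set_title(title or "style difference (5 levels)")
    fig.colorbar(im, ax=ax, ticks=range(1, 6))
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)
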