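"""Image-quality and color-accuracy metrics.

Color accuracy is anchored on the Citrus Color Index

    CCI = 1000 * a / (L * b)

computed in Hunter Lab coordinates from the mean RGB of the fruit pixels.
CCI is negative for green rinds, near zero at the color break and
positive for orange rinds, and is the standard maturity proxy in citrus
horticulture.  Hunter Lab here uses sRGB primaries with a D65 white point
and Ka = 172.30, Kb = 67.20 (the illuminant-C variant, Ka = 175, Kb = 70,
is available via ``white="C"``).

PSNR is reported against the *input* frame by default: the generated
frame re-fuses the input's background, so input-referenced PSNR is well
defined even though input and target frames have no pixel
correspondence.  ``reference="target"`` switches to the ground truth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage import color as skcolor

from .losses import (StyleConfig, IdentityExtractor, extract_features,
                     layer_masks, local_style_loss)

__all__ = [
    "psnr", "rgb_to_hunterlab", "cci", "cci_error", "mlsl", "mean_hue_degrees",
    "MetricsReport", "evaluate_pairs",
]

# (Xn, Yn, Zn, Ka, Kb) per white point.  The D65 normalization is derived
# from the sRGB matrix itself (XYZ of pure white), so neutral grays map to
# a = b = 0 exactly rather than to matrix-precision residuals.
_D65_WHITE = skcolor.rgb2xyz(np.ones((1, 1, 3))).reshape(3)
_WHITE_POINTS = {
    "D65": (float(_D65_WHITE[0]), float(_D65_WHITE[1]), float(_D65_WHITE[2]),
            172.30, 67.20),
    "C": (0.98074, 1.0, 1.18232, 175.0, 70.0),
}

# |a| and |b| below this are treated as achromatic in the CCI ratio
_NEUTRAL_TOL = 0.05


def psnr(a: np.ndarray, b: np.ndarray, peak: float = 255.0) -> float:
    """10 log10(peak^2 / MSE) over all pixels and channels; inf when a == b."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    mse = np.mean((a - b) ** 2)
    if mse == 0:
        return math.inf
    return float(10.0 * np.log10(peak ** 2 / mse))


def rgb_to_hunterlab(rgb, white: str = "D65"):
    """sRGB triple in [0,255] -> Hunter (L, a, b).

    sRGB is linearized and taken to XYZ (D65), then

        L = 100 sqrt(Y/Yn)
        a = Ka (X/Xn - Y/Yn) / sqrt(Y/Yn)
        b = Kb (Y/Yn - Z/Zn) / sqrt(Y/Yn)

    Neutral grays map to a = b = 0; reference white has L = 100.
    """
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.min() < 0 or rgb.max() > 255:
        raise ValueError("RGB values must lie in [0, 255]")
    xn, yn, zn, ka, kb = _WHITE_POINTS[white]
    xyz = skcolor.rgb2xyz(rgb.reshape(1, 1, 3) / 255.0).reshape(3)
    xr, yr, zr = xyz[0] / xn, xyz[1] / yn, xyz[2] / zn
    if yr <= 0:
        return (0.0, 0.0, 0.0)
    s = math.sqrt(yr)
    return (100.0 * s, ka * (xr - yr) / s, kb * (yr - zr) / s)


def cci(image: np.ndarray, mask: np.ndarray, white: str = "D65") -> float:
    """Citrus Color Index 1000 a / (L b) of the mean fruit color.

    Depends only on pixels inside the mask.  The ratio is undefined when
    L*b vanishes: a neutral color (a ~ 0) returns 0, otherwise a
    near-zero b is clamped at |b| = 1e-6 with a warning and a zero L
    raises.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty fruit mask")
    mean_rgb = np.asarray(image, dtype=np.float64)[mask].mean(axis=0)
    L, a, b = rgb_to_hunterlab(mean_rgb, white=white)
    if abs(a) < _NEUTRAL_TOL and (L == 0 or abs(b) < _NEUTRAL_TOL):
        return 0.0  # achromatic color: index defined as zero
    if L == 0:
        raise ValueError("CCI undefined: L = 0 with chromatic a")
    if abs(b) < 1e-6:
        warnings.warn("near-neutral b clamped to 1e-6 in CCI", stacklevel=2)
        b = math.copysign(1e-6, b if b != 0 else 1.0)
    return 1000.0 * a / (L * b)


def cci_error(pred: np.ndarray, truth: np.ndarray, pred_mask, truth_mask,
              white: str = "D65") -> float:
    """L1 distance between the CCI of the prediction and the ground truth."""
    return abs(cci(pred, pred_mask, white) - cci(truth, truth_mask, white))


def mlsl(pairs, extractor=None, cfg: StyleConfig = StyleConfig(),
         layers=None) -> float:
    """Mean local style loss over (generated, truth, gen_mask, truth_mask)."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("mlsl requires at least one pair")
    extractor = extractor if extractor is not None else IdentityExtractor()
    if layers is None:
        layers = cfg.style_layers or extractor.default_style_layers
    vals = []
    for gen, truth, gen_mask, truth_mask in pairs:
        fg = extract_features(gen, extractor, layers)
        ft = extract_features(truth, extractor, layers)
        vals.append(float(local_style_loss(
            ft, fg, layer_masks(np.asarray(truth_mask), ft),
            layer_masks(np.asarray(gen_mask), fg), cfg, layers=layers)))
    return float(np.mean(vals))


def mean_hue_degrees(image: np.ndarray, mask: np.ndarray) -> float:
    """Mean HSV hue (degrees) over the fruit pixels.

    Plain (non-circular) mean: rind hues live in ~[20, 110] deg, far from
    the 0/360 wrap.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty fruit mask")
    hsv = skcolor.rgb2hsv(np.asarray(image, dtype=np.float64) / 255.0)
    return float(hsv[..., 0][mask].mean() * 360.0)


@dataclass(frozen=True)
class MetricsReport:
    """One evaluation row in the (PSNR, MLSL, CCI error[, MIoU]) layout."""

    psnr: float
    mlsl: float
    cci_error: float
    n_pairs: int
    miou: Optional[float] = None

    def as_row(self) -> dict:
        row = {
            "PSNR": "inf" if math.isinf(self.psnr) else round(self.psnr, 4),
            "MLSL": round(self.mlsl, 6),
            "CCI_error": round(self.cci_error, 6),
            "n_pairs": self.n_pairs,
        }
        if self.miou is not None:
            row["MIoU"] = round(self.miou, 6)
        return row


def evaluate_pairs(predict_fn, pairs, extractor=None,
                   cfg: StyleConfig = StyleConfig(),
                   psnr_reference: str = "input",
                   white: str = "D65") -> MetricsReport:
    """Aggregate metrics of a predictor over paired examples.

    ``predict_fn(image, mask, N) -> image`` is the trained generator's
    forward; ``pairs`` yield dicts with keys x, x_mask, n, y, y_mask.
    PSNR is averaged against the input frame (default) or the target.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty evaluation set")
    psnrs, mlsl_pairs, ccis = [], [], []
    for p in pairs:
        yhat = predict_fn(p["x"], p["x_mask"], p["n"])
        ref = p["x"] if psnr_reference == "input" else p["y"]
        psnrs.append(psnr(yhat, ref))
        mlsl_pairs.append((yhat, p["y"], p["x_mask"], p["y_mask"]))
        ccis.append(cci_error(yhat, p["y"], p["x_mask"], p["y_mask"], white))
    finite = [v for v in psnrs if math.isfinite(v)]
    mean_psnr = float(np.mean(finite)) if finite else math.inf
    return MetricsReport(
        psnr=mean_psnr,
        mlsl=mlsl(mlsl_pairs, extractor, cfg),
        cci_error=float(np.mean(ccis)),
        n_pairs=len(pairs),
    )
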