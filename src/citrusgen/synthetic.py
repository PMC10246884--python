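"""Synthetic orchard image series with exact fruit masks.

Emulates the statistical structure of a field-acquired citrus ripening
dataset: each *sample* (one fruit) is imaged daily over a color
transformation period of several weeks, with the rind hue drifting from
green (~95 deg in HSV) toward orange (~30 deg) at a per-fruit rate, uneven
coloration (stripes and spots), radial shading, varying fruit size and
position, a varying background, and occasional missing frames.  Frames
are rendered as shaded ellipses over smoothed colored-noise backgrounds —
cheap, fully labelled, and with the one-parameter color signal that the
downstream generator must learn to extrapolate.

Not emulated: perspective/3-D shape, specular highlights, occlusion by
leaves, and day-to-day illumination drift beyond a per-fruit gain.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import color as skcolor

from .data import SampleRecord, write_manifest, save_image, save_mask

__all__ = [
    "ColorTrajectory", "SceneParams", "render_frame", "generate_dataset",
    "DEFAULT_IMAGE_SIZE",
]

DEFAULT_IMAGE_SIZE = (64, 64)  # (H, W); the field resolution is (192, 256)

HUE_GREEN = 95.0
HUE_ORANGE = 30.0


@dataclass(frozen=True)
class ColorTrajectory:
    """Deterministic rind-hue schedule for one fruit.

    Hue (HSV degrees) decreases linearly from ``hue_start`` at ``rate``
    degrees/day, clamped at ``hue_end``; ``noise_sd`` is the per-day hue
    jitter applied at render time.
    """

    hue_start: float = HUE_GREEN
    hue_end: float = HUE_ORANGE
    rate: float = 1.5
    noise_sd: float = 2.0

    def hue(self, day: float) -> float:
        return float(np.clip(self.hue_start - self.rate * day,
                             self.hue_end, self.hue_start))


@dataclass(frozen=True)
class SceneParams:
    """Static nuisance factors of one fruit's viewpoint."""

    fruit_center: tuple = (32, 32)   # (x, y) pixels
    fruit_radii: tuple = (18, 16)    # (rx, ry) pixels, each >= 8
    background_seed: int = 0
    lighting_gain: float = 1.0       # in [0.7, 1.3]
    n_blemishes: int = 3
    blemish_size: tuple = (2, 6)     # radius range, pixels
    image_size: tuple = DEFAULT_IMAGE_SIZE

    def __post_init__(self):
        h, w = self.image_size
        cx, cy = self.fruit_center
        rx, ry = self.fruit_radii
        if min(rx, ry) < 8:
            raise ValueError("fruit radii must be >= 8 px")
        if not (cx - rx >= 0 and cx + rx < w and cy - ry >= 0 and cy + ry < h):
            raise ValueError("fruit ellipse must lie fully inside the frame")


def _ellipse_mask(scene: SceneParams) -> np.ndarray:
    h, w = scene.image_size
    cx, cy = scene.fruit_center
    rx, ry = scene.fruit_radii
    yy, xx = np.mgrid[0:h, 0:w]
    return (((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0).astype(np.uint8)


def _smooth_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Low-frequency noise field, roughly unit scale."""
    raw = rng.normal(size=shape)
    sm = ndimage.gaussian_filter(raw, sigma=sigma, mode="reflect")
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def _background(scene: SceneParams) -> np.ndarray:
    """Foliage-like background, a function of background_seed only."""
    rng = np.random.default_rng(scene.background_seed)
    h, w = scene.image_size
    base_hue = rng.uniform(70.0, 160.0)  # greens through blue-greens
    hue = base_hue + 15.0 * _smooth_noise(rng, (h, w), sigma=6.0)
    sat = np.clip(0.45 + 0.15 * _smooth_noise(rng, (h, w), sigma=8.0), 0.1, 0.9)
    val = np.clip(0.35 + 0.15 * _smooth_noise(rng, (h, w), sigma=4.0), 0.05, 0.9)
    hsv = np.stack([np.mod(hue, 360.0) / 360.0, sat, val], axis=-1)
    return skcolor.hsv2rgb(hsv)


def render_frame(scene: SceneParams, traj: ColorTrajectory, day: int,
                 rng_seed: int):
    """Render one (image, mask) frame; bit-deterministic in all arguments.

    The mask is exactly the ellipse support.  Fruit hue is the trajectory
    value at ``day`` plus seeded jitter, textured with low-frequency hue
    mottling, blemish stripes/spots, and multiplicative radial shading —
    all confined to the mask.  The background depends only on
    ``scene.background_seed``, never on ``day``.
    """
    h, w = scene.image_size
    mask = _ellipse_mask(scene)
    rgb = _background(scene).copy()

    rng = np.random.default_rng(rng_seed)
    day_hue = traj.hue(day) + rng.normal(0.0, traj.noise_sd)
    day_hue = float(np.clip(day_hue, traj.hue_end, traj.hue_start))

    hue = np.full((h, w), day_hue)
    hue += 4.0 * _smooth_noise(rng, (h, w), sigma=3.0)  # uneven coloration

    # blemishes: elongated stripes / round spots of shifted hue
    cx, cy = scene.fruit_center
    rx, ry = scene.fruit_radii
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(scene.n_blemishes):
        bx = cx + rng.uniform(-0.7, 0.7) * rx
        by = cy + rng.uniform(-0.7, 0.7) * ry
        r = rng.uniform(*scene.blemish_size)
        elong = rng.uniform(1.0, 4.0)  # >1 makes a stripe
        theta = rng.uniform(0, np.pi)
        dx = (xx - bx) * np.cos(theta) + (yy - by) * np.sin(theta)
        dy = -(xx - bx) * np.sin(theta) + (yy - by) * np.cos(theta)
        blob = (dx / (r * elong)) ** 2 + (dy / r) ** 2 <= 1.0
        hue = np.where(blob, hue + rng.uniform(-12.0, 12.0), hue)

    sat = np.clip(0.80 + 0.05 * _smooth_noise(rng, (h, w), sigma=4.0), 0.0, 1.0)
    rad2 = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2
    shading = 1.0 - 0.35 * np.clip(rad2, 0.0, 1.0)  # brighter at the center
    val = np.clip(0.72 * scene.lighting_gain * shading, 0.0, 1.0)

    hsv = np.stack([np.mod(hue, 360.0) / 360.0, sat, val], axis=-1)
    fruit = skcolor.hsv2rgb(hsv)
    m3 = mask[..., None].astype(float)
    rgb = m3 * fruit + (1.0 - m3) * rgb
    image = np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)
    return image, mask


@dataclass(frozen=True)
class DatasetConfig:
    """Priors for a generated dataset; defaults mirror the study's scale
    per unit: a ~45-day window, hue moving green to orange with per-fruit
    rate variation, frames occasionally missing."""

    image_size: tuple = DEFAULT_IMAGE_SIZE
    rate_mean: float = 1.5           # deg/day; ~45 days green->orange
    rate_sd: float = 0.25
    noise_sd: float = 2.0
    dropout: float = 0.05            # per-frame missing probability
    views: tuple = ("front",)


def generate_dataset(n_samples: int, days: int, views_per_sample: int,
                     out_dir, seed: int,
                     config: DatasetConfig = DatasetConfig()):
    """Write a labelled synthetic dataset and return its manifest path.

    ``days`` frames (day 0 .. days-1) per sample and view, minus seeded
    random drop-outs.  Each sample draws its own trajectory rate, fruit
    geometry, background and lighting gain from the configured priors.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    h, w = config.image_size
    views = ("front", "bottom", "side")[:views_per_sample]
    records = []
    for s in range(n_samples):
        traj = ColorTrajectory(
            rate=float(max(0.2, rng.normal(config.rate_mean, config.rate_sd))),
            noise_sd=config.noise_sd,
        )
        sid = f"s{s:03d}"
        for view in views:
            rmax_x = max(8, int(0.38 * w))
            rmax_y = max(8, int(0.38 * h))
            rx = int(rng.integers(max(8, int(0.2 * w)), rmax_x + 1))
            ry = int(rng.integers(max(8, int(0.2 * h)), rmax_y + 1))
            cx = int(rng.integers(rx, w - rx))
            cy = int(rng.integers(ry, h - ry))
            scene = SceneParams(
                fruit_center=(cx, cy), fruit_radii=(rx, ry),
                background_seed=int(rng.integers(0, 2 ** 31 - 1)),
                lighting_gain=float(rng.uniform(0.7, 1.3)),
                n_blemishes=int(rng.integers(1, 5)),
                image_size=config.image_size,
            )
            for day in range(days):
                frame_seed = int(rng.integers(0, 2 ** 31 - 1))
                dropped = rng.uniform() < config.dropout
                if dropped:
                    continue
                image, mask = render_frame(scene, traj, day, frame_seed)
                stem = f"{sid}_{view}_d{day:03d}"
                img_path = out_dir / f"{stem}.png"
                msk_path = out_dir / f"{stem}_mask.png"
                save_image(image, img_path)
                save_mask(mask, msk_path)
                records.append(SampleRecord(
                    sample_id=sid, day=day, view=view,
                    image_path=img_path.name, mask_path=msk_path.name,
                ))
    manifest = out_dir / "manifest.csv"
    write_manifest(records, manifest)
    return manifest
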