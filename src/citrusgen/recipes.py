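"""Reproducible desk-scale study protocols.

These functions run the full pipeline — synthesize an orchard dataset,
split it by sample, train a network, measure held-out performance — at
sizes a single CPU handles in minutes.  They are the package's reference
experiments: the segmentation study mirrors the field protocol (Dice
training, best-validation-MIoU checkpoint, test-set MIoU) on a
20-sample, 20-day, 64x64 dataset; the generation study trains the
time-conditioned generator on a 100-sample, 36-day, 32x32 dataset
(pair horizons 2..15 days, mirroring the study's multi-week color
transformation window) and measures how well the predicted fruit color
tracks the true forward trajectory:

* Pearson r between predicted and target mean fruit hue on held-out
  (unseen-sample) pairs — color-trajectory recovery;
* Spearman rho between the horizon N and the predicted CCI of a fixed
  input — monotone time conditioning (ripening fruit: CCI increases).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy import stats

from . import data as dm
from . import segmentation as seg
from .generator import GeneratorConfig, train_generator, predict
from .losses import StyleConfig, IdentityExtractor
from .metrics import mean_hue_degrees, cci, evaluate_pairs
from .synthetic import generate_dataset, DatasetConfig

__all__ = ["segmentation_study", "generation_study",
           "SEG_STUDY_CONFIG", "GEN_STUDY_CONFIG", "GEN_STYLE_CONFIG"]

SEG_STUDY_CONFIG = seg.SegConfig(
    input_size=(64, 64), encoder_depth=4, base_channels=8,
    learning_rate=1e-3, batch_size=8, epochs=12, norm="instance",
    augment_flips=True)

GEN_STUDY_CONFIG = GeneratorConfig(
    input_size=(32, 32), n_resblocks=2, batch_size=16, epochs=16,
    learning_rate=1e-3, n_max=45)

GEN_STYLE_CONFIG = StyleConfig(
    prefactor_convention="channels_only", style_weight=10.0,
    content_weight=1.0)

CCI_SWEEP = (2, 5, 8, 10)


def _items(records):
    return [(dm.load_image(r.image_path), dm.load_mask(r.mask_path))
            for r in records]


def segmentation_study(work_dir, seed: int = 11, n_samples: int = 20,
                       days: int = 20, cfg: seg.SegConfig = SEG_STUDY_CONFIG,
                       verbose: bool = False) -> dict:
    """Train the U-Net end to end and report held-out MIoU."""
    manifest = generate_dataset(
        n_samples, days, 1, Path(work_dir) / "seg_data", seed=seed,
        config=DatasetConfig(image_size=cfg.input_size))
    records = dm.load_manifest(manifest)
    assignment = dm.split_by_sample(records, (3, 1, 1), seed=seed)
    parts = {lab: [r for r in records if assignment[r.sample_id] == lab]
             for lab in ("train", "val", "test")}
    model, history = seg.train_segmentation(
        _items(parts["train"]), cfg, seed=seed + 1,
        val_items=_items(parts["val"]), verbose=verbose)
    test_items = _items(parts["test"])
    preds = [seg.predict_mask(model, im) for im, _ in test_items]
    test_miou = seg.miou(preds, [mk for _, mk in test_items])
    return {
        "model": model,
        "history": history,
        "miou_val_best": float(history["val_miou"].max()),
        "miou_test": float(test_miou),
        "n_frames": len(records),
        "n_train": len(parts["train"]),
        "epochs": cfg.epochs,
    }


def _sample_pairs(records, n_min, n_max, cap, rng):
    pairs = dm.build_pairs(records, n_min, n_max)
    if len(pairs) > cap:
        idx = rng.choice(len(pairs), size=cap, replace=False)
        pairs = [pairs[i] for i in sorted(idx)]
    return dm.realize_pairs(pairs)


def generation_study(work_dir, seed: int = 5, n_samples: int = 100,
                     days: int = 36, n_range=(2, 15),
                     caps=(420, 60, 80),
                     cfg: GeneratorConfig = GEN_STUDY_CONFIG,
                     style: StyleConfig = GEN_STYLE_CONFIG,
                     verbose: bool = False) -> dict:
    """Train the generator and measure held-out color-trajectory recovery."""
    manifest = generate_dataset(
        n_samples, days, 1, Path(work_dir) / "gen_data", seed=seed,
        config=DatasetConfig(image_size=cfg.input_size))
    records = dm.load_manifest(manifest)
    assignment = dm.split_by_sample(records, (3, 1, 1), seed=seed)
    parts = {lab: [r for r in records if assignment[r.sample_id] == lab]
             for lab in ("train", "val", "test")}
    rng = np.random.default_rng(seed)
    train_pairs = _sample_pairs(parts["train"], *n_range, caps[0], rng)
    val_pairs = _sample_pairs(parts["val"], *n_range, caps[1], rng)
    test_pairs = _sample_pairs(parts["test"], *n_range, caps[2], rng)

    extractor = IdentityExtractor(augment_constant=True)
    model, history = train_generator(
        train_pairs, style, cfg, extractor=extractor, seed=seed + 1,
        val_pairs=val_pairs, verbose=verbose)

    pred_hue, target_hue, input_hue = [], [], []
    for p in test_pairs:
        yhat = predict(model, p["x"], p["x_mask"], p["n"])
        pred_hue.append(mean_hue_degrees(yhat, p["x_mask"]))
        target_hue.append(mean_hue_degrees(p["y"], p["y_mask"]))
        input_hue.append(mean_hue_degrees(p["x"], p["x_mask"]))
    r = stats.pearsonr(pred_hue, target_hue).statistic

    # monotone conditioning: CCI of a fixed input swept over horizons
    rhos = []
    for p in test_pairs[:5]:
        ccis = [cci(predict(model, p["x"], p["x_mask"], n), p["x_mask"])
                for n in CCI_SWEEP]
        rhos.append(stats.spearmanr(CCI_SWEEP, ccis).statistic)

    report = evaluate_pairs(
        lambda im, mk, n: predict(model, im, mk, n), test_pairs,
        extractor=extractor, cfg=style)
    return {
        "model": model,
        "history": history,
        "hue_pearson_r": float(r),
        "hue_pearson_r_input_baseline": float(
            stats.pearsonr(input_hue, target_hue).statistic),
        "cci_spearman_rho": float(rhos[0]),
        "cci_spearman_rhos": [float(v) for v in rhos],
        "mean_abs_hue_error": float(np.mean(np.abs(
            np.array(pred_hue) - np.array(target_hue)))),
        "test_report": report,
        "n_train_pairs": len(train_pairs),
        "n_test_pairs": len(test_pairs),
        "test_pairs": test_pairs,
        "epochs": cfg.epochs,
    }
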