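"""Dataset manifest, image/mask I/O, temporal pairing and sample-wise splits.

A dataset is a flat directory of RGB frames plus binary fruit masks,
indexed by a manifest with one row per acquisition:
``sample_id, day, view, image_path, mask_path``.  ``day`` is a relative
integer index into each fruit's series; calendar dates are resolved to day
indices before the manifest is written.  Training examples are (input
frame at day d, horizon N, target frame at day d+N) triples drawn from a
single fruit's series, and all train/validation/test partitioning is done
at the level of whole fruits so no fruit leaks across sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "SampleRecord", "PairedExample", "VIEWS",
    "load_manifest", "write_manifest", "load_image", "save_image",
    "load_mask", "save_mask", "build_pairs", "split_by_sample",
    "kfold_by_sample", "save_split", "load_split",
]

VIEWS = ("front", "bottom", "side")
MANIFEST_COLUMNS = ["sample_id", "day", "view", "image_path", "mask_path"]


@dataclass(frozen=True)
class SampleRecord:
    """One acquisition: a frame of one fruit on one day from one view."""

    sample_id: str
    day: int
    view: str
    image_path: str
    mask_path: str

    def __post_init__(self):
        if self.day < 0:
            raise ValueError(f"day must be >= 0, got {self.day}")
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}, got {self.view!r}")

    @property
    def key(self):
        return (self.sample_id, self.day, self.view)


@dataclass(frozen=True)
class PairedExample:
    """(input frame, horizon in days, target frame) within one fruit."""

    input: SampleRecord
    interval_days: int
    target: SampleRecord

    def __post_init__(self):
        if self.input.sample_id != self.target.sample_id:
            raise ValueError("paired frames must come from the same sample")
        if self.target.day - self.input.day != self.interval_days:
            raise ValueError("interval_days must equal the day difference")
        if self.interval_days < 1:
            raise ValueError("interval_days must be >= 1")


# ---------------------------------------------------------------------------
# manifest I/O

def load_manifest(path) -> list:
    """Read a CSV or JSON manifest into validated SampleRecords.

    Duplicate (sample_id, day, view) keys and dangling image/mask paths are
    rejected.  Relative paths are resolved against the manifest's directory.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    text = path.read_text()
    if not text.strip():
        return []
    if path.suffix.lower() == ".json":
        rows = json.loads(text)
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns: {missing}")

    base = path.parent
    records = []
    seen = set()
    for row in df.itertuples(index=False):
        rec = SampleRecord(
            sample_id=str(row.sample_id),
            day=int(row.day),
            view=str(row.view),
            image_path=str(row.image_path),
            mask_path=str(row.mask_path),
        )
        if rec.key in seen:
            raise ValueError(f"duplicate manifest key {rec.key} in {path}")
        seen.add(rec.key)
        for attr in ("image_path", "mask_path"):
            p = Path(getattr(rec, attr))
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                raise FileNotFoundError(f"{attr} {p} referenced by {path} is missing")
            rec = replace(rec, **{attr: str(p)})
        records.append(rec)
    return records


def write_manifest(records: Iterable[SampleRecord], path) -> Path:
    path = Path(path)
    df = pd.DataFrame([
        {
            "sample_id": r.sample_id, "day": r.day, "view": r.view,
            "image_path": r.image_path, "mask_path": r.mask_path,
        }
        for r in records
    ], columns=MANIFEST_COLUMNS)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=1))
    else:
        df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# image / mask I/O

def load_image(path) -> np.ndarray:
    """RGB frame as uint8 H x W x 3."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


def save_image(image: np.ndarray, path) -> None:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected HxWx3 image, got shape {image.shape}")
    Image.fromarray(np.clip(np.round(image), 0, 255).astype(np.uint8)).save(path)


def load_mask(path, threshold: int = 127) -> np.ndarray:
    """Binary fruit mask (uint8 {0,1}); 8-bit PNG binarized at >threshold."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return (arr > threshold).astype(np.uint8)


def save_mask(mask: np.ndarray, path) -> None:
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be strictly binary")
    Image.fromarray((mask * 255).astype(np.uint8)).save(path)


# ---------------------------------------------------------------------------
# pairing

def build_pairs(records: Sequence[SampleRecord], n_min: int, n_max: int,
                same_view: bool = False) -> list:
    """All (input, N, target) pairs with day gap in [n_min, n_max].

    Pairs never cross samples.  With ``same_view`` the input and target
    views must match; by default any view pair within a sample is allowed
    (the style objective needs no pixel correspondence).
    """
    if n_min < 1:
        raise ValueError(f"n_min must be >= 1, got {n_min}")
    if n_max < n_min:
        raise ValueError("n_max must be >= n_min")
    by_sample: dict = {}
    for rec in records:
        by_sample.setdefault(rec.sample_id, []).append(rec)
    pairs = []
    for sid in sorted(by_sample):
        recs = sorted(by_sample[sid], key=lambda r: (r.day, r.view))
        for a in recs:
            for b in recs:
                gap = b.day - a.day
                if n_min <= gap <= n_max and (not same_view or a.view == b.view):
                    pairs.append(PairedExample(input=a, interval_days=gap, target=b))
    return pairs


def realize_pairs(pairs: Sequence[PairedExample]) -> list:
    """Load pair records into training dicts {x, x_mask, n, y, y_mask}."""
    out = []
    for p in pairs:
        out.append({
            "x": load_image(p.input.image_path),
            "x_mask": load_mask(p.input.mask_path),
            "n": p.interval_days,
            "y": load_image(p.target.image_path),
            "y_mask": load_mask(p.target.mask_path),
        })
    return out


# ---------------------------------------------------------------------------
# sample-wise splitting

def _largest_remainder(n: int, ratios: Sequence[float]) -> list:
    """Apportion n into len(ratios) integer parts proportional to ratios."""
    total = float(sum(ratios))
    quotas = [n * r / total for r in ratios]
    floors = [int(np.floor(q)) for q in quotas]
    leftover = n - sum(floors)
    order = sorted(range(len(ratios)), key=lambda i: quotas[i] - floors[i],
                   reverse=True)
    for i in order[:leftover]:
        floors[i] += 1
    return floors


def split_by_sample(records: Sequence[SampleRecord],
                    ratios: Sequence[float] = (3, 1, 1),
                    seed: int = 0) -> dict:
    """Assign whole samples to train/val/test in the given ratios.

    Returns {sample_id: "train"|"val"|"test"}.  Deterministic in
    (records, ratios, seed); largest-remainder rounding keeps counts as
    close to the ratios as integers allow.
    """
    labels = ("train", "val", "test")[:len(ratios)]
    sids = sorted({r.sample_id for r in records})
    if len(sids) < len(ratios):
        raise ValueError(
            f"need at least {len(ratios)} samples to split, got {len(sids)}"
        )
    rng = np.random.default_rng(seed)
    order = [sids[i] for i in rng.permutation(len(sids))]
    sizes = _largest_remainder(len(sids), ratios)
    assignment = {}
    start = 0
    for label, size in zip(labels, sizes):
        for sid in order[start:start + size]:
            assignment[sid] = label
        start += size
    return assignment


def kfold_by_sample(records: Sequence[SampleRecord], k: int = 5,
                    seed: int = 0) -> list:
    """k sample-disjoint folds; element i is {sample_id: "train"|"test"}.

    Every sample lands in the test partition of exactly one fold; fold
    sizes differ by at most one.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    sids = sorted({r.sample_id for r in records})
    if k > len(sids):
        raise ValueError(f"k={k} exceeds number of samples ({len(sids)})")
    rng = np.random.default_rng(seed)
    order = [sids[i] for i in rng.permutation(len(sids))]
    folds = [list(order[i::k]) for i in range(k)]
    assignments = []
    for test_fold in folds:
        test = set(test_fold)
        assignments.append({sid: ("test" if sid in test else "train")
                            for sid in sids})
    return assignments


def save_split(assignment: dict, path) -> None:
    Path(path).write_text(json.dumps(assignment, indent=1, sort_keys=True))


def load_split(path) -> dict:
    return json.loads(Path(path).read_text())
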