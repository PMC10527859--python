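"""ISIC-2018-Task-2-style dataset handling.

A dataset directory holds RGB lesion photographs (JPEG/PNG) and, for every
image and every attribute, one binary mask PNG named
``<image-id>_attribute_<attribute>.png`` (0/255 on disk, {0,1} in memory).
This module scans that layout into a manifest, summarises per-attribute
prevalence, resizes image/mask pairs to the training resolution, splits the
data deterministically, and balances the extreme image-level imbalance by
down-sampling the blank-mask majority class to the positive count — the
per-attribute preparation each of the five attribute models trains on.
Balancing precedes splitting and is done per attribute, since the five
models are independent.

Coordinates are row-major with the origin at the top-left; masks are
per-pixel labels with no sub-pixel geometry.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "ATTRIBUTES",
    "DatasetManifest",
    "SplitSpec",
    "scan_isic_layout",
    "summarize_prevalence",
    "load_image",
    "load_mask",
    "write_mask",
    "resize_pair",
    "split_dataset",
    "balance_downsample",
]

#: The five dermoscopic attributes of ISIC 2018 Task 2, with the exact
#: string encodings used in the mask-file suffixes.
ATTRIBUTES: tuple[str, ...] = (
    "pigment_network",
    "negative_network",
    "milia_like_cyst",
    "globules",
    "streaks",
)

_IMAGE_EXTENSIONS = (".jpg", ".jpeg", ".png")


@dataclass(frozen=True)
class SplitSpec:
    """Deterministic train/val/test partition sizes.

    ``train_fraction`` of the data is train+validation and the rest test;
    ``val_fraction`` of the train+validation part is then held out for
    early stopping.
    """

    train_fraction: float = 0.8
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")
        if not (0.0 <= self.val_fraction < 1.0):
            raise ValueError("val_fraction must lie in [0, 1)")


class DatasetManifest:
    """Table of (image id, image path, per-attribute mask path and positive count)."""

    def __init__(self, df: pd.DataFrame):
        required = {"image_id", "image_path"}
        for attr in ATTRIBUTES:
            required |= {f"mask_{attr}", f"pos_{attr}"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        if df["image_id"].duplicated().any():
            raise ValueError("duplicate image ids in manifest")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, DatasetManifest) and self.df.equals(other.df)

    @property
    def image_ids(self) -> list[str]:
        return list(self.df["image_id"])

    def positives(self, attribute: str) -> pd.DataFrame:
        _check_attribute(attribute)
        return self.df[self.df[f"pos_{attribute}"] > 0]

    def attribute_counts(self) -> dict[str, int]:
        """Number of images positive (>= 1 foreground pixel) per attribute."""
        return {a: int((self.df[f"pos_{a}"] > 0).sum()) for a in ATTRIBUTES}

    def subset(self, image_ids: Sequence[str]) -> "DatasetManifest":
        wanted = set(image_ids)
        return DatasetManifest(self.df[self.df["image_id"].isin(wanted)].copy())

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DatasetManifest":
        return cls(pd.read_csv(path, dtype={"image_id": str}))


def _check_attribute(attribute: str) -> None:
    if attribute not in ATTRIBUTES:
        raise ValueError(f"unknown attribute {attribute!r}; expected one of {ATTRIBUTES}")


def scan_isic_layout(directory) -> DatasetManifest:
    """Scan a dataset directory into a manifest.

    Every file with an image extension whose name does not contain
    ``_attribute_`` is an image; for each, all five attribute masks must
    exist.  An image is positive for an attribute iff its mask has at least
    one foreground pixel.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"not a directory: {directory}")
    image_files = sorted(
        f
        for f in directory.iterdir()
        if f.suffix.lower() in _IMAGE_EXTENSIONS and "_attribute_" not in f.name
    )
    if not image_files:
        raise FileNotFoundError(f"no images found in {directory}")
    rows = []
    for img in image_files:
        image_id = img.stem
        row: dict = {"image_id": image_id, "image_path": str(img)}
        missing = []
        for attr in ATTRIBUTES:
            mask_path = directory / f"{image_id}_attribute_{attr}.png"
            if not mask_path.exists():
                missing.append(str(mask_path))
                continue
            mask = load_mask(mask_path)
            row[f"mask_{attr}"] = str(mask_path)
            row[f"pos_{attr}"] = int(mask.sum())
        if missing:
            raise FileNotFoundError(
                f"image {image_id} is missing attribute masks: {missing}"
            )
        rows.append(row)
    return DatasetManifest(pd.DataFrame(rows))


def summarize_prevalence(manifest: DatasetManifest) -> pd.DataFrame:
    """Per-attribute positive-image counts and percentages (one decimal)."""
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    total = len(manifest)
    counts = manifest.attribute_counts()
    return pd.DataFrame(
        {
            "attribute": list(ATTRIBUTES),
            "count": [counts[a] for a in ATTRIBUTES],
            "percent": [round(100.0 * counts[a] / total, 1) for a in ATTRIBUTES],
        }
    )


# ---------------------------------------------------------------------------
# Pixel IO


def load_image(path) -> np.ndarray:
    """RGB image as float32 HWC in [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.float32) / 255.0
    return arr


def load_mask(path) -> np.ndarray:
    """Binary mask as uint8 {0, 1} (disk convention: 0/255 grayscale PNG)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return (arr > 127).astype(np.uint8)


def write_mask(path, mask: np.ndarray) -> None:
    mask = np.asarray(mask)
    if not np.all((mask == 0) | (mask == 1)):
        raise ValueError("mask must be binary {0, 1}")
    Image.fromarray((mask * 255).astype(np.uint8), mode="L").save(path)


def resize_pair(image: np.ndarray, mask: np.ndarray, side: int) -> tuple[np.ndarray, np.ndarray]:
    """Resize an image/mask pair to ``side x side``.

    The image is interpolated bilinearly; the mask with nearest-neighbour so
    it stays binary.  A pair already at the target size is returned
    unchanged (bit-identical mask).
    """
    if side % 32 != 0:
        raise ValueError("target side must be divisible by 32")
    if image.shape[:2] != mask.shape[:2]:
        raise ValueError("image and mask spatial shapes differ")
    if image.shape[:2] == (side, side):
        return image, mask
    img_u8 = np.clip(image * 255.0, 0, 255).astype(np.uint8)
    img = Image.fromarray(img_u8).resize((side, side), Image.BILINEAR)
    msk = Image.fromarray(mask.astype(np.uint8), mode="L").resize((side, side), Image.NEAREST)
    out_mask = np.asarray(msk)
    if not np.all((out_mask == 0) | (out_mask == 1)):
        raise AssertionError("mask became non-binary after nearest-neighbour resize")
    return np.asarray(img, dtype=np.float32) / 255.0, out_mask.astype(np.uint8)


# ---------------------------------------------------------------------------
# Splitting and balancing


def _strata(manifest: DatasetManifest) -> pd.Series:
    # one stratum per attribute-positivity pattern
    bits = [(manifest.df[f"pos_{a}"] > 0).astype(int).astype(str) for a in ATTRIBUTES]
    out = bits[0]
    for b in bits[1:]:
        out = out + b
    return out


def _stratified_take(df: pd.DataFrame, strata: pd.Series, n_take: int, rng) -> pd.Index:
    """Pick ``n_take`` rows, spreading the quota across strata (largest remainder)."""
    groups = df.groupby(strata, sort=True).groups
    keys = sorted(groups)
    quotas = {k: n_take * len(groups[k]) / len(df) for k in keys}
    base = {k: int(np.floor(quotas[k])) for k in keys}
    short = n_take - sum(base.values())
    by_remainder = sorted(keys, key=lambda k: (-(quotas[k] - base[k]), k))
    for k in by_remainder[:short]:
        base[k] += 1
    picked = []
    for k in keys:
        idx = np.array(sorted(groups[k]))
        take = min(base[k], len(idx))
        picked.extend(idx[rng.permutation(len(idx))[:take]])
    # strata smaller than their (rounded-up) quota can leave a shortfall
    shortfall = n_take - len(picked)
    if shortfall > 0:
        rest = df.index.difference(picked)
        order = rng.permutation(len(rest))
        picked.extend(np.array(sorted(rest))[order[:shortfall]])
    return pd.Index(sorted(picked))


def split_dataset(
    manifest: DatasetManifest, spec: SplitSpec = SplitSpec()
) -> tuple[DatasetManifest, DatasetManifest, DatasetManifest]:
    """Deterministic stratified train/val/test split.

    ``floor(train_fraction * N)`` records form train+validation; validation
    is then carved from them with ``val_fraction``.  Stratification follows
    the attribute-positivity pattern of each image.
    """
    n = len(manifest)
    if n < 5:
        raise ValueError("need at least 5 records to split")
    df = manifest.df
    strata = _strata(manifest)
    rng = np.random.default_rng(spec.seed)
    n_trainval = int(np.floor(spec.train_fraction * n))
    n_test = n - n_trainval
    if n_trainval == 0 or n_test == 0:
        raise ValueError("split fractions produce an empty partition")
    test_idx = _stratified_take(df, strata, n_test, rng)
    trainval = df.drop(index=test_idx)
    n_val = int(np.floor(spec.val_fraction * len(trainval)))
    val_idx = (
        _stratified_take(trainval, strata.loc[trainval.index], n_val, rng)
        if n_val
        else pd.Index([])
    )
    train = trainval.drop(index=val_idx)
    return (
        DatasetManifest(train.copy()),
        DatasetManifest(trainval.loc[val_idx].copy()),
        DatasetManifest(df.loc[test_idx].copy()),
    )


def balance_downsample(
    manifest: DatasetManifest, attribute: str, seed: int = 0
) -> DatasetManifest:
    """Majority-class down-sampling for one attribute.

    Keeps every image with a non-empty mask for ``attribute`` and a seeded
    random subsample of the blank-mask images of equal count (all of them if
    they are fewer).  Never drops a positive and never duplicates an image.
    """
    _check_attribute(attribute)
    df = manifest.df
    pos = df[df[f"pos_{attribute}"] > 0]
    neg = df[df[f"pos_{attribute}"] == 0]
    if len(pos) == 0:
        raise ValueError(f"no positive images for attribute {attribute!r}")
    rng = np.random.default_rng(seed)
    k = min(len(neg), len(pos))
    neg_keep = neg.iloc[np.sort(rng.permutation(len(neg))[:k])]
    out = pd.concat([pos, neg_keep]).sort_index()
    return DatasetManifest(out.copy())
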