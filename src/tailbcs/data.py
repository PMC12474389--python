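"""Manifest reading, tail cropping, dataset splitting and preprocessing.

Coordinates are 0-based, half-open ``[x0, x1) x [y0, y1)``, so a bbox's width
is ``x1 - x0`` and its height ``y1 - y0``.  The 7:2:1 split takes
``floor(0.7 n)`` items for training, ``floor(0.2 n)`` for validation and the
remainder for testing, after a seeded shuffle.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .bcs import BCS_VALUES, value_to_index
from .synthetic import MANIFEST_COLUMNS

__all__ = [
    "ImageRecord",
    "SplitIndices",
    "IMAGENET_MEAN",
    "IMAGENET_SD",
    "read_manifest",
    "crop_tail",
    "split_dataset",
    "preprocess",
    "load_arrays",
    "write_split_manifests",
]

# Channel statistics of the pretrained-reference input pipeline.
IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], np.float32)
IMAGENET_SD = np.array([0.229, 0.224, 0.225], np.float32)


@dataclass
class ImageRecord:
    path: Path
    bbox: tuple[int, int, int, int]
    label: float

    @property
    def label_index(self) -> int:
        return value_to_index(self.label)

    def load_pixels(self) -> np.ndarray:
        return np.asarray(Image.open(self.path).convert("RGB"))


@dataclass
class SplitIndices:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray

    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train), len(self.val), len(self.test))


def read_manifest(path: str | os.PathLike, validate_bounds: bool = True) -> list[ImageRecord]:
    """Read a ``path,x0,y0,x1,y1,bcs`` manifest into validated records.

    Every row is checked eagerly: the label must be on the five-value scale,
    the bbox non-empty and (when ``validate_bounds``) inside the image, and
    paths must be unique.  Validation errors name the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns {sorted(missing)}")
    root = path.parent
    records: list[ImageRecord] = []
    seen: set[str] = set()
    for row_no, row in enumerate(df.itertuples(index=False)):
        where = f"manifest row {row_no}"
        if row.path in seen:
            raise ValueError(f"{where}: duplicate path {row.path!r}")
        seen.add(row.path)
        try:
            label_index = value_to_index(row.bcs)
        except ValueError as exc:
            raise ValueError(f"{where}: {exc}") from exc
        bbox = (int(row.x0), int(row.y0), int(row.x1), int(row.y1))
        if not (bbox[0] < bbox[2] and bbox[1] < bbox[3]):
            raise ValueError(f"{where}: empty or inverted bbox {bbox}")
        if min(bbox) < 0:
            raise ValueError(f"{where}: negative bbox coordinate {bbox}")
        img_path = root / row.path
        if validate_bounds:
            if not img_path.exists():
                raise ValueError(f"{where}: image {img_path} does not exist")
            with Image.open(img_path) as im:
                w, h = im.size
            if bbox[2] > w or bbox[3] > h:
                raise ValueError(
                    f"{where}: bbox {bbox} exceeds image bounds {w}x{h}"
                )
        records.append(ImageRecord(path=img_path, bbox=bbox,
                                   label=BCS_VALUES[label_index]))
    return records


def crop_tail(pixels: np.ndarray, bbox: tuple[int, int, int, int]) -> np.ndarray:
    """Extract the half-open sub-rectangle ``[y0:y1, x0:x1]``."""
    x0, y0, x1, y1 = (int(v) for v in bbox)
    h, w = pixels.shape[:2]
    if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
        raise ValueError(f"bbox {bbox} out of bounds for {w}x{h} image")
    return pixels[y0:y1, x0:x1]


def split_dataset(n: int, ratios: tuple[float, float, float] = (0.7, 0.2, 0.1),
                  seed: int = 0) -> SplitIndices:
    """Seeded shuffle of 0..n-1 followed by the floor-remainder 7:2:1 cut."""
    if n < 3:
        raise ValueError("need at least 3 items to split")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(np.floor(ratios[0] * n))
    n_val = int(np.floor(ratios[1] * n))
    return SplitIndices(
        train=order[:n_train],
        val=order[n_train : n_train + n_val],
        test=order[n_train + n_val :],
    )


def preprocess(pixels: np.ndarray, input_size: int = 224) -> np.ndarray:
    """Resize to ``input_size`` square, scale to [0, 1], channel-normalize.

    Returns a C×H×W float32 array normalized with the fixed channel mean/sd
    of the reference input pipeline.
    """
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError("expected an H×W×3 RGB image")
    if pixels.shape[0] == 0 or pixels.shape[1] == 0:
        raise ValueError("empty image")
    if pixels.dtype != np.uint8:
        pixels = np.clip(pixels, 0, 255).astype(np.uint8)
    im = Image.fromarray(pixels).resize((input_size, input_size),
                                        Image.Resampling.BILINEAR)
    arr = np.asarray(im, np.float32) / 255.0
    arr = (arr - IMAGENET_MEAN) / IMAGENET_SD
    return np.ascontiguousarray(arr.transpose(2, 0, 1))


def load_arrays(records: list[ImageRecord], input_size: int = 224,
                images: np.ndarray | None = None,
                bboxes: np.ndarray | None = None,
                labels: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Crop + preprocess a dataset into ``(X, y)`` network inputs.

    Either pass manifest ``records`` (images read from disk) or raw
    ``images``/``bboxes``/``labels`` arrays from the synthetic generator.
    ``y`` holds class indices.
    """
    if images is not None:
        n = len(images)
        xs = np.empty((n, 3, input_size, input_size), np.float32)
        for i in range(n):
            xs[i] = preprocess(crop_tail(images[i], bboxes[i]), input_size)
        y = np.array([value_to_index(v) for v in labels])
        return xs, y
    n = len(records)
    xs = np.empty((n, 3, input_size, input_size), np.float32)
    y = np.empty(n, int)
    for i, rec in enumerate(records):
        xs[i] = preprocess(crop_tail(rec.load_pixels(), rec.bbox), input_size)
        y[i] = rec.label_index
    return xs, y


def write_split_manifests(manifest_path: str | os.PathLike, seed: int = 0,
                          out_dir: str | os.PathLike | None = None) -> dict[str, Path]:
    """Split a manifest 7:2:1 and write train/val/test manifest files."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    split = split_dataset(len(df), seed=seed)
    out_dir = Path(out_dir) if out_dir else manifest_path.parent
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, idx in (("train", split.train), ("val", split.val), ("test", split.test)):
        p = out_dir / f"manifest_{name}.csv"
        df.iloc[np.sort(idx)].to_csv(p, index=False)
        paths[name] = p
    return paths
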