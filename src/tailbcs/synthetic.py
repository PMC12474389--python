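"""Class-conditional synthetic tail images.

The generator encodes the one morphological feature that separates the five
condition classes — the depth of the depression flanking the tail root, deep
in lean cows and flat in well-conditioned ones — plus the nuisance factors a
rear-view farm photograph carries (pixel noise, brightness variation, mild
pose jitter).  Each image is a hide-toned background with a vertical tail
shape and two flanking depression patches whose darkening scales with the
class's depression depth.

Geometry, noise and lighting are all drawn from a generator seeded by
``(spec.seed, class_index, item_seed)``, so corpus generation is a pure
function of the spec.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .bcs import BCS_VALUES, NUM_CLASSES, index_to_value

__all__ = [
    "SyntheticSpec",
    "MANIFEST_COLUMNS",
    "tail_geometry",
    "generate_tail_image",
    "generate_arrays",
    "generate_dataset",
]

MANIFEST_COLUMNS = ("path", "x0", "y0", "x1", "y1", "bcs")

# Maximum darkening (8-bit intensity units) of the depression centre at
# depth 1.0; adjacent classes at the default depth ladder differ by 0.2 of it.
_DEPRESSION_STRENGTH = 110.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the synthetic corpus.

    ``depression_depths`` must be strictly monotone across class index; the
    default ladder decreases with BCS (fatter cow, flatter tail root).
    ``noise_sd`` is the additive Gaussian pixel noise; ``lighting_jitter`` the
    half-range of the multiplicative brightness factor (0 disables it).
    """

    image_size: int = 256
    n_per_class: int = 100
    seed: int = 0
    depression_depths: tuple[float, ...] = (0.9, 0.7, 0.5, 0.3, 0.1)
    noise_sd: float = 8.0
    lighting_jitter: float = 0.08

    def __post_init__(self):
        if self.image_size < 32:
            raise ValueError("image_size must be at least 32 pixels")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be at least 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0 <= self.lighting_jitter < 1:
            raise ValueError("lighting_jitter must lie in [0, 1)")
        d = np.asarray(self.depression_depths, float)
        if d.size != NUM_CLASSES:
            raise ValueError(f"need {NUM_CLASSES} depression depths")
        if (d < 0).any() or (d > 1).any():
            raise ValueError("depression depths must lie in [0, 1]")
        diffs = np.diff(d)
        if not ((diffs > 0).all() or (diffs < 0).all()):
            raise ValueError("depression depths must be strictly monotone")


def _item_rng(spec: SyntheticSpec, class_index: int, item_seed: int):
    return np.random.default_rng(
        np.random.SeedSequence([spec.seed, class_index, item_seed])
    )


def tail_geometry(class_index: int, spec: SyntheticSpec, item_seed: int) -> dict:
    """Deterministic per-item geometry: tail capsule and depression masks.

    Returns float masks in [0, 1] of shape (S, S) plus the tight bounding box
    of the tail structure (half-open pixel coordinates).
    """
    if not 0 <= class_index < NUM_CLASSES:
        raise ValueError(f"class_index must lie in 0..{NUM_CLASSES - 1}")
    rng = _item_rng(spec, class_index, item_seed)
    s = spec.image_size
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)

    cx = s * (0.5 + rng.uniform(-0.05, 0.05))
    top = s * (0.20 + rng.uniform(-0.03, 0.03))
    length = s * (0.55 + rng.uniform(-0.05, 0.05))
    half_w = s * (0.045 + rng.uniform(-0.008, 0.008))

    # vertical capsule (rounded rectangle) for the tail
    dy = np.clip(np.maximum(top - yy, yy - (top + length)), 0, None)
    dist2 = (xx - cx) ** 2 + dy**2
    tail = np.clip(1.5 * (half_w - np.sqrt(dist2)) / half_w + 0.5, 0.0, 1.0)

    # two depression patches flanking the tail root
    dep_cy = top + s * 0.13
    dep_dx = half_w + s * 0.055
    a, b = s * 0.05, s * 0.105  # elliptical semi-axes
    depression = np.zeros((s, s))
    for sign in (-1.0, 1.0):
        dcx = cx + sign * dep_dx
        r2 = ((xx - dcx) / a) ** 2 + ((yy - dep_cy) / b) ** 2
        depression += np.exp(-1.2 * r2) * (r2 < 4.0)
    depression = np.clip(depression, 0.0, 1.0)

    struct = (tail > 0.05) | (depression > 0.05)
    ys, xs = np.nonzero(struct)
    bbox = (int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)
    return {
        "tail": tail,
        "depression": depression,
        "bbox": bbox,
        "rng": rng,
        "depression_center_mask": depression > 0.3,
    }


def generate_tail_image(
    class_index: int, spec: SyntheticSpec, item_seed: int
) -> tuple[np.ndarray, tuple[int, int, int, int], float]:
    """Render one synthetic tail image.

    Returns ``(pixels, bbox, label)`` with uint8 H×W×3 pixels, the tight
    half-open bounding box of the tail structure, and the BCS value of the
    class.
    """
    geom = tail_geometry(class_index, spec, item_seed)
    rng = geom["rng"]
    s = spec.image_size
    yy = np.mgrid[0:s, 0:s][0].astype(np.float64)

    base = np.array([168.0, 150.0, 136.0]) + rng.uniform(-8, 8, 3)  # hide tone
    img = np.broadcast_to(base, (s, s, 3)).copy()
    img += ((yy - s / 2) / s * rng.uniform(-18, 18))[:, :, None]  # soft gradient

    img -= (geom["tail"] * 32.0)[:, :, None]  # tail slightly darker than hide
    depth = float(spec.depression_depths[class_index])
    img -= (geom["depression"] * depth * _DEPRESSION_STRENGTH)[:, :, None]

    if spec.lighting_jitter > 0:
        img *= 1.0 + rng.uniform(-spec.lighting_jitter, spec.lighting_jitter)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, (s, s, 3))

    pixels = np.clip(img, 0, 255).astype(np.uint8)
    return pixels, geom["bbox"], index_to_value(class_index)


def generate_arrays(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate the full corpus in memory.

    Returns ``(images, bboxes, labels)`` with images ``(N, S, S, 3)`` uint8,
    bboxes ``(N, 4)`` and labels the BCS values, class-blocked in order.
    """
    n = spec.n_per_class * NUM_CLASSES
    images = np.empty((n, spec.image_size, spec.image_size, 3), np.uint8)
    bboxes = np.empty((n, 4), int)
    labels = np.empty(n, float)
    i = 0
    for class_index in range(NUM_CLASSES):
        for item in range(spec.n_per_class):
            img, bbox, label = generate_tail_image(class_index, spec, item)
            images[i], bboxes[i], labels[i] = img, bbox, label
            i += 1
    return images, bboxes, labels


def generate_dataset(spec: SyntheticSpec, out_dir: str | os.PathLike) -> pd.DataFrame:
    """Write the corpus to ``out_dir`` as PNGs plus a ``manifest.csv``.

    The manifest has columns ``path,x0,y0,x1,y1,bcs`` with paths relative to
    ``out_dir``; class counts are exactly balanced.
    """
    out = Path(out_dir)
    try:
        (out / "images").mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    rows = []
    for class_index in range(NUM_CLASSES):
        label = index_to_value(class_index)
        for item in range(spec.n_per_class):
            img, bbox, _ = generate_tail_image(class_index, spec, item)
            rel = f"images/bcs{label:.2f}_{item:05d}.png"
            Image.fromarray(img).save(out / rel)
            rows.append({"path": rel, "x0": bbox[0], "y0": bbox[1],
                         "x1": bbox[2], "y1": bbox[3], "bcs": label})
    manifest = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
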