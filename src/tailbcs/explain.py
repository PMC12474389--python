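"""Grad-CAM class-activation heatmaps and colormap overlays.

The heatmap for a target class is the ReLU of the channel-weighted sum of a
convolutional feature map, where each channel's weight is the spatial mean of
the target logit's gradient with respect to that channel.  The raw map is
bilinearly upsampled to the input size and min-max normalized to [0, 1]
(identically zero maps stay zero).
"""

from __future__ import annotations

import numpy as np
from PIL import Image

from .zoo.base import ImageClassifier

__all__ = ["grad_cam", "overlay"]


def _upsample(raw: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    im = Image.fromarray(raw.astype(np.float32), mode="F")
    return np.asarray(im.resize((size[1], size[0]), Image.Resampling.BILINEAR))


def grad_cam(model: ImageClassifier, x: np.ndarray,
             target_class: int | None = None,
             layer: int | None = None) -> np.ndarray:
    """Compute a Grad-CAM heatmap for one input.

    ``x`` is a single preprocessed input ``(3, H, W)`` or ``(1, 3, H, W)``.
    By default the target layer is the last convolutional feature map before
    pooling (the head input, after any attention blocks); passing an integer
    ``layer`` targets the output of that index of ``model.features`` instead.
    ``target_class`` defaults to the predicted class.  Returns an ``(H, W)``
    map in [0, 1].
    """
    x = np.asarray(x, np.float32)
    if x.ndim == 3:
        x = x[None]
    if x.shape[0] != 1:
        raise ValueError("grad_cam explains a single input")
    model.eval()

    if layer is None:
        fmap = model.forward_features(x)
        logits = model.head(fmap)
    else:
        if not -len(model.features) <= layer < len(model.features):
            raise ValueError(
                f"layer index {layer} outside features range 0..{len(model.features) - 1}"
            )
        layer = layer % len(model.features)
        fmap = model.features.forward_upto(x, layer)
        out = model.features.forward_from(fmap, layer)
        if model.se is not None:
            out = model.se(out)
        if model.spatial is not None:
            out = model.spatial(out)
        logits = model.head(out)
    if fmap.ndim != 4:
        raise ValueError("the selected layer does not produce a feature map")

    if target_class is None:
        target_class = int(logits[0].argmax())
    seed = np.zeros_like(logits)
    seed[0, target_class] = 1.0
    model.zero_grad()
    if layer is None:
        grad = model.head.backward(seed)
    else:
        g = model.head.backward(seed)
        if model.spatial is not None:
            g = model.spatial.backward(g)
        if model.se is not None:
            g = model.se.backward(g)
        grad = model.features.backward_to(g, layer)
    model.zero_grad()

    weights = grad[0].mean(axis=(1, 2))  # per-channel spatial mean of gradient
    raw = np.maximum((weights[:, None, None] * fmap[0]).sum(axis=0), 0.0)
    up = _upsample(raw, (x.shape[2], x.shape[3]))
    lo, hi = float(up.min()), float(up.max())
    if hi - lo <= 0:
        return np.zeros_like(up)
    return np.clip((up - lo) / (hi - lo), 0.0, 1.0)


def overlay(heatmap: np.ndarray, image: np.ndarray, alpha: float = 0.5) -> np.ndarray:
    """Blend a blue-to-red colormapped heatmap over an RGB image.

    ``alpha=0`` returns the image, ``alpha=1`` the pure colormap.  High
    attention renders red, low attention blue ("jet" colormap).
    """
    import matplotlib

    heatmap = np.asarray(heatmap, np.float64)
    image = np.asarray(image, np.float64)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be H×W×3")
    if heatmap.shape != image.shape[:2]:
        raise ValueError(
            f"heatmap {heatmap.shape} does not match image {image.shape[:2]}"
        )
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    cmap = matplotlib.colormaps["jet"]
    colored = cmap(np.clip(heatmap, 0, 1))[:, :, :3] * 255.0
    blended = (1.0 - alpha) * image + alpha * colored
    return np.clip(blended, 0, 255).astype(np.uint8)
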