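"""Classification heads beyond each backbone's native one."""

from __future__ import annotations

import numpy as np

from ..nn.core import Sequential
from ..nn.layers import GlobalAvgPool, Linear
from .blocks import conv_bn_act


def build_yolo_head(in_channels: int, num_classes: int,
                    rng: np.random.Generator | None = None) -> Sequential:
    """A light convolutional classification head in the YOLO style.

    Pointwise conv (in -> 512) + BN + SiLU, a 3x3 depthwise conv on the 512
    channels + BN + SiLU, pointwise conv (512 -> 1280) + BN + SiLU, global
    average pooling, and a linear 1280 -> num_classes layer.  The depthwise-
    separable structure keeps the head cheap relative to a dense classifier
    over the same widths.  Softmax is applied at inference only.
    """
    if in_channels < num_classes:
        raise ValueError("in_channels must be at least num_classes")
    rng = rng or np.random.default_rng(0)
    return Sequential(
        conv_bn_act(in_channels, 512, 1, act="silu", rng=rng),
        conv_bn_act(512, 512, 3, groups=512, act="silu", rng=rng),
        conv_bn_act(512, 1280, 1, act="silu", rng=rng),
        GlobalAvgPool(),
        Linear(1280, num_classes, rng=rng),
    )
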