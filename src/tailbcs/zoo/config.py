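"""Model configuration and the A1-A8 ablation presets.

The eight presets sweep the design axes of the scoring model: channel (SE)
attention, spatial attention, label-smoothing loss and the YOLO-style
convolutional head, all on the EfficientNet-B0 backbone.  A1 is the bare
backbone with its native linear head and plain cross entropy; A8 combines
every module.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ..nn.attention import SEBlock, SpatialAttention
from .backbones import BACKBONES, build_backbone
from .base import ImageClassifier
from .heads import build_yolo_head

__all__ = ["ModelConfig", "ABLATION_PRESETS", "build_composite"]

_EXTRA_BACKBONES = ("tiny",)  # desk-scale extension, not part of the fixed six


@dataclass(frozen=True)
class ModelConfig:
    backbone: str = "efficientnet_b0"
    use_se: bool = False
    use_spatial: bool = False
    head: str = "linear"  # "linear" | "yolo"
    num_classes: int = 5
    loss: str = "cross_entropy"  # "cross_entropy" | "label_smoothing"
    se_reduction: int = 16

    def __post_init__(self):
        if self.backbone not in BACKBONES + _EXTRA_BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.head not in ("linear", "yolo"):
            raise ValueError(f"unknown head {self.head!r}")
        if self.num_classes < 2:
            raise ValueError("num_classes must be at least 2")
        if self.loss not in ("cross_entropy", "label_smoothing"):
            raise ValueError(f"unknown loss {self.loss!r}")

    def with_backbone(self, backbone: str) -> "ModelConfig":
        return replace(self, backbone=backbone)


# Attention/loss/head axes per ablation variant. A4 swaps in label smoothing,
# A5 the convolutional head; A6-A8 stack the modules (A8 = everything).
ABLATION_PRESETS: dict[str, ModelConfig] = {
    "A1": ModelConfig(),
    "A2": ModelConfig(use_se=True),
    "A3": ModelConfig(use_spatial=True),
    "A4": ModelConfig(loss="label_smoothing"),
    "A5": ModelConfig(head="yolo"),
    "A6": ModelConfig(use_se=True, use_spatial=True),
    "A7": ModelConfig(use_se=True, use_spatial=True, loss="label_smoothing"),
    "A8": ModelConfig(use_se=True, use_spatial=True, loss="label_smoothing",
                      head="yolo"),
}


def build_composite(config: ModelConfig, seed: int = 0) -> ImageClassifier:
    """Assemble backbone -> [SE] -> [spatial] -> head from a config.

    The SE block sits on the final feature map (reduction ``se_reduction``,
    both projections with biases); the spatial block follows it, before
    global pooling.  ``head="linear"`` keeps the backbone's native classifier;
    ``head="yolo"`` swaps in the convolutional head.
    """
    model = build_backbone(config.backbone, config.num_classes, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA77]))
    c = model.feature_channels
    if config.use_se:
        if c % config.se_reduction:
            raise ValueError(
                f"SE reduction {config.se_reduction} must divide {c} channels"
            )
        model.se = SEBlock(c, reduction=config.se_reduction, rng=rng)
    if config.use_spatial:
        model.spatial = SpatialAttention(rng=rng)
    if config.head == "yolo":
        model.head = build_yolo_head(c, config.num_classes, rng=rng)
    model.name = f"{config.backbone}[se={config.use_se},spatial={config.use_spatial},head={config.head}]"
    return model
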