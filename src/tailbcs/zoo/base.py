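"""Classifier container: features -> optional attention -> head."""

from __future__ import annotations

import numpy as np

from ..nn.attention import SEBlock, SpatialAttention
from ..nn.core import Module, Sequential


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class ImageClassifier(Module):
    """A backbone feature extractor with optional attention and a head.

    ``features`` maps an image batch to the final convolutional feature map;
    ``se`` and ``spatial`` (when present) rescale that map; ``head`` pools and
    classifies it into logits.
    """

    def __init__(self, features: Sequential, head: Module, feature_channels: int,
                 se: SEBlock | None = None, spatial: SpatialAttention | None = None,
                 name: str = "model"):
        super().__init__()
        self.features = features
        if se is not None:
            self.se = se
        else:
            object.__setattr__(self, "se", None)
        if spatial is not None:
            self.spatial = spatial
        else:
            object.__setattr__(self, "spatial", None)
        self.head = head
        self.feature_channels = feature_channels
        self.name = name

    def forward_features(self, x: np.ndarray) -> np.ndarray:
        x = self.features(x)
        if self.se is not None:
            x = self.se(x)
        if self.spatial is not None:
            x = self.spatial(x)
        return x

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.head(self.forward_features(x))

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        g = self.head.backward(grad_out)
        if self.spatial is not None:
            g = self.spatial.backward(g)
        if self.se is not None:
            g = self.se.backward(g)
        return self.features.backward(g)

    def backward_to_featuremap(self, grad_out: np.ndarray) -> np.ndarray:
        """Gradient of the logit seed w.r.t. the backbone feature map
        (i.e. the output of ``features``, before any attention block)."""
        g = self.head.backward(grad_out)
        if self.spatial is not None:
            g = self.spatial.backward(g)
        if self.se is not None:
            g = self.se.backward(g)
        return g

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x))
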