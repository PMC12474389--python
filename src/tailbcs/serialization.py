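"""Checkpoint save/load: npz weight archives plus a JSON model config."""

from __future__ import annotations

import json
import os
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .zoo.base import ImageClassifier
from .zoo.config import ModelConfig, build_composite

__all__ = ["save_checkpoint", "load_checkpoint"]


def save_checkpoint(model: ImageClassifier, config: ModelConfig,
                    path: str | os.PathLike) -> None:
    """Write model weights and the building config to an ``.npz`` archive."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(asdict(config)).encode(), dtype=np.uint8
    )
    np.savez(path, **state)


def load_checkpoint(path: str | os.PathLike) -> tuple[ImageClassifier, ModelConfig]:
    """Rebuild a model from an archive written by :func:`save_checkpoint`."""
    with np.load(Path(path)) as archive:
        cfg_raw = archive["__config__"].tobytes().decode()
        config = ModelConfig(**json.loads(cfg_raw))
        model = build_composite(config, seed=0)
        state = {k: archive[k] for k in archive.files if k != "__config__"}
    model.load_state_dict(state)
    model.eval()
    return model, config
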