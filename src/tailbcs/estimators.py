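"""Scikit-learn style estimators wrapping the model zoo and trainer.

:class:`BCSClassifier` is the primary user-facing surface: configure a
backbone/attention/head/loss combination, ``fit`` on preprocessed image
batches, ``predict`` BCS values.  :class:`DistilledBCSClassifier` trains a
compact student against a fitted teacher.  Both compose with sklearn
pipelines and model selection (``get_params``/``set_params`` via
``BaseEstimator``).

Inputs ``X`` are float32 arrays of shape ``(n_samples, 3, size, size)`` as
produced by :func:`tailbcs.data.preprocess`; targets ``y`` may be BCS values
(3.25..4.25) or class indices (0..4).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .bcs import BCS_VALUES, NUM_CLASSES
from .evaluation import EvalReport, evaluate_predictions
from .losses import DistillSpec
from .training import TrainConfig, predict_indices, train_model
from .zoo.base import softmax
from .zoo.config import ModelConfig, build_composite

__all__ = ["BCSClassifier", "DistilledBCSClassifier"]


def _as_indices(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind == "f" and y.size and y.max() > NUM_CLASSES - 1:
        from .bcs import values_to_indices

        return values_to_indices(y)
    return y.astype(int)


class BCSClassifier(ClassifierMixin, BaseEstimator):
    """Five-class tail-image body-condition classifier.

    Parameters mirror the model-zoo configuration (backbone, SE/spatial
    attention, head and loss choice) plus the trainer's optimisation
    settings.  ``backbone="tiny"`` is the desk-scale default; the six
    reference backbones are available under their standard names.
    """

    def __init__(self, backbone: str = "tiny", use_se: bool = False,
                 use_spatial: bool = False, head: str = "linear",
                 loss: str = "cross_entropy", smoothing_eps: float = 0.1,
                 learning_rate: float = 1e-3, batch_size: int = 32,
                 max_epochs: int = 20, patience: int = 10,
                 min_delta: float = 1e-4, val_fraction: float = 0.2,
                 seed: int = 0):
        self.backbone = backbone
        self.use_se = use_se
        self.use_spatial = use_spatial
        self.head = head
        self.loss = loss
        self.smoothing_eps = smoothing_eps
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.min_delta = min_delta
        self.val_fraction = val_fraction
        self.seed = seed

    # ------------------------------------------------------------------
    def _model_config(self) -> ModelConfig:
        return ModelConfig(backbone=self.backbone, use_se=self.use_se,
                           use_spatial=self.use_spatial, head=self.head,
                           loss=self.loss)

    def _train_config(self) -> TrainConfig:
        return TrainConfig(learning_rate=self.learning_rate,
                           batch_size=self.batch_size,
                           max_epochs=self.max_epochs,
                           early_stop_patience=self.patience,
                           min_delta=self.min_delta, seed=self.seed,
                           loss=self.loss, smoothing_eps=self.smoothing_eps)

    def _split_val(self, x, y):
        rng = np.random.default_rng(self.seed)
        n = len(x)
        n_val = max(1, int(round(self.val_fraction * n)))
        order = rng.permutation(n)
        val, train = order[:n_val], order[n_val:]
        return (x[train], y[train]), (x[val], y[val])

    def fit(self, X, y, X_val=None, y_val=None) -> "BCSClassifier":
        X = np.asarray(X, np.float32)
        if X.ndim != 4 or X.shape[1] != 3:
            raise ValueError("X must have shape (n_samples, 3, size, size)")
        y_idx = _as_indices(y)
        if X_val is not None:
            train, val = (X, y_idx), (np.asarray(X_val, np.float32), _as_indices(y_val))
        else:
            train, val = self._split_val(X, y_idx)
        model = build_composite(self._model_config(), seed=self.seed)
        self.model_, self.history_ = train_model(model, train, val,
                                                 self._train_config())
        self.classes_ = np.asarray(BCS_VALUES)
        self.n_features_in_ = X.shape[1] * X.shape[2] * X.shape[3]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        self.model_.eval()
        from .training import _forward_in_batches

        return softmax(_forward_in_batches(self.model_, np.asarray(X, np.float32)))

    def predict_indices(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return predict_indices(self.model_, np.asarray(X, np.float32))

    def predict(self, X) -> np.ndarray:
        idx = self.predict_indices(X)
        return self.classes_[idx]

    def score(self, X, y, sample_weight=None) -> float:
        y_idx = _as_indices(y)
        return float((self.predict_indices(X) == y_idx).mean())

    def evaluate(self, X, y) -> EvalReport:
        return evaluate_predictions(_as_indices(y), self.predict_indices(X))


class DistilledBCSClassifier(BCSClassifier):
    """Student classifier trained by knowledge distillation.

    ``teacher`` is a fitted :class:`BCSClassifier` (or any object exposing a
    ``model_`` with matching class count).  The student minimises the
    temperature-softened teacher KL plus hard-label cross entropy.
    """

    def __init__(self, teacher: BCSClassifier | None = None,
                 backbone: str = "tiny", use_se: bool = False,
                 use_spatial: bool = False, head: str = "linear",
                 temperature: float = 4.0, alpha: float = 0.7,
                 learning_rate: float = 1e-3, batch_size: int = 32,
                 max_epochs: int = 20, patience: int = 10,
                 min_delta: float = 1e-4, val_fraction: float = 0.2,
                 seed: int = 0):
        super().__init__(backbone=backbone, use_se=use_se,
                         use_spatial=use_spatial, head=head,
                         learning_rate=learning_rate, batch_size=batch_size,
                         max_epochs=max_epochs, patience=patience,
                         min_delta=min_delta, val_fraction=val_fraction,
                         seed=seed)
        self.teacher = teacher
        self.temperature = temperature
        self.alpha = alpha

    def fit(self, X, y, X_val=None, y_val=None) -> "DistilledBCSClassifier":
        if self.teacher is None:
            raise ValueError("a fitted teacher is required for distillation")
        check_is_fitted(self.teacher, "model_")
        X = np.asarray(X, np.float32)
        y_idx = _as_indices(y)
        if X_val is not None:
            train, val = (X, y_idx), (np.asarray(X_val, np.float32), _as_indices(y_val))
        else:
            train, val = self._split_val(X, y_idx)
        cfg = TrainConfig(learning_rate=self.learning_rate,
                          batch_size=self.batch_size,
                          max_epochs=self.max_epochs,
                          early_stop_patience=self.patience,
                          min_delta=self.min_delta, seed=self.seed,
                          loss="distillation")
        dspec = DistillSpec(temperature=self.temperature, alpha=self.alpha)
        model = build_composite(self._model_config(), seed=self.seed)
        self.model_, self.history_ = train_model(
            model, train, val, cfg, teacher=self.teacher.model_, dspec=dspec
        )
        self.classes_ = np.asarray(BCS_VALUES)
        self.n_features_in_ = X.shape[1] * X.shape[2] * X.shape[3]
        return self
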