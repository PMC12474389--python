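"""Training: Adam optimisation, early stopping, grid search, distillation.

Everything is deterministic given the configuration seed: model initialisation
is seeded at build time, data order by ``TrainConfig.seed``, and numpy does the
rest.  Epoch losses are sample-weighted means, so they are independent of
batch order at fixed weights.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .losses import DistillSpec, softmax
from .nn.core import Module

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "Adam",
    "early_stop_update",
    "train_model",
    "grid_search",
    "distill",
    "predict_indices",
]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 20
    early_stop_patience: int = 10
    min_delta: float = 1e-4
    seed: int = 0
    loss: str = "cross_entropy"  # cross_entropy | label_smoothing | distillation
    smoothing_eps: float = 0.1
    optimizer: str = "adam"

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be positive")
        if self.early_stop_patience < 1:
            raise ValueError("patience must be at least 1")
        if self.loss not in ("cross_entropy", "label_smoothing", "distillation"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        if self.lr == 0.0:
            return
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - self.b1) * (p.grad - m)
            v += (1 - self.b2) * (p.grad**2 - v)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def early_stop_update(state: dict | None, val_loss: float, patience: int,
                      min_delta: float) -> tuple[dict, bool]:
    """Update early-stopping state; stop after ``patience`` non-improvements.

    An improvement must beat the best loss by strictly more than ``min_delta``
    (an improvement of exactly ``min_delta`` does not count).
    """
    if patience < 1:
        raise ValueError("patience must be at least 1")
    if state is None:
        state = {"best": np.inf, "bad": 0}
    if state["best"] - val_loss > min_delta:
        state = {"best": float(val_loss), "bad": 0}
        return state, False
    state = {"best": state["best"], "bad": state["bad"] + 1}
    return state, state["bad"] >= patience


def _one_hot(y: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((y.size, k), np.float64)
    out[np.arange(y.size), y] = 1.0
    return out


def _batch_loss_grad(logits: np.ndarray, y: np.ndarray, cfg: TrainConfig,
                     teacher_logits: np.ndarray | None = None,
                     dspec: DistillSpec | None = None):
    """Mean loss over the batch and its gradient w.r.t. the logits."""
    k = logits.shape[1]
    b = logits.shape[0]
    p = softmax(logits)
    onehot = _one_hot(y, k)
    logp = np.log(np.maximum(p, 1e-12))
    if cfg.loss == "cross_entropy":
        loss = float(-(onehot * logp).sum() / b)
        grad = (p - onehot) / b
    elif cfg.loss == "label_smoothing":
        ytilde = (1.0 - cfg.smoothing_eps) * onehot + cfg.smoothing_eps / k
        loss = float(-(ytilde * logp).sum() / b)
        grad = (p - ytilde) / b
    else:  # distillation
        t, alpha = dspec.temperature, dspec.alpha
        ps_t = softmax(logits / t)
        pt_t = softmax(teacher_logits / t)
        kl = (pt_t * (np.log(np.maximum(pt_t, 1e-12))
                      - np.log(np.maximum(ps_t, 1e-12)))).sum() / b
        hard = -(onehot * logp).sum() / b
        loss = float(alpha * t**2 * kl + (1 - alpha) * hard)
        grad = (alpha * t * (ps_t - pt_t) + (1 - alpha) * (p - onehot)) / b
    return loss, grad.astype(np.float32)


def _forward_in_batches(model: Module, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
    outs = [model(x[i : i + batch_size]) for i in range(0, len(x), batch_size)]
    return np.concatenate(outs, axis=0)


def predict_indices(model: Module, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
    model.eval()
    return _forward_in_batches(model, x, batch_size).argmax(axis=1)


def _eval_pass(model: Module, x: np.ndarray, y: np.ndarray, cfg: TrainConfig,
               teacher_logits: np.ndarray | None, dspec: DistillSpec | None):
    model.eval()
    logits = _forward_in_batches(model, x, max(cfg.batch_size, 64))
    loss, _ = _batch_loss_grad(logits, y, cfg, teacher_logits, dspec)
    acc = float((logits.argmax(axis=1) == y).mean())
    return loss, acc


def train_model(model: Module, train_data, val_data, cfg: TrainConfig,
                teacher: Module | None = None,
                dspec: DistillSpec | None = None) -> tuple[Module, TrainHistory]:
    """Minimise the configured loss with Adam; restore best-val-loss weights.

    ``train_data`` / ``val_data`` are ``(X, y)`` pairs of preprocessed inputs
    and class indices.  For ``cfg.loss == "distillation"`` a frozen teacher
    model and a :class:`DistillSpec` must be supplied; teacher logits are
    precomputed once.
    """
    x_train, y_train = train_data
    x_val, y_val = val_data
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("training and validation sets must be nonempty")
    y_train = np.asarray(y_train, int)
    y_val = np.asarray(y_val, int)
    if cfg.loss == "distillation":
        if teacher is None or dspec is None:
            raise ValueError("distillation requires a teacher model and a DistillSpec")
        teacher.eval()
        t_train = _forward_in_batches(teacher, x_train)
        t_val = _forward_in_batches(teacher, x_val)
    else:
        t_train = t_val = None

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    history = TrainHistory()
    es_state = None
    best_state = copy.deepcopy(model.state_dict())
    best_loss = np.inf
    n = len(x_train)

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        model.train()
        loss_sum = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = model(x_train[idx])
            tb = t_train[idx] if t_train is not None else None
            loss, grad = _batch_loss_grad(logits, y_train[idx], cfg, tb, dspec)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            loss_sum += loss * len(idx)
            model.zero_grad()
            model.backward(grad)
            opt.step()
        history.train_loss.append(loss_sum / n)
        val_loss, val_acc = _eval_pass(model, x_val, y_val, cfg, t_val, dspec)
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
        history.stopped_epoch = epoch
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = copy.deepcopy(model.state_dict())
            history.best_epoch = epoch
        es_state, stop = early_stop_update(es_state, val_loss,
                                           cfg.early_stop_patience, cfg.min_delta)
        if stop:
            break
    model.load_state_dict(best_state)
    model.eval()
    return model, history


def grid_search(grid: Sequence[TrainConfig],
                model_factory: Callable[[TrainConfig], Module],
                train_data, val_data):
    """Train one model per config; pick the highest best-epoch val accuracy.

    Ties go to the earliest config in the declared grid order.  Returns
    ``(best_config, results)`` where results is a list of
    ``(config, model, history)`` in grid order.
    """
    if len(grid) == 0:
        raise ValueError("the search grid must be nonempty")
    results = []
    best_cfg, best_acc = None, -1.0
    for cfg in grid:
        model = model_factory(cfg)
        model, history = train_model(model, train_data, val_data, cfg)
        acc = history.val_accuracy[history.best_epoch - 1]
        results.append((cfg, model, history))
        if acc > best_acc:
            best_cfg, best_acc = cfg, acc
    return best_cfg, results


def distill(teacher: Module, student_config, train_data, val_data,
            dspec: DistillSpec, cfg: TrainConfig) -> tuple[Module, TrainHistory]:
    """Train a student against a frozen teacher with the distillation loss."""
    from .zoo.config import build_composite

    student = build_composite(student_config, seed=cfg.seed)
    t_probe = teacher(np.zeros((1,) + train_data[0].shape[1:], np.float32))
    if t_probe.shape[1] != student_config.num_classes:
        raise ValueError(
            f"teacher emits {t_probe.shape[1]} classes, student expects "
            f"{student_config.num_classes}"
        )
    cfg = replace(cfg, loss="distillation")
    return train_model(student, train_data, val_data, cfg,
                       teacher=teacher, dspec=dspec)


DEFAULT_GRID = tuple(
    TrainConfig(learning_rate=lr, batch_size=bs)
    for lr in (1e-4, 3e-4, 1e-3)
    for bs in (16, 32)
)
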