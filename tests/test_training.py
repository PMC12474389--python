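"""Trainer behaviour: no-op optimisation, determinism, early stopping,
grid search and distillation mechanics."""

import copy

import numpy as np
import pytest

from tailbcs import DistillSpec, TrainConfig, distill, early_stop_update, grid_search, train_model
from tailbcs.nn.core import Sequential
from tailbcs.nn.layers import Conv2d, GlobalAvgPool, Linear, ReLU
from tailbcs.training import predict_indices
from tailbcs.zoo import ModelConfig, build_composite
from tailbcs.zoo.base import ImageClassifier


def _bn_free_model(seed=0):
    rng = np.random.default_rng(seed)
    feats = Sequential(Conv2d(3, 4, 3, stride=2, padding=1, rng=rng), ReLU())
    head = Sequential(GlobalAvgPool(), Linear(4, 5, rng=rng))
    return ImageClassifier(feats, head, 4)


@pytest.fixture
def toy_data(rng):
    x = rng.normal(0, 1, (40, 3, 8, 8)).astype(np.float32)
    y = rng.integers(0, 5, 40)
    return (x[:30], y[:30]), (x[30:], y[30:])


class TestTrainModel:
    def test_zero_learning_rate_is_noop(self, toy_data):
        train, val = toy_data
        model = _bn_free_model()
        before = copy.deepcopy(model.state_dict())
        cfg = TrainConfig(learning_rate=0.0, max_epochs=4, seed=0)
        model, history = train_model(model, train, val, cfg)
        after = model.state_dict()
        for key in before:
            np.testing.assert_array_equal(before[key], after[key])
        assert np.ptp(history.train_loss) < 1e-6  # constant across epochs

    def test_seeded_determinism(self, toy_data):
        train, val = toy_data
        cfg = TrainConfig(learning_rate=1e-3, max_epochs=3, seed=11)
        _, h1 = train_model(_bn_free_model(1), train, val, cfg)
        _, h2 = train_model(_bn_free_model(1), train, val, cfg)
        assert h1.train_loss == h2.train_loss
        assert h1.val_loss == h2.val_loss
        assert h1.val_accuracy == h2.val_accuracy

    def test_best_epoch_is_val_loss_minimum(self, toy_data):
        train, val = toy_data
        cfg = TrainConfig(learning_rate=1e-3, max_epochs=5, seed=2)
        _, history = train_model(_bn_free_model(2), train, val, cfg)
        assert history.val_loss[history.best_epoch - 1] == min(history.val_loss)

    def test_empty_dataset_rejected(self, toy_data):
        _, val = toy_data
        x = np.empty((0, 3, 8, 8), np.float32)
        with pytest.raises(ValueError, match="nonempty"):
            train_model(_bn_free_model(), (x, np.empty(0, int)), val, TrainConfig())

    def test_divergence_names_epoch(self, toy_data):
        train, val = toy_data
        model = _bn_free_model()
        # simulate numerical blow-up: an overflowed logit makes the loss NaN
        model.head[1].bias.data[0] = np.float32(np.inf)
        cfg = TrainConfig(learning_rate=1e-3, max_epochs=2, seed=0)
        with pytest.raises(RuntimeError, match="epoch"):
            with np.errstate(all="ignore"):
                train_model(model, train, val, cfg)


class TestEarlyStopping:
    def test_strictly_decreasing_never_stops(self):
        state = None
        for loss in np.linspace(1.0, 0.1, 20):
            state, stop = early_stop_update(state, loss, patience=3, min_delta=1e-6)
            assert not stop

    def test_constant_losses_stop_on_fourth_call(self):
        state, calls = None, 0
        stop = False
        while not stop:
            state, stop = early_stop_update(state, 1.0, patience=3, min_delta=1e-4)
            calls += 1
        assert calls == 4

    def test_exact_min_delta_counts_as_no_improvement(self):
        state, _ = early_stop_update(None, 1.0, patience=1, min_delta=0.1)
        state, stop = early_stop_update(state, 0.9, patience=1, min_delta=0.1)
        assert stop  # improved by exactly min_delta -> not an improvement


class TestGridSearch:
    def test_single_config_returned(self, toy_data):
        train, val = toy_data
        cfg = TrainConfig(learning_rate=1e-3, max_epochs=2)
        best, results = grid_search([cfg], lambda c: _bn_free_model(), train, val)
        assert best is cfg and len(results) == 1

    def test_tie_goes_to_first(self, toy_data):
        train, val = toy_data
        a = TrainConfig(learning_rate=1e-3, max_epochs=2, seed=3)
        b = TrainConfig(learning_rate=1e-3, max_epochs=2, seed=3)
        best, _ = grid_search([a, b], lambda c: _bn_free_model(5), train, val)
        assert best is a

    def test_empty_grid_rejected(self, toy_data):
        train, val = toy_data
        with pytest.raises(ValueError, match="nonempty"):
            grid_search([], lambda c: _bn_free_model(), train, val)

    def test_learning_beats_frozen_arm(self, cropped_splits):
        """On the synthetic corpus a learning rate of 1e-3 must outrank the
        lr=0 arm, which cannot learn."""
        (xt, yt), (xv, yv), _ = cropped_splits
        sub = slice(0, 150)
        grid = [
            TrainConfig(learning_rate=0.0, max_epochs=3, seed=0),
            TrainConfig(learning_rate=1e-3, max_epochs=3, seed=0),
        ]
        best, _ = grid_search(
            grid,
            lambda c: build_composite(ModelConfig(backbone="tiny"), seed=0),
            (xt[sub], yt[sub]),
            (xv[:50], yv[:50]),
        )
        assert best.learning_rate == 1e-3


class TestDistill:
    def test_class_count_mismatch_rejected(self, toy_data):
        train, val = toy_data
        teacher = _bn_free_model()  # emits 5 classes
        cfg = TrainConfig(max_epochs=1)
        with pytest.raises(ValueError, match="classes"):
            distill(teacher, ModelConfig(backbone="tiny", num_classes=3),
                    train, val, DistillSpec(), cfg)

    def test_identical_teacher_student_zero_soft_loss(self, toy_data):
        """alpha=1 with teacher == student gives an initial loss of zero and a
        zero gradient on the soft term."""
        from tailbcs.training import _batch_loss_grad

        train, _ = toy_data
        model = _bn_free_model(3)
        model.eval()
        logits = model(train[0][:8])
        cfg = TrainConfig(loss="distillation")
        loss, grad = _batch_loss_grad(logits, train[1][:8], cfg,
                                      teacher_logits=logits,
                                      dspec=DistillSpec(alpha=1.0))
        assert loss == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(grad, 0.0, atol=1e-12)

    def test_student_smaller_than_teacher(self):
        from tailbcs.profiling import count_parameters

        teacher = build_composite(ModelConfig(backbone="tiny", use_se=True,
                                              use_spatial=True, head="yolo"))
        student = build_composite(ModelConfig(backbone="tiny"))
        assert count_parameters(student) < count_parameters(teacher)

    def test_reference_student_parameter_count(self):
        """The compact student architecture counts 2.23 M parameters."""
        from tailbcs.profiling import count_parameters

        student = build_composite(ModelConfig(backbone="mobilenet_v2"))
        assert count_parameters(student) == 2_230_277
        assert round(count_parameters(student) / 1e6, 2) == 2.23
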