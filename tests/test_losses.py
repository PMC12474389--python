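"""Losses: closed-form values, Gibbs inequality, permutation equivariance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tailbcs.losses import (
    DistillSpec,
    SmoothingSpec,
    cross_entropy,
    distillation_loss,
    label_smoothing_loss,
    smooth_labels,
    softmax,
)


def one_hot(i, k=5):
    y = np.zeros(k)
    y[i] = 1.0
    return y


def random_probs(rng, k=5):
    p = rng.dirichlet(np.ones(k))
    return p / p.sum()


class TestSmoothLabels:
    def test_default_eps_five_classes(self):
        y = smooth_labels(one_hot(2), SmoothingSpec(eps=0.1, num_classes=5))
        np.testing.assert_allclose(y, [0.02, 0.02, 0.92, 0.02, 0.02], atol=1e-12)
        assert y.sum() == pytest.approx(1.0, abs=1e-12)

    def test_eps_zero_is_identity(self):
        np.testing.assert_array_equal(
            smooth_labels(one_hot(1), SmoothingSpec(eps=0.0)), one_hot(1)
        )

    def test_eps_one_is_uniform(self):
        np.testing.assert_allclose(
            smooth_labels(one_hot(4), SmoothingSpec(eps=1.0)), np.full(5, 0.2)
        )

    def test_rejects_non_one_hot(self):
        with pytest.raises(ValueError, match="one-hot"):
            smooth_labels(np.array([0.5, 0.5, 0, 0, 0]), SmoothingSpec())


class TestLossValues:
    def test_uniform_prediction_gives_log_k(self):
        p = np.full(5, 0.2)
        spec = SmoothingSpec(eps=0.1)
        assert label_smoothing_loss(p, one_hot(3), spec) == pytest.approx(np.log(5), abs=1e-9)
        assert cross_entropy(p, one_hot(0)) == pytest.approx(np.log(5), abs=1e-9)

    def test_perfect_prediction_zero_loss(self):
        assert cross_entropy(one_hot(2), one_hot(2)) == 0.0
        assert label_smoothing_loss(one_hot(2) * 0.999999 + 2.5e-7, one_hot(2),
                                    SmoothingSpec(eps=0.0)) < 1e-5

    def test_half_confidence(self):
        p = np.array([0.5, 0.5, 0, 0, 0])
        assert cross_entropy(p, one_hot(0)) == pytest.approx(np.log(2), abs=1e-9)

    def test_loss_at_smoothed_target_equals_its_entropy(self):
        """-sum(y~ log y~) = -(0.92 ln 0.92 + 4 * 0.02 ln 0.02) = 0.38967."""
        spec = SmoothingSpec(eps=0.1)
        ytilde = smooth_labels(one_hot(2), spec)
        val = label_smoothing_loss(ytilde, one_hot(2), spec)
        assert val == pytest.approx(0.38967, abs=1e-5)

    def test_gibbs_inequality(self, rng):
        """The smoothed loss is bounded below by entropy(y~), equal iff p = y~."""
        spec = SmoothingSpec(eps=0.1)
        y = one_hot(1)
        ytilde = smooth_labels(y, spec)
        entropy = -(ytilde * np.log(ytilde)).sum()
        for _ in range(50):
            p = random_probs(rng)
            assert label_smoothing_loss(p, y, spec) >= entropy - 1e-9
        assert label_smoothing_loss(ytilde, y, spec) == pytest.approx(entropy, abs=1e-9)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 4), st.integers(0, 2**31 - 1))
    def test_eps_zero_equals_cross_entropy(self, true_class, seed):
        p = random_probs(np.random.default_rng(seed))
        y = one_hot(true_class)
        assert label_smoothing_loss(p, y, SmoothingSpec(eps=0.0)) == pytest.approx(
            cross_entropy(p, y), abs=1e-9
        )

    def test_permutation_equivariance(self, rng):
        spec = SmoothingSpec(eps=0.1)
        for _ in range(20):
            p = random_probs(rng)
            y = one_hot(rng.integers(5))
            perm = rng.permutation(5)
            assert label_smoothing_loss(p[perm], y[perm], spec) == pytest.approx(
                label_smoothing_loss(p, y, spec), abs=1e-9
            )
            assert cross_entropy(p[perm], y[perm]) == pytest.approx(
                cross_entropy(p, y), abs=1e-9
            )


class TestDistillation:
    def test_identical_logits_zero_soft_loss(self, rng):
        z = rng.normal(0, 1, 5)
        spec = DistillSpec(temperature=4.0, alpha=1.0)
        assert distillation_loss(z, z, one_hot(0), spec) == pytest.approx(0.0, abs=1e-12)

    def test_alpha_zero_reduces_to_cross_entropy(self, rng):
        s, t = rng.normal(0, 1, 5), rng.normal(0, 1, 5)
        y = one_hot(3)
        spec = DistillSpec(temperature=2.0, alpha=0.0)
        assert distillation_loss(s, t, y, spec) == pytest.approx(
            cross_entropy(softmax(s), y), abs=1e-9
        )

    def test_two_class_hand_computed_kl(self):
        """student (0,0), teacher (0, ln 3), T=1, alpha=1:
        KL((0.25, 0.75) || (0.5, 0.5)) = 0.13081."""
        spec = DistillSpec(temperature=1.0, alpha=1.0)
        val = distillation_loss(np.zeros(2), np.array([0.0, np.log(3)]),
                                one_hot(0, 2), spec)
        assert val == pytest.approx(0.13081, abs=1e-5)

    def test_alpha_decomposition(self, rng):
        s, t = rng.normal(0, 1, 5), rng.normal(0, 1, 5)
        y = one_hot(2)
        for temp in (0.5, 1.0, 4.0):
            soft = distillation_loss(s, t, y, DistillSpec(temp, 1.0))
            hard = distillation_loss(s, t, y, DistillSpec(temp, 0.0))
            mixed = distillation_loss(s, t, y, DistillSpec(temp, 0.7))
            assert mixed == pytest.approx(0.7 * soft + 0.3 * hard, rel=1e-9)

    def test_continuous_in_temperature(self, rng):
        s, t = rng.normal(0, 1, 5), rng.normal(0, 1, 5)
        y = one_hot(0)
        base = distillation_loss(s, t, y, DistillSpec(2.0, 0.7))
        near = distillation_loss(s, t, y, DistillSpec(2.0 + 1e-6, 0.7))
        assert abs(base - near) < 1e-4

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="equal-length"):
            distillation_loss(np.zeros(5), np.zeros(4), one_hot(0), DistillSpec())

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            DistillSpec(temperature=0.0)
        with pytest.raises(ValueError):
            DistillSpec(alpha=1.5)
        with pytest.raises(ValueError):
            SmoothingSpec(eps=-0.1)
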