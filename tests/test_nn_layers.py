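"""Layer primitives: forward arithmetic against independent oracles and
finite-difference gradient checks."""

import numpy as np
import pytest
from scipy.signal import correlate2d

from tailbcs.nn.core import Sequential
from tailbcs.nn.layers import (
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Linear,
    MaxPool2d,
    ReLU,
    SiLU,
)


def directional_grad_check(module, x, atol=5e-3, train=True):
    """Compare backward() against central differences of <r, module(x)>."""
    module.train(train)
    out = module(x.copy())
    r = np.random.default_rng(7).normal(0, 1, out.shape)

    def loss(arr=None):
        return float((r * module(x.copy())).sum())

    for p in module.parameters():
        p.grad[...] = 0
    gx = module.backward(r.astype(np.float32))

    def num_grad(arr):
        g = np.zeros_like(arr, dtype=np.float64)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            old = arr[i]
            arr[i] = old + 1e-3
            fp = loss()
            arr[i] = old - 1e-3
            fm = loss()
            arr[i] = old
            g[i] = (fp - fm) / 2e-3
        return g

    ngx = num_grad(x)
    scale = max(np.abs(ngx).max(), 1.0)
    assert np.abs(gx - ngx).max() / scale < atol
    for name, p in module.named_parameters():
        ng = num_grad(p.data)
        scale = max(np.abs(ng).max(), 1.0)
        assert np.abs(p.grad - ng).max() / scale < atol, name


@pytest.fixture
def x_small(rng):
    return rng.normal(0, 1, (2, 4, 6, 6)).astype(np.float32)


class TestConv2d:
    def test_matches_scipy_correlate(self, rng):
        """A plain convolution equals scipy's 2-D cross-correlation."""
        conv = Conv2d(2, 3, 3, stride=1, padding=1, rng=rng)
        x = rng.normal(0, 1, (1, 2, 8, 8)).astype(np.float32)
        out = conv(x)
        for o in range(3):
            ref = sum(
                correlate2d(x[0, c], conv.weight.data[o, c], mode="same")
                for c in range(2)
            ) + conv.bias.data[o]
            np.testing.assert_allclose(out[0, o], ref, rtol=1e-4, atol=1e-5)

    def test_stride_and_output_shape(self, rng):
        conv = Conv2d(3, 5, 3, stride=2, padding=1, rng=rng)
        out = conv(rng.normal(0, 1, (2, 3, 9, 9)).astype(np.float32))
        assert out.shape == (2, 5, 5, 5)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(in_channels=4, out_channels=6, kernel_size=3, stride=2, padding=1),
            dict(in_channels=4, out_channels=4, kernel_size=3, padding=1, groups=4),
            dict(in_channels=4, out_channels=6, kernel_size=3, padding=1, groups=2),
            dict(in_channels=4, out_channels=3, kernel_size=1, bias=False),
        ],
    )
    def test_gradients(self, kwargs, x_small, rng):
        directional_grad_check(Conv2d(**kwargs, rng=rng), x_small)

    def test_channel_mismatch_raises(self, x_small, rng):
        with pytest.raises(ValueError, match="channels"):
            Conv2d(3, 4, 3, rng=rng)(x_small)


class TestBatchNorm:
    def test_train_normalizes_batch(self, x_small):
        bn = BatchNorm2d(4)
        bn.train()
        out = bn(x_small)
        np.testing.assert_allclose(out.mean(axis=(0, 2, 3)), 0, atol=1e-5)
        np.testing.assert_allclose(out.std(axis=(0, 2, 3)), 1, atol=1e-3)

    def test_eval_uses_running_stats(self, x_small):
        bn = BatchNorm2d(4)
        bn.train()
        for _ in range(200):
            bn(x_small)
        bn.eval()
        out = bn(x_small)
        np.testing.assert_allclose(out.mean(axis=(0, 2, 3)), 0, atol=1e-2)

    def test_gradients_train_and_eval(self, x_small):
        directional_grad_check(BatchNorm2d(4), x_small)
        bn = BatchNorm2d(4)
        bn.train()
        bn(x_small)
        directional_grad_check(bn, x_small, train=False)


class TestPooling:
    def test_maxpool_matches_naive(self, rng):
        pool = MaxPool2d(3, 2, padding=1)
        x = rng.normal(0, 1, (1, 2, 7, 7)).astype(np.float32)
        out = pool(x)
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)), constant_values=-np.inf)
        for i in range(out.shape[2]):
            for j in range(out.shape[3]):
                ref = xp[:, :, 2 * i : 2 * i + 3, 2 * j : 2 * j + 3].max(axis=(2, 3))
                np.testing.assert_array_equal(out[:, :, i, j], ref)

    def test_ceil_mode_output_size(self, rng):
        # 13 -> ceil((13 - 3) / 2) + 1 = 6 rather than floor's 6... use 12:
        # floor: (12 - 3) // 2 + 1 = 5; ceil: 6
        x = rng.normal(0, 1, (1, 1, 12, 12)).astype(np.float32)
        assert MaxPool2d(3, 2).forward(x).shape[-1] == 5
        assert MaxPool2d(3, 2, ceil_mode=True).forward(x).shape[-1] == 6

    def test_maxpool_gradients(self):
        # distinct, well-separated values so finite differences never
        # straddle an argmax switch
        vals = np.random.default_rng(0).permutation(2 * 4 * 6 * 6) * 0.1
        x = vals.reshape(2, 4, 6, 6).astype(np.float32)
        directional_grad_check(MaxPool2d(3, 2, padding=1), x)

    def test_global_avg_pool(self, x_small):
        out = GlobalAvgPool()(x_small)
        np.testing.assert_allclose(out, x_small.mean(axis=(2, 3)), rtol=1e-6)


class TestComposites:
    def test_sequential_backward_chains(self, rng):
        model = Sequential(
            Conv2d(3, 4, 3, padding=1, rng=rng),
            ReLU(),
            Conv2d(4, 2, 3, padding=1, rng=rng),
            SiLU(),
        )
        x = rng.normal(0, 1, (2, 3, 5, 5)).astype(np.float32)
        directional_grad_check(model, x)

    def test_linear_gradients(self, rng):
        lin = Linear(5, 4, rng=rng)
        directional_grad_check(lin, rng.normal(0, 1, (3, 5)).astype(np.float32))

    def test_state_dict_roundtrip(self, rng):
        model = Sequential(Conv2d(3, 4, 3, padding=1, rng=rng), BatchNorm2d(4))
        state = model.state_dict()
        model2 = Sequential(Conv2d(3, 4, 3, padding=1), BatchNorm2d(4))
        model2.load_state_dict(state)
        x = rng.normal(0, 1, (1, 3, 5, 5)).astype(np.float32)
        model.eval(), model2.eval()
        np.testing.assert_array_equal(model(x), model2(x))
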