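"""Autodiff engine and network topology checks.

Every differentiable op is validated against central finite differences
computed in float64, on tiny tensors where the quadrature is reliable.
"""

import numpy as np
import pytest

from ettloc.nn import autograd as ag
from ettloc.nn.autograd import Tensor
from ettloc.nn.layers import SCSE, AvgPool2d, BatchNorm2d, Conv2d, MaxPool2d, Sequential
from ettloc.nn.network import KeypointNetwork, NetConfig


def numeric_grad(f, x, eps=1e-3):
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = float(x[i])
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g


def weighted_loss(out, w):
    return ag.mean_all(ag.mul(out, Tensor(w)))


class TestOpGradients:
    """Analytic vs numeric input gradients for each spatial op."""

    @pytest.mark.parametrize(
        "opname",
        ["conv", "conv_stride2", "scse", "maxpool", "avgpool", "resize", "sigmoid_abs"],
    )
    def test_input_gradient(self, opname, rng):
        shape = (2, 4, 6, 6)
        x0 = rng.normal(0, 1, shape).astype(np.float32)
        if opname == "conv":
            mod = Conv2d(4, 3, 3, rng=rng)
            op = lambda t: mod(t)
        elif opname == "conv_stride2":
            mod = Conv2d(4, 3, 3, stride=2, rng=rng)
            op = lambda t: mod(t)
        elif opname == "scse":
            mod = SCSE(4, rng=rng)
            op = lambda t: mod(t)
        elif opname == "maxpool":
            op = lambda t: ag.maxpool2d(t, 3, 2, 1)
        elif opname == "avgpool":
            op = lambda t: ag.avgpool2d(t, 2)
        elif opname == "resize":
            op = lambda t: ag.resize_bilinear(t, (9, 13))
        else:
            op = lambda t: ag.absolute(ag.sigmoid(t))
        probe = rng.normal(0, 1, op(Tensor(x0)).shape).astype(np.float32)

        x = Tensor(x0, requires_grad=True)
        loss = weighted_loss(op(x), probe)
        loss.backward()
        analytic = x.grad.astype(np.float64)
        numeric = numeric_grad(lambda: float(weighted_loss(op(Tensor(x0)), probe).data), x0)
        scale = max(np.abs(numeric).max(), 1e-6)
        assert np.abs(analytic - numeric).max() / scale < 5e-3

    def test_conv_weight_gradient(self, rng):
        x0 = rng.normal(0, 1, (2, 2, 5, 5)).astype(np.float32)
        conv = Conv2d(2, 3, 3, rng=rng)
        probe = rng.normal(0, 1, (2, 3, 5, 5)).astype(np.float32)
        loss = weighted_loss(conv(Tensor(x0)), probe)
        loss.backward()
        analytic = conv.weight.grad.astype(np.float64)
        numeric = numeric_grad(
            lambda: float(weighted_loss(conv(Tensor(x0)), probe).data), conv.weight.data
        )
        assert np.abs(analytic - numeric).max() / np.abs(numeric).max() < 5e-3

    def test_batchnorm_gradient_matches_float64_reference(self, rng):
        x0 = rng.normal(0, 1, (2, 2, 3, 3)).astype(np.float32)
        probe = rng.normal(0, 1, x0.shape).astype(np.float32)
        gamma = np.array([1.3, 0.7])
        beta = np.array([0.1, -0.2])

        def forward64(xd):
            m = xd.mean(axis=(0, 2, 3))
            v = xd.var(axis=(0, 2, 3))
            xhat = (xd - m[None, :, None, None]) / np.sqrt(v + 1e-5)[None, :, None, None]
            y = gamma[None, :, None, None] * xhat + beta[None, :, None, None]
            return float((y * probe).mean())

        x = Tensor(x0, requires_grad=True)
        out = ag.batchnorm(
            x, Tensor(gamma.astype(np.float32), requires_grad=True),
            Tensor(beta.astype(np.float32), requires_grad=True),
            np.zeros(2, dtype=np.float32), np.ones(2, dtype=np.float32), training=True,
        )
        weighted_loss(out, probe).backward()
        x64 = x0.astype(np.float64)
        numeric = numeric_grad(lambda: forward64(x64), x64, eps=1e-5)
        assert np.abs(x.grad - numeric).max() / np.abs(numeric).max() < 1e-3

    def test_l1_loss_value_and_gradient(self):
        pred = Tensor(np.array([[0.2, 0.8]], dtype=np.float32), requires_grad=True)
        target = np.array([[0.5, 0.5]], dtype=np.float32)
        loss = ag.l1_loss(pred, target)
        assert float(loss.data) == pytest.approx(0.3)
        loss.backward()
        assert np.allclose(pred.grad, [[-0.5, 0.5]])

    def test_bce_loss_gradient(self, rng):
        p0 = rng.uniform(0.1, 0.9, (2, 3)).astype(np.float32)
        t = rng.uniform(0, 1, (2, 3)).astype(np.float32)
        pred = Tensor(p0, requires_grad=True)
        ag.bce_loss(pred, t).backward()
        numeric = numeric_grad(lambda: float(ag.bce_loss(Tensor(p0), t).data), p0)
        assert np.abs(pred.grad - numeric).max() / np.abs(numeric).max() < 5e-3


class TestGraph:
    def test_gradient_accumulates_over_shared_input(self, rng):
        x = Tensor(rng.normal(0, 1, (3,)).astype(np.float32), requires_grad=True)
        out = ag.sum_all(ag.add(ag.mul(x, x), x))  # d/dx (x^2 + x) = 2x + 1
        out.backward()
        assert np.allclose(x.grad, 2 * x.data + 1, atol=1e-6)

    def test_concat_splits_gradient(self, rng):
        a = Tensor(rng.normal(0, 1, (1, 2, 2, 2)).astype(np.float32), requires_grad=True)
        b = Tensor(rng.normal(0, 1, (1, 3, 2, 2)).astype(np.float32), requires_grad=True)
        w = rng.normal(0, 1, (1, 5, 2, 2)).astype(np.float32)
        weighted_loss(ag.concat([a, b], axis=1), w).backward()
        assert np.allclose(a.grad, w[:, :2] / w.size)
        assert np.allclose(b.grad, w[:, 2:] / w.size)


class TestNetwork:
    def test_output_shape_matches_input(self):
        cfg = NetConfig(encoder="small", working_size=(64, 64), base_channels=4)
        net = KeypointNetwork(cfg, seed=0)
        out = net.forward(np.zeros((2, 1, 64, 64), dtype=np.float32))
        assert out.data.shape == (2, 4, 64, 64)
        assert np.all((out.data >= 0) & (out.data <= 1))  # sigmoid head

    def test_eval_mode_deterministic(self, rng):
        cfg = NetConfig(encoder="small", working_size=(64, 64), base_channels=4)
        net = KeypointNetwork(cfg, seed=0)
        x = rng.random((1, 1, 64, 64)).astype(np.float32)
        assert np.array_equal(net.predict_surfaces(x), net.predict_surfaces(x))

    def test_wrong_input_shape_rejected(self):
        cfg = NetConfig(encoder="small", working_size=(64, 64), base_channels=4)
        net = KeypointNetwork(cfg, seed=0)
        with pytest.raises(ValueError, match="expected input"):
            net.forward(np.zeros((1, 1, 32, 32), dtype=np.float32))

    def test_dense_topology_shape(self):
        cfg = NetConfig(encoder="dense", dense_blocks=(2, 2), growth=4,
                        working_size=(64, 64))
        net = KeypointNetwork(cfg, seed=0)
        out = net.forward(np.zeros((1, 1, 64, 64), dtype=np.float32))
        assert out.data.shape == (1, 4, 64, 64)

    def test_dense121_block_structure(self):
        cfg = NetConfig(encoder="dense121", working_size=(64, 64))
        net = KeypointNetwork(cfg, seed=0)
        # DenseNet-121 channel progression ends at 1024 before the decoder
        assert net.encoder.c_out == 1024

    def test_pretrained_flag_rejected(self):
        with pytest.raises(ValueError, match="pretrained"):
            NetConfig(encoder="dense121", pretrained=True)

    def test_same_seed_identical_init(self):
        cfg = NetConfig(encoder="small", working_size=(64, 64), base_channels=4)
        a = KeypointNetwork(cfg, seed=5)
        b = KeypointNetwork(cfg, seed=5)
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.data, pb.data)
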