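"""Neural-network modules built on the autograd engine.

Includes the spatial-and-channel squeeze-and-excitation (SCSE) block used
in the decoder: a channel gate (global average pool -> bottleneck ->
sigmoid, applied per channel) and a spatial gate (1x1 convolution ->
sigmoid, applied per pixel) whose recalibrated maps are combined by
element-wise addition.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "Module", "Sequential", "Conv2d", "BatchNorm2d", "ReLU", "Sigmoid",
    "MaxPool2d", "AvgPool2d", "Upsample2x", "SCSE", "DenseBlock", "Transition",
]

_F = np.float32


class Module:
    """Base class: parameter collection and train/eval mode switching."""

    def __init__(self):
        self._params: list[Tensor] = []
        self._children: list[Module] = []
        self.training = True

    def register(self, tensor: Tensor) -> Tensor:
        tensor.requires_grad = True
        self._params.append(tensor)
        return tensor

    def add_child(self, module: "Module") -> "Module":
        self._children.append(module)
        return module

    def parameters(self) -> list[Tensor]:
        out = list(self._params)
        for child in self._children:
            out.extend(child.parameters())
        return out

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for child in self._children:
            child.set_training(flag)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        """All arrays that define the module (weights + running stats)."""
        out = [p.data for p in self._params]
        for child in self._children:
            out.extend(child.state_arrays())
        return out

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        own = self.state_arrays()
        if len(own) != len(arrays):
            raise ValueError(f"state mismatch: have {len(own)} arrays, got {len(arrays)}")
        for dst, src in zip(own, arrays):
            if dst.shape != src.shape:
                raise ValueError(f"shape mismatch {dst.shape} vs {src.shape}")
            dst[...] = src

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.modules = [self.add_child(m) for m in modules]

    def forward(self, x: Tensor) -> Tensor:
        for m in self.modules:
            x = m(x)
        return x


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, stride: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        std = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.weight = self.register(Tensor(rng.normal(0.0, std, size=(c_out, c_in, k, k)).astype(_F)))
        self.bias = self.register(Tensor(np.zeros(c_out, dtype=_F))) if bias else None
        self.stride = stride

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, stride=self.stride)


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = self.register(Tensor(np.ones(c, dtype=_F)))
        self.beta = self.register(Tensor(np.zeros(c, dtype=_F)))
        self.running_mean = np.zeros(c, dtype=_F)
        self.running_var = np.ones(c, dtype=_F)
        self.momentum = momentum
        self.eps = eps

    def state_arrays(self) -> list[np.ndarray]:
        return [self.gamma.data, self.beta.data, self.running_mean, self.running_var]

    def forward(self, x: Tensor) -> Tensor:
        return ag.batchnorm(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            training=self.training, momentum=self.momentum, eps=self.eps,
        )


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.relu(x)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.sigmoid(x)


class MaxPool2d(Module):
    def __init__(self, k: int = 2, stride: int | None = None, pad: int = 0):
        super().__init__()
        self.k, self.stride, self.pad = k, stride or k, pad

    def forward(self, x: Tensor) -> Tensor:
        return ag.maxpool2d(x, self.k, self.stride, self.pad)


class AvgPool2d(Module):
    def __init__(self, k: int = 2):
        super().__init__()
        self.k = k

    def forward(self, x: Tensor) -> Tensor:
        return ag.avgpool2d(x, self.k)


class Upsample2x(Module):
    def forward(self, x: Tensor) -> Tensor:
        _, _, h, w = x.shape
        return ag.resize_bilinear(x, (2 * h, 2 * w))


class SCSE(Module):
    """Spatial-and-channel squeeze-and-excitation recalibration (add variant)."""

    def __init__(self, c: int, reduction: int = 2, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        c_mid = max(1, c // reduction)
        # channel gate: GAP -> 1x1 bottleneck -> 1x1 expand -> sigmoid
        self.fc1 = self.add_child(Conv2d(c, c_mid, 1, rng=rng))
        self.fc2 = self.add_child(Conv2d(c_mid, c, 1, rng=rng))
        # spatial gate: 1x1 conv to a single map -> sigmoid
        self.spatial = self.add_child(Conv2d(c, 1, 1, rng=rng))

    def forward(self, x: Tensor) -> Tensor:
        pooled = ag.mean_axes(x, (2, 3), keepdims=True)
        cgate = ag.sigmoid(self.fc2(ag.relu(self.fc1(pooled))))
        sgate = ag.sigmoid(self.spatial(x))
        return ag.add(ag.mul(x, cgate), ag.mul(x, sgate))


class _DenseLayer(Module):
    """BN-ReLU-Conv1x1(4k)-BN-ReLU-Conv3x3(k) with concatenative connectivity."""

    def __init__(self, c_in: int, growth: int, rng: np.random.Generator):
        super().__init__()
        bottleneck = 4 * growth
        self.block = self.add_child(Sequential(
            BatchNorm2d(c_in), ReLU(), Conv2d(c_in, bottleneck, 1, bias=False, rng=rng),
            BatchNorm2d(bottleneck), ReLU(), Conv2d(bottleneck, growth, 3, bias=False, rng=rng),
        ))

    def forward(self, x: Tensor) -> Tensor:
        return ag.concat([x, self.block(x)], axis=1)


class DenseBlock(Module):
    def __init__(self, c_in: int, n_layers: int, growth: int, rng: np.random.Generator):
        super().__init__()
        self.layers = []
        c = c_in
        for _ in range(n_layers):
            self.layers.append(self.add_child(_DenseLayer(c, growth, rng)))
            c += growth
        self.c_out = c

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Transition(Module):
    """BN-ReLU-Conv1x1 (compression) followed by 2x average pooling."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.block = self.add_child(Sequential(
            BatchNorm2d(c_in), ReLU(), Conv2d(c_in, c_out, 1, bias=False, rng=rng), AvgPool2d(2),
        ))

    def forward(self, x: Tensor) -> Tensor:
        return self.block(x)
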