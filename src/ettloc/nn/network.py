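"""Encoder-decoder topologies for four-landmark heatmap regression.

The same architecture is used in both detection stages: an encoder
downsamples the single-channel working-resolution image to a feature map,
and a decoder of three convolutional blocks — each followed by SCSE
recalibration and bilinear upsampling — restores the working resolution
before a final 1x1 convolution to four channels and a sigmoid, so the
predicted surfaces live in [0, 1] like the Gaussian targets.

Two encoders are provided:

* ``"small"`` — four stride-2 convolutional blocks; trains quickly on a
  single CPU and is the topology used for desk-scale experiments.
* ``"dense121"`` — the DenseNet-121 connectivity (dense blocks of
  6/12/24/16 bottleneck layers, growth 32, 0.5-compression transitions)
  for full-scale use.  No pretrained weights are bundled, so
  ``pretrained=True`` is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .layers import (
    SCSE, BatchNorm2d, Conv2d, DenseBlock, MaxPool2d, Module,
    ReLU, Sequential, Transition, Upsample2x,
)

__all__ = ["NetConfig", "KeypointNetwork"]

N_LANDMARKS = 4


@dataclass(frozen=True)
class NetConfig:
    """Architecture hyperparameters.

    ``encoder`` selects the topology; ``working_size`` the (width, height)
    of input and output; ``base_channels`` scales the small encoder's
    width.  ``dense_blocks``/``growth`` only apply to dense encoders.
    """

    encoder: str = "small"          # "small" | "dense121" | "dense"
    pretrained: bool = False
    working_size: tuple[int, int] = (512, 512)
    base_channels: int = 8
    dense_blocks: tuple[int, ...] = (6, 12, 24, 16)
    growth: int = 32
    loss: str = "l1"                # "l1" | "bce"

    def __post_init__(self) -> None:
        if self.pretrained:
            raise ValueError(
                "no pretrained weights are bundled with this package; "
                "train from random initialization (pretrained=False)"
            )
        if self.encoder not in ("small", "dense121", "dense"):
            raise ValueError(f"unknown encoder {self.encoder!r}")
        if self.loss not in ("l1", "bce"):
            raise ValueError(f"unknown loss {self.loss!r}")


class _SmallEncoder(Module):
    """Stem plus four stride-2 conv-BN-ReLU blocks (downsampling x16)."""

    def __init__(self, base: int, rng: np.random.Generator):
        super().__init__()
        c = base
        layers = [Conv2d(1, c, 3, rng=rng), BatchNorm2d(c), ReLU()]
        for mult in (2, 4, 6, 8):
            c_out = base * mult
            layers += [Conv2d(c, c_out, 3, stride=2, rng=rng), BatchNorm2d(c_out), ReLU()]
            c = c_out
        self.body = self.add_child(Sequential(*layers))
        self.c_out = c

    def forward(self, x: Tensor) -> Tensor:
        return self.body(x)


class _DenseEncoder(Module):
    """DenseNet-style encoder: 7x7 stem, max-pool, dense blocks + transitions."""

    def __init__(self, blocks: tuple[int, ...], growth: int, rng: np.random.Generator):
        super().__init__()
        c = 2 * growth
        stem = [Conv2d(1, c, 7, stride=2, bias=False, rng=rng), BatchNorm2d(c), ReLU(),
                MaxPool2d(3, stride=2, pad=1)]
        self.stem = self.add_child(Sequential(*stem))
        self.blocks: list[Module] = []
        for i, n_layers in enumerate(blocks):
            block = self.add_child(DenseBlock(c, n_layers, growth, rng))
            self.blocks.append(block)
            c = block.c_out
            if i < len(blocks) - 1:
                trans = self.add_child(Transition(c, c // 2, rng))
                self.blocks.append(trans)
                c = c // 2
        self.head = self.add_child(Sequential(BatchNorm2d(c), ReLU()))
        self.c_out = c

    def forward(self, x: Tensor) -> Tensor:
        x = self.stem(x)
        for block in self.blocks:
            x = block(x)
        return self.head(x)


class _Decoder(Module):
    """Three upsample->conv->BN->ReLU->SCSE blocks, then 1x1 conv to 4 maps."""

    def __init__(self, c_in: int, working_size: tuple[int, int], rng: np.random.Generator):
        super().__init__()
        self.working_size = working_size
        channels = [max(c_in // 2, 8), max(c_in // 4, 8), max(c_in // 8, 8)]
        self.blocks = []
        c = c_in
        for c_out in channels:
            self.blocks.append(self.add_child(Sequential(
                Upsample2x(), Conv2d(c, c_out, 3, rng=rng), BatchNorm2d(c_out), ReLU(),
                SCSE(c_out, rng=rng),
            )))
            c = c_out
        self.head = self.add_child(Conv2d(c, N_LANDMARKS, 1, rng=rng))

    def forward(self, x: Tensor) -> Tensor:
        for block in self.blocks:
            x = block(x)
        tw, th = self.working_size
        x = ag.resize_bilinear(x, (th, tw))
        return ag.sigmoid(self.head(x))


class KeypointNetwork(Module):
    """Full encoder-decoder network; input (N,1,H,W) -> output (N,4,H,W)."""

    def __init__(self, cfg: NetConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        if cfg.encoder == "small":
            self.encoder = self.add_child(_SmallEncoder(cfg.base_channels, rng))
        else:
            blocks = (6, 12, 24, 16) if cfg.encoder == "dense121" else cfg.dense_blocks
            self.encoder = self.add_child(_DenseEncoder(blocks, cfg.growth, rng))
        self.decoder = self.add_child(_Decoder(self.encoder.c_out, cfg.working_size, rng))

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        tw, th = self.cfg.working_size
        if x.data.ndim == 2:
            x = Tensor(x.data[None, None])
        if x.data.ndim != 4 or x.data.shape[1] != 1 or x.data.shape[2:] != (th, tw):
            raise ValueError(
                f"expected input (N, 1, {th}, {tw}), got {x.data.shape}"
            )
        return self.decoder(self.encoder(x))

    def predict_surfaces(self, grids: np.ndarray) -> np.ndarray:
        """Eval-mode forward pass returning plain (N, 4, H, W) arrays."""
        was_training = self.training
        self.set_training(False)
        try:
            out = self.forward(grids).data
        finally:
            self.set_training(was_training)
        return out
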