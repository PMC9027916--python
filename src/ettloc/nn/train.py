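"""Training and inference for the two-stage landmark detector.

Stage 1 regresses the four Gaussian heatmaps on the whole working-
resolution image.  Stage 2 is the same architecture retrained on windows
cropped around the four landmarks; during training the windows come from
the annotated points (never from stage-1 predictions), while at inference
the stage-1 predictions define the window.  Stage-2 output refines only
the tube end and carina; the clavicular heads keep their stage-1
positions.

One integer seed drives weight initialization, shuffling and
augmentation, and all computation is single-threaded numpy, so two runs
with the same seed produce identical loss histories.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ..augment import AugmentConfig, augment
from ..heatmap import CropSpec, HeatmapConfig, HeatmapStack, decode, encode, make_crop
from ..io import AnnotatedImage, FrameTransform, KeypointSet, to_working
from . import autograd as ag
from .network import KeypointNetwork, NetConfig

__all__ = ["TrainConfig", "Adam", "train_stage", "predict", "PredictionResult",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings: Adam, lr 1e-4, batch 8, L1 heatmap loss."""

    learning_rate: float = 1e-4
    batch_size: int = 8
    epochs: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


class Adam:
    """Adam optimizer over a parameter list."""

    def __init__(self, params, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def _stage_samples(
    dataset: list[AnnotatedImage],
    stage: int,
    heatmap_cfg: HeatmapConfig,
    crop_margin: float,
) -> list[tuple[np.ndarray, KeypointSet]]:
    """Working-frame (pixels, keypoints) pairs for one training stage."""
    samples = []
    for img in dataset:
        if img.keypoints is None:
            raise ValueError(f"image {img.image_id!r} has no annotation")
        if stage == 1:
            grid, ft = to_working(img, heatmap_cfg.working_size)
            samples.append((grid.astype(np.float32), ft.map_keypoints(img.keypoints)))
        elif stage == 2:
            spec = make_crop(
                img.keypoints, img.native_size,
                margin_fraction=crop_margin, target_size=heatmap_cfg.working_size,
            )
            grid = spec.extract(img.pixels)
            kps = img.keypoints.transform(spec.to_crop)
            samples.append((grid.astype(np.float32), kps))
        else:
            raise ValueError("stage must be 1 or 2")
    return samples


def train_stage(
    dataset: list[AnnotatedImage],
    stage: int,
    net_cfg: NetConfig,
    train_cfg: TrainConfig,
    aug_cfg: AugmentConfig | None = None,
    heatmap_cfg: HeatmapConfig | None = None,
    crop_margin: float = 0.25,
    callback=None,
) -> tuple[KeypointNetwork, list[float]]:
    """Train one detection stage; returns the network and per-epoch loss.

    Stage-2 samples are built from the *annotated* keypoints (the window a
    stage-1 detector would aim for), never from stage-1 predictions.
    """
    if not dataset:
        raise ValueError("empty dataset")
    heatmap_cfg = heatmap_cfg or HeatmapConfig(working_size=net_cfg.working_size)
    if heatmap_cfg.working_size != net_cfg.working_size:
        raise ValueError("heatmap and network working sizes must agree")
    aug_cfg = aug_cfg if aug_cfg is not None else AugmentConfig()
    samples = _stage_samples(dataset, stage, heatmap_cfg, crop_margin)

    # distinct but deterministic streams per stage
    net = KeypointNetwork(net_cfg, seed=train_cfg.seed * 2 + stage)
    rng = np.random.default_rng((train_cfg.seed * 2 + stage) ^ 0x5EED)
    opt = Adam(net.parameters(), lr=train_cfg.learning_rate)

    history: list[float] = []
    n = len(samples)
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start : start + train_cfg.batch_size]
            grids = []
            targets = []
            for i in idx:
                grid, kps = samples[i]
                grid_a, kps_a = augment(grid, kps, aug_cfg, rng)
                grids.append(grid_a[None])
                targets.append(encode(kps_a, heatmap_cfg).surfaces)
            x = np.stack(grids).astype(np.float32)
            t = np.stack(targets).astype(np.float32)
            net.zero_grad()
            pred = net.forward(x)
            loss = ag.l1_loss(pred, t) if net_cfg.loss == "l1" else ag.bce_loss(pred, t)
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        history.append(epoch_loss / n_batches)
        if callback is not None:
            callback(epoch, history[-1])
    return net, history


@dataclass
class PredictionResult:
    """Predicted landmarks in the native frame, with stage-level detail."""

    keypoints: KeypointSet
    stage1_keypoints: KeypointSet
    crop: CropSpec | None
    used_stage2: bool


def _is_degenerate(surfaces: np.ndarray) -> bool:
    return bool(np.all(np.ptp(surfaces.reshape(surfaces.shape[0], -1), axis=1) == 0))


def predict(
    img: AnnotatedImage,
    stage1: KeypointNetwork,
    stage2: KeypointNetwork | None = None,
    heatmap_cfg: HeatmapConfig | None = None,
    crop_margin: float = 0.25,
) -> PredictionResult:
    """Run the full two-stage pipeline on one image.

    Stage 1 decodes landmarks at working resolution; its predictions define
    the refinement window from which stage 2 re-estimates the tube end and
    carina.  With ``stage2=None`` (or a degenerate stage-1 output) the
    stage-1 result is returned as-is.
    """
    heatmap_cfg = heatmap_cfg or HeatmapConfig(working_size=stage1.cfg.working_size)
    grid, ft = to_working(img, heatmap_cfg.working_size)
    surfaces = stage1.predict_surfaces(grid.astype(np.float32)[None, None])[0]
    kps1 = decode(HeatmapStack(surfaces, ft))
    if stage2 is None:
        return PredictionResult(kps1, kps1, None, used_stage2=False)
    if _is_degenerate(surfaces):
        warnings.warn(
            f"stage-1 output for {img.image_id!r} is flat; returning stage-1-only result",
            RuntimeWarning,
            stacklevel=2,
        )
        return PredictionResult(kps1, kps1, None, used_stage2=False)

    spec = make_crop(kps1, img.native_size, margin_fraction=crop_margin,
                     target_size=heatmap_cfg.working_size)
    crop_grid = spec.extract(img.pixels)
    surfaces2 = stage2.predict_surfaces(crop_grid.astype(np.float32)[None, None])[0]
    kps2_crop = decode(HeatmapStack(surfaces2, FrameTransform.identity(heatmap_cfg.working_size)))
    kps2_native = kps2_crop.transform(spec.from_crop)
    # stage 2 refines only tube end and carina; clavicles keep stage-1 positions
    refined = KeypointSet(
        tube_end=tuple(kps2_native.tube_end),
        carina=tuple(kps2_native.carina),
        clavicle_left=tuple(kps1.clavicle_left),
        clavicle_right=tuple(kps1.clavicle_right),
    )
    return PredictionResult(refined, kps1, spec, used_stage2=True)


def save_checkpoint(path: str | Path, net: KeypointNetwork, train_cfg: TrainConfig,
                    history: list[float] | None = None) -> None:
    """Serialize weights together with the configs and seed that made them."""
    meta = {
        "net_cfg": asdict(net.cfg),
        "train_cfg": asdict(train_cfg),
        "history": list(history or []),
    }
    arrays = {f"arr_{i}": a for i, a in enumerate(net.state_arrays())}
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> tuple[KeypointNetwork, TrainConfig, list[float]]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        arrays = [data[f"arr_{i}"] for i in range(len(data.files) - 1)]
    net_meta = meta["net_cfg"]
    for key in ("working_size", "dense_blocks"):
        net_meta[key] = tuple(net_meta[key])
    net_cfg = NetConfig(**net_meta)
    train_cfg = TrainConfig(**meta["train_cfg"])
    net = KeypointNetwork(net_cfg, seed=train_cfg.seed)
    net.load_state_arrays(arrays)
    return net, train_cfg, meta.get("history", [])
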