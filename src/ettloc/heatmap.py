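"""Gaussian heatmap encoding/decoding and the coarse-to-fine crop window.

Each landmark is represented during training as an unnormalized 2-D
Gaussian surface of fixed standard deviation (default sigma = 10 px at the
working resolution), peak value 1 at the landmark pixel.  Predicted
surfaces are decoded by taking the location of the highest value per
channel — deliberately without sub-pixel refinement, so the decoder is the
plain argmax read-out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .io import KEYPOINT_NAMES, FrameTransform, KeypointSet

__all__ = ["HeatmapConfig", "HeatmapStack", "CropSpec", "encode", "decode", "make_crop"]


@dataclass(frozen=True)
class HeatmapConfig:
    """Parameters of the Gaussian target surfaces."""

    sigma: float = 10.0           # px, standard deviation of the target Gaussian
    working_size: tuple[int, int] = (512, 512)
    peak_value: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass
class HeatmapStack:
    """Four per-landmark surfaces plus the transform back to the source frame.

    Channel order is the canonical landmark order
    ``(tube_end, carina, clavicle_left, clavicle_right)``.
    """

    surfaces: np.ndarray  # (4, H, W)
    frame: FrameTransform

    def __post_init__(self) -> None:
        self.surfaces = np.asarray(self.surfaces)
        if self.surfaces.ndim != 3 or self.surfaces.shape[0] != len(KEYPOINT_NAMES):
            raise ValueError(f"expected (4, H, W) surfaces, got {self.surfaces.shape}")
        if not np.all(np.isfinite(self.surfaces)):
            raise ValueError("heatmap surfaces contain non-finite values")


def encode(points: KeypointSet, cfg: HeatmapConfig, frame: FrameTransform | None = None) -> HeatmapStack:
    """Encode working-frame keypoints as Gaussian target surfaces.

    Channel ``c`` holds ``peak * exp(-||p - center_c||^2 / (2 sigma^2))``.
    The centre is quantized to the nearest pixel so the channel maximum is
    exactly ``peak_value`` at the rounded keypoint; the half-pixel
    quantization is negligible against sigma.  Surfaces are peak-normalized
    amplitudes, not probability densities.
    """
    tw, th = cfg.working_size
    ys = np.arange(th, dtype=np.float64)[:, None]
    xs = np.arange(tw, dtype=np.float64)[None, :]
    surfaces = np.empty((len(KEYPOINT_NAMES), th, tw), dtype=np.float64)
    inv_two_sigma2 = 1.0 / (2.0 * cfg.sigma**2)
    for c, name in enumerate(KEYPOINT_NAMES):
        cx, cy = np.round(np.asarray(getattr(points, name), dtype=float))
        d2 = (xs - cx) ** 2 + (ys - cy) ** 2
        surfaces[c] = cfg.peak_value * np.exp(-d2 * inv_two_sigma2)
    if frame is None:
        frame = FrameTransform.identity((tw, th))
    return HeatmapStack(surfaces=surfaces, frame=frame)


def decode(stack: HeatmapStack, to_source: bool = True) -> KeypointSet:
    """Decode a stack to keypoints at the per-channel maximum.

    Ties are broken deterministically toward the first maximum in row-major
    order.  A completely flat channel is degenerate: it decodes (with a
    warning) to the first pixel.
    When ``to_source`` the points are mapped through the stored frame
    transform back into the source image coordinates.
    """
    coords = []
    for c in range(stack.surfaces.shape[0]):
        chan = stack.surfaces[c]
        if np.all(chan == chan.flat[0]):
            warnings.warn(
                f"heatmap channel {KEYPOINT_NAMES[c]!r} is flat; decoding is degenerate",
                RuntimeWarning,
                stacklevel=2,
            )
        iy, ix = np.unravel_index(int(np.argmax(chan)), chan.shape)
        coords.append((float(ix), float(iy)))
    pts = KeypointSet(*coords)
    if to_source:
        pts = stack.frame.unmap_keypoints(pts)
    return pts


@dataclass(frozen=True)
class CropSpec:
    """Invertible geometry of the stage-2 refinement window.

    ``rect = (x0, y0, x1, y1)`` is an integer pixel rectangle in the source
    (native) frame; the window is resampled to ``target_size`` for the
    stage-2 network.
    """

    rect: tuple[int, int, int, int]
    target_size: tuple[int, int] = (512, 512)
    margin_fraction: float = 0.25

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.rect
        if not (x1 > x0 and y1 > y0):
            raise ValueError(f"degenerate crop rectangle {self.rect}")

    @property
    def transform(self) -> FrameTransform:
        """Native-frame point -> crop-frame point."""
        x0, y0, x1, y1 = self.rect
        tw, th = self.target_size
        sx = tw / (x1 - x0)
        sy = th / (y1 - y0)
        return FrameTransform(
            scale=(sx, sy),
            offset=(-x0 * sx, -y0 * sy),
            source_size=(x1 - x0, y1 - y0),
            target_size=self.target_size,
        )

    def to_crop(self, point) -> np.ndarray:
        return self.transform.map(point)

    def from_crop(self, point) -> np.ndarray:
        return self.transform.unmap(point)

    def extract(self, pixels: np.ndarray) -> np.ndarray:
        """Cut the rectangle out of a native-frame image and resize it."""
        x0, y0, x1, y1 = self.rect
        window = np.asarray(pixels, dtype=np.float64)[y0:y1, x0:x1]
        tw, th = self.target_size
        if window.shape == (th, tw):
            return window
        return _sk_resize(window, (th, tw), order=1, mode="edge", anti_aliasing=False, preserve_range=True)


def make_crop(
    points: KeypointSet,
    image_size: tuple[int, int],
    margin_fraction: float = 0.25,
    target_size: tuple[int, int] = (512, 512),
    min_side: int = 64,
) -> CropSpec:
    """Build the stage-2 window around the four keypoints.

    The axis-aligned bounding box of the points is expanded by
    ``margin_fraction`` of its side length on each side, then grown to the
    minimum side length if needed and clipped to the image bounds.  The
    margin keeps the carina and tube inside the window even when stage-1
    errs by a few millimetres.
    """
    w, h = image_size
    a = points.as_array()
    bx0, by0 = a.min(axis=0)
    bx1, by1 = a.max(axis=0)
    mx = margin_fraction * (bx1 - bx0)
    my = margin_fraction * (by1 - by0)
    x0, x1 = bx0 - mx, bx1 + mx
    y0, y1 = by0 - my, by1 + my
    # enforce a minimum side length, centred on the box
    min_w = min(min_side, w)
    min_h = min(min_side, h)
    if x1 - x0 < min_w:
        cx = 0.5 * (x0 + x1)
        x0, x1 = cx - min_w / 2, cx + min_w / 2
    if y1 - y0 < min_h:
        cy = 0.5 * (y0 + y1)
        y0, y1 = cy - min_h / 2, cy + min_h / 2
    # clip to bounds, preserving the side length where possible
    x0, x1 = _shift_into([x0, x1], 0, w)
    y0, y1 = _shift_into([y0, y1], 0, h)
    rect = (int(np.floor(x0)), int(np.floor(y0)), int(np.ceil(x1)), int(np.ceil(y1)))
    rect = (max(rect[0], 0), max(rect[1], 0), min(rect[2], w), min(rect[3], h))
    return CropSpec(rect=rect, target_size=target_size, margin_fraction=margin_fraction)


def _shift_into(interval, lo, hi):
    """Shift an interval into [lo, hi], shrinking only if it does not fit."""
    a, b = interval
    if b - a > hi - lo:
        return float(lo), float(hi)
    if a < lo:
        b += lo - a
        a = lo
    if b > hi:
        a -= b - hi
        b = hi
    return float(a), float(b)
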