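"""Training-time augmentation: one random affine per sample.

A uniform field-of-view scale (0.90 = zoom-in to 1.25 = zoom-out) followed
by a rotation about the image centre is applied identically to the pixel
grid and the keypoints, so the point-to-anatomy correspondence is
preserved exactly.  If any keypoint would leave the frame the transform is
re-drawn a bounded number of times; when all tries fail the untransformed
pair is returned, so augmentation never produces an invalid sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import KeypointSet

__all__ = ["AugmentConfig", "augment", "affine_points"]


@dataclass(frozen=True)
class AugmentConfig:
    scale_range: tuple[float, float] = (0.90, 1.25)     # field-of-view magnification
    rotation_range: tuple[float, float] = (-45.0, 45.0)  # degrees
    max_resample_tries: int = 10

    def __post_init__(self) -> None:
        if not self.scale_range[0] <= self.scale_range[1]:
            raise ValueError("scale_range must be ordered")
        if self.scale_range[0] <= 0:
            raise ValueError("scale must be strictly positive")
        if not self.rotation_range[0] <= self.rotation_range[1]:
            raise ValueError("rotation_range must be ordered")


def _rotation(theta_deg: float) -> np.ndarray:
    t = np.deg2rad(theta_deg)
    return np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])


def affine_points(points: KeypointSet, scale: float, rotation_deg: float,
                  center: tuple[float, float]) -> KeypointSet:
    """Map keypoints under scale-then-rotate about ``center`` (x, y).

    A field-of-view factor < 1 magnifies the anatomy, so point offsets from
    the centre grow by 1/scale.
    """
    c = np.asarray(center, dtype=float)
    r = _rotation(rotation_deg)
    return points.transform(lambda p: c + r @ ((p - c) / scale))


def _warp_image(grid: np.ndarray, scale: float, rotation_deg: float,
                center: tuple[float, float]) -> np.ndarray:
    # ndimage indexes (row, col) = (y, x); build the inverse map in that order
    cx, cy = center
    c_yx = np.array([cy, cx])
    r_xy = _rotation(-rotation_deg)  # inverse rotation
    r_yx = np.array([[r_xy[1, 1], r_xy[1, 0]], [r_xy[0, 1], r_xy[0, 0]]])
    m = scale * r_yx
    offset = c_yx - m @ c_yx
    return ndimage.affine_transform(grid, m, offset=offset, order=1, mode="constant", cval=0.0)


def augment(
    grid: np.ndarray,
    points: KeypointSet,
    cfg: AugmentConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, KeypointSet]:
    """Return one augmented (pixels, keypoints) pair in the same frame."""
    h, w = grid.shape
    center = ((w - 1) / 2.0, (h - 1) / 2.0)
    for _ in range(cfg.max_resample_tries):
        scale = rng.uniform(*cfg.scale_range)
        theta = rng.uniform(*cfg.rotation_range)
        new_points = affine_points(points, scale, theta, center)
        if new_points.in_frame((w, h)):
            return _warp_image(grid, scale, theta, center), new_points
    return grid.copy(), points
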