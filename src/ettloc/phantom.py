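"""Synthetic chest-radiograph phantoms with known landmark ground truth.

The phantom is a *stylized* frontal chest image: a brighter mediastinal
band between two dark lung fields, a midline tracheal stripe that
bifurcates at the carina, two clavicular arcs whose medial endpoints are
the clavicular-head landmarks, and a radio-opaque tube line terminating at
the tube-end landmark, plus additive Gaussian noise.  Anatomy is
deliberately schematic: the detector has to learn landmark geometry, not
chest anatomy, which keeps desk-scale training honest and fast.

Tube placement is sampled from configurable distributions: normal cases
draw the tube-to-carina distance uniformly inside the adequacy band
(default 20-55 mm) with the tube below the clavicular midpoint; abnormal
cases are stratified in equal thirds over the three clinically distinct
failure modes (tube too deep, tube too shallow, tube above the clavicular
midpoint).  Every image's landmark coordinates, pixel spacing and the
label implied by the sampled geometry are recorded exactly, and the label
is verified against the distance rules at generation time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AnnotatedImage, KeypointSet
from .rules import RuleSet, classify, distances

__all__ = ["PhantomConfig", "generate", "generate_coordinates_only"]


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and sampling parameters of the phantom population.

    Default size 128x128 at 0.8 mm/px, so the 20-55 mm adequacy band spans
    25-69 px — a usable range for desk-scale experiments.  The default
    abnormal fraction of 1/3 mirrors a 2:1 normal:abnormal case mix.
    """

    image_size: tuple[int, int] = (128, 128)      # (width, height) px
    pixel_spacing: tuple[float, float] = (0.8, 0.8)  # mm/px (x, y)
    n_images: int = 100
    abnormal_fraction: float = 1.0 / 3.0
    normal_band: tuple[float, float] = (20.0, 55.0)  # mm, tube-to-carina adequacy band
    # fractional-coordinate anatomy ranges (of width/height)
    carina_x_range: tuple[float, float] = (0.48, 0.52)
    carina_y_range: tuple[float, float] = (0.75, 0.80)
    clavicle_y_range: tuple[float, float] = (0.14, 0.19)
    clavicle_y_range_low: tuple[float, float] = (0.32, 0.40)  # raised-shoulder mode
    clavicle_x_offset_range: tuple[float, float] = (0.18, 0.28)
    noise_level: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.abnormal_fraction <= 1.0):
            raise ValueError("abnormal_fraction must be in [0, 1]")
        lo, hi = self.normal_band
        if not (0 < lo < hi):
            raise ValueError("normal_band must be a non-degenerate positive interval")


_ABNORMAL_MODES = ("too_deep", "too_shallow", "above_clavicle")
_MAX_TRIES = 200


def _sample_case(rng: np.random.Generator, cfg: PhantomConfig, mode: str):
    """Sample one case's landmark geometry; returns (KeypointSet, label, mode)."""
    w, h = cfg.image_size
    sx, sy = cfg.pixel_spacing
    lo, hi = cfg.normal_band

    carina_x = rng.uniform(*cfg.carina_x_range) * w
    carina_y = rng.uniform(*cfg.carina_y_range) * h

    clav_y_range = cfg.clavicle_y_range_low if mode == "above_clavicle" else cfg.clavicle_y_range
    mid_y = rng.uniform(*clav_y_range) * h
    off_l = rng.uniform(*cfg.clavicle_x_offset_range) * w
    off_r = rng.uniform(*cfg.clavicle_x_offset_range) * w
    jit = 0.015 * h
    left = (carina_x - off_l, mid_y + rng.uniform(-jit, jit))
    right = (carina_x + off_r, mid_y + rng.uniform(-jit, jit))
    mid_y_actual = 0.5 * (left[1] + right[1])

    for _ in range(_MAX_TRIES):
        if mode == "normal":
            d = rng.uniform(lo, hi)
            tube_y = carina_y - d / sy
            if tube_y < mid_y_actual + 2.0:  # must sit below the clavicular midpoint
                continue
        elif mode == "too_deep":
            d = rng.uniform(min(3.0, lo - 2.0), lo - 2.0)
            tube_y = carina_y - d / sy
        elif mode == "too_shallow":
            d = rng.uniform(hi + 3.0, hi + 14.0)
            tube_y = carina_y - d / sy
            if tube_y < 3.0:
                continue
        elif mode == "above_clavicle":
            upper = mid_y_actual - 3.0
            lower = carina_y - (hi - 1.0) / sy
            if upper <= lower:
                continue
            tube_y = rng.uniform(lower, upper)
        else:  # pragma: no cover
            raise ValueError(mode)
        tube_x = carina_x + rng.uniform(-1.5, 1.5)
        kps = KeypointSet(
            tube_end=(tube_x, tube_y),
            carina=(carina_x, carina_y),
            clavicle_left=left,
            clavicle_right=right,
        )
        if not kps.in_frame((w, h)):
            continue
        rule = RuleSet(lo, hi, use_clavicle=True, clavicle_threshold=0.0)
        label = classify(distances(kps, cfg.pixel_spacing), rule)
        expected = 1 if mode == "normal" else 0
        if label != expected:
            continue
        return kps, label, mode
    raise ValueError(
        f"phantom band configuration infeasible: could not realize mode {mode!r} "
        f"with band {cfg.normal_band} inside a {cfg.image_size} frame"
    )


def _sample_population(rng: np.random.Generator, cfg: PhantomConfig):
    cases = []
    abnormal_counter = 0
    for _ in range(cfg.n_images):
        if rng.random() < cfg.abnormal_fraction:
            mode = _ABNORMAL_MODES[abnormal_counter % len(_ABNORMAL_MODES)]
            abnormal_counter += 1
        else:
            mode = "normal"
        cases.append(_sample_case(rng, cfg, mode))
    return cases


def generate_coordinates_only(
    cfg: PhantomConfig, seed: int | None = None
) -> list[tuple[KeypointSet, tuple[float, float], int]]:
    """Sample landmark geometry without rendering (fast rules/ROC testing).

    Returns ``(keypoints, pixel_spacing, label)`` triples drawn from the
    same stream as :func:`generate`, so the two functions agree case by
    case for a given seed.
    """
    ss = np.random.SeedSequence(cfg.seed if seed is None else seed)
    coord_rng, _ = (np.random.default_rng(s) for s in ss.spawn(2))
    return [(kps, cfg.pixel_spacing, label) for kps, label, _mode in _sample_population(coord_rng, cfg)]


def generate(cfg: PhantomConfig, seed: int | None = None) -> list[AnnotatedImage]:
    """Render the phantom population as annotated images."""
    ss = np.random.SeedSequence(cfg.seed if seed is None else seed)
    coord_rng, render_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    cases = _sample_population(coord_rng, cfg)
    images = []
    for i, (kps, label, _mode) in enumerate(cases):
        pixels = _render(kps, cfg, render_rng)
        images.append(
            AnnotatedImage(
                image_id=f"phantom_{i:04d}",
                pixels=pixels,
                pixel_spacing=cfg.pixel_spacing,
                keypoints=kps,
                label=label,
            )
        )
    return images


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _paint_curve(img: np.ndarray, path: np.ndarray, width: float, value: float) -> None:
    """Overwrite pixels within ``width`` px of a densely sampled polyline."""
    h, w = img.shape
    x0 = max(int(path[:, 0].min() - width - 1), 0)
    x1 = min(int(path[:, 0].max() + width + 2), w)
    y0 = max(int(path[:, 1].min() - width - 1), 0)
    y1 = min(int(path[:, 1].max() + width + 2), h)
    if x1 <= x0 or y1 <= y0:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    pix = np.stack([xs.ravel(), ys.ravel()], axis=1).astype(np.float64)
    # min distance from each pixel to the sampled path
    d2 = ((pix[:, None, :] - path[None, :, :]) ** 2).sum(axis=2).min(axis=1)
    mask = (d2 <= width**2).reshape(y1 - y0, x1 - x0)
    img[y0:y1, x0:x1][mask] = value


def _sample_path(p0, p1, bend=0.0, n=None) -> np.ndarray:
    """Quadratic path from p0 to p1 with lateral ``bend`` at the start."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    if n is None:
        n = max(8, int(2 * np.abs(p1 - p0).max()))
    t = np.linspace(0.0, 1.0, n)[:, None]
    straight = (1 - t) * p0 + t * p1
    straight[:, 0] += bend * (1 - t[:, 0]) ** 2
    return straight


def _render(kps: KeypointSet, cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    w, h = cfg.image_size
    img = np.full((h, w), 0.50, dtype=np.float64)
    ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)

    # dark bilateral lung fields
    for cx_frac in (0.27, 0.73):
        cx, cy = cx_frac * w, 0.55 * h
        rx, ry = 0.19 * w, 0.30 * h
        mask = ((xs - cx) / rx) ** 2 + ((ys - cy) / ry) ** 2 <= 1.0
        img[mask] = 0.22

    carina = np.asarray(kps.carina)
    tube = np.asarray(kps.tube_end)

    # bright mediastinal band around the midline
    band_half = 0.09 * w
    band = np.abs(xs - carina[0]) <= band_half
    img[band] = 0.72

    # tracheal stripe down to the carina, then the bifurcation
    _paint_curve(img, _sample_path((carina[0], 0.0), carina), width=2.0, value=0.38)
    branch_len = 0.12 * h
    for sign in (-1.0, 1.0):
        end = carina + np.array([sign * branch_len * 0.8, branch_len])
        _paint_curve(img, _sample_path(carina, end), width=1.8, value=0.38)

    # clavicular arcs: medial endpoints are the landmarks
    for head, sign in ((np.asarray(kps.clavicle_left), -1.0), (np.asarray(kps.clavicle_right), 1.0)):
        outer = head + np.array([sign * 0.20 * w, -0.06 * h])
        _paint_curve(img, _sample_path(head, outer, bend=0.0), width=1.6, value=0.88)

    # radio-opaque tube terminating exactly at the tube-end landmark
    top = (tube[0] + rng.uniform(-2.0, 2.0), 0.0)
    _paint_curve(img, _sample_path(top, tube, bend=rng.uniform(-1.5, 1.5)), width=1.2, value=1.0)

    img += rng.normal(0.0, cfg.noise_level, size=img.shape)
    np.clip(img, 0.0, 1.0, out=img)
    return img
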