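"""Radiograph and annotation I/O with exact coordinate bookkeeping.

Coordinate convention used throughout the package: ``x`` is the column
index, ``y`` the row index, both 0-based and continuous (sub-pixel
positions allowed), origin at the top-left pixel centre.  Physical
distances are always derived in the *native* image frame using the
per-axis pixel spacing in mm/px, so anisotropic resizing to the working
resolution can never corrupt geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

KEYPOINT_NAMES = ("tube_end", "carina", "clavicle_left", "clavicle_right")

__all__ = [
    "KEYPOINT_NAMES",
    "KeypointSet",
    "FrameTransform",
    "AnnotatedImage",
    "read_image",
    "normalize_intensities",
    "to_working",
    "read_annotations",
    "write_annotations",
]


@dataclass(frozen=True)
class KeypointSet:
    """The four anatomical landmarks of one radiograph, in pixel coordinates.

    ``tube_end`` is the radiographic tip of the endotracheal tube,
    ``carina`` the tracheal bifurcation, and ``clavicle_left`` /
    ``clavicle_right`` the medial clavicular heads.
    """

    tube_end: tuple[float, float]
    carina: tuple[float, float]
    clavicle_left: tuple[float, float]
    clavicle_right: tuple[float, float]

    def __post_init__(self) -> None:
        for name in KEYPOINT_NAMES:
            p = getattr(self, name)
            if len(p) != 2 or not all(np.isfinite(c) for c in p):
                raise ValueError(f"keypoint {name!r} must be a finite (x, y) pair, got {p!r}")

    def as_array(self) -> np.ndarray:
        """Return the points as a (4, 2) float array in canonical order."""
        return np.array([getattr(self, n) for n in KEYPOINT_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "KeypointSet":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (4, 2):
            raise ValueError(f"expected (4, 2) array, got {arr.shape}")
        return cls(*(tuple(row) for row in arr))

    def transform(self, fn) -> "KeypointSet":
        """Apply ``fn((x, y)) -> (x, y)`` to every landmark."""
        return KeypointSet(*(tuple(fn(np.asarray(getattr(self, n), dtype=float))) for n in KEYPOINT_NAMES))

    def in_frame(self, size: tuple[int, int]) -> bool:
        """True if all landmarks lie within ``[0, width) x [0, height)``."""
        w, h = size
        a = self.as_array()
        return bool(np.all(a[:, 0] >= 0) and np.all(a[:, 0] < w) and np.all(a[:, 1] >= 0) and np.all(a[:, 1] < h))


@dataclass(frozen=True)
class FrameTransform:
    """Invertible affine map between two image frames: ``p' = p * scale + offset``."""

    scale: tuple[float, float]
    offset: tuple[float, float] = (0.0, 0.0)
    source_size: tuple[int, int] | None = None
    target_size: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.scale[0] == 0 or self.scale[1] == 0:
            raise ValueError("FrameTransform scale components must be nonzero")

    def map(self, point: Sequence[float]) -> np.ndarray:
        p = np.asarray(point, dtype=float)
        return p * np.asarray(self.scale) + np.asarray(self.offset)

    def unmap(self, point: Sequence[float]) -> np.ndarray:
        p = np.asarray(point, dtype=float)
        return (p - np.asarray(self.offset)) / np.asarray(self.scale)

    def map_keypoints(self, pts: KeypointSet) -> KeypointSet:
        return pts.transform(self.map)

    def unmap_keypoints(self, pts: KeypointSet) -> KeypointSet:
        return pts.transform(self.unmap)

    @property
    def inverse(self) -> "FrameTransform":
        sx, sy = self.scale
        ox, oy = self.offset
        return FrameTransform(
            scale=(1.0 / sx, 1.0 / sy),
            offset=(-ox / sx, -oy / sy),
            source_size=self.target_size,
            target_size=self.source_size,
        )

    @classmethod
    def identity(cls, size: tuple[int, int] | None = None) -> "FrameTransform":
        return cls(scale=(1.0, 1.0), offset=(0.0, 0.0), source_size=size, target_size=size)


@dataclass
class AnnotatedImage:
    """One radiograph with its pixel spacing and (optional) annotation.

    Parameters
    ----------
    image_id : str
        Opaque identifier; used to match predictions against annotations.
    pixels : ndarray
        2-D intensity grid (rows x cols), values in [0, 1].
    pixel_spacing : (float, float)
        (mm per pixel along x, mm per pixel along y); both > 0.
    keypoints : KeypointSet, optional
        Landmarks in native pixel coordinates.
    label : int, optional
        1 = adequate tube position, 0 = abnormal.
    """

    image_id: str
    pixels: np.ndarray
    pixel_spacing: tuple[float, float]
    keypoints: KeypointSet | None = None
    label: int | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grid")
        if float(self.pixels.min(initial=0.0)) < 0.0 or float(self.pixels.max(initial=0.0)) > 1.0 + 1e-6:
            raise ValueError("intensities must be normalized to [0, 1]")
        if not (self.pixel_spacing[0] > 0 and self.pixel_spacing[1] > 0):
            raise ValueError("pixel_spacing components must be > 0")
        if self.keypoints is not None and not self.keypoints.in_frame(self.native_size):
            raise ValueError(f"keypoints of {self.image_id!r} fall outside the image frame")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError("label must be 0, 1 or None")

    @property
    def native_size(self) -> tuple[int, int]:
        """(width, height) in pixels."""
        h, w = self.pixels.shape
        return (w, h)


def normalize_intensities(raw: np.ndarray) -> np.ndarray:
    """Min-max normalize an intensity grid to [0, 1].

    A constant image maps to all zeros (the degenerate zero-range case),
    so the operation is always defined.
    """
    raw = np.asarray(raw, dtype=np.float64)
    lo = float(raw.min())
    hi = float(raw.max())
    if hi == lo:
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo)


def _dicom_spacing(ds) -> tuple[float, float] | None:
    # DICOM stores (row spacing, column spacing) = (y, x); we return (x, y).
    # ImagerPixelSpacing is preferred for projection radiography.
    for attr in ("ImagerPixelSpacing", "PixelSpacing"):
        value = getattr(ds, attr, None)
        if value is not None:
            sy, sx = float(value[0]), float(value[1])
            return (sx, sy)
    return None


def read_image(
    path: str | Path,
    spacing_override: tuple[float, float] | None = None,
    image_id: str | None = None,
) -> AnnotatedImage:
    """Read a DICOM or PNG radiograph into an :class:`AnnotatedImage`.

    Intensities are min-max normalized to [0, 1].  Pixel spacing is taken
    from DICOM metadata when available, else from ``spacing_override``;
    a missing spacing is an error, never a silent default, because every
    downstream clinical distance depends on it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom", ""):
        import pydicom

        ds = pydicom.dcmread(str(path))
        raw = ds.pixel_array.astype(np.float64)
        spacing = _dicom_spacing(ds) or spacing_override
    elif suffix == ".png":
        import imageio.v3 as iio

        raw = np.asarray(iio.imread(str(path)))
        if raw.ndim == 3:  # collapse accidental RGB to grayscale
            raw = raw.mean(axis=2)
        spacing = spacing_override
    else:
        raise IOError(f"unsupported image format: {path.name} (expected DICOM or PNG)")
    if raw.ndim != 2:
        raise IOError(f"{path.name}: expected a single-frame 2-D image, got shape {raw.shape}")
    if spacing is None:
        raise ValueError(
            f"{path.name}: no pixel spacing in metadata and no spacing_override given; "
            "mm distances would be undefined"
        )
    return AnnotatedImage(
        image_id=image_id or path.stem,
        pixels=normalize_intensities(raw),
        pixel_spacing=(float(spacing[0]), float(spacing[1])),
    )


def to_working(
    img: AnnotatedImage, working_size: tuple[int, int] = (512, 512)
) -> tuple[np.ndarray, FrameTransform]:
    """Resize to the working resolution used for modelling.

    Non-square images are stretched anisotropically (per-axis scale factors
    are recorded in the returned :class:`FrameTransform`); mm distances are
    always computed in the native frame so anisotropy is harmless here.
    Bilinear interpolation.
    """
    tw, th = working_size
    w, h = img.native_size
    if (w, h) == (tw, th):
        grid = np.asarray(img.pixels, dtype=np.float64)
    else:
        grid = _sk_resize(
            np.asarray(img.pixels, dtype=np.float64),
            (th, tw),
            order=1,
            mode="edge",
            anti_aliasing=False,
            preserve_range=True,
        )
    transform = FrameTransform(
        scale=(tw / w, th / h), offset=(0.0, 0.0), source_size=(w, h), target_size=(tw, th)
    )
    return grid, transform


# ---------------------------------------------------------------------------
# Annotation files: JSON-lines, one record per image.
# Fields: image_id, points {name: [x, y]}, optional label (0/1),
# optional spacing_mm [sx, sy].
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotationRecord:
    image_id: str
    keypoints: KeypointSet
    label: int | None = None
    spacing_mm: tuple[float, float] | None = None


def _parse_record(obj: dict, index: int) -> AnnotationRecord:
    if "image_id" not in obj:
        raise ValueError(f"record {index}: missing 'image_id'")
    points = obj.get("points")
    if not isinstance(points, dict):
        raise ValueError(f"record {index}: missing or malformed 'points' object")
    coords = {}
    for name in KEYPOINT_NAMES:
        if name not in points:
            raise ValueError(f"record {index}: missing point {name!r}")
        xy = points[name]
        try:
            coords[name] = (float(xy[0]), float(xy[1]))
        except (TypeError, ValueError, IndexError) as exc:
            raise ValueError(f"record {index}: non-numeric coordinate for {name!r}") from exc
    label = obj.get("label")
    if label is not None:
        label = int(label)
        if label not in (0, 1):
            raise ValueError(f"record {index}: label must be 0 or 1")
    spacing = obj.get("spacing_mm")
    if spacing is not None:
        spacing = (float(spacing[0]), float(spacing[1]))
    return AnnotationRecord(str(obj["image_id"]), KeypointSet(**coords), label, spacing)


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Read a JSON-lines annotation file; empty file yields an empty list."""
    records = []
    with open(path, "r", encoding="utf-8") as fh:
        for index, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"record {index}: invalid JSON") from exc
            records.append(_parse_record(obj, index))
    return records


def write_annotations(path: str | Path, records: Iterable[AnnotationRecord]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            obj: dict = {
                "image_id": rec.image_id,
                "points": {n: list(map(float, getattr(rec.keypoints, n))) for n in KEYPOINT_NAMES},
            }
            if rec.label is not None:
                obj["label"] = int(rec.label)
            if rec.spacing_mm is not None:
                obj["spacing_mm"] = [float(rec.spacing_mm[0]), float(rec.spacing_mm[1])]
            fh.write(json.dumps(obj) + "\n")
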