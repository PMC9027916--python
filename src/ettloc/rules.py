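"""Clinical distance rules for endotracheal-tube placement.

From the four landmarks two clinical quantities are derived in the native
image frame:

* **tube-to-carina distance** — signed craniocaudal (vertical) separation
  in mm between the tube tip and the carina; positive when the tube end
  lies above (cranial to) the carina.  Adequacy is an interval criterion
  on this value, e.g. 20 mm <= d < 55 mm.
* **tube-to-clavicle distance** — signed vertical separation in mm between
  the tube tip and the midpoint of the two clavicular heads; >= 0 means
  the tube end lies below (caudal to) the midpoint.

Signed vertical distances (rather than Euclidean) are the default because
the clavicle rule's "below the midpoint" semantics and the failure mode of
a tube at or past the carina both require a sign; a Euclidean mode is
available for sensitivity analysis.

A :class:`RuleSet` is a single binary criterion; :class:`EnsembleGrid`
averages the binary calls of a grid of 1936 rule variants into a weighted
appropriateness score in [0, 1], the quantity used for ROC analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import KeypointSet

__all__ = [
    "DistanceReport",
    "RuleSet",
    "EnsembleGrid",
    "NAMED_RULES",
    "distances",
    "classify",
    "ensemble_score",
    "grid_size",
    "consensus_keypoints",
]


@dataclass(frozen=True)
class DistanceReport:
    """Clinical distances for one image, in native-frame millimetres."""

    tube_to_carina: float          # mm; positive = tube end above carina
    clav_midpoint: tuple[float, float]  # px, native frame
    tube_to_clavicle: float        # mm; >= 0 = tube end below the clavicular midpoint


@dataclass(frozen=True)
class RuleSet:
    """One appropriateness criterion.

    Normal (1) iff ``carina_low <= tube_to_carina < carina_high`` and, when
    the clavicle clause is enabled, ``tube_to_clavicle >= clavicle_threshold``.
    The interval is closed below and open above, following the convention
    the thresholds are quoted in (``30 <= d < 70``).
    """

    carina_low: float
    carina_high: float
    use_clavicle: bool = False
    clavicle_threshold: float = 0.0

    def __post_init__(self) -> None:
        if not self.carina_low < self.carina_high:
            raise ValueError("carina_low must be < carina_high")


#: The four named tube-to-carina criteria evaluated in the field
#: (carina clause only; add use_clavicle=True for the combined variants).
NAMED_RULES: dict[str, RuleSet] = {
    "30-70": RuleSet(30.0, 70.0),
    "30-60": RuleSet(30.0, 60.0),
    "20-60": RuleSet(20.0, 60.0),
    "20-55": RuleSet(20.0, 55.0),
}


@dataclass(frozen=True)
class EnsembleGrid:
    """Grid of rule variants for the weighted appropriateness score.

    Defaults: carina lower bound 20..30 mm, upper bound 55..70 mm, clavicle
    threshold -5..5 mm, all at 1 mm steps — 11 x 16 x 11 = 1936
    combinations.  The clavicle clause is always active inside the
    ensemble; its threshold is one of the grid axes.
    """

    carina_low_values: tuple[float, ...] = tuple(float(v) for v in range(20, 31))
    carina_high_values: tuple[float, ...] = tuple(float(v) for v in range(55, 71))
    clavicle_threshold_values: tuple[float, ...] = tuple(float(v) for v in range(-5, 6))

    def __post_init__(self) -> None:
        if not (self.carina_low_values and self.carina_high_values and self.clavicle_threshold_values):
            raise ValueError("every grid axis needs at least one value")

    def rules(self) -> Iterable[RuleSet]:
        """Enumerate every rule combination (clavicle clause on)."""
        for low in self.carina_low_values:
            for high in self.carina_high_values:
                for thr in self.clavicle_threshold_values:
                    yield RuleSet(low, high, use_clavicle=True, clavicle_threshold=thr)


def grid_size(grid: EnsembleGrid) -> int:
    """Number of rule combinations in the grid."""
    return (
        len(grid.carina_low_values)
        * len(grid.carina_high_values)
        * len(grid.clavicle_threshold_values)
    )


def distances(
    points: KeypointSet,
    spacing: tuple[float, float],
    euclidean: bool = False,
) -> DistanceReport:
    """Compute the clinical distance report from native-frame landmarks.

    ``spacing`` is (mm/px along x, mm/px along y).  Vertical separations use
    the y spacing, so anisotropic detectors are handled exactly.  With
    ``euclidean=True`` the tube-to-carina magnitude is the Euclidean mm
    distance, signed by the vertical direction (sensitivity-analysis mode).
    """
    sx, sy = spacing
    if sx <= 0 or sy <= 0:
        raise ValueError("pixel spacing must be positive")
    tube = np.asarray(points.tube_end, dtype=float)
    carina = np.asarray(points.carina, dtype=float)
    left = np.asarray(points.clavicle_left, dtype=float)
    right = np.asarray(points.clavicle_right, dtype=float)
    mid = 0.5 * (left + right)
    if euclidean:
        delta_mm = (carina - tube) * (sx, sy)
        t2c = float(np.sign(delta_mm[1]) * np.hypot(*delta_mm))
    else:
        t2c = float((carina[1] - tube[1]) * sy)
    t2clav = float((tube[1] - mid[1]) * sy)
    return DistanceReport(tube_to_carina=t2c, clav_midpoint=(float(mid[0]), float(mid[1])), tube_to_clavicle=t2clav)


def classify(report: DistanceReport, rule: RuleSet) -> int:
    """Binary appropriateness call under one rule set (1 = adequate)."""
    ok = rule.carina_low <= report.tube_to_carina < rule.carina_high
    if rule.use_clavicle:
        ok = ok and report.tube_to_clavicle >= rule.clavicle_threshold
    return int(ok)


def ensemble_score(report: DistanceReport, grid: EnsembleGrid | None = None) -> float:
    """Weighted appropriateness score: mean binary call over the grid.

    Because the three clauses act independently on the two distances, the
    passing count factorizes into a product of per-axis counts; the result
    is exactly ``(number of passing combinations) / grid_size``.
    """
    if grid is None:
        grid = EnsembleGrid()
    d = report.tube_to_carina
    t = report.tube_to_clavicle
    n_low = int(np.sum(np.asarray(grid.carina_low_values) <= d))
    n_high = int(np.sum(d < np.asarray(grid.carina_high_values)))
    n_thr = int(np.sum(t >= np.asarray(grid.clavicle_threshold_values)))
    return (n_low * n_high * n_thr) / grid_size(grid)


def consensus_keypoints(annotations: Sequence[KeypointSet]) -> KeypointSet:
    """Component-wise mean of several annotators' keypoint sets."""
    if not annotations:
        raise ValueError("need at least one annotation")
    stacked = np.stack([a.as_array() for a in annotations])
    return KeypointSet.from_array(stacked.mean(axis=0))
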