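"""Performance statistics: landmark error, sensitivity/specificity, ROC.

The ROC sweep calls a case positive when ``score >= threshold`` and sweeps
the distinct score values plus a +inf sentinel, so (0, 0) is always on the
curve.  AUC is computed by the trapezoidal rule, which across tied-score
blocks is equivalent to the Mann-Whitney pair-count estimator with ties
counted 1/2 — relevant here because the ensemble score takes a finite set
of rational values and ties are common.  The reported operating point
maximizes the Youden index J = sensitivity + specificity - 1, ties broken
toward higher sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io import KEYPOINT_NAMES, KeypointSet

__all__ = ["ScoredCase", "RocSummary", "mean_absolute_distance", "sens_spec", "roc"]


@dataclass(frozen=True)
class ScoredCase:
    """One image's appropriateness score (ensemble or binary) and truth label."""

    image_id: str
    score: float
    truth: int

    def __post_init__(self) -> None:
        if self.truth not in (0, 1):
            raise ValueError("truth must be 0 or 1")


@dataclass(frozen=True)
class RocSummary:
    thresholds: tuple[float, ...]
    fpr: tuple[float, ...]
    tpr: tuple[float, ...]
    auc: float
    youden_threshold: float
    youden_sensitivity: float  # percent
    youden_specificity: float  # percent


def mean_absolute_distance(
    pred: Mapping[str, KeypointSet],
    truth: Mapping[str, KeypointSet],
    spacings: Mapping[str, tuple[float, float]],
) -> dict[str, float]:
    """Per-landmark mean Euclidean error in mm over matched images.

    ``pred`` and ``truth`` must cover the same image ids; ``spacings`` maps
    each id to its (mm/px x, mm/px y) so errors are physical distances in
    the native frame.
    """
    if set(pred) != set(truth):
        missing = set(pred) ^ set(truth)
        raise ValueError(f"prediction/truth id mismatch: {sorted(missing)[:5]}")
    if not pred:
        raise ValueError("no images to evaluate")
    sums = {name: 0.0 for name in KEYPOINT_NAMES}
    for image_id in pred:
        sx, sy = spacings[image_id]
        dp = pred[image_id].as_array() - truth[image_id].as_array()
        err_mm = np.hypot(dp[:, 0] * sx, dp[:, 1] * sy)
        for name, e in zip(KEYPOINT_NAMES, err_mm):
            sums[name] += float(e)
    n = len(pred)
    return {name: sums[name] / n for name in KEYPOINT_NAMES}


def sens_spec(
    truths: Sequence[int], calls: Sequence[int]
) -> tuple[float | None, float | None]:
    """Sensitivity and specificity in percent.

    An index whose class is absent from the truths (no positives, or no
    negatives) is not applicable and reported as ``None``.
    """
    truths = np.asarray(truths, dtype=int)
    calls = np.asarray(calls, dtype=int)
    if truths.size == 0:
        raise ValueError("empty input")
    if truths.shape != calls.shape:
        raise ValueError("truths and calls must have equal length")
    tp = int(np.sum((truths == 1) & (calls == 1)))
    fn = int(np.sum((truths == 1) & (calls == 0)))
    tn = int(np.sum((truths == 0) & (calls == 0)))
    fp = int(np.sum((truths == 0) & (calls == 1)))
    sensitivity = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else None
    specificity = 100.0 * tn / (tn + fp) if (tn + fp) > 0 else None
    return sensitivity, specificity


def roc(cases: Sequence[ScoredCase]) -> RocSummary:
    """ROC sweep, trapezoidal AUC and the Youden-optimal operating point."""
    if not cases:
        raise ValueError("empty input")
    scores = np.array([c.score for c in cases], dtype=float)
    truths = np.array([c.truth for c in cases], dtype=int)
    n_pos = int(truths.sum())
    n_neg = int(truths.size - n_pos)
    if n_pos == 0:
        raise ValueError("no positive cases: ROC undefined")
    if n_neg == 0:
        raise ValueError("no negative cases: ROC undefined")

    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    fpr = np.empty(thresholds.size)
    tpr = np.empty(thresholds.size)
    for i, thr in enumerate(thresholds):
        called = scores >= thr
        tpr[i] = np.sum(called & (truths == 1)) / n_pos
        fpr[i] = np.sum(called & (truths == 0)) / n_neg
    auc = float(np.trapezoid(tpr, fpr))

    youden = tpr - fpr
    best = np.flatnonzero(youden == youden.max())
    # ties broken toward higher sensitivity
    best_i = best[np.argmax(tpr[best])]
    return RocSummary(
        thresholds=tuple(float(t) for t in thresholds),
        fpr=tuple(map(float, fpr)),
        tpr=tuple(map(float, tpr)),
        auc=auc,
        youden_threshold=float(thresholds[best_i]),
        youden_sensitivity=float(100.0 * tpr[best_i]),
        youden_specificity=float(100.0 * (1.0 - fpr[best_i])),
    )
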