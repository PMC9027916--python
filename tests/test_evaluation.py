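"""Landmark error, sensitivity/specificity and ROC statistics."""

import numpy as np
import pytest

from ettloc.evaluation import RocSummary, ScoredCase, mean_absolute_distance, roc, sens_spec
from ettloc.io import KEYPOINT_NAMES, KeypointSet


def mann_whitney_auc(scores, truths):
    """Independent all-pairs oracle with ties counted 1/2."""
    pos = [s for s, t in zip(scores, truths) if t == 1]
    neg = [s for s, t in zip(scores, truths) if t == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def _cases(scores, truths):
    return [ScoredCase(f"c{i}", s, t) for i, (s, t) in enumerate(zip(scores, truths))]


class TestMeanAbsoluteDistance:
    def _kps(self, offset=(0.0, 0.0)):
        base = np.array([[10, 10], [20, 20], [30, 30], [40, 40]], dtype=float)
        return KeypointSet.from_array(base + np.asarray(offset))

    def test_identical_predictions_zero_error(self):
        pred = {"a": self._kps()}
        out = mean_absolute_distance(pred, pred, {"a": (0.7, 0.7)})
        assert all(v == 0.0 for v in out.values())

    def test_three_four_five_triangle(self):
        pred = {"a": self._kps((3.0, 4.0))}
        truth = {"a": self._kps()}
        out = mean_absolute_distance(pred, truth, {"a": (1.0, 1.0)})
        assert out["tube_end"] == pytest.approx(5.0)

    def test_mean_over_images(self):
        pred = {"a": self._kps((2.0, 0.0)), "b": self._kps((4.0, 0.0))}
        truth = {"a": self._kps(), "b": self._kps()}
        out = mean_absolute_distance(pred, truth, {"a": (1.0, 1.0), "b": (1.0, 1.0)})
        assert out["carina"] == pytest.approx(3.0)

    def test_spacing_converts_px_to_mm(self):
        pred = {"a": self._kps((0.0, 10.0))}
        truth = {"a": self._kps()}
        out = mean_absolute_distance(pred, truth, {"a": (1.0, 0.5)})
        assert out["tube_end"] == pytest.approx(5.0)

    def test_id_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            mean_absolute_distance({"a": self._kps()}, {"b": self._kps()}, {})


class TestSensSpec:
    def test_all_correct(self):
        assert sens_spec([1, 1, 0, 0], [1, 1, 0, 0]) == (100.0, 100.0)

    def test_counts(self):
        # 14 positives with 10 called positive; 26 negatives with 24 called negative
        truths = [1] * 14 + [0] * 26
        calls = [1] * 10 + [0] * 4 + [0] * 24 + [1] * 2
        sens, spec = sens_spec(truths, calls)
        assert sens == pytest.approx(100 * 10 / 14)
        assert spec == pytest.approx(100 * 24 / 26)

    def test_specificity_na_without_negatives(self):
        sens, spec = sens_spec([1, 1, 1], [1, 0, 1])
        assert spec is None
        assert sens == pytest.approx(100 * 2 / 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sens_spec([], [])


class TestRoc:
    def test_perfect_separation(self):
        summary = roc(_cases([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]))
        assert summary.auc == pytest.approx(1.0)
        assert summary.youden_sensitivity == pytest.approx(100.0)
        assert summary.youden_specificity == pytest.approx(100.0)

    def test_constant_scores_chance_auc(self):
        summary = roc(_cases([0.5] * 10, [1, 0] * 5))
        assert summary.auc == pytest.approx(0.5)

    def test_curve_anchored_and_monotone(self, rng):
        cases = _cases(rng.random(60), rng.integers(0, 2, 60).tolist() or [1])
        truths = [c.truth for c in cases]
        if len(set(truths)) < 2:
            cases[0] = ScoredCase("c0", 0.5, 1 - truths[1])
        summary = roc(cases)
        assert summary.fpr[0] == 0.0 and summary.tpr[0] == 0.0
        assert summary.fpr[-1] == 1.0 and summary.tpr[-1] == 1.0
        assert all(a <= b for a, b in zip(summary.fpr, summary.fpr[1:]))
        assert all(a <= b for a, b in zip(summary.tpr, summary.tpr[1:]))

    def test_auc_equals_mann_whitney_with_ties(self, rng):
        # discrete scores force ties, the regime the ensemble operates in
        scores = rng.integers(0, 8, 100) / 7.0
        truths = rng.integers(0, 2, 100)
        truths[0], truths[1] = 0, 1
        summary = roc(_cases(scores, truths))
        assert summary.auc == pytest.approx(mann_whitney_auc(scores, truths), abs=1e-12)

    def test_auc_matches_sklearn(self, rng):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        scores = rng.random(80)
        truths = rng.integers(0, 2, 80)
        truths[0], truths[1] = 0, 1
        summary = roc(_cases(scores, truths))
        assert summary.auc == pytest.approx(sklearn_metrics.roc_auc_score(truths, scores), abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self, rng):
        scores = rng.random(50)
        truths = rng.integers(0, 2, 50)
        truths[0], truths[1] = 0, 1
        a1 = roc(_cases(scores, truths)).auc
        a2 = roc(_cases(np.exp(3 * scores), truths)).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_label_reversal_maps_auc(self, rng):
        scores = rng.random(50)
        truths = rng.integers(0, 2, 50)
        truths[0], truths[1] = 0, 1
        a1 = roc(_cases(scores, truths)).auc
        a2 = roc(_cases(scores, 1 - truths)).auc
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    def test_youden_point_is_roc_vertex(self, rng):
        scores = rng.integers(0, 5, 60) / 4.0
        truths = rng.integers(0, 2, 60)
        truths[0], truths[1] = 0, 1
        summary = roc(_cases(scores, truths))
        vertices = set(zip(summary.tpr, summary.fpr))
        point = (summary.youden_sensitivity / 100.0, 1.0 - summary.youden_specificity / 100.0)
        assert any(abs(point[0] - t) < 1e-12 and abs(point[1] - f) < 1e-12 for t, f in vertices)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            roc(_cases([0.1, 0.9], [1, 1]))
        with pytest.raises(ValueError, match="positive"):
            roc(_cases([0.1, 0.9], [0, 0]))
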