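"""Model/Results interface over the full placement-assessment pipeline.

:class:`TwoStageKeypointModel` is built from a list of annotated images
(typically phantoms or a hospital training set); :meth:`fit` trains both
detection stages and returns a :class:`KeypointResults` object carrying
the trained networks, loss histories, and methods to predict landmarks,
assess placement appropriateness and evaluate against held-out truth.

Example
-------
>>> from ettloc import phantom, model
>>> imgs = phantom.generate(phantom.PhantomConfig(n_images=40, seed=0))
>>> m = model.TwoStageKeypointModel(imgs, epochs=20, seed=0)
>>> res = m.fit()
>>> pred = res.predict(imgs[0])          # KeypointSet, native frame
>>> print(res.summary())                  # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .augment import AugmentConfig
from .evaluation import RocSummary, ScoredCase, mean_absolute_distance, roc, sens_spec
from .heatmap import HeatmapConfig
from .io import KEYPOINT_NAMES, AnnotatedImage, KeypointSet
from .nn import KeypointNetwork, NetConfig, TrainConfig, predict as _predict, train_stage
from .rules import EnsembleGrid, RuleSet, classify, distances, ensemble_score

__all__ = ["TwoStageKeypointModel", "KeypointResults"]


class TwoStageKeypointModel:
    """Two-stage heatmap landmark detector plus distance-rule assessor.

    Parameters
    ----------
    images : sequence of AnnotatedImage
        Training images with four-landmark annotations.
    net_config, train_config, augment_config, heatmap_config :
        Architecture, optimization, augmentation and target-surface
        settings; sensible defaults are derived from the training images'
        size when omitted.
    epochs, seed :
        Convenience overrides applied to ``train_config``.
    crop_margin : float
        Margin fraction of the stage-2 refinement window.
    """

    def __init__(
        self,
        images: Sequence[AnnotatedImage],
        net_config: NetConfig | None = None,
        train_config: TrainConfig | None = None,
        augment_config: AugmentConfig | None = None,
        heatmap_config: HeatmapConfig | None = None,
        epochs: int | None = None,
        seed: int | None = None,
        crop_margin: float = 0.25,
    ):
        if not images:
            raise ValueError("need at least one training image")
        for img in images:
            if img.keypoints is None:
                raise ValueError(f"training image {img.image_id!r} lacks keypoints")
        self.images = list(images)
        if net_config is None:
            # default the working size to the (common) native size of the data
            w, h = self.images[0].native_size
            net_config = NetConfig(encoder="small", working_size=(w, h))
        self.net_config = net_config
        train_config = train_config or TrainConfig()
        if epochs is not None:
            train_config = replace(train_config, epochs=epochs)
        if seed is not None:
            train_config = replace(train_config, seed=seed)
        self.train_config = train_config
        self.augment_config = augment_config if augment_config is not None else AugmentConfig()
        self.heatmap_config = heatmap_config or HeatmapConfig(working_size=net_config.working_size)
        self.crop_margin = crop_margin

    def fit(self, stages: tuple[int, ...] = (1, 2), callback=None) -> "KeypointResults":
        """Train the requested stages (each trained separately) and return results."""
        nets: dict[int, KeypointNetwork] = {}
        histories: dict[int, list[float]] = {}
        for stage in stages:
            cb = (lambda e, l, s=stage: callback(s, e, l)) if callback else None
            net, hist = train_stage(
                self.images, stage, self.net_config, self.train_config,
                self.augment_config, self.heatmap_config, self.crop_margin, callback=cb,
            )
            nets[stage] = net
            histories[stage] = hist
        return KeypointResults(self, nets.get(1), nets.get(2), histories)


@dataclass
class KeypointResults:
    """Fitted two-stage detector: predictions, assessment, evaluation."""

    model: TwoStageKeypointModel
    stage1: KeypointNetwork | None
    stage2: KeypointNetwork | None
    loss_history: dict[int, list[float]]

    def predict_full(self, img: AnnotatedImage, use_stage2: bool = True):
        if self.stage1 is None:
            raise ValueError("stage 1 was not fitted")
        return _predict(
            img, self.stage1, self.stage2 if use_stage2 else None,
            self.model.heatmap_config, self.model.crop_margin,
        )

    def predict(self, img: AnnotatedImage, use_stage2: bool = True) -> KeypointSet:
        """Predicted landmarks in the native frame of ``img``."""
        return self.predict_full(img, use_stage2).keypoints

    def assess(
        self,
        img: AnnotatedImage,
        rule: RuleSet | None = None,
        grid: EnsembleGrid | None = None,
        keypoints: KeypointSet | None = None,
    ) -> dict:
        """Distances, single-rule call and ensemble score for one image.

        ``keypoints`` overrides the detector (e.g. to assess annotated
        points); otherwise the fitted detector is run.
        """
        kps = keypoints if keypoints is not None else self.predict(img)
        report = distances(kps, img.pixel_spacing)
        rule = rule or RuleSet(20.0, 55.0, use_clavicle=True)
        return {
            "image_id": img.image_id,
            "tube_to_carina_mm": report.tube_to_carina,
            "tube_to_clavicle_mm": report.tube_to_clavicle,
            "rule_call": classify(report, rule),
            "ensemble_score": ensemble_score(report, grid),
        }

    def evaluate(
        self,
        test_images: Sequence[AnnotatedImage],
        rule: RuleSet | None = None,
        grid: EnsembleGrid | None = None,
    ) -> dict:
        """Landmark error, rule sensitivity/specificity and ensemble ROC.

        Every test image needs keypoints; label-dependent statistics are
        computed over the labelled subset and ROC requires both classes.
        """
        rule = rule or RuleSet(20.0, 55.0, use_clavicle=True)
        preds, truths, spacings = {}, {}, {}
        pred1 = {}
        cases, rule_truths, rule_calls = [], [], []
        for img in test_images:
            if img.keypoints is None:
                raise ValueError(f"test image {img.image_id!r} lacks ground-truth keypoints")
            full = self.predict_full(img)
            preds[img.image_id] = full.keypoints
            pred1[img.image_id] = full.stage1_keypoints
            truths[img.image_id] = img.keypoints
            spacings[img.image_id] = img.pixel_spacing
            if img.label is not None:
                report = distances(full.keypoints, img.pixel_spacing)
                cases.append(ScoredCase(img.image_id, ensemble_score(report, grid), img.label))
                rule_truths.append(img.label)
                rule_calls.append(classify(report, rule))
        out = {
            "mad_mm": mean_absolute_distance(preds, truths, spacings),
            "mad_mm_stage1": mean_absolute_distance(pred1, truths, spacings),
            "n_images": len(preds),
        }
        if rule_truths:
            sens, spec = sens_spec(rule_truths, rule_calls)
            out["rule_sensitivity_pct"] = sens
            out["rule_specificity_pct"] = spec
        if cases and len({c.truth for c in cases}) == 2:
            out["roc"] = roc(cases)
            out["cases"] = cases
        return out

    def summary(self, evaluation: dict | None = None) -> str:
        """Human-readable fit summary, statsmodels-style."""
        lines = ["Two-stage keypoint placement model", "=" * 36]
        cfg = self.model.net_config
        lines.append(f"encoder: {cfg.encoder}   working size: {cfg.working_size}")
        tc = self.model.train_config
        lines.append(f"optimizer: Adam lr={tc.learning_rate} batch={tc.batch_size} "
                     f"epochs={tc.epochs} seed={tc.seed}")
        lines.append(f"training images: {len(self.model.images)}")
        for stage, hist in sorted(self.loss_history.items()):
            if hist:
                lines.append(f"stage {stage}: loss {hist[0]:.5f} -> {hist[-1]:.5f} "
                             f"({len(hist)} epochs)")
        if evaluation:
            lines.append("-" * 36)
            for name in KEYPOINT_NAMES:
                lines.append(f"MAD {name:>15}: {evaluation['mad_mm'][name]:6.2f} mm")
            if "rule_sensitivity_pct" in evaluation:
                s = evaluation["rule_sensitivity_pct"]
                p = evaluation["rule_specificity_pct"]
                fmt = lambda v: "N/A" if v is None else f"{v:.2f}%"
                lines.append(f"rule 20-55+clavicle: sensitivity {fmt(s)}, specificity {fmt(p)}")
            if "roc" in evaluation:
                r: RocSummary = evaluation["roc"]
                lines.append(f"ensemble AUC: {r.auc:.4f}  Youden point: "
                             f"sens {r.youden_sensitivity:.2f}%, spec {r.youden_specificity:.2f}%")
        return "\n".join(lines)
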