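"""The reproducible desk-scale phantom study.

This is the package's reference experiment: generate a phantom training
population and a held-out test population, train both detection stages of
the small topology from scratch, and measure landmark recovery, rule
agreement with the generated labels, and the ensemble-score ROC.

Problem sizes are deliberately desk-scale — 200 training and 50 test
phantoms at 128x128 px (0.8 mm/px), 50 epochs — so the whole study runs
on a single CPU in minutes.  The learning rate is raised to 3e-3 for
these short from-scratch runs; the 1e-4 default of
:class:`~ettloc.nn.TrainConfig` is tuned for long schedules with a large
pretrained encoder.
"""

from __future__ import annotations

import numpy as np

from . import phantom
from .evaluation import sens_spec
from .model import TwoStageKeypointModel
from .nn import NetConfig, TrainConfig
from .rules import EnsembleGrid, RuleSet, classify, distances, grid_size

__all__ = ["run_desk_study"]


def run_desk_study(
    seed: int = 1,
    n_train: int = 200,
    n_test: int = 50,
    epochs: int = 50,
    learning_rate: float = 3e-3,
    image_size: tuple[int, int] = (128, 128),
    pixel_spacing: float = 0.8,
    progress=None,
) -> dict:
    """Run the full study; returns a flat dict of its headline numbers.

    ``seed`` drives phantom sampling (test population uses a derived
    stream), weight initialization, shuffling and augmentation.
    """
    seed = int(seed) % (2**31 - 10_000)
    spacing = (pixel_spacing, pixel_spacing)
    train_cfg_ph = phantom.PhantomConfig(
        image_size=image_size, pixel_spacing=spacing, n_images=n_train, seed=seed
    )
    test_cfg_ph = phantom.PhantomConfig(
        image_size=image_size, pixel_spacing=spacing, n_images=n_test, seed=seed + 9_001
    )
    train_imgs = phantom.generate(train_cfg_ph)
    test_imgs = phantom.generate(test_cfg_ph)

    model = TwoStageKeypointModel(
        train_imgs,
        net_config=NetConfig(encoder="small", working_size=image_size),
        train_config=TrainConfig(learning_rate=learning_rate, epochs=epochs, seed=seed),
    )
    results = model.fit(callback=progress)
    evaluation = results.evaluate(test_imgs)

    rule = RuleSet(20.0, 55.0, use_clavicle=True)
    grid = EnsembleGrid()

    # appropriateness from the TRUE keypoints: the label-consistency check
    true_truths = [img.label for img in test_imgs]
    true_calls = [classify(distances(img.keypoints, img.pixel_spacing), rule) for img in test_imgs]
    true_sens, true_spec = sens_spec(true_truths, true_calls)

    mad = evaluation["mad_mm"]
    mad1 = evaluation["mad_mm_stage1"]
    mean_err_px = float(np.mean([mad[n] for n in mad])) / pixel_spacing
    tube_carina_px = float(np.mean([mad["tube_end"], mad["carina"]])) / pixel_spacing
    tube_carina_px_stage1 = float(np.mean([mad1["tube_end"], mad1["carina"]])) / pixel_spacing

    out = {
        "ensemble_combinations": grid_size(grid),
        "n_train": n_train,
        "n_test": n_test,
        "epochs": epochs,
        "stage1_final_loss": results.loss_history[1][-1],
        "stage2_final_loss": results.loss_history[2][-1],
        "mean_landmark_error_px": mean_err_px,
        "mean_landmark_error_mm": mean_err_px * pixel_spacing,
        "tube_carina_error_px_stage1": tube_carina_px_stage1,
        "tube_carina_error_px_stage2": tube_carina_px,
        "mad_mm": {k: float(v) for k, v in mad.items()},
        "true_keypoint_sensitivity_pct": true_sens,
        "true_keypoint_specificity_pct": true_spec,
    }
    if "roc" in evaluation:
        summary = evaluation["roc"]
        out["predicted_ensemble_auc"] = summary.auc
        out["youden_sensitivity_pct"] = summary.youden_sensitivity
        out["youden_specificity_pct"] = summary.youden_specificity
    out["rule_sensitivity_pct"] = evaluation.get("rule_sensitivity_pct")
    out["rule_specificity_pct"] = evaluation.get("rule_specificity_pct")
    out["_results"] = results
    out["_evaluation"] = evaluation
    out["_test_images"] = test_imgs
    return out
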