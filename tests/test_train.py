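"""Training loop, reproducibility and the two-stage inference contract."""

import numpy as np
import pytest

from ettloc.augment import AugmentConfig
from ettloc.heatmap import HeatmapConfig, encode
from ettloc.io import FrameTransform, KeypointSet
from ettloc.nn import (NetConfig, TrainConfig, load_checkpoint, predict,
                       save_checkpoint, train_stage)
from ettloc.nn.network import KeypointNetwork

NET64 = NetConfig(encoder="small", working_size=(64, 64), base_channels=4)
NOAUG = AugmentConfig(scale_range=(1.0, 1.0), rotation_range=(0.0, 0.0))


class TestTrainStage:
    def test_loss_decreases_on_small_set(self, tiny_phantoms_64):
        tc = TrainConfig(learning_rate=3e-3, epochs=8, seed=0)
        net, history = train_stage(tiny_phantoms_64, 1, NET64, tc)
        assert len(history) == 8
        assert history[-1] < history[0]

    def test_same_seed_identical_history(self, tiny_phantoms_64):
        tc = TrainConfig(learning_rate=1e-3, epochs=3, seed=11)
        _, h1 = train_stage(tiny_phantoms_64[:6], 1, NET64, tc)
        _, h2 = train_stage(tiny_phantoms_64[:6], 1, NET64, tc)
        assert h1 == h2

    def test_different_seed_differs(self, tiny_phantoms_64):
        _, h1 = train_stage(tiny_phantoms_64[:6], 1, NET64, TrainConfig(epochs=2, seed=1))
        _, h2 = train_stage(tiny_phantoms_64[:6], 1, NET64, TrainConfig(epochs=2, seed=2))
        assert h1 != h2

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_stage([], 1, NET64, TrainConfig(epochs=1))

    def test_overfit_single_phantom_beats_zero_baseline(self, tiny_phantoms_64):
        # repeating one image: the loss must drop below the all-zero
        # prediction's L1 (the trivial background-only solution)
        img = tiny_phantoms_64[0]
        hm = HeatmapConfig(sigma=5.0, working_size=(64, 64))
        target = encode(img.keypoints, hm).surfaces
        zero_baseline = float(np.abs(target).mean())
        tc = TrainConfig(learning_rate=3e-3, batch_size=1, epochs=50, seed=0)
        _, history = train_stage([img] * 8, 1, NET64, tc, aug_cfg=NOAUG, heatmap_cfg=hm)
        assert history[-1] < zero_baseline

    def test_swapped_target_channels_learn_swapped_landmarks(self, tiny_phantoms_64):
        # relabelling tube_end <-> carina in the annotations must make the
        # "tube_end" output channel localize the carina instead
        import dataclasses

        swapped = [
            dataclasses.replace(
                img,
                keypoints=KeypointSet(
                    tube_end=img.keypoints.carina,
                    carina=img.keypoints.tube_end,
                    clavicle_left=img.keypoints.clavicle_left,
                    clavicle_right=img.keypoints.clavicle_right,
                ),
            )
            for img in tiny_phantoms_64
        ]
        tc = TrainConfig(learning_rate=3e-3, epochs=10, seed=0)
        net, _ = train_stage(swapped, 1, NET64, tc)
        hits = 0
        for img in tiny_phantoms_64[:6]:
            pred = predict(img, net, None).keypoints
            to_carina = np.linalg.norm(np.subtract(pred.tube_end, img.keypoints.carina))
            to_tube = np.linalg.norm(np.subtract(pred.tube_end, img.keypoints.tube_end))
            if to_carina < to_tube:
                hits += 1
        assert hits >= 5

    def test_stage2_trains_on_annotation_crops(self, tiny_phantoms_64):
        tc = TrainConfig(learning_rate=1e-3, epochs=2, seed=0)
        net, history = train_stage(tiny_phantoms_64, 2, NET64, tc)
        assert len(history) == 2
        assert isinstance(net, KeypointNetwork)


@pytest.fixture(scope="module")
def trained(tiny_phantoms_64):
    tc = TrainConfig(learning_rate=3e-3, epochs=10, seed=0)
    net1, _ = train_stage(tiny_phantoms_64, 1, NET64, tc)
    net2, _ = train_stage(tiny_phantoms_64, 2, NET64, tc)
    return net1, net2


class TestPredict:
    def test_stage2_disabled_equals_stage1(self, trained, tiny_phantoms_64):
        net1, _ = trained
        result = predict(tiny_phantoms_64[0], net1, None)
        assert not result.used_stage2
        assert np.array_equal(result.keypoints.as_array(), result.stage1_keypoints.as_array())

    def test_identical_image_identical_predictions(self, trained, tiny_phantoms_64):
        net1, net2 = trained
        a = predict(tiny_phantoms_64[1], net1, net2)
        b = predict(tiny_phantoms_64[1], net1, net2)
        assert np.array_equal(a.keypoints.as_array(), b.keypoints.as_array())

    def test_stage2_refinement_stays_inside_crop(self, trained, tiny_phantoms_64):
        net1, net2 = trained
        for img in tiny_phantoms_64[:5]:
            result = predict(img, net1, net2)
            if not result.used_stage2:
                continue
            x0, y0, x1, y1 = result.crop.rect
            for name in ("tube_end", "carina"):
                x, y = getattr(result.keypoints, name)
                assert x0 <= x <= x1 and y0 <= y <= y1

    def test_clavicles_keep_stage1_positions(self, trained, tiny_phantoms_64):
        net1, net2 = trained
        result = predict(tiny_phantoms_64[2], net1, net2)
        if result.used_stage2:
            assert result.keypoints.clavicle_left == result.stage1_keypoints.clavicle_left
            assert result.keypoints.clavicle_right == result.stage1_keypoints.clavicle_right

    def test_degenerate_stage1_flagged(self, trained, tiny_phantoms_64):
        net1, net2 = trained

        class FlatStage1:
            cfg = NET64

            def predict_surfaces(self, grids):
                return np.zeros((grids.shape[0], 4, 64, 64), dtype=np.float32)

        with pytest.warns(RuntimeWarning):
            result = predict(tiny_phantoms_64[0], FlatStage1(), net2)
        assert not result.used_stage2


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, tmp_path, tiny_phantoms_64, rng):
        tc = TrainConfig(learning_rate=1e-3, epochs=2, seed=4)
        net, history = train_stage(tiny_phantoms_64[:4], 1, NET64, tc)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, net, tc, history)
        net2, tc2, hist2 = load_checkpoint(path)
        assert tc2 == tc and hist2 == history
        x = rng.random((1, 1, 64, 64)).astype(np.float32)
        assert np.array_equal(net.predict_surfaces(x), net2.predict_surfaces(x))
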