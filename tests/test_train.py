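"""Fold construction, boundary loss, two-stage training contracts."""

import numpy as np
import pytest

import cacaflow as cf
from cacaflow.io import MaskImage
from cacaflow.net import DoubleHeadResUNet
from cacaflow.train import (
    PatchDataset,
    TrainConfig,
    boundary_loss,
    build_folds,
    signed_distance_map,
    train_classifier,
    train_decoder,
)


class TestFolds:
    def test_three_acquisitions_three_folds(self):
        plan = build_folds(["a", "b", "c"])
        assert [test for _, test in plan.folds] == ["a", "b", "c"]
        for train_ids, test in plan.folds:
            assert test not in train_ids
            assert sorted(train_ids + [test]) == ["a", "b", "c"]

    def test_forty_four_acquisitions_forty_four_folds(self):
        ids = [f"acq{i:02d}" for i in range(44)]
        plan = build_folds(ids)
        assert len(plan.folds) == 44
        tests = [t for _, t in plan.folds]
        assert sorted(tests) == sorted(ids)          # disjoint, union = all

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            build_folds(["only"])


class TestBoundaryLoss:
    def test_empty_prediction_has_zero_loss(self):
        gt = np.zeros((10, 10), np.uint8)
        gt[3:7, 3:7] = 1
        assert boundary_loss(np.zeros((10, 10)), gt) == 0.0

    def test_perfect_indicator_on_square_is_negative(self):
        gt = np.zeros((20, 20), np.uint8)
        gt[5:15, 5:15] = 1                           # 10x10 square target
        assert boundary_loss(gt.astype(float), gt) < 0.0

    def test_moving_mass_inward_strictly_decreases_loss(self):
        gt = np.zeros((20, 20), np.uint8)
        gt[5:15, 5:15] = 1
        pred_out = np.zeros((20, 20))
        pred_out[0, 0] = 1.0                         # far outside
        pred_in = np.zeros((20, 20))
        pred_in[10, 10] = 1.0                        # deep inside
        assert boundary_loss(pred_in, gt) < boundary_loss(pred_out, gt)

    def test_signed_distance_signs(self):
        gt = np.zeros((16, 16), np.uint8)
        gt[4:12, 4:12] = 1
        d = signed_distance_map(gt)
        assert d[8, 8] < 0                            # interior
        assert d[0, 0] > 0                            # exterior
        assert d[4, 4] == 0.0                         # inner boundary ring
        empty = signed_distance_map(np.zeros((16, 16), np.uint8))
        assert np.all(empty > 0)

    def test_scores_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            boundary_loss(np.full((4, 4), 1.5), np.zeros((4, 4), np.uint8))


class TestTraining:
    def test_overfit_reaches_perfect_training_f1(self, overfit_run):
        assert overfit_run["stage1"][-1]["f1"] == 1.0
        assert len(overfit_run["stage1"]) <= 200

    def test_decoder_overfit_reaches_high_iom(self, overfit_run):
        assert overfit_run["stage2"][-1]["iom"] >= 0.9
        assert len(overfit_run["stage2"]) <= 200

    def test_stage1_loss_decreases_early(self, overfit_run):
        losses = [h["loss"] for h in overfit_run["stage1"]]
        assert losses[min(5, len(losses) - 1)] < losses[0]

    def test_encoder_frozen_through_stage2(self, overfit_patches, tiny_net_cfg):
        model = DoubleHeadResUNet(tiny_net_cfg)
        cfg = TrainConfig(batch_size=8, epochs=1, seed=0)
        before = [a.copy() for m in model.encoder_modules() for a in m.state_arrays()]
        dec_before = [p.data.copy() for p in model.decoder_parameters()]
        train_decoder(overfit_patches, model, cfg)
        after = [a for m in model.encoder_modules() for a in m.state_arrays()]
        assert all(np.array_equal(x, y) for x, y in zip(before, after))
        dec_after = [p.data for p in model.decoder_parameters()]
        assert any(not np.array_equal(x, y) for x, y in zip(dec_before, dec_after))

    def test_same_seed_reproduces_training_exactly(self, overfit_patches, tiny_net_cfg):
        results = []
        for _ in range(2):
            model = DoubleHeadResUNet(tiny_net_cfg)
            h = train_classifier(overfit_patches, model, TrainConfig(batch_size=8, epochs=2, seed=5))
            results.append(([h[-1]["loss"], h[-1]["f1"]],
                            [p.data.copy() for p in model.encoder_parameters()]))
        assert results[0][0] == results[1][0]
        assert all(np.array_equal(a, b) for a, b in zip(results[0][1], results[1][1]))

    def test_empty_dataset_rejected_and_no_positive_warns(self, tiny_net_cfg):
        model = DoubleHeadResUNet(tiny_net_cfg)
        cfg = TrainConfig(batch_size=4, epochs=1, seed=0)
        empty = PatchDataset(pairs=np.zeros((0, 2, 128, 128), np.float32),
                             labels=np.zeros(0, np.uint8))
        with pytest.raises(ValueError, match="empty"):
            train_classifier(empty, model, cfg)
        rng = np.random.default_rng(0)
        allneg = PatchDataset(pairs=rng.random((2, 2, 128, 128)).astype(np.float32),
                              labels=np.zeros(2, np.uint8))
        with pytest.warns(UserWarning, match="no positive"):
            train_classifier(allneg, model, cfg)

    def test_positive_fraction_exposed(self, overfit_patches):
        assert overfit_patches.positive_fraction == 0.5
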