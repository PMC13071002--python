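"""Detector assembly, metrics, FLOP counting, checkpoints, training smoke."""

import numpy as np
import pytest

from orchardet.detector import (
    DetectionSet,
    ModelConfig,
    assemble,
    assign_targets,
    average_precision,
    cam_heatmap,
    count_params_flops,
    evaluate,
    load_checkpoint,
    nms,
    save_checkpoint,
    train_tiny,
)
from orchardet.nn import Conv2d, Tensor


def _tiny_config(**kw):
    base = dict(width=4, input_size=64, density_condition_source="uniform", seed=0)
    base.update(kw)
    return ModelConfig(**base)


class TestAssembly:
    def test_each_toggle_changes_parameter_count_upward(self):
        base = assemble(_tiny_config(use_aspc=False, use_cgwa=False, use_dadu=False)).num_parameters()
        for toggle in ("use_aspc", "use_cgwa", "use_dadu"):
            kw = dict(use_aspc=False, use_cgwa=False, use_dadu=False)
            kw[toggle] = True
            n = assemble(_tiny_config(**kw)).num_parameters()
            assert n > base, toggle

    @pytest.mark.parametrize("size", [32, 64])
    def test_forward_shape_contract(self, size):
        model = assemble(_tiny_config()).eval()
        x = Tensor(np.random.default_rng(0).random((1, 3, size, size)))
        outs, _ = model.forward(
            x, occlusion=np.zeros((1, 1, size, size)), density=np.full((1, 1, size, size), 0.5)
        )
        assert [o.shape for o in outs] == [
            (1, 8, size // 8, size // 8),
            (1, 8, size // 16, size // 16),
            (1, 8, size // 32, size // 32),
        ]

    def test_full_model_contains_exactly_two_dadu_instances(self):
        model = assemble(_tiny_config())
        assert model.dadu_instances() == 2
        assert assemble(_tiny_config(use_dadu=False)).dadu_instances() == 0

    def test_invalid_density_source_rejected(self):
        with pytest.raises(ValueError, match="density"):
            _tiny_config(density_condition_source="oracle")


class TestParamsFlops:
    def test_single_conv_parameter_count(self):
        conv = Conv2d(4, 8, 1, bias=True)
        assert conv.weight.size + conv.bias.size == 40

    def test_count_invariant_to_input_size(self):
        model = assemble(_tiny_config())
        p32, _ = count_params_flops(model, 32)
        p64, _ = count_params_flops(model, 64)
        assert p32 == p64 == model.num_parameters()

    def test_two_layer_toy_net_matches_hand_summed_macs(self):
        """3->4 conv3x3 then 4->2 conv1x1 on 8x8: analytic MAC ledger."""
        from orchardet import nn
        from orchardet.nn import tensor as tmod

        net = nn.Sequential(
            nn.Conv2d(3, 4, 3, padding=1),
            nn.Conv2d(4, 2, 1),
        )
        x = Tensor(np.zeros((1, 3, 8, 8)))
        tmod.MAC_COUNTER["enabled"] = True
        tmod.MAC_COUNTER["macs"] = 0
        net(x)
        macs = tmod.MAC_COUNTER["macs"]
        tmod.MAC_COUNTER["enabled"] = False
        assert macs == 1 * 4 * 8 * 8 * 3 * 9 + 1 * 2 * 8 * 8 * 4 * 1

    def test_flops_deterministic(self):
        model = assemble(_tiny_config())
        a = count_params_flops(model, 32)
        b = count_params_flops(model, 32)
        assert a == b


class TestEvaluate:
    def _one_truth(self):
        tb = [np.array([[10.0, 10.0, 20.0, 20.0], [40.0, 40.0, 52.0, 52.0]])]
        tc = [np.array([0, 0])]
        return tb, tc

    def test_perfect_detections_score_one(self):
        tb, tc = self._one_truth()
        det = [DetectionSet(tb[0], np.array([1.0, 1.0]), tc[0])]
        m = evaluate(det, tb, tc, num_classes=1)
        assert m["mAP@0.5"] == 1.0
        assert m["precision"] == m["recall"] == m["F1"] == 1.0

    def test_no_detections_zero_recall_and_map(self):
        tb, tc = self._one_truth()
        m = evaluate([DetectionSet()], tb, tc, num_classes=1)
        assert m["recall"] == 0.0 and m["mAP@0.5"] == 0.0

    def test_hand_computed_ap_half_for_one_tp_one_fp(self):
        """2 truths, TP at 0.9 then FP at 0.8 -> envelope AP = 0.5."""
        tb, tc = self._one_truth()
        det = [
            DetectionSet(
                np.array([[10.0, 10.0, 20.0, 20.0], [70.0, 70.0, 80.0, 80.0]]),
                np.array([0.9, 0.8]),
                np.array([0, 0]),
            )
        ]
        m = evaluate(det, tb, tc, num_classes=1)
        assert m["per_class_AP"][0] == pytest.approx(0.5, abs=1e-12)

    def test_f1_consistent_with_reported_p_and_r(self):
        tb, tc = self._one_truth()
        det = [
            DetectionSet(
                np.array([[10.0, 10.0, 20.0, 20.0], [70.0, 70.0, 80.0, 80.0]]),
                np.array([0.9, 0.8]),
                np.array([0, 0]),
            )
        ]
        m = evaluate(det, tb, tc, num_classes=1)
        p, r = m["precision"], m["recall"]
        assert m["F1"] == pytest.approx(2 * p * r / (p + r), abs=1e-9)

    def test_invariant_to_image_ordering(self, rng):
        tb = [np.array([[0.0, 0.0, 10.0, 10.0]]), np.array([[5.0, 5.0, 18.0, 18.0]])]
        tc = [np.array([1]), np.array([2])]
        dets = [
            DetectionSet(tb[0], np.array([0.7]), tc[0]),
            DetectionSet(np.array([[30.0, 30.0, 40.0, 40.0]]), np.array([0.6]), np.array([2])),
        ]
        a = evaluate(dets, tb, tc)
        b = evaluate(dets[::-1], tb[::-1], tc[::-1])
        assert a["mAP@0.5"] == b["mAP@0.5"] and a["F1"] == b["F1"]

    def test_confusion_matrix_background_row_and_column(self):
        tb = [np.array([[0.0, 0.0, 10.0, 10.0]])]
        tc = [np.array([1])]
        # one matched det with wrong class + one unmatched false alarm
        det = [
            DetectionSet(
                np.array([[0.0, 0.0, 10.0, 10.0], [50.0, 50.0, 60.0, 60.0]]),
                np.array([0.9, 0.8]),
                np.array([2, 0]),
            )
        ]
        m = evaluate(det, tb, tc, num_classes=3)
        cm = m["confusion_matrix"]
        assert cm[1, 2] == 1  # truth class 1 predicted as 2
        assert cm[3, 0] == 1  # background row false alarm
        assert cm.shape == (4, 4)

    def test_nms_suppresses_overlapping_same_class_only(self):
        boxes = np.array([[0, 0, 10, 10], [1, 1, 11, 11], [0, 0, 10, 10]], dtype=float)
        det = DetectionSet(boxes, np.array([0.9, 0.8, 0.7]), np.array([0, 0, 1]))
        kept = nms(det, iou_threshold=0.5)
        assert len(kept.boxes) == 2
        assert set(kept.class_ids.tolist()) == {0, 1}

    def test_average_precision_empty_truth_is_nan(self):
        ap, _, _ = average_precision(np.zeros(0, dtype=bool), np.zeros(0), 0)
        assert np.isnan(ap)


class TestAssignTargets:
    def test_small_box_covers_its_fine_scale_cells(self):
        """12 px box: all four stride-8 cells with centers inside it."""
        rec = assign_targets(np.array([[10.0, 10.0, 22.0, 22.0]]), np.array([1]), 64)
        assert len(rec) == 4 and all(r[0] == 0 for r in rec)
        by_cell = {(r[1], r[2]): r for r in rec}
        scale, gy, gx, l, t, r, b, cid = by_cell[(1, 1)]  # cell center (12, 12)
        assert cid == 1
        assert (l, t, r, b) == pytest.approx((0.25, 0.25, 1.25, 1.25))

    def test_large_boxes_route_to_coarse_scale(self):
        rec = assign_targets(np.array([[0.0, 0.0, 50.0, 50.0]]), np.array([0]), 64)
        assert all(r[0] == 2 for r in rec)

    def test_tiny_box_still_gets_one_cell(self):
        rec = assign_targets(np.array([[8.5, 8.5, 11.0, 11.0]]), np.array([2]), 64)
        assert len(rec) == 1 and rec[0][0] == 0

    def test_overlapping_boxes_give_smaller_box_the_cell(self):
        boxes = np.array([[0.0, 0.0, 16.0, 16.0], [2.0, 2.0, 14.0, 14.0]])
        rec = assign_targets(boxes, np.array([0, 1]), 64)
        by_cell = {(r[1], r[2]): r for r in rec}
        assert by_cell[(0, 0)][7] == 1  # inner (smaller) box wins the shared cell


@pytest.fixture(scope="module")
def tiny_dataset(tmp_path_factory):
    from dataclasses import replace

    from orchardet.synthetic_orchard import SceneSpec, write_dataset

    out = tmp_path_factory.mktemp("ds")
    base = SceneSpec(image_size=64, n_fruits=3, radius_range=(5.0, 9.0), occluder_density=0.0, seed=0)
    write_dataset([replace(base, seed=i) for i in range(4)], out, split=(1.0, 0.0, 0.0))
    return out


class TestTrainingAndCheckpoint:
    def test_one_epoch_smoke_and_decreasing_trend(self, tiny_dataset):
        model = assemble(_tiny_config())
        res = train_tiny(model, tiny_dataset, epochs=6, seed=0, batch_size=4, max_steps=6)
        assert res["steps"] == 6
        assert res["loss_trace"][-1] < res["loss_trace"][0]

    def test_checkpoint_roundtrip_reproduces_predictions(self, tiny_dataset, tmp_path):
        model = assemble(_tiny_config())
        train_tiny(model, tiny_dataset, epochs=2, seed=0, batch_size=4, max_steps=2)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        clone = load_checkpoint(path)
        x = Tensor(np.random.default_rng(3).random((1, 3, 64, 64)))
        occ = np.zeros((1, 1, 64, 64))
        den = np.full((1, 1, 64, 64), 0.5)
        a, _ = model.forward(x, occlusion=occ, density=den)
        b, _ = clone.forward(x, occlusion=occ, density=den)
        for ta, tb_ in zip(a, b):
            np.testing.assert_array_equal(ta.data, tb_.data)

    def test_training_deterministic_per_seed(self, tiny_dataset):
        r1 = train_tiny(assemble(_tiny_config()), tiny_dataset, epochs=2, seed=5, batch_size=4, max_steps=2)
        r2 = train_tiny(assemble(_tiny_config()), tiny_dataset, epochs=2, seed=5, batch_size=4, max_steps=2)
        assert r1["loss_trace"] == r2["loss_trace"]

    def test_empty_dataset_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            train_tiny(assemble(_tiny_config()), tmp_path, epochs=1, seed=0)


class TestCam:
    def test_heatmap_range_and_shape(self, rng):
        model = assemble(_tiny_config())
        img = rng.integers(0, 256, size=(64, 64, 3)).astype(np.uint8)
        heat = cam_heatmap(model, img, target_scale=0)
        assert heat.shape == (64, 64)
        assert heat.min() >= 0.0 and heat.max() <= 1.0
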