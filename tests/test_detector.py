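"""Detector geometry, attention/fusion modules, decoding, and checkpoints."""

import dataclasses

import numpy as np
import pytest

from ctcdet import autodiff as ad
from ctcdet.autodiff import Tensor
from ctcdet.detector import (ANCHORS_PER_LOC, CBAM, ConfigurationError,
                             FusionBlock, NetworkConfig, build_detector,
                             decode_and_filter, decode_boxes, desk_config,
                             encode_boxes, expected_anchor_count, feature_plan,
                             generate_anchors, load_checkpoint, nms,
                             save_checkpoint, _plan_upsample)
from conftest import TINY


class TestGeometry:
    def test_standard_feature_grids(self):
        grids, _ = feature_plan(300)
        assert grids == [38, 19, 10, 5, 3, 1]
        assert feature_plan(150)[0] == [19, 10, 5, 3, 2, 1]

    def test_grids_strictly_decreasing(self):
        for size in (150, 300):
            grids, _ = feature_plan(size)
            assert all(a > b for a, b in zip(grids, grids[1:]))

    def test_standard_anchor_count_is_8732(self):
        anchors = generate_anchors(NetworkConfig(input_size=300))
        # closed form: 4*38^2 + 6*19^2 + 6*10^2 + 6*5^2 + 4*3^2 + 4*1^2
        assert len(anchors) == 8732
        assert expected_anchor_count([38, 19, 10, 5, 3, 1]) == 8732

    def test_anchor_size_list_appears_in_geometry(self):
        anchors = generate_anchors(NetworkConfig(input_size=300))
        assert anchors.sizes == (21, 45, 99, 153, 207, 261, 315)
        squares = anchors.boxes[np.isclose(anchors.boxes[:, 2], anchors.boxes[:, 3])]
        present = {round(float(w), 6) for w in squares[:, 2]}
        for s in (21, 45, 99, 153, 207, 261):
            assert s in present

    def test_anchor_centers_inside_frame_and_positive_sizes(self, tiny_anchors):
        b = tiny_anchors.boxes
        assert np.all(b[:, 0] > 0) and np.all(b[:, 0] < TINY.input_size)
        assert np.all(b[:, 1] > 0) and np.all(b[:, 1] < TINY.input_size)
        assert np.all(b[:, 2] > 0) and np.all(b[:, 3] > 0)
        assert len(tiny_anchors) == expected_anchor_count(feature_plan(150)[0])

    def test_size_list_length_mismatch_raises(self):
        cfg = NetworkConfig(input_size=300, anchor_sizes=(21, 45, 99))
        with pytest.raises(ConfigurationError):
            generate_anchors(cfg)

    def test_degenerate_single_location_layer(self):
        anchors = generate_anchors(NetworkConfig(input_size=300))
        last = anchors.boxes[anchors.layer_of_origin == 5]
        assert last.shape[0] == 4
        np.testing.assert_allclose(last[:, 0], 150.0)
        np.testing.assert_allclose(last[:, 1], 150.0)


class TestCBAM:
    def test_zero_parameters_give_quarter_gain(self, rng):
        cbam = CBAM(16, 4, rng)
        for _, p in cbam.named_parameters():
            p.data = np.zeros_like(p.data)
        x = Tensor(rng.normal(size=(2, 16, 6, 6)).astype(np.float32))
        out = cbam(x)
        np.testing.assert_allclose(out.data, 0.25 * x.data, atol=1e-6)

    def test_shape_contract(self, rng):
        cbam = CBAM(32, 8, rng)
        x = Tensor(rng.normal(size=(3, 32, 5, 7)).astype(np.float32))
        assert cbam(x).shape == x.shape

    def test_channel_gate_ordering_invariant_to_positive_scaling(self, rng):
        """With zero biases the shared MLP is positively homogeneous, so the
        channel-attention logits scale by the same constant and their ordering
        across channels is unchanged (the sigmoid is monotone)."""
        cbam = CBAM(16, 4, rng)

        def gate_logits(arr):
            t = Tensor(arr.astype(np.float64))
            avg = ad.tmean(t, axis=(2, 3))
            mx = ad.amax(ad.amax(t, axis=3, keepdims=False), axis=2, keepdims=False)
            shared = lambda v: cbam.fc2(ad.relu(cbam.fc1(v)))
            return ad.add(shared(avg), shared(mx)).data

        for _ in range(10):
            x = rng.normal(size=(1, 16, 4, 4))
            base = gate_logits(x)[0]
            scaled = gate_logits(3.7 * x)[0]
            np.testing.assert_allclose(scaled, 3.7 * base, rtol=1e-4, atol=1e-6)
            np.testing.assert_array_equal(np.argsort(base, kind="stable"),
                                          np.argsort(scaled / 3.7, kind="stable"))

    def test_indivisible_channels_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            CBAM(10, 4, rng)


class TestFusion:
    def test_shape_contract(self, rng):
        fb = FusionBlock(8, 16, 5, 10, rng)
        high = Tensor(rng.normal(size=(1, 8, 5, 5)).astype(np.float32))
        low = Tensor(rng.normal(size=(1, 16, 10, 10)).astype(np.float32))
        assert fb(high, low).shape == (1, 16, 10, 10)

    def test_constructed_kernel_reproduces_nn_upsampling(self, rng):
        c = 4
        fb = FusionBlock(c, c, 3, 6, rng)
        up_w = np.zeros_like(fb.up.weight.data)
        for ch in range(c):
            up_w[ch, ch] = 1.0        # exact 2x nearest-neighbor kernel
        fb.up.weight.data = up_w
        fb.up.bias.data[:] = 0
        proj_w = np.zeros_like(fb.proj.weight.data)
        for ch in range(c):
            proj_w[ch, ch, 0, 0] = 1.0  # identity projection of the high channels
        fb.proj.weight.data = proj_w
        fb.proj.bias.data[:] = 0
        high = Tensor(rng.uniform(0, 1, size=(1, c, 3, 3)).astype(np.float32))
        low = Tensor(np.zeros((1, c, 6, 6), dtype=np.float32))
        out = fb(high, low)
        expected = np.repeat(np.repeat(high.data, 2, axis=2), 2, axis=3)
        np.testing.assert_allclose(out.data, expected, atol=1e-6)

    def test_impossible_grid_pair_rejected(self):
        with pytest.raises(ConfigurationError):
            _plan_upsample(3, 9)

    @pytest.mark.parametrize("gh,gl", [(19, 38), (10, 19), (5, 10), (3, 5), (2, 3)])
    def test_planned_upsample_hits_target_grid(self, gh, gl):
        k, s, p = _plan_upsample(gh, gl)
        assert s * (gh - 1) + k - 2 * p == gl


class TestForward:
    def test_shapes_and_determinism(self, tiny_model, tiny_anchors, rng):
        x = rng.normal(size=(2, 3, 150, 150)).astype(np.float32)
        with ad.no_grad():
            conf, loc, feats = tiny_model.forward(x)
            conf2, loc2, _ = tiny_model.forward(x.copy())
        a = len(tiny_anchors)
        assert conf.shape == (2, a, 3) and loc.shape == (2, a, 4)
        assert [f.shape[2] for f in feats] == [19, 10, 5, 3, 2, 1]
        np.testing.assert_array_equal(conf.data, conf2.data)
        np.testing.assert_array_equal(loc.data, loc2.data)

    def test_wrong_input_size_rejected(self, tiny_model, rng):
        with pytest.raises(ValueError):
            tiny_model.forward(rng.normal(size=(1, 3, 120, 120)).astype(np.float32))

    def test_ablation_changes_only_declared_parameter_groups(self):
        def n_params(att, fus):
            cfg = dataclasses.replace(TINY, attention=att, fusion=fus)
            return build_detector(cfg, seed=0).num_parameters()

        base = n_params(False, False)
        plus_att = n_params(True, False)
        plus_fus = n_params(False, True)
        both = n_params(True, True)

        model = build_detector(TINY, seed=0)
        fch = model.feature_channels
        r = TINY.cbam_reduction

        def cbam_params(c):
            return 2 * (c * (c // r)) + (c // r) + c + (1 * 2 * 7 * 7 + 1)

        grids = feature_plan(TINY.input_size)[0]

        def fusion_params(l):
            ch, cl = fch[l + 1], fch[l]
            k, _, _ = _plan_upsample(grids[l + 1], grids[l])
            return ch * ch * k * k + ch + cl * (ch + cl) + cl

        expected_att = sum(cbam_params(fch[i]) for i in range(4))
        expected_fus = sum(fusion_params(l) for l in range(3))
        assert plus_att - base == expected_att
        assert plus_fus - base == expected_fus
        assert both - base == expected_att + expected_fus


class TestEncodeDecode:
    def test_zero_offsets_decode_to_anchors(self, tiny_anchors):
        decoded = decode_boxes(np.zeros((len(tiny_anchors), 4)), tiny_anchors.boxes)
        np.testing.assert_allclose(decoded, tiny_anchors.as_corners(), atol=1e-5)

    def test_encode_decode_round_trip(self, rng):
        anchors = np.column_stack([rng.uniform(20, 280, 200), rng.uniform(20, 280, 200),
                                   rng.uniform(10, 100, 200), rng.uniform(10, 100, 200)])
        cx, cy = rng.uniform(30, 270, 200), rng.uniform(30, 270, 200)
        w, h = rng.uniform(5, 80, 200), rng.uniform(5, 80, 200)
        boxes = np.column_stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2])
        back = decode_boxes(encode_boxes(boxes, anchors), anchors)
        np.testing.assert_allclose(back, boxes, atol=1e-5)


class TestNMS:
    def test_exact_duplicate_suppressed(self):
        boxes = np.array([[0, 0, 10, 10], [0, 0, 10, 10.0]])
        assert nms(boxes, [0.9, 0.8], 0.5) == [0]

    def test_greedy_chain_hand_example(self):
        # IOU(A,B)=0.6, IOU(B,C)=0.6, IOU(A,C)=1/3: A suppresses B, C survives
        a = [0.0, 0, 10, 10]
        b = [2.5, 0, 12.5, 10]
        c = [5.0, 0, 15, 10]
        kept = nms(np.array([a, b, c]), [0.9, 0.8, 0.7], 0.5)
        assert kept == [0, 2]

    def test_kept_subset_with_bounded_pairwise_iou(self, rng):
        from ctcdet.evaluation import iou as box_iou
        from ctcdet.imaging_io import BoundingBox
        for _ in range(50):
            n = int(rng.integers(1, 15))
            x0 = rng.uniform(0, 60, n)
            y0 = rng.uniform(0, 60, n)
            w, h = rng.uniform(5, 40, n), rng.uniform(5, 40, n)
            boxes = np.column_stack([x0, y0, x0 + w, y0 + h])
            scores = rng.uniform(size=n)
            kept = nms(boxes, scores, 0.5)
            assert set(kept) <= set(range(n))
            for i, ki in enumerate(kept):
                for kj in kept[i + 1:]:
                    bi = BoundingBox(*boxes[ki])
                    bj = BoundingBox(*boxes[kj])
                    assert box_iou(bi, bj) <= 0.5 + 1e-12


class TestDecodeAndFilter:
    def test_zero_offsets_with_confident_scores_return_anchor_boxes(self, tiny_anchors):
        a = len(tiny_anchors)
        conf = np.zeros((a, 3))
        conf[10, 1] = 10.0          # one confident CTC at anchor 10
        loc = np.zeros((a, 4))
        res = decode_and_filter(conf, loc, tiny_anchors, TINY, image_id="t")
        assert len(res.boxes) >= 1
        assert res.anchor_indices[0] == 10
        box = res.boxes[0]
        expect = tiny_anchors.as_corners()[10]
        got = np.array([box.xmin, box.ymin, box.xmax, box.ymax])
        clipped = np.clip(expect, 0, TINY.input_size)
        np.testing.assert_allclose(got, clipped, atol=1e-4)
        assert box.label == "CTC" and 0 <= box.score <= 1


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, tiny_model, rng):
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, tiny_model, extra={"note": 1})
        back = load_checkpoint(path)
        assert back.config == tiny_model.config
        x = rng.normal(size=(1, 3, 150, 150)).astype(np.float32)
        with ad.no_grad():
            c1, l1, _ = tiny_model.forward(x)
            c2, l2, _ = back.forward(x)
        np.testing.assert_array_equal(c1.data, c2.data)
        np.testing.assert_array_equal(l1.data, l2.data)


class TestBackboneImport:
    def test_partial_state_loads_backbone_only(self, tiny_model):
        import copy
        donor = {k: v + 1.0 for k, v in tiny_model.state_dict().items()
                 if k.startswith("blocks.0")}
        from ctcdet.detector import build_detector
        from conftest import TINY
        target = build_detector(TINY, seed=99)
        before_head = {k: v.copy() for k, v in target.state_dict().items()
                       if k.startswith("cls_heads")}
        n = target.load_backbone(donor)
        assert n == len(donor)
        after = target.state_dict()
        for k, v in donor.items():
            np.testing.assert_array_equal(after[k], v)
        for k, v in before_head.items():
            np.testing.assert_array_equal(after[k], v)

    def test_empty_state_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.load_backbone({"cls_heads.0.weight": np.zeros(1)})
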