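"""Anchor matching, composite-loss contract, and training-loop behavior."""

import dataclasses
import math

import numpy as np
import pytest

from ctcdet import autodiff as ad
from ctcdet.autodiff import Tensor
from ctcdet.detector import AnchorSet, build_detector, generate_anchors
from ctcdet.imaging_io import Annotation, BoundingBox
from ctcdet.synthetic import easy_config, simulate_in_memory
from ctcdet.training import (LossBreakdown, RawPredictions, TrainConfig,
                             compute_loss, fit, match_anchors)
from conftest import TINY


def _toy_anchors():
    """A small hand-made anchor set for loss tests."""
    boxes = np.array([
        [20, 20, 20, 20], [60, 20, 24, 24], [100, 20, 30, 30],
        [20, 60, 20, 20], [60, 60, 24, 24], [100, 60, 30, 30],
        [20, 100, 20, 20], [60, 100, 24, 24], [100, 100, 30, 30],
    ], dtype=np.float32)
    return AnchorSet(boxes, np.zeros(len(boxes), dtype=np.int32),
                     (20,), [3], (1,), 150)


class TestMatchAnchors:
    def test_anchor_identical_to_truth_is_positive(self):
        anchors = _toy_anchors()
        truth = Annotation("t", 150, 150, [BoundingBox(10, 10, 30, 30, label="CTC")])
        m = match_anchors(anchors, truth, 0.5)
        assert m.assignment[0] == 0
        assert m.best_iou[0] == pytest.approx(1.0)

    def test_no_truth_all_negative(self):
        m = match_anchors(_toy_anchors(), Annotation("t", 150, 150, []), 0.5)
        assert np.all(m.assignment == -1)

    def test_argmax_anchor_forced_positive_below_threshold(self):
        anchors = _toy_anchors()
        # a tiny box overlapping anchor 4 only slightly: IOU < 0.5 everywhere
        truth = Annotation("t", 150, 150, [BoundingBox(58, 58, 64, 64, label="WBC")])
        m = match_anchors(anchors, truth, 0.5)
        assert (m.assignment >= 0).sum() == 1
        # brute-force argmax over IOUs
        from ctcdet.evaluation import iou
        gt = truth.boxes[0]
        corners = anchors.as_corners()
        ious = [iou(BoundingBox(*c), gt) for c in corners]
        assert m.assignment[int(np.argmax(ious))] == 0
        assert max(ious) < 0.5

    def test_invalid_inputs(self):
        truth = Annotation("t", 150, 150, [])
        with pytest.raises(ValueError):
            match_anchors(_toy_anchors(), truth, 1.5)
        empty = AnchorSet(np.zeros((0, 4)), np.zeros(0, dtype=np.int32),
                          (20,), [0], (1,), 150)
        with pytest.raises(ValueError):
            match_anchors(empty, truth, 0.5)


def _raw(rng, n_anchors, k=3, requires_grad=True):
    conf = Tensor(rng.normal(size=(n_anchors, k)).astype(np.float32),
                  requires_grad=requires_grad)
    loc = Tensor(rng.normal(size=(n_anchors, 4)).astype(np.float32),
                 requires_grad=requires_grad)
    return RawPredictions(conf, loc)


class TestComputeLoss:
    def _instance(self, rng, n_truth=2):
        anchors = _toy_anchors()
        boxes = [BoundingBox(10, 10, 30, 30, label="CTC"),
                 BoundingBox(85, 85, 115, 115, label="WBC")][:n_truth]
        truth = Annotation("t", 150, 150, boxes)
        match = match_anchors(anchors, truth, 0.5)
        return anchors, truth, match

    def test_total_is_exact_sum_of_terms(self, rng):
        anchors, truth, match = self._instance(rng)
        lb = compute_loss(_raw(rng, len(anchors)), match, truth, anchors)
        parts = lb.reg_pos.item() + lb.clas_pos.item() + lb.clas_neg.item()
        assert lb.total.item() == pytest.approx(parts, rel=1e-6, abs=1e-6)

    def test_perfect_predictions_drive_losses_to_zero(self, rng):
        from ctcdet.detector import encode_boxes
        anchors, truth, match = self._instance(rng)
        pos = match.positive_indices
        gt = np.array([[b.xmin, b.ymin, b.xmax, b.ymax] for b in truth.boxes])
        loc = np.zeros((len(anchors), 4), dtype=np.float32)
        loc[pos] = encode_boxes(gt[match.assignment[pos]], anchors.boxes[pos])
        conf = np.full((len(anchors), 3), 0.0, dtype=np.float32)
        conf[:, 0] = 40.0                                  # saturated background
        labels = {1: "CTC", 2: "WBC"}
        for ai in pos:
            truth_label = truth.boxes[match.assignment[ai]].label
            ci = 1 if truth_label == "CTC" else 2
            conf[ai] = 0.0
            conf[ai, ci] = 40.0                            # saturated correct class
        raw = RawPredictions(Tensor(conf), Tensor(loc))
        lb = compute_loss(raw, match, truth, anchors)
        assert lb.reg_pos.item() == pytest.approx(0.0, abs=1e-6)
        assert lb.clas_pos.item() < 1e-3

    def test_mined_negative_count_follows_ratio(self, rng):
        """10 positives at ratio 1.2 mine exactly 12 negatives, and they are
        the top-12 background cross-entropies among all negatives."""
        n_anchors = 64
        boxes = np.column_stack([np.full(n_anchors, 50.0), np.full(n_anchors, 50.0),
                                 np.full(n_anchors, 20.0), np.full(n_anchors, 20.0)])
        anchors = AnchorSet(boxes.astype(np.float32),
                            np.zeros(n_anchors, dtype=np.int32), (20,), [8], (1,), 150)
        assignment = np.full(n_anchors, -1, dtype=np.int32)
        assignment[:10] = 0
        from ctcdet.training import MatchResult
        match = MatchResult(assignment, np.ones(n_anchors))
        truth = Annotation("t", 150, 150, [BoundingBox(40, 40, 60, 60, label="CTC")])
        raw = _raw(rng, n_anchors)
        lb = compute_loss(raw, match, truth, anchors, ratio=1.2)
        # brute-force: background CE of every negative anchor, top-12 by loss
        z = raw.conf.data - raw.conf.data.max(axis=1, keepdims=True)
        lsm = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
        neg_ce = -lsm[10:, 0]
        k = math.floor(1.2 * 10)
        assert k == 12
        expected = np.sort(neg_ce)[-k:].sum() / 10
        assert lb.clas_neg.item() == pytest.approx(expected, rel=1e-5)

    def test_zero_positives_falls_back_to_one_mined_negative(self, rng, caplog):
        anchors = _toy_anchors()
        truth = Annotation("t", 150, 150, [])
        match = match_anchors(anchors, truth, 0.5)
        with caplog.at_level("WARNING"):
            lb = compute_loss(_raw(rng, len(anchors)), match, truth, anchors)
        assert lb.reg_pos.item() == 0.0
        assert lb.clas_neg.item() > 0
        assert "zero positive" in caplog.text

    def test_regression_gradient_zero_for_negative_anchors(self, rng):
        anchors, truth, match = self._instance(rng)
        raw = _raw(rng, len(anchors))
        lb = compute_loss(raw, match, truth, anchors)
        lb.reg_pos.backward()
        neg = match.negative_indices
        assert raw.loc.grad is not None
        np.testing.assert_array_equal(raw.loc.grad[neg], 0.0)
        pos = match.positive_indices
        assert np.any(raw.loc.grad[pos] != 0.0)


@pytest.fixture(scope="module")
def tiny_dataset():
    cfg = easy_config(seed=3)
    samples = simulate_in_memory(cfg, 10)
    return samples[:8], samples[8:]


class TestFit:
    def test_freeze_keeps_backbone_bitwise_unchanged(self, tiny_dataset):
        train, val = tiny_dataset
        model = build_detector(TINY, seed=2)
        before = {k: v.copy() for k, v in model.state_dict().items()}
        tc = TrainConfig(epochs=2, freeze_epochs=2, patience=10, batch_size=4, seed=0)
        result = fit(train, val, TINY, tc, model=model)
        after = result.model.state_dict()
        backbone = [k for k in after if k.startswith(("blocks", "fc"))]
        heads = [k for k in after if not k.startswith(("blocks", "fc"))]
        assert backbone and heads
        for k in backbone:
            np.testing.assert_array_equal(after[k], before[k])
        assert any(not np.array_equal(after[k], before[k]) for k in heads)

    def test_unfrozen_phase_updates_backbone(self, tiny_dataset):
        train, val = tiny_dataset
        model = build_detector(TINY, seed=2)
        before = {k: v.copy() for k, v in model.state_dict().items()}
        tc = TrainConfig(epochs=1, freeze_epochs=0, patience=10, batch_size=4, seed=0)
        result = fit(train, val, TINY, tc, model=model)
        after = result.model.state_dict()
        changed = [k for k in after if k.startswith("blocks")
                   and not np.array_equal(after[k], before[k])]
        assert changed

    def test_fixed_seed_reproduces_loss_curve(self, tiny_dataset):
        train, val = tiny_dataset
        tc = TrainConfig(epochs=2, freeze_epochs=0, patience=10, batch_size=4, seed=5)
        h1 = fit(train, val, TINY, tc).history
        h2 = fit(train, val, TINY, tc).history
        assert [r["L_total"] for r in h1] == [r["L_total"] for r in h2]
        assert [r["val_loss"] for r in h1] == [r["val_loss"] for r in h2]

    def test_history_records_all_loss_terms(self, tiny_dataset):
        train, val = tiny_dataset
        tc = TrainConfig(epochs=1, freeze_epochs=0, patience=5, batch_size=4, seed=0)
        row = fit(train, val, TINY, tc).history[0]
        for key in ("epoch", "lr", "L_total", "L_reg_pos", "L_clas_pos",
                    "L_clas_neg", "val_loss"):
            assert key in row
        assert row["L_total"] == pytest.approx(
            row["L_reg_pos"] + row["L_clas_pos"] + row["L_clas_neg"], abs=1e-4)

    def test_empty_split_rejected(self, tiny_dataset):
        train, _ = tiny_dataset
        with pytest.raises(ValueError):
            fit(train, [], TINY, TrainConfig(epochs=1, freeze_epochs=0))


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(epochs=10, freeze_epochs=20)
    with pytest.raises(ValueError):
        TrainConfig(neg_pos_ratio=0.0)


def test_cosine_schedule_decays_from_initial_rate():
    from ctcdet.nn import cosine_lr
    lr0 = 6e-4
    values = [cosine_lr(e, 50, lr0) for e in range(50)]
    assert values[0] == pytest.approx(lr0)
    assert values[-1] == pytest.approx(1e-6, abs=1e-9)
    assert all(a >= b for a, b in zip(values, values[1:]))
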