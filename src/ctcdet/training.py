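"""Anchor matching, composite detection loss, and the training loop.

The loss is the SSD composite with explicit bookkeeping of its three terms:

``L_total = L_reg_pos + L_clas_pos + L_clas_neg``

where ``L_reg_pos`` is the smooth-L1 localization loss over positive anchors,
``L_clas_pos`` the cross-entropy of positive anchors against their class, and
``L_clas_neg`` the cross-entropy of the hardest background anchors against
the background class, mined at a fixed negative:positive ratio (default 1.2).
All three terms are normalized by the number of positives.

Optimization follows a freeze/unfreeze schedule: during the frozen phase the
backbone receives no updates at all, then every parameter trains.  Adam
(beta1 0.9, beta2 0.999) with initial learning rate 6e-4, cosine decay to a
1e-6 floor over the full horizon, weight decay 5e-4, and early stopping on
validation loss.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .detector import (AnchorSet, NetworkConfig, SSDDetector, _iou_matrix,
                       build_detector, encode_boxes, generate_anchors,
                       prepare_input)
from .imaging_io import (Annotation, DatasetIndex, RasterImage,
                         read_image, read_voc_annotation, CLASSES)
from .nn import Adam, cosine_lr

logger = logging.getLogger(__name__)

__all__ = ["MatchResult", "RawPredictions", "LossBreakdown", "TrainConfig",
           "TrainResult", "match_anchors", "compute_loss", "fit", "train",
           "prepare_sample", "save_history_csv"]

CLASS_INDEX = {name: i + 1 for i, name in enumerate(CLASSES)}  # background = 0


@dataclass
class MatchResult:
    """Per-anchor assignment: gt index for positives, -1 for negatives."""

    assignment: np.ndarray   # (A,) int32
    best_iou: np.ndarray     # (A,) float64

    @property
    def positive_indices(self) -> np.ndarray:
        return np.nonzero(self.assignment >= 0)[0]

    @property
    def negative_indices(self) -> np.ndarray:
        return np.nonzero(self.assignment < 0)[0]


@dataclass
class RawPredictions:
    """Pre-normalization per-anchor class scores and box offsets (one image)."""

    conf: Tensor   # (A, K)
    loc: Tensor    # (A, 4)


@dataclass
class LossBreakdown:
    reg_pos: Tensor
    clas_pos: Tensor
    clas_neg: Tensor

    @property
    def total(self) -> Tensor:
        return ad.add(ad.add(self.reg_pos, self.clas_pos), self.clas_neg)

    def as_floats(self) -> dict[str, float]:
        return {"L_total": self.total.item(), "L_reg_pos": self.reg_pos.item(),
                "L_clas_pos": self.clas_pos.item(), "L_clas_neg": self.clas_neg.item()}


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    freeze_epochs: int = 50
    lr: float = 6e-4
    lr_floor: float = 1e-6
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 5e-4
    neg_pos_ratio: float = 1.2
    patience: int = 10
    batch_size: int = 8
    iou_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.freeze_epochs > self.epochs:
            raise ValueError("freeze_epochs cannot exceed epochs")
        if self.neg_pos_ratio <= 0:
            raise ValueError("neg:pos ratio must be positive")


def match_anchors(anchors: AnchorSet, truth: Annotation,
                  iou_threshold: float = 0.5) -> MatchResult:
    """Assign anchors to ground-truth boxes.

    Anchors whose best IOU reaches the threshold become positive for their
    best-overlapping truth; additionally every truth's single best anchor is
    forced positive so no object goes unmatched.
    """
    if len(anchors) == 0:
        raise ValueError("empty anchor set")
    if not (0.0 < iou_threshold < 1.0):
        raise ValueError("iou threshold must lie in (0, 1)")
    a_corners = anchors.as_corners()
    if not truth.boxes:
        return MatchResult(np.full(len(anchors), -1, dtype=np.int32),
                           np.zeros(len(anchors)))
    gt = np.array([[b.xmin, b.ymin, b.xmax, b.ymax] for b in truth.boxes])
    iou = _iou_matrix(a_corners, gt)          # (A, M)
    best_gt = iou.argmax(axis=1)
    best_iou = iou[np.arange(len(anchors)), best_gt]
    assignment = np.where(best_iou >= iou_threshold, best_gt, -1).astype(np.int32)
    for j in range(gt.shape[0]):              # force each truth's argmax anchor
        ai = int(iou[:, j].argmax())
        assignment[ai] = j
        best_iou[ai] = iou[ai, j]
    return MatchResult(assignment, best_iou)


def compute_loss(raw: RawPredictions, match: MatchResult, truth: Annotation,
                 anchors: AnchorSet, ratio: float = 1.2,
                 variances=(0.1, 0.1, 0.2, 0.2)) -> LossBreakdown:
    """Composite loss with hard-negative mining; see module docstring."""
    if raw.conf.shape[0] != len(anchors):
        raise ValueError("predictions inconsistent with anchor count")
    lsm = ad.log_softmax(raw.conf, axis=1)
    pos = match.positive_indices
    neg = match.negative_indices
    n_pos = len(pos)
    zero = Tensor(np.zeros(()))

    if n_pos > 0:
        gt = np.array([[b.xmin, b.ymin, b.xmax, b.ymax] for b in truth.boxes])
        labels = np.array([CLASS_INDEX[b.label] for b in truth.boxes])
        assigned = match.assignment[pos]
        targets = encode_boxes(gt[assigned], anchors.boxes[pos], variances)
        diff = ad.sub(ad.take(raw.loc, pos, axis=0), Tensor(targets.astype(np.float32)))
        norm = Tensor(np.asarray(1.0 / n_pos, dtype=np.float32))
        l_reg = ad.mul(ad.tsum(ad.smooth_l1(diff)), norm)
        l_pos = ad.mul(ad.neg(ad.tsum(ad.take2d(lsm, pos, labels[assigned]))), norm)
        k = max(1, int(math.floor(ratio * n_pos)))
    else:
        logger.warning("batch with zero positive anchors: loss is mined-negative only")
        l_reg, l_pos = zero, zero
        norm = Tensor(np.ones((), dtype=np.float32))
        k = 1

    # hardest negatives = largest background cross-entropy, selected outside the graph
    neg_ce = -lsm.data[neg, 0]
    k = min(k, len(neg))
    mined = neg[np.argsort(-neg_ce, kind="stable")[:k]]
    l_neg = ad.mul(ad.neg(ad.tsum(ad.take2d(lsm, mined, np.zeros(k, dtype=int)))), norm)
    return LossBreakdown(l_reg, l_pos, l_neg)


# ---------------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------------

@dataclass
class _Sample:
    x: np.ndarray            # (C, S, S) normalized input
    truth: Annotation        # boxes in input-pixel coordinates
    match: MatchResult


def prepare_sample(image: RasterImage, annotation: Annotation,
                   config: NetworkConfig, anchors: AnchorSet,
                   iou_threshold: float = 0.5) -> "_Sample":
    x = prepare_input(image, config)
    s = config.input_size
    if annotation.width != s or annotation.height != s:
        sx = s / annotation.width
        sy = s / annotation.height
        boxes = [type(b)(b.xmin * sx, b.ymin * sy, b.xmax * sx, b.ymax * sy,
                         label=b.label) for b in annotation.boxes]
        annotation = Annotation(annotation.image_id, s, s, boxes)
    return _Sample(x, annotation, match_anchors(anchors, annotation, iou_threshold))


@dataclass
class TrainResult:
    model: SSDDetector
    history: list[dict]
    best_epoch: int
    best_val_loss: float


def _epoch_pass(model, samples, anchors, cfg, opt=None, rng=None):
    """One pass over samples; updates parameters when ``opt`` is given."""
    order = rng.permutation(len(samples)) if rng is not None else np.arange(len(samples))
    sums = {"L_total": 0.0, "L_reg_pos": 0.0, "L_clas_pos": 0.0, "L_clas_neg": 0.0}
    n_batches = 0
    for start in range(0, len(order), cfg.batch_size):
        idx = order[start:start + cfg.batch_size]
        batch = [samples[i] for i in idx]
        xb = np.stack([s.x for s in batch])
        if opt is None:
            with ad.no_grad():
                conf, loc, _ = model.forward(xb)
                losses = _batch_loss(conf, loc, batch, anchors, cfg)
        else:
            conf, loc, _ = model.forward(xb)
            losses = _batch_loss(conf, loc, batch, anchors, cfg)
        total = losses["_tensor"]
        if not np.isfinite(total.item()):
            raise RuntimeError(f"training diverged: non-finite loss {total.item()}")
        if opt is not None:
            opt.zero_grad()
            total.backward()
            opt.step()
        for key in sums:
            sums[key] += losses[key]
        n_batches += 1
    return {k: v / max(1, n_batches) for k, v in sums.items()}


def _batch_loss(conf, loc, batch, anchors, cfg):
    parts = []
    agg = {"L_reg_pos": 0.0, "L_clas_pos": 0.0, "L_clas_neg": 0.0}
    for bi, sample in enumerate(batch):
        raw = RawPredictions(
            ad.reshape(ad.take(conf, np.array([bi]), axis=0), conf.shape[1:]),
            ad.reshape(ad.take(loc, np.array([bi]), axis=0), loc.shape[1:]))
        lb = compute_loss(raw, sample.match, sample.truth, anchors,
                          ratio=cfg.neg_pos_ratio)
        parts.append(lb.total)
        for key, t in (("L_reg_pos", lb.reg_pos), ("L_clas_pos", lb.clas_pos),
                       ("L_clas_neg", lb.clas_neg)):
            agg[key] += t.item() / len(batch)
    total = parts[0]
    for p in parts[1:]:
        total = ad.add(total, p)
    total = ad.mul(total, Tensor(np.asarray(1.0 / len(batch), dtype=np.float32)))
    out = dict(agg)
    out["L_total"] = total.item()
    out["_tensor"] = total
    return out


def fit(train_samples: list[tuple[RasterImage, Annotation]],
        val_samples: list[tuple[RasterImage, Annotation]],
        net_config: NetworkConfig, train_config: TrainConfig,
        model: SSDDetector | None = None) -> TrainResult:
    """Train a detector on in-memory samples; returns the best-val model."""
    if not train_samples or not val_samples:
        raise ValueError("train and val splits must be nonempty")
    anchors = generate_anchors(net_config)
    model = model or build_detector(net_config, seed=train_config.seed)
    tr = [prepare_sample(im, an, net_config, anchors, train_config.iou_threshold)
          for im, an in train_samples]
    va = [prepare_sample(im, an, net_config, anchors, train_config.iou_threshold)
          for im, an in val_samples]

    opt = Adam(list(model.named_parameters()), lr=train_config.lr,
               beta1=train_config.beta1, beta2=train_config.beta2,
               weight_decay=train_config.weight_decay)
    rng = np.random.default_rng(train_config.seed)
    history: list[dict] = []
    best_val = np.inf
    best_state = model.state_dict()
    best_epoch = -1
    since_best = 0
    for epoch in range(train_config.epochs):
        if epoch < train_config.freeze_epochs:
            opt.freeze(SSDDetector.BACKBONE_PREFIXES)
        else:
            opt.unfreeze_all()
        opt.lr = cosine_lr(epoch, train_config.epochs, train_config.lr,
                           train_config.lr_floor)
        row = _epoch_pass(model, tr, anchors, train_config, opt=opt, rng=rng)
        val = _epoch_pass(model, va, anchors, train_config, opt=None)
        row = {"epoch": epoch, "lr": opt.lr, **row, "val_loss": val["L_total"]}
        history.append(row)
        logger.info("epoch %d: train %.4f val %.4f", epoch, row["L_total"], row["val_loss"])
        if val["L_total"] < best_val - 1e-6:
            best_val = val["L_total"]
            best_state = model.state_dict()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best > train_config.patience:
                logger.info("early stopping at epoch %d", epoch)
                break
    model.load_state_dict(best_state)
    return TrainResult(model, history, best_epoch, float(best_val))


def _load_split(index: DatasetIndex, split: str) -> list[tuple[RasterImage, Annotation]]:
    return [(read_image(img), read_voc_annotation(xml))
            for img, xml in index.paths(split)]


def train(dataset: DatasetIndex, net_config: NetworkConfig,
          train_config: TrainConfig) -> TrainResult:
    """Train from an on-disk dataset index with train/val splits."""
    if "train" not in dataset.splits:
        raise ValueError("dataset index has no split assignment; run make_splits first")
    return fit(_load_split(dataset, "train"), _load_split(dataset, "val"),
               net_config, train_config)


def save_history_csv(history: list[dict], path: str | Path):
    cols = ["epoch", "lr", "L_total", "L_reg_pos", "L_clas_pos", "L_clas_neg", "val_loss"]
    lines = [",".join(cols)]
    for row in history:
        lines.append(",".join(f"{row[c]:.6g}" if c != "epoch" else str(row[c])
                              for c in cols))
    Path(path).write_text("\n".join(lines) + "\n")
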