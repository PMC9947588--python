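"""Detection metrics: IOU, confusion counts, precision/recall, PR curve, AP.

Matching follows the strict overlap rule used for scoring: a detection is a
true positive only when its IOU with an unmatched same-class truth box
*exceeds* the threshold (an IOU exactly at the threshold counts as a false
positive).  Average precision integrates the precision-recall curve with
all-point interpolation: the precision envelope is made monotone
non-increasing before summing the area under the recall steps.

Degenerate conventions: with no detections, precision is 1.0 (nothing was
wrongly flagged); with no truths, recall is 1.0 (nothing was missed).
Dataset-level AP over zero truth boxes is undefined and raises.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detector import DetectionResult
from .imaging_io import Annotation, BoundingBox, CLASSES

__all__ = ["ConfusionCounts", "PRCurve", "iou", "match_detections",
           "precision_recall", "average_precision", "evaluate_dataset"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass
class PRCurve:
    """(recall, precision) points swept over the score threshold, plus AP."""

    recall: np.ndarray
    precision: np.ndarray
    ap: float


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes; 0 for disjoint boxes."""
    ix = max(0.0, min(a.xmax, b.xmax) - max(a.xmin, b.xmin))
    iy = max(0.0, min(a.ymax, b.ymax) - max(a.ymin, b.ymin))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def match_detections(detections: DetectionResult | list[BoundingBox],
                     truth: Annotation, iou_threshold: float = 0.5) -> ConfusionCounts:
    """Greedy score-ordered matching of detections to truths of the same class."""
    if not (0.0 < iou_threshold < 1.0):
        raise ValueError("iou threshold must lie in (0, 1)")
    dets = detections.boxes if isinstance(detections, DetectionResult) else list(detections)
    order = sorted(range(len(dets)), key=lambda i: -(dets[i].score or 0.0))
    matched = [False] * len(truth.boxes)
    tp = fp = 0
    for di in order:
        det = dets[di]
        best_iou, best_j = 0.0, -1
        for j, gt in enumerate(truth.boxes):
            if matched[j] or gt.label != det.label:
                continue
            v = iou(det, gt)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou > iou_threshold:
            matched[best_j] = True
            tp += 1
        else:
            fp += 1
    fn = matched.count(False)
    return ConfusionCounts(tp, fp, fn)


def precision_recall(counts: ConfusionCounts) -> tuple[float, float]:
    precision = counts.tp / (counts.tp + counts.fp) if (counts.tp + counts.fp) else 1.0
    recall = counts.tp / (counts.tp + counts.fn) if (counts.tp + counts.fn) else 1.0
    return precision, recall


def _envelope_ap(recall: np.ndarray, precision: np.ndarray) -> float:
    """All-point interpolation: area under the monotone precision envelope."""
    r = np.concatenate([[0.0], recall, [recall[-1] if len(recall) else 0.0]])
    p = np.concatenate([[1.0], precision, [0.0]])
    for i in range(len(p) - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    ap = 0.0
    for i in range(1, len(r)):
        ap += (r[i] - r[i - 1]) * p[i]
    return float(ap)


def average_precision(detections: list[DetectionResult],
                      truths: list[Annotation], iou_threshold: float = 0.5,
                      label: str | None = None) -> PRCurve:
    """Dataset-level PR curve and AP, optionally restricted to one class.

    Detections across all images are ranked by score; each, in rank order, is
    greedily matched (IOU strictly above threshold) to an unmatched truth of
    its class in its own image.  Cumulative precision/recall at each rank
    gives the swept curve, integrated by all-point interpolation.
    """
    by_id = {t.image_id: t for t in truths}
    gt_matched: dict[str, list[bool]] = {t.image_id: [False] * len(t.boxes) for t in truths}
    n_truth = sum(1 for t in truths for b in t.boxes
                  if label is None or b.label == label)
    if n_truth == 0:
        raise ValueError("AP undefined: no ground-truth boxes" +
                         (f" of class {label}" if label else ""))
    ranked = []
    for det in detections:
        for box in det.boxes:
            if label is None or box.label == label:
                ranked.append((box.score or 0.0, det.image_id, box))
    ranked.sort(key=lambda t: -t[0])

    tps = np.zeros(len(ranked))
    fps = np.zeros(len(ranked))
    for rank, (_score, image_id, box) in enumerate(ranked):
        t = by_id.get(image_id)
        best_iou, best_j = 0.0, -1
        if t is not None:
            for j, gt in enumerate(t.boxes):
                if gt_matched[image_id][j] or gt.label != box.label:
                    continue
                v = iou(box, gt)
                if v > best_iou:
                    best_iou, best_j = v, j
        if best_j >= 0 and best_iou > iou_threshold:
            gt_matched[image_id][best_j] = True
            tps[rank] = 1
        else:
            fps[rank] = 1
    ctp = np.cumsum(tps)
    cfp = np.cumsum(fps)
    recall = ctp / n_truth
    precision = np.where(ctp + cfp > 0, ctp / np.maximum(ctp + cfp, 1), 1.0)
    return PRCurve(recall, precision, _envelope_ap(recall, precision))


def evaluate_dataset(detections: list[DetectionResult], truths: list[Annotation],
                     iou_threshold: float = 0.5) -> dict:
    """Per-class AP plus precision/recall at the operating score threshold."""
    report: dict = {"classes": {}}
    aps = []
    for cls in CLASSES:
        have_truth = any(b.label == cls for t in truths for b in t.boxes)
        entry: dict = {}
        if have_truth:
            curve = average_precision(detections, truths, iou_threshold, label=cls)
            entry["ap"] = curve.ap
            aps.append(curve.ap)
        counts = ConfusionCounts()
        for det in detections:
            t = next((x for x in truths if x.image_id == det.image_id), None)
            if t is None:
                continue
            cls_det = [b for b in det.boxes if b.label == cls]
            cls_truth = Annotation(t.image_id, t.height, t.width, t.of_class(cls))
            counts = counts + match_detections(cls_det, cls_truth, iou_threshold)
        p, r = precision_recall(counts)
        entry.update({"precision": p, "recall": r,
                      "tp": counts.tp, "fp": counts.fp, "fn": counts.fn})
        report["classes"][cls] = entry
    if aps:
        report["macro_ap"] = float(np.mean(aps))
    return report
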