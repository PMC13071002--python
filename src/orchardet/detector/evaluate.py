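"""Detection metrics: mAP@0.5, precision/recall/F1, PR curves, confusion.

Matching is greedy per class by descending score at IoU >= 0.5, one
match per ground-truth box; score ties and IoU ties break toward the
lower box index so evaluation is bit-reproducible.  AP uses all-point
interpolation (the precision envelope), and mAP is the unweighted mean
over classes that have ground truth.  The confusion matrix carries a
background row/column: rows are ground-truth classes, columns
predictions; misses land in the background column and false alarms in
the background row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..boxes import iou_matrix

__all__ = ["DetectionSet", "nms", "evaluate", "average_precision"]


@dataclass
class DetectionSet:
    """Detections for one image: absolute xyxy boxes, scores, class ids."""

    boxes: np.ndarray = field(default_factory=lambda: np.zeros((0, 4)))
    scores: np.ndarray = field(default_factory=lambda: np.zeros(0))
    class_ids: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))

    def __post_init__(self):
        self.boxes = np.asarray(self.boxes, dtype=np.float64).reshape(-1, 4)
        self.scores = np.asarray(self.scores, dtype=np.float64).reshape(-1)
        self.class_ids = np.asarray(self.class_ids, dtype=np.int64).reshape(-1)
        if not (len(self.boxes) == len(self.scores) == len(self.class_ids)):
            raise ValueError("boxes, scores and class_ids must have equal length")
        if self.scores.size and (self.scores.min() < 0 or self.scores.max() > 1):
            raise ValueError("scores must lie in [0, 1]")


def _sort_desc_stable(scores: np.ndarray) -> np.ndarray:
    """Descending-score order with ties broken by lower index."""
    return np.argsort(-scores, kind="stable")


def nms(det: DetectionSet, iou_threshold: float = 0.5) -> DetectionSet:
    """Greedy per-class non-maximum suppression."""
    keep = []
    for cid in np.unique(det.class_ids):
        idx = np.nonzero(det.class_ids == cid)[0]
        order = idx[_sort_desc_stable(det.scores[idx])]
        alive = list(order)
        while alive:
            best = alive.pop(0)
            keep.append(best)
            if not alive:
                break
            ious = iou_matrix(det.boxes[[best]], det.boxes[alive])[0]
            alive = [a for a, i in zip(alive, ious) if i < iou_threshold]
    keep = sorted(keep)
    return DetectionSet(det.boxes[keep], det.scores[keep], det.class_ids[keep])


def average_precision(tp_flags: np.ndarray, scores: np.ndarray, n_truth: int) -> tuple[float, np.ndarray, np.ndarray]:
    """All-point interpolated AP from per-detection TP flags.

    Returns (AP, recall curve, precision curve) with detections taken
    in descending-score order.
    """
    if n_truth == 0:
        return float("nan"), np.zeros(0), np.zeros(0)
    order = _sort_desc_stable(scores)
    tp = tp_flags[order].astype(np.float64)
    fp = 1.0 - tp
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(fp)
    recall = cum_tp / n_truth
    precision = cum_tp / np.maximum(cum_tp + cum_fp, 1e-12)
    # precision envelope: monotone non-increasing from the right
    env = precision.copy()
    for i in range(len(env) - 2, -1, -1):
        env[i] = max(env[i], env[i + 1])
    # integrate over recall steps (all-point interpolation)
    r_prev = 0.0
    ap = 0.0
    for r, p in zip(recall, env):
        if r > r_prev:
            ap += (r - r_prev) * p
            r_prev = r
    return float(ap), recall, precision


def _match_image(
    det: DetectionSet, truth_boxes: np.ndarray, truth_classes: np.ndarray, iou_threshold: float, class_agnostic: bool = False
):
    """Greedy matching; returns per-detection matched truth index (-1 = FP)."""
    matches = np.full(len(det.boxes), -1, dtype=np.int64)
    taken = np.zeros(len(truth_boxes), dtype=bool)
    if len(det.boxes) == 0 or len(truth_boxes) == 0:
        return matches
    ious = iou_matrix(det.boxes, truth_boxes)
    for di in _sort_desc_stable(det.scores):
        best_iou, best_ti = -1.0, -1
        for ti in range(len(truth_boxes)):
            if taken[ti]:
                continue
            if not class_agnostic and truth_classes[ti] != det.class_ids[di]:
                continue
            # strict > keeps IoU ties at the lower truth index
            if ious[di, ti] >= iou_threshold and ious[di, ti] > best_iou:
                best_iou, best_ti = ious[di, ti], ti
        if best_ti >= 0:
            taken[best_ti] = True
            matches[di] = best_ti
    return matches


def evaluate(
    detections: list[DetectionSet],
    truth_boxes: list[np.ndarray],
    truth_classes: list[np.ndarray],
    num_classes: int = 3,
    iou_threshold: float = 0.5,
) -> dict:
    """Compute mAP@IoU, micro precision/recall/F1, per-class AP and curves.

    ``detections[i]`` pairs with ``truth_boxes[i]`` (N_i, 4 xyxy) and
    ``truth_classes[i]`` (N_i,).  Results are invariant to image order.
    """
    if not (len(detections) == len(truth_boxes) == len(truth_classes)):
        raise ValueError("detections and truth lists must align per image")
    per_class_ap: dict[int, float] = {}
    pr_curves: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    total_tp = total_det = total_truth = 0
    confusion = np.zeros((num_classes + 1, num_classes + 1), dtype=np.int64)

    # class-aware matching per image, pooled over the dataset for AP
    for cid in range(num_classes):
        flags, scores = [], []
        n_truth = 0
        for det, tb, tc in zip(detections, truth_boxes, truth_classes):
            tb = np.asarray(tb, dtype=np.float64).reshape(-1, 4)
            tc = np.asarray(tc, dtype=np.int64).reshape(-1)
            sel = det.class_ids == cid
            sub = DetectionSet(det.boxes[sel], det.scores[sel], det.class_ids[sel])
            tsel = tc == cid
            n_truth += int(tsel.sum())
            matches = _match_image(sub, tb[tsel], tc[tsel], iou_threshold)
            flags.append(matches >= 0)
            scores.append(sub.scores)
        flags = np.concatenate(flags) if flags else np.zeros(0, dtype=bool)
        scores = np.concatenate(scores) if scores else np.zeros(0)
        if n_truth > 0:
            ap, recall, precision = average_precision(flags, scores, n_truth)
            per_class_ap[cid] = ap
            pr_curves[cid] = (recall, precision)
            total_tp += int(flags.sum())
        total_det += len(flags)
        total_truth += n_truth

    # confusion matrix via class-agnostic matching
    for det, tb, tc in zip(detections, truth_boxes, truth_classes):
        tb = np.asarray(tb, dtype=np.float64).reshape(-1, 4)
        tc = np.asarray(tc, dtype=np.int64).reshape(-1)
        matches = _match_image(det, tb, tc, iou_threshold, class_agnostic=True)
        matched_truth = set()
        for di, ti in enumerate(matches):
            if ti >= 0:
                confusion[tc[ti], det.class_ids[di]] += 1
                matched_truth.add(int(ti))
            else:
                confusion[num_classes, det.class_ids[di]] += 1  # false alarm
        for ti in range(len(tb)):
            if ti not in matched_truth:
                confusion[tc[ti], num_classes] += 1  # miss

    precision = total_tp / total_det if total_det else 0.0
    recall = total_tp / total_truth if total_truth else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    aps = [ap for ap in per_class_ap.values() if not np.isnan(ap)]
    return {
        "mAP@0.5": float(np.mean(aps)) if aps else 0.0,
        "precision": float(precision),
        "recall": float(recall),
        "F1": float(f1),
        "per_class_AP": per_class_ap,
        "pr_curves": pr_curves,
        "confusion_matrix": confusion,
    }
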