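"""Detection metrics: confusion counts, P/R/F1, COCO-style AP/mAP, FPS.

Detections are given per image as ``(boxes, scores)`` with corner-format
boxes; ground truth as per-image box arrays.  Matching is greedy in
descending score order with each ground-truth box claimable once.  AP
uses the 101-point interpolation of the precision-recall integral
(precision envelope sampled at recall 0.00, 0.01, ..., 1.00);
mAP@0.5:0.95 averages AP over IoU thresholds 0.50 to 0.95 in steps of
0.05.  Percentages are reported on the 0-100 scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .losses import iou_corners

__all__ = [
    "MetricReport", "confusion_counts", "precision_recall_f1",
    "average_precision", "map50", "map50_95", "evaluate_detections", "fps",
]

IOU_GRID = np.arange(0.50, 0.96, 0.05).round(2)
RECALL_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class MetricReport:
    precision: float
    recall: float
    f1: float
    map50: float
    map50_95: float
    tp: int
    fp: int
    fn: int
    iou_thr: float = 0.5
    score_thr: float = 0.5


def _greedy_match(boxes: np.ndarray, scores: np.ndarray, gt: np.ndarray,
                  iou_thr: float) -> np.ndarray:
    """For detections sorted by descending score, a bool 'hit' flag per
    detection (each gt matched at most once, best IoU >= thr wins)."""
    hits = np.zeros(len(boxes), dtype=bool)
    if len(gt) == 0 or len(boxes) == 0:
        return hits
    iou = iou_corners(boxes, gt)
    taken = np.zeros(len(gt), dtype=bool)
    for d in range(len(boxes)):
        cand = np.where(~taken & (iou[d] >= iou_thr))[0]
        if len(cand):
            best = cand[np.argmax(iou[d][cand])]
            taken[best] = True
            hits[d] = True
    return hits


def confusion_counts(detections, ground_truth, iou_thr: float = 0.5,
                     score_thr: float = 0.5) -> tuple[int, int, int]:
    """(TP, FP, FN) over a dataset at one operating point.

    detections: per image (boxes (n,4), scores (n,)); ground_truth: per
    image (m, 4) arrays.
    """
    tp = fp = fn = 0
    for (boxes, scores), gt in zip(detections, ground_truth):
        boxes = np.asarray(boxes, np.float32).reshape(-1, 4)
        scores = np.asarray(scores, np.float32).reshape(-1)
        gt = np.asarray(gt, np.float32).reshape(-1, 4)
        keep = scores >= score_thr
        boxes, scores = boxes[keep], scores[keep]
        order = np.argsort(-scores, kind="stable")
        hits = _greedy_match(boxes[order], scores[order], gt, iou_thr)
        tp += int(hits.sum())
        fp += int((~hits).sum())
        fn += int(len(gt) - hits.sum())
    return tp, fp, fn


def precision_recall_f1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """P, R and their harmonic mean, zero by convention on empty
    denominators; returned as fractions in [0, 1]."""
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def average_precision(detections, ground_truth, iou_thr: float = 0.5) -> float:
    """COCO-style 101-point interpolated AP over the whole dataset."""
    all_scores, all_hits, n_gt = [], [], 0
    for (boxes, scores), gt in zip(detections, ground_truth):
        boxes = np.asarray(boxes, np.float32).reshape(-1, 4)
        scores = np.asarray(scores, np.float32).reshape(-1)
        gt = np.asarray(gt, np.float32).reshape(-1, 4)
        n_gt += len(gt)
        order = np.argsort(-scores, kind="stable")
        hits = _greedy_match(boxes[order], scores[order], gt, iou_thr)
        all_scores.append(scores[order])
        all_hits.append(hits)
    if n_gt == 0:
        return 0.0
    scores = np.concatenate(all_scores) if all_scores else np.zeros(0)
    hits = np.concatenate(all_hits) if all_hits else np.zeros(0, bool)
    if len(scores) == 0:
        return 0.0
    order = np.argsort(-scores, kind="stable")
    hits = hits[order]
    tp_cum = np.cumsum(hits)
    fp_cum = np.cumsum(~hits)
    recall = tp_cum / n_gt
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1)
    # precision envelope, then sample the 101 recall points
    env = np.maximum.accumulate(precision[::-1])[::-1]
    idx = np.searchsorted(recall, RECALL_GRID, side="left")
    ap = np.where(idx < len(env), env[np.minimum(idx, len(env) - 1)], 0.0).mean()
    return float(ap)


def map50(detections, ground_truth) -> float:
    """mAP at IoU 0.5 as a percentage (single foreground class)."""
    return 100.0 * average_precision(detections, ground_truth, 0.5)


def map50_95(detections, ground_truth) -> float:
    """mAP averaged over IoU 0.50:0.05:0.95, as a percentage."""
    aps = [average_precision(detections, ground_truth, float(t)) for t in IOU_GRID]
    return 100.0 * float(np.mean(aps))


def evaluate_detections(detections, ground_truth, iou_thr: float = 0.5,
                        score_thr: float = 0.5) -> MetricReport:
    tp, fp, fn = confusion_counts(detections, ground_truth, iou_thr, score_thr)
    p, r, f1 = precision_recall_f1(tp, fp, fn)
    return MetricReport(
        precision=100.0 * p, recall=100.0 * r, f1=100.0 * f1,
        map50=map50(detections, ground_truth),
        map50_95=map50_95(detections, ground_truth),
        tp=tp, fp=fp, fn=fn, iou_thr=iou_thr, score_thr=score_thr)


def fps(t_pre_ms: float, t_inf_ms: float, t_nms_ms: float = 0.0) -> float:
    """Frames per second from per-stage mean latencies in milliseconds."""
    return 1000.0 / (t_pre_ms + t_inf_ms + t_nms_ms)
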