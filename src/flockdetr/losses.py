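"""Classification and box losses plus bipartite matching.

Two IoU-aware classification losses are provided.  The varifocal loss
weighs positive targets by their localization quality q (the IoU of the
predicted box against its assigned ground truth):

    L_VFL(p, q) = -q (q log p + (1 - q) log(1 - p))        q > 0
                  -alpha p^gamma log(1 - p)                 q = 0

The matchability-aware loss instead replaces the soft positive label q
by q^gamma and drops the negative-side alpha balance entirely:

    L_MAL(p, q, y) = -(q^gamma log p + (1 - q^gamma) log(1 - p))   y = 1
                     -p^gamma log(1 - p)                            y = 0

For a fixed match quality q < 1 the positive branch is a soft-label
cross-entropy minimized at p = q^gamma, so confidence is pulled toward
(a sharpened version of) localization quality; on the negative branch
the p^gamma factor focuses gradient on confident false positives.

Box terms use the L1 distance on normalized (cx, cy, w, h) boxes and
the generalized IoU penalty 1 - GIoU.  One-to-one assignment between
queries and ground-truth boxes is the Hungarian minimum of

    cost = w_cls (1 - p) + w_l1 ||b - b*||_1 + w_giou (1 - GIoU)

All loss functions are differentiable through the autodiff engine; the
match itself (and the q targets) are treated as constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .engine import tensor as T
from .engine.tensor import Tensor

__all__ = [
    "LossWeights", "MatchResult", "vfl_loss", "mal_loss",
    "box_cxcywh_to_corners", "iou_corners", "giou", "giou_corners",
    "hungarian_match", "total_loss",
]

EPS_P = 1e-7           # probability clamp (smallest float32-effective gap at 1)


@dataclass(frozen=True)
class LossWeights:
    lambda_cls: float = 1.0
    lambda_l1: float = 5.0
    lambda_giou: float = 2.0
    gamma: float = 2.0
    loss_type: str = "mal"            # "mal" or "vfl"
    alpha: float = 0.75               # vfl negative balance only
    cost_cls: float = 2.0
    cost_l1: float = 5.0
    cost_giou: float = 2.0

    def __post_init__(self):
        if min(self.lambda_cls, self.lambda_l1, self.lambda_giou) < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.loss_type in ("slide", "emaslide"):
            raise NotImplementedError(
                f"loss type {self.loss_type!r} is recognized but not implemented")
        if self.loss_type not in ("mal", "vfl"):
            raise ValueError(f"unknown loss type {self.loss_type!r}")


@dataclass
class MatchResult:
    """One-to-one query/ground-truth assignment for a batch.

    Per image: ``pairs[i]`` is an (m_i, 2) int array of (query, gt)
    indices, ``quality[i]`` the per-pair IoU q, and ``labels[i]`` the
    binary y over all queries (1 iff matched).
    """

    pairs: list[np.ndarray] = field(default_factory=list)
    quality: list[np.ndarray] = field(default_factory=list)
    labels: list[np.ndarray] = field(default_factory=list)

    @property
    def num_matched(self) -> int:
        return int(sum(len(p) for p in self.pairs))


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _clamp_p(p: Tensor) -> Tensor:
    return T.clip(p, EPS_P, 1.0 - EPS_P)


def vfl_loss(p, q, alpha: float = 0.75, gamma: float = 2.0) -> Tensor:
    """Elementwise varifocal loss; q > 0 selects the positive branch."""
    p, q = _as_tensor(p), _as_tensor(q)
    pc = _clamp_p(p)
    pos = -(q * (q * T.log(pc) + (1.0 - q) * T.log(1.0 - pc)))
    neg = -(alpha * T.power(pc, gamma) * T.log(1.0 - pc))
    mask = Tensor((q.data > 0).astype(np.float32))
    return mask * pos + (1.0 - mask) * neg


def mal_loss(p, q, y, gamma: float = 2.0) -> Tensor:
    """Elementwise matchability-aware loss; y in {0, 1}."""
    p, q, y = _as_tensor(p), _as_tensor(q), _as_tensor(y)
    pc = _clamp_p(p)
    qg = T.power(q, gamma)
    pos = -(qg * T.log(pc) + (1.0 - qg) * T.log(1.0 - pc))
    neg = -(T.power(pc, gamma) * T.log(1.0 - pc))
    return y * pos + (1.0 - y) * neg


def box_cxcywh_to_corners(b):
    """(cx, cy, w, h) -> (x0, y0, x1, y1); works on Tensor or ndarray."""
    if isinstance(b, Tensor):
        cx, cy, w, h = b[..., 0], b[..., 1], b[..., 2], b[..., 3]
        stack = [cx - 0.5 * w, cy - 0.5 * h, cx + 0.5 * w, cy + 0.5 * h]
        expanded = [s.reshape(s.shape + (1,)) for s in stack]
        return T.concat(expanded, axis=-1)
    b = np.asarray(b, dtype=np.float32)
    cx, cy, w, h = b[..., 0], b[..., 1], b[..., 2], b[..., 3]
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=-1)


def iou_corners(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (n, 4) and (m, 4) corner boxes -> (n, m)."""
    a, b = np.asarray(a, np.float64), np.asarray(b, np.float64)
    x0 = np.maximum(a[:, None, 0], b[None, :, 0])
    y0 = np.maximum(a[:, None, 1], b[None, :, 1])
    x1 = np.minimum(a[:, None, 2], b[None, :, 2])
    y1 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(x1 - x0, 0, None) * np.clip(y1 - y0, 0, None)
    area_a = np.clip(a[:, 2] - a[:, 0], 0, None) * np.clip(a[:, 3] - a[:, 1], 0, None)
    area_b = np.clip(b[:, 2] - b[:, 0], 0, None) * np.clip(b[:, 3] - b[:, 1], 0, None)
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def giou_corners(a, b) -> Tensor:
    """Elementwise GIoU between corner boxes of identical leading shape
    (..., 4); differentiable."""
    a, b = _as_tensor(a), _as_tensor(b)
    ix0 = T.maximum(a[..., 0], b[..., 0])
    iy0 = T.maximum(a[..., 1], b[..., 1])
    ix1 = T.minimum(a[..., 2], b[..., 2])
    iy1 = T.minimum(a[..., 3], b[..., 3])
    inter = T.clip(ix1 - ix0, 0.0, None) * T.clip(iy1 - iy0, 0.0, None)
    area_a = T.clip(a[..., 2] - a[..., 0], 0.0, None) * T.clip(a[..., 3] - a[..., 1], 0.0, None)
    area_b = T.clip(b[..., 2] - b[..., 0], 0.0, None) * T.clip(b[..., 3] - b[..., 1], 0.0, None)
    union = area_a + area_b - inter
    iou = inter * T.power(union + 1e-12, -1.0)
    ex0 = T.minimum(a[..., 0], b[..., 0])
    ey0 = T.minimum(a[..., 1], b[..., 1])
    ex1 = T.maximum(a[..., 2], b[..., 2])
    ey1 = T.maximum(a[..., 3], b[..., 3])
    enclose = (ex1 - ex0) * (ey1 - ey0)
    return iou - (enclose - union) * T.power(enclose + 1e-12, -1.0)


def giou(b, b_star) -> Tensor:
    """GIoU of two boxes given in corner format (x0, y0, x1, y1)."""
    return giou_corners(b, b_star)


def hungarian_match(scores: np.ndarray, boxes: np.ndarray,
                    targets: list[np.ndarray],
                    weights: LossWeights = LossWeights()) -> MatchResult:
    """Minimum-cost one-to-one assignment per image.

    scores: (B, Q) foreground probabilities; boxes: (B, Q, 4) normalized
    cxcywh; targets: per-image (n_i, 4) normalized cxcywh ground truth.
    Unmatched queries get label 0; q is the IoU of each matched pair.
    """
    result = MatchResult()
    for img, gt in enumerate(targets):
        Q = scores.shape[1]
        y = np.zeros(Q, dtype=np.float32)
        gt = np.asarray(gt, dtype=np.float32).reshape(-1, 4)
        if len(gt) == 0:
            result.pairs.append(np.zeros((0, 2), dtype=int))
            result.quality.append(np.zeros(0, dtype=np.float32))
            result.labels.append(y)
            continue
        p = scores[img]
        pb = box_cxcywh_to_corners(boxes[img])
        gb = box_cxcywh_to_corners(gt)
        cost_cls = weights.cost_cls * (1.0 - p)[:, None]
        cost_l1 = weights.cost_l1 * np.abs(
            boxes[img][:, None, :] - gt[None, :, :]).sum(-1)
        g = giou_corners(
            np.repeat(pb[:, None, :], len(gt), axis=1),
            np.repeat(gb[None, :, :], Q, axis=0)).data
        cost = cost_cls + cost_l1 + weights.cost_giou * (1.0 - g)
        qi, gi = linear_sum_assignment(cost)
        iou = iou_corners(pb, gb)[qi, gi].astype(np.float32)
        y[qi] = 1.0
        result.pairs.append(np.stack([qi, gi], axis=1))
        result.quality.append(iou)
        result.labels.append(y)
    return result


def total_loss(scores: Tensor, boxes: Tensor, targets: list[np.ndarray],
               weights: LossWeights = LossWeights(),
               match: MatchResult | None = None) -> tuple[Tensor, dict]:
    """Composite objective over a batch.

    scores: (B, Q) probabilities (Tensor); boxes: (B, Q, 4) cxcywh
    (Tensor); targets: per-image (n_i, 4) ground truth.  Returns the
    scalar total and a components dict (floats, same normalization).
    Normalization divides every term by the number of matched pairs
    (minimum 1, so an all-negative batch yields a pure classification
    penalty).
    """
    B, Q = scores.shape
    if match is None:
        match = hungarian_match(scores.data, boxes.data, targets, weights)
    n_match = max(match.num_matched, 1)

    qmap = np.zeros((B, Q), dtype=np.float32)
    ymap = np.zeros((B, Q), dtype=np.float32)
    for img in range(B):
        pairs = match.pairs[img]
        if len(pairs):
            qmap[img, pairs[:, 0]] = match.quality[img]
        ymap[img] = match.labels[img]

    if weights.loss_type == "vfl":
        cls_el = vfl_loss(scores, Tensor(qmap), weights.alpha, weights.gamma)
    else:
        cls_el = mal_loss(scores, Tensor(qmap), Tensor(ymap), weights.gamma)
    cls = cls_el.sum() * (1.0 / n_match)

    l1_sum: Tensor | float = Tensor(np.zeros(()))
    giou_sum: Tensor | float = Tensor(np.zeros(()))
    for img in range(B):
        pairs = match.pairs[img]
        if not len(pairs):
            continue
        gt = np.asarray(targets[img], dtype=np.float32).reshape(-1, 4)
        pred_b = boxes[img][pairs[:, 0]]
        gt_b = Tensor(gt[pairs[:, 1]])
        l1_sum = l1_sum + abs_sum(pred_b - gt_b)
        gv = giou_corners(box_cxcywh_to_corners(pred_b),
                          box_cxcywh_to_corners(gt_b))
        giou_sum = giou_sum + (1.0 - gv).sum()
    l1 = l1_sum * (1.0 / n_match)
    gl = giou_sum * (1.0 / n_match)

    total = weights.lambda_cls * cls + weights.lambda_l1 * l1 + weights.lambda_giou * gl
    comps = {"cls": float(cls.data) * weights.lambda_cls,
             "l1": float(l1.data) * weights.lambda_l1,
             "giou": float(gl.data) * weights.lambda_giou,
             "num_matched": match.num_matched}
    return total, comps


def abs_sum(x: Tensor) -> Tensor:
    """Sum of absolute values (L1), differentiable."""
    pos = T.clip(x, 0.0, None)
    neg = T.clip(-1.0 * x, 0.0, None)
    return (pos + neg).sum()
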