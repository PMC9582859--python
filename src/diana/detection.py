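"""Anchor machinery, the class/box prediction subnetworks, their losses and
decoding into final detections.

Anchors: ``N_a`` boxes per spatial location of every pyramid level, the base
size proportional to the level's stride.  Assignment follows the standard
single-stage convention: anchors with max IoU >= 0.5 against a ground truth
are positive, < 0.4 negative, in between ignored; every ground truth is
force-matched to its best anchor.  Classification uses the focal loss
(alpha = 0.25, gamma = 1.8), box regression a smooth-L1 on anchor-relative
offsets (center shifts normalized by anchor size, log size ratios), both
normalized by the number of positive anchors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import tensor as T
from .metrics import box_iou


@dataclass(frozen=True)
class DetectionHeadConfig:
    n_classes: int = 6
    m_class: int = 4
    m_box: int = 4
    scales: tuple = (1.0, 2 ** 0.5)
    ratios: tuple = (1.0, 2.0)
    anchor_scale: float = 4.0
    assign_pos_iou: float = 0.5
    assign_neg_iou: float = 0.4
    score_thresh: float = 0.25
    nms_iou: float = 0.5
    top_k: int = 100
    prior_prob: float = 0.01

    @property
    def n_anchors(self) -> int:
        return len(self.scales) * len(self.ratios)

    def __post_init__(self):
        if self.assign_neg_iou > self.assign_pos_iou:
            raise ValueError("assign_neg_iou must be <= assign_pos_iou")


@dataclass
class Detection:
    box: np.ndarray       # corner form (x0, y0, x1, y1), input-image pixels
    class_id: int         # 1..N_cls
    score: float


# -- anchors -----------------------------------------------------------------

def generate_anchors(level_shapes: dict, strides: dict,
                     cfg: DetectionHeadConfig) -> dict:
    """Corner-form anchors per level: array (H*W*N_a, 4), centered on cell
    centers, base size = stride * anchor_scale."""
    out = {}
    for l, (h, w) in level_shapes.items():
        stride = strides[l]
        base = stride * cfg.anchor_scale
        sizes = []
        for scale in cfg.scales:
            for ratio in cfg.ratios:
                bw = base * scale * np.sqrt(ratio)
                bh = base * scale / np.sqrt(ratio)
                sizes.append((bw, bh))
        cy, cx = np.mgrid[0:h, 0:w].astype(np.float64)
        cx = (cx + 0.5) * stride
        cy = (cy + 0.5) * stride
        anchors = np.empty((h, w, len(sizes), 4))
        for a, (bw, bh) in enumerate(sizes):
            anchors[..., a, 0] = cx - bw / 2
            anchors[..., a, 1] = cy - bh / 2
            anchors[..., a, 2] = cx + bw / 2
            anchors[..., a, 3] = cy + bh / 2
        out[l] = anchors.reshape(-1, 4)
    return out


# -- box transform -----------------------------------------------------------

def encode_boxes(anchors: np.ndarray, boxes: np.ndarray) -> np.ndarray:
    """Anchor-relative offsets {x, y, w, h}: center shift / anchor size and
    log size ratios.  Exact inverse of :func:`decode_boxes`."""
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    acx = anchors[:, 0] + aw / 2
    acy = anchors[:, 1] + ah / 2
    bw = boxes[:, 2] - boxes[:, 0]
    bh = boxes[:, 3] - boxes[:, 1]
    bcx = boxes[:, 0] + bw / 2
    bcy = boxes[:, 1] + bh / 2
    return np.stack([(bcx - acx) / aw, (bcy - acy) / ah,
                     np.log(bw / aw), np.log(bh / ah)], axis=1)


def decode_boxes(anchors: np.ndarray, deltas: np.ndarray) -> np.ndarray:
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    acx = anchors[:, 0] + aw / 2
    acy = anchors[:, 1] + ah / 2
    bcx = deltas[:, 0] * aw + acx
    bcy = deltas[:, 1] * ah + acy
    bw = np.exp(deltas[:, 2]) * aw
    bh = np.exp(deltas[:, 3]) * ah
    return np.stack([bcx - bw / 2, bcy - bh / 2,
                     bcx + bw / 2, bcy + bh / 2], axis=1)


# -- subnetworks ---------------------------------------------------------------

class PredictionSubnet(nn.Module):
    """M 3x3 conv + ReLU layers then a prediction conv; parameters are shared
    across pyramid levels (forward is applied level by level)."""

    def __init__(self, channels: int, depth: int, out_per_anchor: int,
                 n_anchors: int, prior_prob: float | None = None,
                 dropout: float = 0.0, rng=None):
        super().__init__()
        self.hidden = [nn.Conv2d(channels, channels, k=3, rng=rng)
                       for _ in range(depth)]
        self.dropout = nn.Dropout(dropout, rng=rng) if dropout > 0 else None
        self.pred = nn.Conv2d(channels, n_anchors * out_per_anchor, k=3, rng=rng)
        self.pred.weight.data *= 0.01  # small head init stabilizes early steps
        if prior_prob is not None:
            self.pred.bias.data[:] = -np.log((1 - prior_prob) / prior_prob)
        self.out_per_anchor = out_per_anchor
        self.n_anchors = n_anchors

    def forward(self, p: nn.Tensor) -> nn.Tensor:
        """Returns (N, H*W*N_a, out_per_anchor) raw outputs for one level."""
        h = p
        for conv in self.hidden:
            h = T.relu(conv(h))
        if self.dropout is not None:
            h = self.dropout(h)
        h = self.pred(h)
        n, c, hh, ww = h.shape
        h = h.reshape(n, self.n_anchors, self.out_per_anchor, hh, ww)
        h = h.transpose(0, 3, 4, 1, 2)
        return h.reshape(n, hh * ww * self.n_anchors, self.out_per_anchor)


def class_subnet(cfg: DetectionHeadConfig, channels: int, dropout: float = 0.0,
                 rng=None) -> PredictionSubnet:
    return PredictionSubnet(channels, cfg.m_class, cfg.n_classes,
                            cfg.n_anchors, prior_prob=cfg.prior_prob,
                            dropout=dropout, rng=rng)


def box_subnet(cfg: DetectionHeadConfig, channels: int, rng=None) -> PredictionSubnet:
    return PredictionSubnet(channels, cfg.m_box, 4, cfg.n_anchors, rng=rng)


# -- target assignment ---------------------------------------------------------

def assign_targets(anchors: np.ndarray, gt_boxes: np.ndarray,
                   gt_classes: np.ndarray, cfg: DetectionHeadConfig):
    """Per-anchor classification/regression targets.

    Returns (cls_target (A, N_cls) one-hot, cls_weight (A,), box_target
    (A, 4) deltas, box_weight (A,)).  cls_weight 0 marks ignored anchors.
    """
    a = len(anchors)
    cls_target = np.zeros((a, cfg.n_classes), dtype=np.float32)
    cls_weight = np.ones(a, dtype=np.float32)
    box_target = np.zeros((a, 4), dtype=np.float32)
    box_weight = np.zeros(a, dtype=np.float32)
    if len(gt_boxes) == 0:
        return cls_target, cls_weight, box_target, box_weight
    ious = box_iou(anchors, gt_boxes)          # (A, G)
    best_gt = ious.argmax(axis=1)
    best_iou = ious[np.arange(a), best_gt]
    pos = best_iou >= cfg.assign_pos_iou
    ignore = (~pos) & (best_iou >= cfg.assign_neg_iou)
    # force-match: every gt claims its best anchor
    forced = ious.argmax(axis=0)
    best_gt[forced] = np.arange(len(gt_boxes))
    pos[forced] = True
    ignore[forced] = False
    cls_weight[ignore] = 0.0
    idx = np.nonzero(pos)[0]
    cls_target[idx, gt_classes[best_gt[idx]] - 1] = 1.0
    box_target[idx] = encode_boxes(anchors[idx], gt_boxes[best_gt[idx]]
                                   ).astype(np.float32)
    box_weight[idx] = 1.0
    return cls_target, cls_weight, box_target, box_weight


# -- losses --------------------------------------------------------------------

_EPS = 1e-6


def focal_loss(probs: nn.Tensor, cls_target: np.ndarray, cls_weight: np.ndarray,
               alpha: float = 0.25, gamma: float = 1.8) -> nn.Tensor:
    """Focal loss over per-anchor class probabilities, summed over anchors
    and classes and normalized by the positive-anchor count.

    ``probs`` are post-sigmoid probabilities (A, N_cls); targets one-hot.
    """
    dtype = probs.data.dtype
    y = cls_target.astype(dtype)
    p = T.clip(probs, _EPS, 1.0 - _EPS)
    p_t = p * nn.Tensor(y) + (1.0 - p) * nn.Tensor(1.0 - y)
    alpha_t = nn.Tensor((alpha * y + (1 - alpha) * (1 - y)).astype(dtype))
    w = nn.Tensor(cls_weight[..., None].astype(dtype))
    loss = alpha_t * ((1.0 - p_t) ** gamma) * (-T.log(p_t)) * w
    n_pos = max(float((cls_target.sum(axis=-1) > 0).sum()), 1.0)
    return loss.sum() / n_pos


def smooth_l1(pred: nn.Tensor, box_target: np.ndarray, box_weight: np.ndarray,
              beta: float = 0.1) -> nn.Tensor:
    """Huber-style regression loss on positive anchors: 0.5 d^2/beta for
    |d| < beta else |d| - beta/2, summed over the 4 coordinates and averaged
    over positives.  Returns 0 when there are no positives."""
    n_pos = float((box_weight > 0).sum())
    if n_pos == 0:
        return nn.Tensor(np.zeros((), dtype=np.float32))
    d = pred - nn.Tensor(box_target)
    absd = np.abs(d.data)
    quad_mask = absd < beta
    quad = (d ** 2.0) * (0.5 / beta)
    lin_sign = nn.Tensor(np.sign(d.data))
    lin = d * lin_sign - 0.5 * beta
    elem = T.where_mask(quad_mask, quad, lin)
    w = nn.Tensor(box_weight[..., None].astype(np.float32))
    return (elem * w).sum() / n_pos


def smooth_l1_reference(d: np.ndarray, beta: float = 0.1) -> np.ndarray:
    """Closed-form elementwise value (for tests / reporting)."""
    absd = np.abs(d)
    return np.where(absd < beta, 0.5 * d ** 2 / beta, absd - 0.5 * beta)


# -- decoding ------------------------------------------------------------------

def nms(boxes: np.ndarray, scores: np.ndarray, iou_thresh: float) -> list:
    """Greedy non-maximum suppression; returns kept indices, score order."""
    order = np.argsort(-scores, kind="stable")
    keep = []
    suppressed = np.zeros(len(boxes), dtype=bool)
    for i in order:
        if suppressed[i]:
            continue
        keep.append(int(i))
        if len(boxes) > 1:
            remaining = order[~suppressed[order]]
            ious = box_iou(boxes[i][None], boxes[remaining])[0]
            suppressed[remaining[ious > iou_thresh]] = True
            suppressed[i] = True
    return keep


def decode_detections(cls_probs: np.ndarray, box_deltas: np.ndarray,
                      anchors: np.ndarray, cfg: DetectionHeadConfig,
                      image_hw: tuple) -> list:
    """Apply deltas, clip to the image, threshold scores, per-class NMS,
    and cap at top-k; one image's outputs."""
    h, w = image_hw
    boxes = decode_boxes(anchors, box_deltas)
    boxes[:, 0::2] = np.clip(boxes[:, 0::2], 0, w)
    boxes[:, 1::2] = np.clip(boxes[:, 1::2], 0, h)
    detections = []
    for c in range(cls_probs.shape[1]):
        scores = cls_probs[:, c]
        sel = scores >= cfg.score_thresh
        if not sel.any():
            continue
        keep = nms(boxes[sel], scores[sel], cfg.nms_iou)
        idx = np.nonzero(sel)[0][keep]
        detections.extend(Detection(boxes[i].copy(), c + 1, float(scores[i]))
                          for i in idx)
    detections.sort(key=lambda d: -d.score)
    return detections[:cfg.top_k]


def detections_to_coco(detections: list, image_id: int) -> list:
    """COCO "results" records (image_id, category_id, bbox xywh, score)."""
    out = []
    for det in detections:
        x0, y0, x1, y1 = det.box
        out.append({"image_id": image_id, "category_id": det.class_id,
                    "bbox": [float(x0), float(y0), float(x1 - x0), float(y1 - y0)],
                    "score": det.score})
    return out
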