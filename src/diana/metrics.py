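"""Evaluation stack: IoU, PASCAL/COCO average precision, panoptic quality
with DQ/SQ decomposition, mean IoU, size-stratified AP, confusion matrices
and precision-recall curves.

Conventions:

* Boxes are corner-form ``(x0, y0, x1, y1)``, 0-based half-open.
* Instance segments are pixel sets; within one side (prediction or ground
  truth) segments must be disjoint.
* Panoptic quality matches segments at IoU strictly greater than 0.5, which
  makes the matching unique; ``DQ = TP / (TP + FP/2 + FN/2)`` (an F1 score),
  ``SQ`` is the mean IoU over matched pairs, and ``PQ = DQ * SQ``.
* Classes absent from both ground truth and predictions are excluded from
  class means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


# -- IoU ---------------------------------------------------------------------

def box_iou(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between two corner-form box arrays (M,4) x (N,4)."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    ix0 = np.maximum(a[:, None, 0], b[None, :, 0])
    iy0 = np.maximum(a[:, None, 1], b[None, :, 1])
    ix1 = np.minimum(a[:, None, 2], b[None, :, 2])
    iy1 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(ix1 - ix0, 0, None) * np.clip(iy1 - iy0, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def iou(x, y) -> float:
    """IoU of two boxes (corner form, length 4) or two boolean pixel masks.

    Raises ValueError when both operands are empty (undefined ratio).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.ndim == 1 and x.size == 4:
        val = float(box_iou(x[None], y[None])[0, 0])
        if (x[2] - x[0]) * (x[3] - x[1]) == 0 and (y[2] - y[0]) * (y[3] - y[1]) == 0:
            raise ValueError("IoU undefined: both boxes empty")
        return val
    x = x.astype(bool)
    y = y.astype(bool)
    union = np.logical_or(x, y).sum()
    if union == 0:
        raise ValueError("IoU undefined: both pixel sets empty")
    return float(np.logical_and(x, y).sum() / union)


# -- average precision -------------------------------------------------------

def _match_detections(det_boxes, det_scores, gt_boxes, iou_thresh):
    """Greedy score-descending matching, one detection per ground truth.

    Returns a boolean TP flag per detection (in score-descending order) and
    the score order used.
    """
    order = np.argsort(-np.asarray(det_scores), kind="stable")
    matched = np.zeros(len(gt_boxes), dtype=bool)
    tp = np.zeros(len(order), dtype=bool)
    if len(gt_boxes) and len(order):
        ious = box_iou(np.asarray(det_boxes)[order], np.asarray(gt_boxes))
        for i in range(len(order)):
            j = int(np.argmax(np.where(matched, -1.0, ious[i])))
            if not matched[j] and ious[i, j] >= iou_thresh:
                matched[j] = True
                tp[i] = True
    return tp, order


def _ap_from_tp(tp: np.ndarray, n_gt: int) -> float:
    """All-point interpolated AP from score-ordered TP flags."""
    if n_gt == 0:
        return float("nan")
    if len(tp) == 0:
        return 0.0
    cum_tp = np.cumsum(tp)
    recall = cum_tp / n_gt
    precision = cum_tp / np.arange(1, len(tp) + 1)
    # precision envelope, integrated over recall steps
    mrec = np.concatenate([[0.0], recall, [1.0]])
    mpre = np.concatenate([[0.0], precision, [0.0]])
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    idx = np.nonzero(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


def average_precision(detections, ground_truths, iou_thresh: float = 0.5,
                      coco_style: bool = False) -> dict:
    """Per-class AP and class-mean AP.

    ``detections``: list of (image_id, class_id, box(corner), score).
    ``ground_truths``: list of (image_id, class_id, box(corner)).
    Classes with zero ground truths and zero detections are excluded from
    the mean.  With ``coco_style=True`` AP is averaged over IoU thresholds
    0.50:0.05:0.95.
    """
    thresholds = (np.arange(0.5, 1.0, 0.05) if coco_style
                  else np.asarray([iou_thresh]))
    classes = sorted({d[1] for d in detections} | {g[1] for g in ground_truths})
    per_class = {}
    for c in classes:
        dets_c = [d for d in detections if d[1] == c]
        gts_c = [g for g in ground_truths if g[1] == c]
        n_gt = len(gts_c)
        aps = []
        for t in thresholds:
            tps = []
            image_ids = {d[0] for d in dets_c} | {g[0] for g in gts_c}
            for img in sorted(image_ids):
                db = [d[2] for d in dets_c if d[0] == img]
                ds = [d[3] for d in dets_c if d[0] == img]
                gb = [g[2] for g in gts_c if g[0] == img]
                tp, order = _match_detections(db, ds, gb, t)
                tps.extend(zip([ds[i] for i in order], tp))
            tps.sort(key=lambda x: -x[0])
            aps.append(_ap_from_tp(np.array([f for _s, f in tps], dtype=bool), n_gt))
        per_class[c] = float(np.mean(aps))
    valid = [v for v in per_class.values() if not np.isnan(v)]
    return {"per_class": per_class,
            "mAP": float(np.mean(valid)) if valid else float("nan")}


def size_stratified_ap(detections, ground_truths, iou_thresh: float = 0.5) -> dict:
    """AP within ground-truth pixel-area bins: small < 32^2, medium in
    [32^2, 92^2] (closed lower bound), large > 92^2.  Detections are matched
    only against in-bin ground truths; empty bins are reported as absent."""
    bins = {"small": lambda a: a < 32 ** 2,
            "medium": lambda a: 32 ** 2 <= a <= 92 ** 2,
            "large": lambda a: a > 92 ** 2}
    out = {}
    for name, pred in bins.items():
        gts = [g for g in ground_truths
               if pred((g[2][2] - g[2][0]) * (g[2][3] - g[2][1]))]
        if not gts:
            continue
        res = average_precision(detections, gts, iou_thresh)
        out[name] = res["mAP"]
    return out


# -- panoptic quality --------------------------------------------------------

@dataclass
class PQResult:
    per_class: dict = field(default_factory=dict)  # class -> dict(TP,FP,FN,DQ,SQ,PQ)
    mPQ: float = float("nan")
    mDQ: float = float("nan")
    mSQ: float = float("nan")


def _check_disjoint(instances, side: str):
    if not instances:
        return
    acc = None
    for _cls, m in instances:
        m = np.asarray(m, dtype=bool)
        if acc is None:
            acc = m.copy()
        else:
            if np.logical_and(acc, m).any():
                raise ValueError(f"overlapping instances within {side}")
            acc |= m
    return


def panoptic_quality(pred_instances, gt_instances) -> PQResult:
    """Panoptic quality over instance segments.

    Each side is a list of ``(class_id, bool mask)``.  Segments of the same
    class match iff IoU > 0.5 (unique by construction).  Per class:
    DQ = TP / (TP + FP/2 + FN/2), SQ = mean IoU over TPs (0 with a flag when
    TP = 0), PQ = DQ * SQ; means are over classes present on either side.
    """
    _check_disjoint(pred_instances, "prediction")
    _check_disjoint(gt_instances, "ground truth")
    classes = sorted({c for c, _ in pred_instances} | {c for c, _ in gt_instances})
    result = PQResult()
    for c in classes:
        preds = [np.asarray(m, bool) for cc, m in pred_instances if cc == c]
        gts = [np.asarray(m, bool) for cc, m in gt_instances if cc == c]
        tp, iou_sum = 0, 0.0
        matched_pred = set()
        matched_gt = set()
        for gi, g in enumerate(gts):
            for pi, p in enumerate(preds):
                if pi in matched_pred:
                    continue
                inter = np.logical_and(g, p).sum()
                if inter == 0:
                    continue
                union = np.logical_or(g, p).sum()
                v = inter / union
                if v > 0.5:
                    tp += 1
                    iou_sum += v
                    matched_pred.add(pi)
                    matched_gt.add(gi)
                    break
        fp = len(preds) - len(matched_pred)
        fn = len(gts) - len(matched_gt)
        dq = tp / (tp + 0.5 * fp + 0.5 * fn) if (tp + fp + fn) else float("nan")
        sq = iou_sum / tp if tp else 0.0
        result.per_class[c] = {"TP": tp, "FP": fp, "FN": fn, "DQ": dq,
                               "SQ": sq, "PQ": dq * sq,
                               "SQ_defined": tp > 0}
    vals = [v for v in result.per_class.values() if not np.isnan(v["DQ"])]
    if vals:
        result.mPQ = float(np.mean([v["PQ"] for v in vals]))
        result.mDQ = float(np.mean([v["DQ"] for v in vals]))
        result.mSQ = float(np.mean([v["SQ"] for v in vals]))
    return result


# -- semantic segmentation ---------------------------------------------------

def miou(pred_mask: np.ndarray, gt_mask: np.ndarray,
         n_classes: int | None = None, ignore_background: bool = True) -> dict:
    """Per-class IoU on label masks; mean over classes present in gt or pred.

    Label 0 is background and excluded from the mean unless
    ``ignore_background`` is False.
    """
    pred_mask = np.asarray(pred_mask)
    gt_mask = np.asarray(gt_mask)
    if pred_mask.shape != gt_mask.shape:
        raise ValueError("mask shapes differ")
    labels = np.union1d(np.unique(pred_mask), np.unique(gt_mask))
    if ignore_background:
        labels = labels[labels != 0]
    per_class = {}
    for c in labels:
        p = pred_mask == c
        g = gt_mask == c
        union = np.logical_or(p, g).sum()
        per_class[int(c)] = float(np.logical_and(p, g).sum() / union)
    vals = list(per_class.values())
    return {"per_class": per_class,
            "mIOU": float(np.mean(vals)) if vals else float("nan")}


# -- confusion matrices & PR curves -----------------------------------------

def detection_confusion(detections, ground_truths, n_classes: int,
                        iou_thresh: float = 0.5) -> np.ndarray:
    """(n_classes+1) x (n_classes+1) matrix; row = ground-truth class,
    column = predicted class, index 0 = background (FN row / FP column)."""
    cm = np.zeros((n_classes + 1, n_classes + 1), dtype=int)
    images = {d[0] for d in detections} | {g[0] for g in ground_truths}
    for img in images:
        dets = sorted([d for d in detections if d[0] == img], key=lambda d: -d[3])
        gts = [g for g in ground_truths if g[0] == img]
        taken = np.zeros(len(gts), dtype=bool)
        for _img, dcls, dbox, _score in dets:
            best_j, best_v = -1, iou_thresh
            for j, (_i, _gcls, gbox) in enumerate(gts):
                if taken[j]:
                    continue
                v = box_iou(np.asarray(dbox)[None], np.asarray(gbox)[None])[0, 0]
                if v >= best_v:
                    best_v, best_j = v, j
            if best_j >= 0:
                taken[best_j] = True
                cm[gts[best_j][1], dcls] += 1
            else:
                cm[0, dcls] += 1  # false positive
        for j, (_i, gcls, _b) in enumerate(gts):
            if not taken[j]:
                cm[gcls, 0] += 1  # false negative
    return cm


def segmentation_confusion(pred_mask, gt_mask, n_classes: int) -> np.ndarray:
    """(n_classes+1)^2 pixel confusion matrix, label 0 = background."""
    pred = np.asarray(pred_mask).ravel()
    gt = np.asarray(gt_mask).ravel()
    k = n_classes + 1
    return np.bincount(gt * k + pred, minlength=k * k).reshape(k, k)


def pr_curve(detections, ground_truths, class_id: int,
             iou_thresh: float = 0.5) -> dict:
    """Precision/recall points at every score threshold for one class."""
    dets_c = [d for d in detections if d[1] == class_id]
    gts_c = [g for g in ground_truths if g[1] == class_id]
    n_gt = len(gts_c)
    pairs = []
    for img in sorted({d[0] for d in dets_c} | {g[0] for g in gts_c}):
        db = [d[2] for d in dets_c if d[0] == img]
        ds = [d[3] for d in dets_c if d[0] == img]
        gb = [g[2] for g in gts_c if g[0] == img]
        tp, order = _match_detections(db, ds, gb, iou_thresh)
        pairs.extend(zip([ds[i] for i in order], tp))
    pairs.sort(key=lambda x: -x[0])
    tp = np.array([f for _s, f in pairs], dtype=float)
    scores = np.array([s for s, _f in pairs], dtype=float)
    cum_tp = np.cumsum(tp)
    precision = cum_tp / np.arange(1, len(tp) + 1) if len(tp) else np.array([])
    recall = cum_tp / n_gt if n_gt else np.zeros(len(tp))
    return {"scores": scores, "precision": precision, "recall": recall}
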