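"""Joint end-to-end training, full-pipeline prediction and evaluation.

Training optimizes the weighted sum of the detector's focal classification
loss and smooth-L1 box regression plus the severity branch's focal-Tversky
loss with SGD (momentum 0.9, L2 weight decay), under a linear-warmup +
cosine-decay learning-rate schedule.  The ``paper`` preset keeps the
published settings (lr 0.08, 3K warmup, batch 3, 100K iterations); the
``tiny`` preset (lr 0.01, batch 2, <= 1K iterations) is the CPU-scale path
exercised by the test suite.

Prediction runs one forward pass, decodes detections, applies the pest
shortcut (scenes with only pest detections skip the severity branch), and
hands the result to the integration unit.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .core_io import ImageSample, pad_to_multiple, stage_catalog
from .detection import (assign_targets, decode_detections, focal_loss,
                        smooth_l1)
from .dsa import focal_tversky_loss, mask_to_onehot
from .integration import (DiagnosisReport, extract_instances, pest_only,
                          render_overlay, render_phrases)
from .metrics import (average_precision, detection_confusion, miou,
                      panoptic_quality, size_stratified_ap)
from .model import DianaModel, ModelConfig, model_preset
from .nn import tensor as T
from skimage import measure

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.08
    warmup_iters: int = 3000
    max_iters: int = 100_000
    momentum: float = 0.9
    weight_decay: float = 5e-4
    batch_size: int = 3
    lambda_cls: float = 1.0
    lambda_reg: float = 1.0
    lambda_seg: float = 1.0
    focal_alpha: float = 0.25
    focal_gamma: float = 1.8
    tversky_alpha: float = 0.3
    tversky_beta: float = 0.7
    tversky_gamma: float = 4.0
    smooth_l1_beta: float = 0.1
    grad_clip: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.warmup_iters >= self.max_iters:
            raise ValueError("warmup_iters must be < max_iters")
        if min(self.lambda_cls, self.lambda_reg, self.lambda_seg) < 0:
            raise ValueError("loss weights must be non-negative")


def train_preset(name: str) -> TrainConfig:
    if name == "paper":
        return TrainConfig()
    if name == "tiny":
        return TrainConfig(learning_rate=0.01, warmup_iters=50, max_iters=1000,
                           batch_size=2)
    raise KeyError(f"unknown training preset {name!r}")


def lr_schedule(step: int, cfg: TrainConfig) -> float:
    """Linear 0 -> base over the warmup, then cosine decay to 0 at
    ``max_iters``; continuous at the warmup boundary."""
    if step < 0:
        raise ValueError("step must be >= 0")
    if step < cfg.warmup_iters:
        return cfg.learning_rate * step / cfg.warmup_iters
    progress = (step - cfg.warmup_iters) / max(cfg.max_iters - cfg.warmup_iters, 1)
    progress = min(progress, 1.0)
    return cfg.learning_rate * 0.5 * (1.0 + math.cos(math.pi * progress))


@dataclass
class LossBreakdown:
    total: float
    cls: float
    reg: float
    seg: float


# -- data plumbing -------------------------------------------------------------

def normalization_stats(samples: list) -> tuple:
    """Per-channel mean/std over a sample list (stored in the checkpoint)."""
    pixels = np.concatenate([s.image.reshape(-1, 3) for s in samples], axis=0)
    return pixels.mean(axis=0).astype(np.float32), \
        (pixels.std(axis=0) + 1e-6).astype(np.float32)


def _to_tensor(image: np.ndarray, mean, std) -> np.ndarray:
    x = (image - mean) / std
    return np.ascontiguousarray(x.transpose(2, 0, 1)[None]).astype(np.float32)


def _prepare_targets(samples: list, model: DianaModel, cfg: TrainConfig):
    """Precompute per-sample anchor targets and one-hot masks."""
    prepared = []
    for s in samples:
        anchors = model.anchors_for((s.height, s.width))
        gt = np.array([b.corners() for b in s.boxes], dtype=np.float64)
        gtc = np.array([b.class_id for b in s.boxes], dtype=int)
        tgt = assign_targets(anchors, gt, gtc, model.cfg.head)
        mask = s.mask if s.mask is not None else \
            np.zeros((s.height, s.width), np.uint8)
        onehot = mask_to_onehot(mask, model.cfg.dsa.n_stages) \
            if model.dsa is not None else None
        prepared.append((s, tgt, onehot))
    return prepared


# -- training ------------------------------------------------------------------

def train(samples: list, model: DianaModel, cfg: TrainConfig,
          log_path=None, callback=None) -> dict:
    """Train in place; returns a checkpoint dict with the final state,
    normalization statistics, configs and the loss history."""
    if not samples:
        raise ValueError("empty training set")
    sizes = {(s.height, s.width) for s in samples}
    if len(sizes) != 1:
        raise ValueError("training currently expects a single image size")
    mean, std = normalization_stats(samples)
    prepared = _prepare_targets(samples, model, cfg)
    tensors = [_to_tensor(s.image, mean, std) for s, _t, _o in prepared]

    params = model.parameters()
    opt = nn.SGD(params, lr=cfg.learning_rate, momentum=cfg.momentum,
                 weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 3]))
    model.train()
    history = []
    writer = None
    log_file = None
    if log_path is not None:
        log_file = open(log_path, "w", newline="")
        writer = csv.writer(log_file)
        writer.writerow(["step", "lr", "total", "cls", "reg", "seg"])
    # epoch-shuffled batching: every sample is visited once per epoch, which
    # keeps rare severity stages in steady rotation on small datasets
    order = rng.permutation(len(prepared))
    cursor = 0

    def next_batch():
        nonlocal order, cursor
        idx = []
        for _ in range(cfg.batch_size):
            if cursor >= len(order):
                order = rng.permutation(len(prepared))
                cursor = 0
            idx.append(int(order[cursor]))
            cursor += 1
        return np.asarray(idx)

    try:
        for step in range(cfg.max_iters):
            idx = next_batch()
            x = nn.Tensor(np.concatenate([tensors[i] for i in idx], axis=0))
            cls_t = np.stack([prepared[i][1][0] for i in idx])
            cls_w = np.stack([prepared[i][1][1] for i in idx])
            box_t = np.stack([prepared[i][1][2] for i in idx])
            box_w = np.stack([prepared[i][1][3] for i in idx])

            opt.lr = lr_schedule(step, cfg)
            opt.zero_grad()
            out = model(x, with_dsa=cfg.lambda_seg > 0 and model.dsa is not None)
            probs = T.sigmoid(out["cls_logits"])
            l_cls = focal_loss(probs, cls_t, cls_w,
                               alpha=cfg.focal_alpha, gamma=cfg.focal_gamma)
            l_reg = smooth_l1(out["box_deltas"], box_t, box_w,
                              beta=cfg.smooth_l1_beta)
            if "seg_logits" in out:
                seg_y = np.stack([prepared[i][2] for i in idx])
                seg_p = T.softmax(out["seg_logits"], axis=1)
                l_seg = focal_tversky_loss(seg_p, seg_y, cfg.tversky_alpha,
                                           cfg.tversky_beta, cfg.tversky_gamma)
            else:
                l_seg = nn.Tensor(np.zeros((), np.float32))
            total = cfg.lambda_cls * l_cls + cfg.lambda_reg * l_reg \
                + cfg.lambda_seg * l_seg
            breakdown = LossBreakdown(float(total.data), float(l_cls.data),
                                      float(l_reg.data), float(l_seg.data))
            if not np.isfinite(breakdown.total):
                raise FloatingPointError(
                    f"non-finite loss at step {step}: {breakdown} "
                    f"(batch indices {idx.tolist()})")
            total.backward()
            _clip_gradients(params, cfg.grad_clip)
            opt.step()
            history.append(breakdown)
            if writer is not None:
                writer.writerow([step, opt.lr, breakdown.total, breakdown.cls,
                                 breakdown.reg, breakdown.seg])
            if callback is not None:
                callback(step, breakdown)
            if step % 100 == 0:
                logger.info("step %d lr %.4g total %.4f (cls %.4f reg %.4f "
                            "seg %.4f)", step, opt.lr, breakdown.total,
                            breakdown.cls, breakdown.reg, breakdown.seg)
    finally:
        if log_file is not None:
            log_file.close()
    model.eval()
    return {"state": model.state_dict(), "norm_mean": mean, "norm_std": std,
            "step": cfg.max_iters, "history": history,
            "velocity": [v.copy() for v in opt._velocity]}


def _clip_gradients(params, max_norm: float):
    if max_norm <= 0:
        return
    total = math.sqrt(sum(float((p.grad ** 2).sum())
                          for p in params if p.grad is not None))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale


# -- inference -----------------------------------------------------------------

def predict(image: np.ndarray, model: DianaModel, norm_mean, norm_std,
            with_overlay: bool = False) -> DiagnosisReport:
    """Full pipeline on one RGB image in [0,1]: detect, gate on the pest
    shortcut, segment severities if needed, integrate and phrase."""
    catalog = stage_catalog()
    total_stride = model.cfg.backbone.level_strides()[-1]
    h, w = image.shape[:2]
    padded = pad_to_multiple(image, total_stride)
    x = nn.Tensor(_to_tensor(padded, norm_mean, norm_std))
    model.eval()
    c0, pyramid = model.forward_features(x)
    cls_out, box_out = model.forward_detection(pyramid)
    probs = 1.0 / (1.0 + np.exp(-cls_out.data[0]))
    anchors = model.anchors_for(padded.shape[:2])
    detections = decode_detections(probs, box_out.data[0].astype(np.float64),
                                   anchors, model.cfg.head, (h, w))
    if model.dsa is not None and not pest_only(detections, catalog):
        logits = model.forward_dsa(c0, pyramid, padded.shape[:2])
        seg = logits.data[0].argmax(axis=0).astype(np.uint8)[:h, :w]
    else:
        seg = np.zeros((h, w), dtype=np.uint8)
    instances = extract_instances(detections, seg, catalog)
    phrases = render_phrases(instances, catalog)
    for inst, phrase in zip(sorted(instances, key=lambda i: i.id), phrases):
        inst.phrase = phrase
    report = DiagnosisReport(instances=instances, phrases=phrases,
                             detections=detections, predicted_mask=seg)
    if with_overlay:
        report.overlay = render_overlay(image, instances)
    return report


# -- evaluation ----------------------------------------------------------------

def _mask_instances(mask: np.ndarray) -> list:
    """(stage, bool-support) instance list from a stage-labeled mask."""
    out = []
    labeled = measure.label(mask, connectivity=2)
    for region in measure.regionprops(labeled):
        stage = int(mask[tuple(region.coords[0])])
        if stage == 0:
            continue
        out.append((stage, labeled == region.label))
    return out


def evaluate(samples: list, model: DianaModel, norm_mean, norm_std) -> dict:
    """Run prediction over a split and compute the full metrics report:
    PASCAL/COCO mAP, size-stratified AP, mIOU, panoptic quality and the
    detection confusion matrix."""
    detections, gts = [], []
    n_stages = model.cfg.dsa.n_stages if model.dsa is not None else 0
    inter = np.zeros(n_stages + 1)
    union = np.zeros(n_stages + 1)
    seen = np.zeros(n_stages + 1, dtype=bool)
    pq_acc: dict = {}
    have_masks = all(s.mask is not None for s in samples)
    for s in samples:
        rep = predict(s.image, model, norm_mean, norm_std)
        for det in rep.detections:
            detections.append((s.image_id, det.class_id, det.box, det.score))
        for b in s.boxes:
            gts.append((s.image_id, b.class_id, b.corners()))
        if model.dsa is not None and have_masks:
            pred_mask = rep.predicted_mask
            for c in range(1, n_stages + 1):
                p = pred_mask == c
                g = s.mask == c
                if p.any() or g.any():
                    seen[c] = True
                inter[c] += np.logical_and(p, g).sum()
                union[c] += np.logical_or(p, g).sum()
            pq = panoptic_quality(_mask_instances(pred_mask),
                                  _mask_instances(s.mask))
            for c, v in pq.per_class.items():
                acc = pq_acc.setdefault(c, {"TP": 0, "FP": 0, "FN": 0,
                                            "iou_sum": 0.0})
                acc["TP"] += v["TP"]
                acc["FP"] += v["FP"]
                acc["FN"] += v["FN"]
                acc["iou_sum"] += v["SQ"] * v["TP"]
    report = {
        "mAP@0.5": average_precision(detections, gts, 0.5)["mAP"],
        "per_class_AP": average_precision(detections, gts, 0.5)["per_class"],
        "mAP@coco": average_precision(detections, gts, coco_style=True)["mAP"],
        "size_AP": size_stratified_ap(detections, gts),
        "confusion": detection_confusion(detections, gts,
                                         model.cfg.head.n_classes),
    }
    if model.dsa is not None and have_masks:
        per_class_iou = {c: float(inter[c] / union[c])
                         for c in range(1, n_stages + 1)
                         if seen[c] and union[c] > 0}
        report["per_class_IOU"] = per_class_iou
        report["mIOU"] = float(np.mean(list(per_class_iou.values()))) \
            if per_class_iou else float("nan")
        pq_per_class = {}
        for c, acc in sorted(pq_acc.items()):
            tp, fp, fn = acc["TP"], acc["FP"], acc["FN"]
            dq = tp / (tp + 0.5 * fp + 0.5 * fn) if (tp + fp + fn) else float("nan")
            sq = acc["iou_sum"] / tp if tp else 0.0
            pq_per_class[c] = {"DQ": dq, "SQ": sq, "PQ": dq * sq}
        report["per_class_PQ"] = pq_per_class
        report["mPQ"] = float(np.mean([v["PQ"] for v in pq_per_class.values()])) \
            if pq_per_class else float("nan")
    elif model.dsa is not None:
        logger.warning("masks missing: PQ/mIOU skipped, mAP still computed")
    return report
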