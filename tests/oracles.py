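"""Independent brute-force reference implementations used to validate the
package's metrics.  Everything here is deliberately naive (python loops,
exhaustive pair checks) and shares no code with diana.metrics beyond
single-pair box IoU arithmetic."""

import numpy as np


def pair_iou(a, b):
    ix0, iy0 = max(a[0], b[0]), max(a[1], b[1])
    ix1, iy1 = min(a[2], b[2]), min(a[3], b[3])
    inter = max(ix1 - ix0, 0.0) * max(iy1 - iy0, 0.0)
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    union = area_a + area_b - inter
    return inter / union if union > 0 else 0.0


def nms_oracle(boxes, scores, thresh):
    """O(n^2): repeatedly keep the best-scoring box, delete overlaps."""
    alive = list(range(len(boxes)))
    keep = []
    while alive:
        best = max(alive, key=lambda i: (scores[i], -i))
        keep.append(best)
        alive = [i for i in alive
                 if i != best and pair_iou(boxes[best], boxes[i]) <= thresh]
    return keep


def ap_oracle(dets, gts, thresh):
    """Single-class AP: python-loop greedy matching per image, then a
    suffix-max precision integral over recall steps."""
    per_image = {}
    for img, _c, box in gts:
        per_image.setdefault(img, []).append(box)
    entries = []
    for img in {d[0] for d in dets} | set(per_image):
        dd = sorted([d for d in dets if d[0] == img], key=lambda d: -d[3])
        used = set()
        for d in dd:
            best_j, best_v = -1, -1.0
            for k, gg in enumerate(per_image.get(img, [])):
                if k in used:
                    continue
                v = pair_iou(d[2], gg)
                if v > best_v:
                    best_v, best_j = v, k
            hit = best_j >= 0 and best_v >= thresh
            if hit:
                used.add(best_j)
            entries.append((d[3], hit))
    entries.sort(key=lambda e: -e[0])
    n_gt = len(gts)
    if n_gt == 0:
        return float("nan")
    tp = 0
    points = []
    for k, (_s, hit) in enumerate(entries, start=1):
        tp += hit
        points.append((tp / n_gt, tp / k))
    ap = 0.0
    prev_r = 0.0
    for i, (r, _p) in enumerate(points):
        if r > prev_r:
            ap += (r - prev_r) * max(p for (_rr, p) in points[i:])
            prev_r = r
    return ap


def pq_oracle(pred, gt):
    """Exhaustive per-class PQ: check every (pred, gt) pair at IoU > 0.5
    (matching must come out unique) and substitute into the definition."""
    pairs = []
    for gi, (gc, g) in enumerate(gt):
        for pi, (pc, p) in enumerate(pred):
            if gc != pc:
                continue
            inter = np.logical_and(g, p).sum()
            union = np.logical_or(g, p).sum()
            if union and inter / union > 0.5:
                pairs.append((gi, pi, inter / union))
    assert len({g for g, _p, _v in pairs}) == len(pairs)
    assert len({p for _g, p, _v in pairs}) == len(pairs)
    out = {}
    classes = {c for c, _ in pred} | {c for c, _ in gt}
    for c in classes:
        matched = [(gi, pi, v) for gi, pi, v in pairs if gt[gi][0] == c]
        tp = len(matched)
        fp = sum(1 for pc, _ in pred if pc == c) - tp
        fn = sum(1 for gc, _ in gt if gc == c) - tp
        dq = tp / (tp + 0.5 * fp + 0.5 * fn)
        sq = sum(v for *_x, v in matched) / tp if tp else 0.0
        out[c] = dq * sq
    return out


def random_instances(rng, n_max=10, size=64, n_classes=3):
    """Disjoint random rectangle instances on a small grid."""
    out = []
    occ = np.zeros((size, size), bool)
    for _ in range(int(rng.integers(0, n_max + 1))):
        w, h = rng.integers(4, 20, 2)
        x, y = rng.integers(0, size - w), rng.integers(0, size - h)
        m = np.zeros((size, size), bool)
        m[y:y + h, x:x + w] = True
        m &= ~occ
        if m.sum() < 4:
            continue
        occ |= m
        out.append((int(rng.integers(1, n_classes + 1)), m))
    return out


def random_boxes(rng, n, span=50):
    xy = rng.uniform(0, span, (n, 2))
    wh = rng.uniform(2, 20, (n, 2))
    return np.concatenate([xy, xy + wh], axis=1)
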