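"""Parameterized phantom "paprika field" scene generator.

Real field imagery of diseased paprika is not redistributable, so every
downstream stage is exercised on synthetic scenes with exactly known boxes
and severity masks.  The generator emulates the structure of the field data
— multi-instance scenes, six anomaly classes of which four carry severity
stages (11 in total), lesions spanning small/medium/large pixel areas,
cluttered backgrounds and fuzzy lesion boundaries — without attempting
photorealism.

Lesions are rendered as wobbled superellipses.  Each anomaly class owns a
hue band and each severity stage within a class an intensity level, so the
taxonomy is visually separable and learnable by a small network.  Pest
instances (snails and slugs, spider mite) produce bounding boxes but no
severity-mask labels.  Scene synthesis is fully deterministic given a seed;
dataset generation draws one independent stream per scene from
``(global_seed, scene_index)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core_io import (BoxAnnotation, ImageSample, N_CLASSES, stage_catalog,
                      write_dataset)

logger = logging.getLogger(__name__)

# Class-keyed hue bands (background foliage sits near hue 0.30, green).
CLASS_HUES = {1: 0.00, 2: 0.12, 3: 0.83, 4: 0.58, 5: 0.70, 6: 0.92}

# Instance-count proportions of the six anomaly classes in the field survey
# the generator emulates (BR, CP, GM, PM, SS, SM).
FIELD_CLASS_WEIGHTS = (0.153, 0.285, 0.121, 0.153, 0.174, 0.114)

# lesion pixel-area bins: small < 32^2, medium in [32^2, 92^2], large > 92^2
_SMALL_AREA = (120.0, 700.0)
_MEDIUM_AREA = (1300.0, 7800.0)
_LARGE_AREA = (8800.0, 20000.0)


@dataclass(frozen=True)
class SceneConfig:
    """Knobs of the phantom-field generator (defaults are the emulated
    study conditions; see docs/methods.md)."""

    image_size: int = 256
    n_instances_range: tuple = (1, 5)
    class_weights: tuple = FIELD_CLASS_WEIGHTS
    size_mix: tuple = (0.35, 0.45, 0.20)  # small / medium / large
    background: float = 0.5               # clutter level in [0, 1]
    boundary_blur: float = 1.5            # px of lesion edge softening
    seed: int = 0

    def __post_init__(self):
        if len(self.class_weights) != N_CLASSES:
            raise ValueError(f"need {N_CLASSES} class weights")
        if not np.isclose(sum(self.class_weights), 1.0):
            raise ValueError("class_weights must sum to 1")
        if not np.isclose(sum(self.size_mix), 1.0):
            raise ValueError("size_mix must sum to 1")


def _hsv_to_rgb(h: float, s: float, v: float) -> np.ndarray:
    i = int(h * 6.0) % 6
    f = h * 6.0 - int(h * 6.0)
    p, q, t = v * (1 - s), v * (1 - s * f), v * (1 - s * (1 - f))
    rgb = [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)][i]
    return np.asarray(rgb, dtype=np.float32)


def _lesion_support(rng: np.random.Generator, area: float, blur: float):
    """Binary support of one wobbled superellipse, on a local grid.

    Returns (support bool array, half-extents used).  The tight box of the
    support is what gets recorded as the annotation.
    """
    aspect = rng.uniform(0.55, 1.8)
    rx = np.sqrt(area * aspect) / 2.0
    ry = np.sqrt(area / aspect) / 2.0
    n_exp = rng.uniform(1.6, 3.0)
    rot = rng.uniform(0, np.pi)
    n_harm = rng.integers(2, 5)
    amps = rng.uniform(0.0, 0.10, size=n_harm) / np.arange(1, n_harm + 1)
    phases = rng.uniform(0, 2 * np.pi, size=n_harm)

    half = int(np.ceil(max(rx, ry) * 1.25 + blur + 2))
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1].astype(np.float32)
    c, s = np.cos(rot), np.sin(rot)
    u = (c * xx + s * yy) / rx
    v = (-s * xx + c * yy) / ry
    theta = np.arctan2(v, u)
    wobble = 1.0 + sum(a * np.sin((k + 1) * theta + ph)
                       for k, (a, ph) in enumerate(zip(amps, phases)))
    r = (np.abs(u) ** n_exp + np.abs(v) ** n_exp) ** (1.0 / n_exp)
    return r <= wobble, half


def _background(rng: np.random.Generator, size: int, clutter: float) -> np.ndarray:
    """Foliage-like canvas: green base + low-frequency mottling + distractors."""
    base_hue = rng.uniform(0.27, 0.34)
    canvas = np.empty((size, size, 3), dtype=np.float32)
    canvas[:] = _hsv_to_rgb(base_hue, 0.55, 0.38)
    lowfreq = ndimage.gaussian_filter(
        rng.normal(0, 1, (size, size)).astype(np.float32), sigma=size / 12.0)
    lowfreq /= max(np.abs(lowfreq).max(), 1e-6)
    canvas *= (1.0 + 0.35 * clutter * lowfreq)[..., None]
    # neutral distractor blobs (dead-leaf / soil tones, away from class hues)
    n_distract = int(round(6 * clutter))
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float32)
    for _ in range(n_distract):
        cx, cy = rng.uniform(0, size, 2)
        rr = rng.uniform(size / 20, size / 7)
        d2 = ((xx - cx) ** 2 + (yy - cy) ** 2) / rr ** 2
        blob = np.exp(-d2 * 2.0)
        gray = rng.uniform(0.18, 0.45)
        color = np.array([gray, gray * rng.uniform(0.85, 1.05), gray * 0.8],
                         dtype=np.float32)
        canvas = canvas * (1 - 0.6 * blob[..., None]) + color * 0.6 * blob[..., None]
    noise = rng.normal(0, 0.015 + 0.02 * clutter, (size, size, 3)).astype(np.float32)
    return np.clip(canvas + noise, 0.0, 1.0).astype(np.float32)


def _stage_color(catalog, class_id: int, stage_id: int | None) -> np.ndarray:
    hue = CLASS_HUES[class_id]
    if stage_id is None:  # pest: fixed mid-intensity
        return _hsv_to_rgb(hue, 0.85, 0.55)
    k = catalog.stage_index_in_class(stage_id)
    n = len(catalog.stages(class_id))
    value = 0.30 + 0.55 * (k - 1) / max(n - 1, 1)
    return _hsv_to_rgb(hue, 0.85, value)


def _area_bins(size: int):
    """Feasible area ranges per bin given the canvas size.

    The cap keeps the lesion's local grid (max half-extent ~0.9*sqrt(A))
    inside the canvas with a margin; bins that cannot fit are disabled and
    the sampler falls back to the next smaller bin.
    """
    cap = ((size / 2.0 - 8.0) / 0.9) ** 2
    bins = []
    for lo, hi in (_SMALL_AREA, _MEDIUM_AREA, _LARGE_AREA):
        if lo < cap:
            bins.append((lo, min(hi, cap)))
        else:
            bins.append(None)
    return bins


def generate_scene(config: SceneConfig, seed: int) -> ImageSample:
    """Render one scene; deterministic in (config, seed).

    Every drawn lesion yields exactly one tight BoxAnnotation, and (for
    disease classes) a mask region whose stage is legal for the class.
    Instances never touch, so connected components of the mask correspond
    one-to-one to annotations.  Raises RuntimeError when the requested
    instance count cannot be placed.
    """
    catalog = stage_catalog()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF]))
    size = config.image_size
    image = _background(rng, size, config.background)
    mask = np.zeros((size, size), dtype=np.uint8)

    lo, hi = config.n_instances_range
    n_inst = int(rng.integers(lo, hi + 1)) if hi > lo else int(lo)
    bins = _area_bins(size)

    boxes: list = []
    occupied: list = []  # (x0, y0, x1, y1) with a safety margin
    for _ in range(n_inst):
        class_id = int(rng.choice(N_CLASSES, p=config.class_weights)) + 1
        stages = catalog.stages(class_id)
        stage_id = int(rng.choice(stages)) if stages else None
        bin_idx = int(rng.choice(3, p=config.size_mix))
        # packing-aware cap so several instances can coexist on the canvas;
        # crowded scenes fall back to smaller size bins, but never below the
        # smallest bin's lower edge, so an over-full request still fails
        # loudly instead of degenerating to dust
        pack_cap = 0.4 * size * size / (1.4 * max(n_inst, 1))
        while bin_idx > 0 and (bins[bin_idx] is None or bins[bin_idx][0] > pack_cap):
            bin_idx -= 1
        lo_b, hi_b = bins[bin_idx]
        area = rng.uniform(lo_b, min(hi_b, max(pack_cap, lo_b)))

        placed = False
        area_try = area
        for _attempt in range(60):
            support, half = _lesion_support(rng, area_try, config.boundary_blur)
            margin = half + 2
            if margin * 2 + 2 >= size:
                area_try = max(area_try * 0.85, 0.35 * area)
                continue
            cx = int(rng.integers(margin, size - margin))
            cy = int(rng.integers(margin, size - margin))
            ys, xs = np.nonzero(support)
            x0, x1 = cx - half + xs.min(), cx - half + xs.max() + 1
            y0, y1 = cy - half + ys.min(), cy - half + ys.max() + 1
            pad = 2
            if any(x0 - pad < bx1 and bx0 < x1 + pad and
                   y0 - pad < by1 and by0 < y1 + pad
                   for bx0, by0, bx1, by1 in occupied):
                area_try = max(area_try * 0.85, 0.35 * area)
                continue
            # paint: soft alpha from blurred support, crisp mask from support
            alpha = ndimage.gaussian_filter(support.astype(np.float32),
                                            sigma=config.boundary_blur)
            alpha = np.clip(alpha, 0.0, 1.0) * 0.95
            color = _stage_color(catalog, class_id, stage_id)
            sl_y = slice(cy - half, cy + half + 1)
            sl_x = slice(cx - half, cx + half + 1)
            region = image[sl_y, sl_x]
            tint = color[None, None, :] * (
                1.0 + rng.normal(0, 0.04, region.shape).astype(np.float32))
            image[sl_y, sl_x] = region * (1 - alpha[..., None]) + tint * alpha[..., None]
            if stage_id is not None:
                mask[sl_y, sl_x][support] = stage_id
            boxes.append(BoxAnnotation(float(x0), float(y0), float(x1 - x0),
                                       float(y1 - y0), class_id))
            occupied.append((x0, y0, x1, y1))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place instance {len(boxes) + 1}/{n_inst} on a "
                f"{size}x{size} canvas; reduce n_instances or lesion sizes")
    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    return ImageSample(image=image, boxes=boxes, mask=mask,
                       image_id=int(seed), stem=f"scene_{int(seed):06d}")


def split_counts(n: int) -> tuple:
    """70/10/20 train/val/test counts (exact when n is divisible by 10)."""
    n_train = int(n * 7) // 10
    n_val = n // 10
    return n_train, n_val, n - n_train - n_val


def generate_dataset(n: int, config: SceneConfig, out_dir, seed: int = 0) -> dict:
    """Generate ``n`` scenes, write them via core_io, and record a
    70/10/20 train/val/test split manifest."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 915]))
    samples = []
    per_class = np.zeros(N_CLASSES, dtype=int)
    for i in range(n):
        scene_seed = int(rng.integers(0, 2 ** 31 - 1))
        sample = generate_scene(config, scene_seed)
        sample.image_id = i + 1
        sample.stem = f"scene_{i:05d}"
        for box in sample.boxes:
            per_class[box.class_id - 1] += 1
        samples.append(sample)
    manifest = write_dataset(samples, out_dir)

    n_train, n_val, n_test = split_counts(n)
    stems = [s.stem for s in samples]
    split = {"train": stems[:n_train],
             "val": stems[n_train:n_train + n_val],
             "test": stems[n_train + n_val:]}
    with open(out_dir / "split.json", "w") as fh:
        json.dump(split, fh, indent=1)
    manifest["split"] = {k: len(v) for k, v in split.items()}
    manifest["instances_per_class"] = per_class.tolist()
    logger.info("generated %d scenes; per-class instance counts: %s",
                n, per_class.tolist())
    return manifest
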