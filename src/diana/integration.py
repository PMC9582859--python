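"""Integration unit: fuses detections with the severity mask into uniquely
ID'd severity instances and renders human-readable diagnosis phrases.

Within each disease-class detection box, connected components (8-connected)
of every severity stage legal for that class become instances.  Components
whose stage is illegal for the box's class are reassigned to an enclosing
box of a legal class when one overlaps, else kept but flagged inconsistent.
Pest detections yield one instance each with no severity stage.  IDs are
assigned 1..K in raster order of the parent boxes' top-left corners (ties
broken by class ID), and each instance gets a templated phrase such as
``"1: stage 3 Cercospora"`` or ``"2: spider mite damage"``.

When a scene contains only pest detections the severity branch carries no
information, so callers gate the segmentation forward pass on
:func:`pest_only` (the "pest shortcut").
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .core_io import ClassCatalog, N_STAGES

logger = logging.getLogger(__name__)

DEFAULT_TEMPLATE = "{id}: {stage_name} {class_name}"
PEST_TEMPLATE = "{id}: {class_name} damage"

MIN_INSTANCE_PIXELS = 10  # components below this are rasterization noise

# fixed stage palette (RGB in [0,1]); index 0 unused (background)
STAGE_PALETTE = np.array([
    [0.0, 0.0, 0.0],
    [1.00, 0.80, 0.60], [1.00, 0.55, 0.30], [0.85, 0.20, 0.05],  # br1..br3
    [0.75, 0.60, 0.95], [0.50, 0.20, 0.80],                      # gm1..gm2
    [0.60, 0.90, 1.00], [0.10, 0.55, 0.95],                      # pm1..pm2
    [1.00, 0.95, 0.50], [0.95, 0.80, 0.15],                      # cp1..cp2
    [0.85, 0.55, 0.05], [0.60, 0.35, 0.00],                      # cp3..cp4
], dtype=np.float32)


@dataclass
class SeverityInstance:
    id: int
    parent_detection: object            # Detection
    stage_id: int | None                # None for pests / inconsistent boxes
    pixel_support: np.ndarray | None    # bool mask at image resolution
    inconsistent: bool = False
    phrase: str = ""


@dataclass
class DiagnosisReport:
    instances: list = field(default_factory=list)
    phrases: list = field(default_factory=list)
    overlay: np.ndarray | None = None
    detections: list = field(default_factory=list)
    predicted_mask: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {"phrases": list(self.phrases),
                "instances": [{
                    "id": inst.id,
                    "class_id": inst.parent_detection.class_id,
                    "stage_id": inst.stage_id,
                    "box": [float(v) for v in inst.parent_detection.box],
                    "score": inst.parent_detection.score,
                    "inconsistent": inst.inconsistent,
                } for inst in self.instances]}


def pest_only(detections: list, catalog: ClassCatalog) -> bool:
    """True iff every detection belongs to a pest class (vacuously true for
    an empty list, with a warning); the caller then skips the severity
    forward pass."""
    if not detections:
        logger.warning("pest_only called with no detections (vacuously true)")
        return True
    return all(catalog.is_pest(d.class_id) for d in detections)


def _box_slice(box, shape):
    x0, y0, x1, y1 = box
    h, w = shape
    return (slice(int(max(np.floor(y0), 0)), int(min(np.ceil(y1), h))),
            slice(int(max(np.floor(x0), 0)), int(min(np.ceil(x1), w))))


def extract_instances(detections: list, mask: np.ndarray,
                      catalog: ClassCatalog,
                      min_pixels: int = MIN_INSTANCE_PIXELS) -> list:
    """Fuse detections and the severity mask into SeverityInstances.

    IDs are consecutive from 1 in raster order of the parent boxes
    (top-left corner y, then x, then class ID).
    """
    order = sorted(range(len(detections)),
                   key=lambda i: (detections[i].box[1], detections[i].box[0],
                                  detections[i].class_id))
    raw = []
    for i in order:
        det = detections[i]
        if catalog.is_pest(det.class_id):
            raw.append(SeverityInstance(0, det, None, None))
            continue
        legal = set(catalog.stages(det.class_id))
        sl = _box_slice(det.box, mask.shape)
        window = mask[sl]
        found = False
        labeled = measure.label(window, connectivity=2)
        for region in measure.regionprops(labeled):
            stage = int(window[tuple(region.coords[0])])
            if stage == 0 or region.area < min_pixels:
                continue
            support = np.zeros(mask.shape, dtype=bool)
            support[sl][labeled == region.label] = True
            if stage in legal:
                raw.append(SeverityInstance(0, det, stage, support))
                found = True
            else:
                # stage illegal for this box: try an enclosing legal box
                owner = None
                for j in range(len(detections)):
                    other = detections[j]
                    if catalog.is_pest(other.class_id):
                        continue
                    if stage in catalog.stages(other.class_id):
                        osl = _box_slice(other.box, mask.shape)
                        inside = np.zeros(mask.shape, dtype=bool)
                        inside[osl] = True
                        if np.logical_and(support, inside).sum() > 0.5 * support.sum():
                            owner = other
                            break
                if owner is not None and owner is not det:
                    continue  # the owning box will pick it up itself
                raw.append(SeverityInstance(0, det, stage, support,
                                            inconsistent=True))
                found = True
        if not found:
            # disease detection with no severity pixels inside: degenerate
            raw.append(SeverityInstance(0, det, None, None, inconsistent=True))
    for k, inst in enumerate(raw, start=1):
        inst.id = k
    return raw


def render_phrases(instances: list, catalog: ClassCatalog,
                   template: str = DEFAULT_TEMPLATE,
                   pest_template: str = PEST_TEMPLATE) -> list:
    """Format one phrase per instance, in ID order.

    Available fields: ``id``, ``class_name``, ``class_code``, ``stage_name``
    ("stage k" within the class), ``stage_code`` ("cp3"), ``score``.
    Unknown fields in a template are a configuration error.
    """
    allowed = {"id", "class_name", "class_code", "stage_name", "stage_code",
               "score"}
    for tpl in (template, pest_template):
        fields = {f for _, f, _, _ in string.Formatter().parse(tpl) if f}
        unknown = fields - allowed
        if unknown:
            raise KeyError(f"unknown template field(s) {sorted(unknown)}; "
                           f"allowed: {sorted(allowed)}")
    phrases = []
    for inst in sorted(instances, key=lambda x: x.id):
        det = inst.parent_detection
        ctx = {"id": inst.id,
               "class_name": catalog.name(det.class_id),
               "class_code": catalog.code(det.class_id),
               "score": det.score}
        if inst.stage_id is None:
            ctx.update(stage_name="", stage_code="")
            phrases.append(pest_template.format(**ctx))
        else:
            ctx.update(
                stage_name=f"stage {catalog.stage_index_in_class(inst.stage_id)}",
                stage_code=catalog.stage_names[inst.stage_id])
            phrases.append(template.format(**ctx))
    return phrases


def render_overlay(image: np.ndarray, instances: list) -> np.ndarray:
    """Burn boxes, per-stage mask tints and ID labels into a copy of the
    image; a pure function of its inputs (fixed palette per stage)."""
    out = image.copy()
    if not instances:
        return out
    h, w = out.shape[:2]
    for inst in instances:
        det = inst.parent_detection
        if inst.pixel_support is not None and inst.stage_id is not None:
            color = STAGE_PALETTE[inst.stage_id]
            out[inst.pixel_support] = (0.45 * out[inst.pixel_support]
                                       + 0.55 * color)
        x0, y0, x1, y1 = (int(round(v)) for v in det.box)
        x0, x1 = np.clip([x0, x1 - 1], 0, w - 1)
        y0, y1 = np.clip([y0, y1 - 1], 0, h - 1)
        edge = (STAGE_PALETTE[inst.stage_id] if inst.stage_id
                else np.array([1.0, 1.0, 1.0], np.float32))
        out[y0, x0:x1 + 1] = edge
        out[y1, x0:x1 + 1] = edge
        out[y0:y1 + 1, x0] = edge
        out[y0:y1 + 1, x1] = edge
        _burn_id(out, inst.id, x0 + 2, y0 + 2)
    return np.clip(out, 0.0, 1.0)


_DIGITS = {  # 3x5 bitmap font for instance IDs
    "0": "111101101101111", "1": "010110010010111", "2": "111001111100111",
    "3": "111001111001111", "4": "101101111001001", "5": "111100111001111",
    "6": "111100111101111", "7": "111001010010010", "8": "111101111101111",
    "9": "111101111001111",
}


def _burn_id(img: np.ndarray, value: int, x: int, y: int) -> None:
    h, w = img.shape[:2]
    for k, ch in enumerate(str(value)):
        bits = _DIGITS[ch]
        for r in range(5):
            for c in range(3):
                if bits[r * 3 + c] == "1":
                    yy, xx = y + r, x + k * 4 + c
                    if 0 <= yy < h and 0 <= xx < w:
                        img[yy, xx] = 1.0
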