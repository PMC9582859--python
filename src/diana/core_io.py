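"""Domain types, the paprika anomaly class/stage catalog, and dataset I/O.

Six anomaly classes are recognized: four viral/fungal diseases that carry
within-class severity stages (blossom end rot 3, gray mold 2, powdery mildew
2, Cercospora 4 — eleven stages in total) and two insect/pest classes
(snails and slugs, spider mite) that carry none.

On disk a dataset is a COCO-dialect instance JSON (``images``,
``annotations`` with ``bbox`` = [x, y, w, h] and ``category_id``,
``categories``) plus one single-channel 8-bit PNG severity mask per image
(pixel value 0 = background, 1..11 = severity stage ID).  Coordinates are
0-based and half-open; boxes are stored as (x_min, y_min, width, height).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

N_CLASSES = 6
N_STAGES = 11

# class IDs fixed alphabetically by code: BR, CP, GM, PM, SS, SM
CLASS_CODES = ("BR", "CP", "GM", "PM", "SS", "SM")
CLASS_NAMES = (
    "blossom end rot",
    "Cercospora",
    "gray mold",
    "powdery mildew",
    "snails and slugs",
    "spider mite",
)

# stage IDs in catalog order: br1..br3, gm1..gm2, pm1..pm2, cp1..cp4
STAGE_CODES = ("br1", "br2", "br3", "gm1", "gm2", "pm1", "pm2",
               "cp1", "cp2", "cp3", "cp4")


@dataclass(frozen=True)
class ClassCatalog:
    """Fixed taxonomy mapping classes to severity stages and pest flags."""

    classes: tuple  # (class_id, code, name)
    stage_map: dict  # class_id -> tuple of stage IDs (catalog order)
    pest_flags: dict  # class_id -> bool
    stage_names: dict  # stage_id -> code ("br1", ...)

    def class_id(self, key) -> int:
        """Resolve a class by ID, code or (case-insensitive) name."""
        if isinstance(key, (int, np.integer)):
            if not 1 <= key <= N_CLASSES:
                raise KeyError(f"class ID {key} out of range 1..{N_CLASSES}")
            return int(key)
        for cid, code, name in self.classes:
            if key == code or key.lower() == name.lower():
                return cid
        raise KeyError(f"unknown class {key!r}")

    def stages(self, key) -> tuple:
        return self.stage_map[self.class_id(key)]

    def is_pest(self, key) -> bool:
        return self.pest_flags[self.class_id(key)]

    def name(self, class_id: int) -> str:
        return self.classes[self.class_id(class_id) - 1][2]

    def code(self, class_id: int) -> str:
        return self.classes[self.class_id(class_id) - 1][1]

    def stage_class(self, stage_id: int) -> int:
        """Class a severity stage belongs to."""
        for cid, stages in self.stage_map.items():
            if stage_id in stages:
                return cid
        raise KeyError(f"stage ID {stage_id} out of range 1..{N_STAGES}")

    def stage_index_in_class(self, stage_id: int) -> int:
        """1-based position of a stage within its class (e.g. cp3 -> 3)."""
        cid = self.stage_class(stage_id)
        return self.stage_map[cid].index(stage_id) + 1


def stage_catalog() -> ClassCatalog:
    """The fixed paprika anomaly catalog (6 classes, 11 severity stages)."""
    classes = tuple((i + 1, CLASS_CODES[i], CLASS_NAMES[i]) for i in range(N_CLASSES))
    stage_map = {
        1: (1, 2, 3),        # blossom end rot: br1..br3
        2: (8, 9, 10, 11),   # Cercospora: cp1..cp4
        3: (4, 5),           # gray mold: gm1..gm2
        4: (6, 7),           # powdery mildew: pm1..pm2
        5: (),               # snails and slugs (pest)
        6: (),               # spider mite (pest)
    }
    pest_flags = {cid: len(stage_map[cid]) == 0 for cid in stage_map}
    stage_names = {i + 1: STAGE_CODES[i] for i in range(N_STAGES)}
    return ClassCatalog(classes, stage_map, pest_flags, stage_names)


@dataclass
class BoxAnnotation:
    """Axis-aligned box, 0-based half-open, COCO (x, y, w, h) encoding."""

    x_min: float
    y_min: float
    width: float
    height: float
    class_id: int

    @property
    def x_max(self) -> float:
        return self.x_min + self.width

    @property
    def y_max(self) -> float:
        return self.y_min + self.height

    @property
    def area(self) -> float:
        return self.width * self.height

    def corners(self) -> np.ndarray:
        return np.array([self.x_min, self.y_min, self.x_max, self.y_max])

    def clipped(self, w: int, h: int) -> "BoxAnnotation":
        x0 = min(max(self.x_min, 0.0), float(w))
        y0 = min(max(self.y_min, 0.0), float(h))
        x1 = min(max(self.x_max, 0.0), float(w))
        y1 = min(max(self.y_max, 0.0), float(h))
        return replace(self, x_min=x0, y_min=y0, width=x1 - x0, height=y1 - y0)


@dataclass
class ImageSample:
    """One scene: RGB image in [0,1], box annotations, severity mask, metadata."""

    image: np.ndarray                 # H x W x 3 float32 in [0,1]
    boxes: list                       # list of BoxAnnotation
    mask: np.ndarray | None = None    # H x W uint8, 0=background, 1..11=stage
    image_id: int = 0
    stem: str = "scene"
    meta: dict = field(default_factory=dict)

    @property
    def height(self) -> int:
        return self.image.shape[0]

    @property
    def width(self) -> int:
        return self.image.shape[1]


def _validate_mask(mask: np.ndarray, stem: str) -> None:
    top = int(mask.max()) if mask.size else 0
    if top > N_STAGES:
        raise ValueError(
            f"mask for {stem!r} contains stage value {top} > N_ss={N_STAGES}")


def read_dataset(annotation_path, mask_dir) -> list:
    """Load a dataset from COCO-dialect JSON plus same-stem PNG masks.

    Boxes are clipped to the image bounds; zero-area boxes (after clipping)
    are dropped with a warning.  A missing mask or an out-of-range mask value
    is a hard error naming the offending image stem.
    """
    annotation_path = Path(annotation_path)
    mask_dir = Path(mask_dir)
    with open(annotation_path) as fh:
        coco = json.load(fh)
    by_image: dict = {im["id"]: [] for im in coco["images"]}
    for ann in coco.get("annotations", []):
        by_image[ann["image_id"]].append(ann)

    samples = []
    root = annotation_path.parent
    for im in coco["images"]:
        stem = Path(im["file_name"]).stem
        img_path = root / im["file_name"]
        image = np.asarray(Image.open(img_path).convert("RGB"),
                           dtype=np.float32) / 255.0
        mask_path = mask_dir / f"{stem}.png"
        if not mask_path.exists():
            raise FileNotFoundError(f"missing severity mask for image {stem!r} "
                                    f"(expected {mask_path})")
        mask = np.asarray(Image.open(mask_path), dtype=np.uint8)
        _validate_mask(mask, stem)
        h, w = image.shape[:2]
        boxes = []
        for ann in by_image[im["id"]]:
            x, y, bw, bh = ann["bbox"]
            box = BoxAnnotation(x, y, bw, bh, ann["category_id"]).clipped(w, h)
            if box.width <= 0 or box.height <= 0:
                logger.warning("dropping zero-area box in image %r", stem)
                continue
            boxes.append(box)
        samples.append(ImageSample(image=image, boxes=boxes, mask=mask,
                                   image_id=im["id"], stem=stem))
    return samples


def write_dataset(samples, out_dir) -> dict:
    """Write samples as PNG images/masks plus a COCO-dialect annotation JSON.

    Returns a manifest dict; ``read_dataset(write_dataset(S))`` reproduces
    boxes and masks bit-exactly (images are quantized to 8 bits).
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    msk_dir = out_dir / "masks"
    img_dir.mkdir(parents=True, exist_ok=True)
    msk_dir.mkdir(parents=True, exist_ok=True)

    catalog = stage_catalog()
    images, annotations = [], []
    ann_id = 1
    for sample in samples:
        fname = f"images/{sample.stem}.png"
        arr = np.clip(np.round(sample.image * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(out_dir / fname)
        mask = sample.mask
        if mask is None:
            mask = np.zeros(sample.image.shape[:2], dtype=np.uint8)
        Image.fromarray(mask.astype(np.uint8)).save(msk_dir / f"{sample.stem}.png")
        images.append({"id": sample.image_id, "file_name": fname,
                       "width": sample.width, "height": sample.height})
        for box in sample.boxes:
            annotations.append({
                "id": ann_id, "image_id": sample.image_id,
                "bbox": [box.x_min, box.y_min, box.width, box.height],
                "category_id": box.class_id,
                "area": box.area, "iscrowd": 0,
            })
            ann_id += 1
    categories = [{"id": cid, "name": name, "supercategory": "plant anomaly"}
                  for cid, _code, name in catalog.classes]
    coco = {"images": images, "annotations": annotations, "categories": categories}
    ann_path = out_dir / "annotations.json"
    with open(ann_path, "w") as fh:
        json.dump(coco, fh)
    return {"annotations": str(ann_path), "mask_dir": str(msk_dir),
            "n_images": len(images), "n_annotations": len(annotations)}


def pad_to_multiple(image: np.ndarray, multiple: int = 128) -> np.ndarray:
    """Zero-pad an H x W x C image on the bottom/right so both spatial sizes
    divide ``multiple`` (keeps every stride-2 stage of the network exact)."""
    h, w = image.shape[:2]
    ph = (-h) % multiple
    pw = (-w) % multiple
    if ph == 0 and pw == 0:
        return image
    return np.pad(image, ((0, ph), (0, pw)) + ((0, 0),) * (image.ndim - 2))
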