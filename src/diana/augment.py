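"""Detection-time data augmentation applied consistently to image, boxes and
severity mask.

Three families:

* geometric (flip, scale, rotate, translate, color temperature): image,
  boxes and mask share one spatial map; masks are resampled with nearest
  neighbor so stage labels survive; boxes are re-tightened from the
  transformed mask when the instance has mask support, else transformed
  geometrically and clipped;
* distortion (median blur, additive Gaussian noise/blur, HSV shifts,
  channel shuffle): pixels only, annotations bit-identical;
* advanced (cut-and-paste of donor instances, mosaic tiling).

The default policy enables only the operations that helped detection in the
source study: flip, scale, translate, rotate, HSV shift, channel shuffle,
cut-and-paste and mosaic; color temperature and the blur/noise distortions
are available but off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage import transform as sktransform

from .core_io import BoxAnnotation, ImageSample, stage_catalog

logger = logging.getLogger(__name__)

GEOMETRIC_OPS = ("flip", "scale", "rotate", "translate", "color_temperature")
DISTORTION_OPS = ("median_blur", "gaussian_noise", "gaussian_blur",
                  "hsv_shift", "channel_shuffle")
ADVANCED_OPS = ("cut_and_paste", "mosaic")

# (op, parameter ranges, probability); the ops and ranges mirror the
# augmentation study, with the harmful ones disabled by default
DEFAULT_POLICY = (
    ("flip", {}, 0.9),
    ("scale", {"x": (0.8, 1.2), "y": (0.8, 1.2)}, 0.5),
    ("translate", {"x": (-0.2, 0.2), "y": (-0.2, 0.2)}, 0.5),
    ("rotate", {"angle": (-30, 30)}, 0.5),
    ("hsv_shift", {"amount": (-8, 15)}, 0.5),
    ("channel_shuffle", {}, 0.55),
)

FULL_REGISTRY = {
    "flip": {},
    "scale": {"x": (0.8, 1.2), "y": (0.8, 1.2)},
    "rotate": {"angle": (-30, 30)},
    "translate": {"x": (-0.2, 0.2), "y": (-0.2, 0.2)},
    "color_temperature": {"kelvin": (1100, 10000)},
    "median_blur": {"k": (3, 7)},
    "gaussian_noise": {"z": (0.0, 12.75)},
    "gaussian_blur": {"sigma": (0.0, 1.0)},
    "hsv_shift": {"amount": (-8, 15)},
    "channel_shuffle": {},
    "cut_and_paste": {"obj_count": (5, 10)},
    "mosaic": {"rows": (1, 2), "columns": (1, 2)},
}


@dataclass(frozen=True)
class AugmentationPolicy:
    ops: tuple = DEFAULT_POLICY

    def __post_init__(self):
        for name, _params, _p in self.ops:
            if name not in FULL_REGISTRY:
                raise KeyError(f"unknown augmentation op {name!r}")


# -- helpers -------------------------------------------------------------------

def _instance_supports(sample: ImageSample):
    """Per-annotation mask support (None for pests / mask-less boxes)."""
    catalog = stage_catalog()
    supports = []
    for box in sample.boxes:
        if sample.mask is None or catalog.is_pest(box.class_id):
            supports.append(None)
            continue
        sl = (slice(int(box.y_min), int(np.ceil(box.y_max))),
              slice(int(box.x_min), int(np.ceil(box.x_max))))
        support = np.zeros(sample.mask.shape, dtype=bool)
        legal = set(catalog.stages(box.class_id))
        window = sample.mask[sl]
        support[sl] = np.isin(window, list(legal))
        supports.append(support if support.any() else None)
    return supports


def _tight_box(support: np.ndarray, class_id: int) -> BoxAnnotation | None:
    ys, xs = np.nonzero(support)
    if len(ys) == 0:
        return None
    return BoxAnnotation(float(xs.min()), float(ys.min()),
                         float(xs.max() + 1 - xs.min()),
                         float(ys.max() + 1 - ys.min()), class_id)


def _warp_sample(sample: ImageSample, tform, out_shape=None) -> ImageSample:
    """Apply one affine map to image (bilinear), mask (nearest) and boxes.

    ``tform`` maps output coordinates to input coordinates (skimage inverse
    convention).  Boxes with mask support are re-tightened from the warped
    support; others are transformed via their corners and clipped.
    """
    out_shape = out_shape or sample.image.shape[:2]
    h, w = out_shape
    image = sktransform.warp(sample.image, tform, output_shape=out_shape,
                             order=1, mode="constant", cval=0.0,
                             preserve_range=True).astype(np.float32)
    mask = None
    if sample.mask is not None:
        mask = sktransform.warp(sample.mask, tform, output_shape=out_shape,
                                order=0, mode="constant", cval=0.0,
                                preserve_range=True).astype(np.uint8)
    supports = _instance_supports(sample)
    inv = tform.inverse  # input -> output coordinates
    boxes = []
    for box, support in zip(sample.boxes, supports):
        if support is not None:
            warped = sktransform.warp(support.astype(np.float32), tform,
                                      output_shape=out_shape, order=0,
                                      mode="constant", cval=0.0,
                                      preserve_range=True) > 0.5
            new = _tight_box(warped, box.class_id)
        else:
            corners = np.array([[box.x_min, box.y_min], [box.x_max, box.y_min],
                                [box.x_min, box.y_max], [box.x_max, box.y_max]])
            mapped = inv(corners)
            x0, y0 = mapped.min(axis=0)
            x1, y1 = mapped.max(axis=0)
            new = BoxAnnotation(x0, y0, x1 - x0, y1 - y0,
                                box.class_id).clipped(w, h)
            if new.width <= 0 or new.height <= 0:
                new = None
        if new is None:
            logger.warning("annotation lost by geometric transform (class %d)",
                           box.class_id)
            continue
        boxes.append(new)
    return ImageSample(image=image, boxes=boxes, mask=mask,
                       image_id=sample.image_id, stem=sample.stem,
                       meta=dict(sample.meta))


def _kelvin_to_rgb_gain(kelvin: float) -> np.ndarray:
    """Approximate RGB gains of a black-body illuminant, normalized so the
    gain at 6600 K is neutral."""
    t = np.clip(kelvin, 1000.0, 40000.0) / 100.0
    if t <= 66:
        r = 255.0
        g = np.clip(99.4708025861 * np.log(t) - 161.1195681661, 0, 255)
        b = 0.0 if t <= 19 else np.clip(
            138.5177312231 * np.log(t - 10) - 305.0447927307, 0, 255)
    else:
        r = np.clip(329.698727446 * ((t - 60) ** -0.1332047592), 0, 255)
        g = np.clip(288.1221695283 * ((t - 60) ** -0.0755148492), 0, 255)
        b = 255.0
    return np.array([r, g, b], dtype=np.float32) / 255.0


# -- geometric ops -------------------------------------------------------------

def apply_geometric(sample: ImageSample, op: str, params: dict,
                    seed: int = 0) -> ImageSample:
    """One geometric augmentation; parameters are concrete values (not
    ranges).  ``flip`` takes no parameter; ``scale`` x/y factors; ``rotate``
    angle in degrees around the image center; ``translate`` fractional
    shifts; ``color_temperature`` a Kelvin value (spatially identity but
    grouped here as in the source study's taxonomy)."""
    h, w = sample.image.shape[:2]
    if op == "flip":
        # horizontal flip is exact: slice reversal, x_min' = W - x_max
        out = _copy_sample(sample)
        out.image = np.ascontiguousarray(sample.image[:, ::-1])
        if sample.mask is not None:
            out.mask = np.ascontiguousarray(sample.mask[:, ::-1])
        out.boxes = [replace(b, x_min=w - b.x_max) for b in sample.boxes]
        return out
    if op == "scale":
        sx, sy = params.get("x", 1.0), params.get("y", 1.0)
        if sx == 1.0 and sy == 1.0:
            return _copy_sample(sample)
        shift = sktransform.AffineTransform(translation=(-w / 2, -h / 2))
        zoom = sktransform.AffineTransform(scale=(1 / sx, 1 / sy))
        back = sktransform.AffineTransform(translation=(w / 2, h / 2))
        return _warp_sample(sample, shift + zoom + back)
    if op == "rotate":
        angle = params.get("angle", 0.0)
        if angle == 0.0:
            return _copy_sample(sample)
        shift = sktransform.AffineTransform(translation=(-w / 2, -h / 2))
        rot = sktransform.AffineTransform(rotation=np.deg2rad(angle))
        back = sktransform.AffineTransform(translation=(w / 2, h / 2))
        return _warp_sample(sample, shift + rot + back)
    if op == "translate":
        tx = params.get("x", 0.0) * w
        ty = params.get("y", 0.0) * h
        tform = sktransform.AffineTransform(translation=(-tx, -ty))
        return _warp_sample(sample, tform)
    if op == "color_temperature":
        gain = _kelvin_to_rgb_gain(params["kelvin"]) / _kelvin_to_rgb_gain(6600.0)
        out = _copy_sample(sample)
        out.image = np.clip(sample.image * gain[None, None, :], 0, 1)
        return out
    raise KeyError(f"unknown geometric op {op!r}")


def _copy_sample(sample: ImageSample) -> ImageSample:
    return ImageSample(image=sample.image.copy(),
                       boxes=[replace(b) for b in sample.boxes],
                       mask=None if sample.mask is None else sample.mask.copy(),
                       image_id=sample.image_id, stem=sample.stem,
                       meta=dict(sample.meta))


# -- distortion ops ------------------------------------------------------------

def apply_distortion(sample: ImageSample, op: str, params: dict,
                     seed: int = 0) -> ImageSample:
    """Pixel-only distortions; boxes and mask are returned bit-identical."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF]))
    out = _copy_sample(sample)
    img = out.image
    if op == "median_blur":
        k = int(params["k"])
        if k % 2 == 0:
            raise ValueError("median blur kernel must be odd")
        out.image = ndimage.median_filter(img, size=(k, k, 1))
    elif op == "gaussian_noise":
        z = params["z"]  # std on the 0..255 intensity scale
        out.image = np.clip(
            img + rng.normal(0, z / 255.0, img.shape).astype(np.float32), 0, 1)
    elif op == "gaussian_blur":
        sigma = params["sigma"]
        if sigma > 0:
            out.image = ndimage.gaussian_filter(img, sigma=(sigma, sigma, 0))
    elif op == "hsv_shift":
        a = params["amount"] / 255.0
        hsv = skcolor.rgb2hsv(img)
        hsv[..., 0] = (hsv[..., 0] + a) % 1.0
        hsv[..., 1:] = np.clip(hsv[..., 1:] + a, 0, 1)
        out.image = skcolor.hsv2rgb(hsv).astype(np.float32)
    elif op == "channel_shuffle":
        perm = rng.permutation(3)
        out.image = img[..., perm]
    else:
        raise KeyError(f"unknown distortion op {op!r}")
    out.image = out.image.astype(np.float32)
    return out


# -- advanced ops --------------------------------------------------------------

def cut_and_paste(sample: ImageSample, donor_pool: list,
                  obj_count_range: tuple = (5, 10), seed: int = 0,
                  occlusion_drop: float = 0.7) -> ImageSample:
    """Paste donor instances (mask support for diseases, box crop for pests)
    at random positions; their boxes and mask labels are added and original
    annotations losing more than ``occlusion_drop`` of their area are
    dropped."""
    if not donor_pool:
        raise ValueError("cut_and_paste requires a non-empty donor pool")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 5]))
    catalog = stage_catalog()
    donors = []
    for ds in donor_pool:
        sups = _instance_supports(ds)
        for box, sup in zip(ds.boxes, sups):
            donors.append((ds, box, sup))
    if not donors:
        raise ValueError("donor pool carries no instances")
    out = _copy_sample(sample)
    if out.mask is None:
        out.mask = np.zeros(out.image.shape[:2], dtype=np.uint8)
    h, w = out.image.shape[:2]
    original_areas = [(b, _clipped_visible_area(out, b)) for b in out.boxes]
    k = int(rng.integers(obj_count_range[0], obj_count_range[1] + 1))
    pasted = []
    for _ in range(k):
        ds, box, sup = donors[int(rng.integers(len(donors)))]
        sl = (slice(int(box.y_min), int(np.ceil(box.y_max))),
              slice(int(box.x_min), int(np.ceil(box.x_max))))
        patch = ds.image[sl]
        ph, pw = patch.shape[:2]
        if ph >= h or pw >= w or ph == 0 or pw == 0:
            continue
        y = int(rng.integers(0, h - ph))
        x = int(rng.integers(0, w - pw))
        if sup is not None:
            local = sup[sl]
            out.image[y:y + ph, x:x + pw][local] = patch[local]
            stage_patch = ds.mask[sl]
            out.mask[y:y + ph, x:x + pw][local] = stage_patch[local]
        else:
            out.image[y:y + ph, x:x + pw] = patch
            local = np.ones((ph, pw), dtype=bool)
        ys, xs = np.nonzero(local)
        pasted.append(BoxAnnotation(float(x + xs.min()), float(y + ys.min()),
                                    float(xs.max() + 1 - xs.min()),
                                    float(ys.max() + 1 - ys.min()),
                                    box.class_id))
    # drop originals mostly occluded by pastes
    kept = []
    for box, area0 in original_areas:
        if area0 <= 0:
            continue
        visible = _clipped_visible_area(out, box, pasted)
        if visible / area0 < (1 - occlusion_drop):
            logger.warning("dropping occluded annotation (class %d)", box.class_id)
            continue
        kept.append(box)
    out.boxes = kept + pasted
    return out


def _clipped_visible_area(sample: ImageSample, box: BoxAnnotation,
                          pasted: list | None = None) -> float:
    area = box.area
    if not pasted:
        return area
    covered = 0.0
    for p in pasted:
        ix0 = max(box.x_min, p.x_min)
        iy0 = max(box.y_min, p.y_min)
        ix1 = min(box.x_max, p.x_max)
        iy1 = min(box.y_max, p.y_max)
        covered += max(ix1 - ix0, 0) * max(iy1 - iy0, 0)
    return max(area - covered, 0.0)


def mosaic(samples: list, rows: int, cols: int, seed: int = 0,
           out_size: tuple | None = None) -> ImageSample:
    """Tile rows x cols samples into one canvas; tile (i, j) is resized into
    the cell with origin (j*W/cols, i*H/rows).  A 1x1 grid is an identity
    resize."""
    if len(samples) != rows * cols:
        raise ValueError(f"mosaic needs {rows * cols} samples, got {len(samples)}")
    h, w = out_size or samples[0].image.shape[:2]
    canvas = np.zeros((h, w, 3), dtype=np.float32)
    mask = np.zeros((h, w), dtype=np.uint8)
    boxes = []
    ch, cw = h // rows, w // cols
    for i in range(rows):
        for j in range(cols):
            s = samples[i * cols + j]
            sh, sw = s.image.shape[:2]
            sy, sx = ch / sh, cw / sw
            y0, x0 = i * ch, j * cw
            canvas[y0:y0 + ch, x0:x0 + cw] = sktransform.resize(
                s.image, (ch, cw), order=1, preserve_range=True,
                anti_aliasing=False).astype(np.float32)
            if s.mask is not None:
                mask[y0:y0 + ch, x0:x0 + cw] = sktransform.resize(
                    s.mask, (ch, cw), order=0, preserve_range=True,
                    anti_aliasing=False).astype(np.uint8)
            for b in s.boxes:
                nb = BoxAnnotation(b.x_min * sx + x0, b.y_min * sy + y0,
                                   b.width * sx, b.height * sy,
                                   b.class_id).clipped(w, h)
                if nb.width >= 1 and nb.height >= 1:
                    boxes.append(nb)
    return ImageSample(image=canvas, boxes=boxes, mask=mask,
                       stem=f"mosaic_{samples[0].stem}")


# -- policy driver -------------------------------------------------------------

def apply_policy(sample: ImageSample, policy: AugmentationPolicy,
                 seed: int = 0) -> ImageSample:
    """Sample parameters from the policy's ranges and apply the enabled ops
    in order (one RNG stream per sample)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 11]))
    out = sample
    for name, ranges, prob in policy.ops:
        if rng.random() > prob:
            continue
        params = {key: float(rng.uniform(*rng_range)) if isinstance(rng_range, tuple)
                  else rng_range for key, rng_range in ranges.items()}
        op_seed = int(rng.integers(2 ** 31))
        if name in GEOMETRIC_OPS:
            out = apply_geometric(out, name, params, seed=op_seed)
        elif name in DISTORTION_OPS:
            if name == "median_blur" and "k" in params:
                k = int(params["k"])
                params["k"] = k + 1 if k % 2 == 0 else k
            out = apply_distortion(out, name, params, seed=op_seed)
        # advanced ops need donor pools / multiple samples: driven by the
        # training loop, not the per-sample policy
    return out
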