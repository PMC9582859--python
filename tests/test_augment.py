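"""Augmentation suite: geometric image/box/mask consistency, annotation-
preserving distortions, cut-and-paste and mosaic conservation laws."""

import numpy as np
import pytest
from skimage import measure

from diana.augment import (AugmentationPolicy, DEFAULT_POLICY, apply_distortion,
                           apply_geometric, apply_policy, cut_and_paste, mosaic)
from diana.core_io import stage_catalog
from diana.metrics import iou
from diana.synthetic import SceneConfig, generate_scene

CATALOG = stage_catalog()


@pytest.fixture(scope="module")
def scene():
    cfg = SceneConfig(image_size=128, n_instances_range=(3, 4), seed=0)
    return generate_scene(cfg, seed=21)


def tight_boxes_from_mask(mask):
    out = []
    labeled = measure.label(mask > 0, connectivity=2)
    for region in measure.regionprops(labeled):
        y0, x0, y1, x1 = region.bbox
        out.append(np.array([x0, y0, x1, y1], float))
    return out


class TestGeometric:
    def test_double_flip_is_identity(self, scene):
        once = apply_geometric(scene, "flip", {})
        twice = apply_geometric(once, "flip", {})
        np.testing.assert_allclose(twice.image, scene.image, atol=1e-6)
        np.testing.assert_array_equal(twice.mask, scene.mask)
        for b0, b1 in zip(scene.boxes, twice.boxes):
            np.testing.assert_allclose(b0.corners(), b1.corners(), atol=1.0)

    def test_identity_parameters_are_identity(self, scene):
        out = apply_geometric(scene, "rotate", {"angle": 0.0})
        np.testing.assert_array_equal(out.image, scene.image)
        out = apply_geometric(scene, "scale", {"x": 1.0, "y": 1.0})
        np.testing.assert_array_equal(out.mask, scene.mask)

    def test_flip_box_coordinate_arithmetic(self, scene):
        w = scene.image.shape[1]
        flipped = apply_geometric(scene, "flip", {})
        # pests keep their geometric transform: x_min' = W - x_min - width
        pests = [(b, fb) for b, fb in zip(scene.boxes, flipped.boxes)
                 if CATALOG.is_pest(b.class_id)]
        for b, fb in pests:
            assert fb.x_min == pytest.approx(w - b.x_min - b.width)
            assert fb.width == pytest.approx(b.width)

    @pytest.mark.parametrize("op,params", [
        ("flip", {}),
        ("scale", {"x": 1.15, "y": 0.85}),
        ("rotate", {"angle": 17.0}),
        ("translate", {"x": 0.1, "y": -0.08}),
    ])
    def test_mask_and_boxes_transform_consistently(self, op, params):
        cfg = SceneConfig(image_size=128, n_instances_range=(2, 3))
        rng = np.random.default_rng(3)
        for _ in range(10):
            sample = generate_scene(cfg, seed=int(rng.integers(2 ** 31)))
            out = apply_geometric(sample, op, params)
            mask_boxes = tight_boxes_from_mask(out.mask)
            disease = [b for b in out.boxes if not CATALOG.is_pest(b.class_id)]
            assert len(mask_boxes) >= len(disease)
            for b in disease:
                best = max((iou(b.corners(), mb) for mb in mask_boxes),
                           default=0.0)
                assert best >= 0.95

    def test_color_temperature_changes_pixels_only(self, scene):
        out = apply_geometric(scene, "color_temperature", {"kelvin": 2500})
        np.testing.assert_array_equal(out.mask, scene.mask)
        assert len(out.boxes) == len(scene.boxes)
        assert not np.array_equal(out.image, scene.image)
        # warm illuminant: red gain above blue gain
        assert out.image[..., 0].mean() >= out.image[..., 2].mean()


class TestDistortion:
    @pytest.mark.parametrize("op,params", [
        ("median_blur", {"k": 3}),
        ("gaussian_noise", {"z": 8.0}),
        ("gaussian_blur", {"sigma": 0.7}),
        ("hsv_shift", {"amount": 10}),
        ("channel_shuffle", {}),
    ])
    def test_annotations_bit_identical(self, scene, op, params):
        out = apply_distortion(scene, op, params, seed=5)
        np.testing.assert_array_equal(out.mask, scene.mask)
        assert [vars(b) for b in out.boxes] == [vars(b) for b in scene.boxes]

    def test_zero_sigma_blur_is_identity(self, scene):
        out = apply_distortion(scene, "gaussian_blur", {"sigma": 0.0})
        np.testing.assert_array_equal(out.image, scene.image)

    def test_zero_noise_is_identity(self, scene):
        out = apply_distortion(scene, "gaussian_noise", {"z": 0.0})
        np.testing.assert_allclose(out.image, scene.image, atol=1e-7)

    def test_even_median_kernel_rejected(self, scene):
        with pytest.raises(ValueError, match="odd"):
            apply_distortion(scene, "median_blur", {"k": 4})


class TestCutAndPaste:
    def test_single_paste_adds_one_box(self, scene):
        donor = generate_scene(SceneConfig(image_size=128,
                                           n_instances_range=(1, 1)), seed=9)
        out = cut_and_paste(scene, [donor], obj_count_range=(1, 1), seed=2)
        assert len(out.boxes) >= len(scene.boxes)  # occlusion may drop some
        assert len(out.boxes) <= len(scene.boxes) + 1

    def test_pasted_disease_stages_appear_in_mask(self):
        base = generate_scene(SceneConfig(image_size=128,
                                          n_instances_range=(0, 0)), seed=1)
        donor = generate_scene(SceneConfig(image_size=128,
                                           n_instances_range=(1, 1),
                                           class_weights=(0, 1, 0, 0, 0, 0)),
                               seed=7)
        out = cut_and_paste(base, [donor], obj_count_range=(1, 1), seed=3)
        assert len(out.boxes) == 1
        stage = {int(v) for v in np.unique(out.mask)} - {0}
        assert stage and stage <= set(CATALOG.stages("CP"))

    def test_deterministic_given_seed(self, scene):
        donor = generate_scene(SceneConfig(image_size=128,
                                           n_instances_range=(2, 2)), seed=4)
        a = cut_and_paste(scene, [donor], obj_count_range=(2, 2), seed=11)
        b = cut_and_paste(scene, [donor], obj_count_range=(2, 2), seed=11)
        np.testing.assert_array_equal(a.image, b.image)
        assert [vars(x) for x in a.boxes] == [vars(x) for x in b.boxes]

    def test_empty_donor_pool_rejected(self, scene):
        with pytest.raises(ValueError, match="donor"):
            cut_and_paste(scene, [], seed=0)


class TestMosaic:
    def test_one_by_one_is_identity_resize(self, scene):
        out = mosaic([scene], rows=1, cols=1, seed=0)
        assert out.image.shape == scene.image.shape
        assert len(out.boxes) == len(scene.boxes)
        np.testing.assert_allclose(out.image, scene.image, atol=1e-6)

    def test_two_by_two_conserves_annotations(self):
        cfg = SceneConfig(image_size=128, n_instances_range=(2, 2))
        sources = [generate_scene(cfg, seed=s) for s in range(4)]
        out = mosaic(sources, rows=2, cols=2, seed=0)
        assert out.image.shape == (128, 128, 3)
        assert len(out.boxes) == sum(len(s.boxes) for s in sources)

    def test_tile_origins(self):
        cfg = SceneConfig(image_size=64, n_instances_range=(1, 1))
        sources = [generate_scene(cfg, seed=s) for s in range(4)]
        out = mosaic(sources, rows=2, cols=2, seed=0, out_size=(64, 64))
        # tile (i, j) boxes live inside cell (j*W/cols, i*H/rows)
        for k, s in enumerate(sources):
            i, j = divmod(k, 2)
            b = out.boxes[k]
            assert b.x_min >= j * 32 - 1e-6 and b.x_max <= (j + 1) * 32 + 1e-6
            assert b.y_min >= i * 32 - 1e-6 and b.y_max <= (i + 1) * 32 + 1e-6

    def test_wrong_source_count_rejected(self, scene):
        with pytest.raises(ValueError, match="needs 4"):
            mosaic([scene], rows=2, cols=2)


class TestPolicy:
    def test_default_policy_excludes_harmful_ops(self):
        names = {name for name, _p, _prob in DEFAULT_POLICY}
        assert {"flip", "scale", "translate", "rotate", "hsv_shift",
                "channel_shuffle"} <= names
        assert not names & {"color_temperature", "median_blur",
                            "gaussian_noise", "gaussian_blur"}

    def test_unknown_op_rejected(self):
        with pytest.raises(KeyError):
            AugmentationPolicy(ops=(("warp_drive", {}, 1.0),))

    def test_policy_application_deterministic(self, scene):
        policy = AugmentationPolicy()
        a = apply_policy(scene, policy, seed=31)
        b = apply_policy(scene, policy, seed=31)
        np.testing.assert_array_equal(a.image, b.image)
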