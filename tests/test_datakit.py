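"""Annotation I/O, augmentations, splitting, and the synthetic
dense-flock scene generator."""

import numpy as np
import pytest

from flockdetr.data import (AnnotatedImage, FlockSceneSpec, augment_gamma_hsv,
                            augment_rotate, augment_salt_pepper,
                            build_augmented_trainset, from_coco_json,
                            generate_flock_dataset, generate_flock_scene,
                            read_voc_xml, split_dataset, to_coco_json,
                            write_voc_xml)


def _random_ann(rng, h=48, w=64, n=3, sid="img"):
    boxes = []
    for _ in range(n):
        x0 = rng.integers(0, w - 8)
        y0 = rng.integers(0, h - 8)
        boxes.append([x0, y0, x0 + rng.integers(2, 8), y0 + rng.integers(2, 8)])
    return AnnotatedImage(
        image=rng.integers(0, 256, (h, w, 3)).astype(np.uint8),
        boxes=np.array(boxes, np.float32), source_id=sid)


class TestVOC:
    def test_roundtrip_many_random_annotations(self, rng, tmp_path):
        for i in range(50):
            ann = _random_ann(rng, sid=f"img{i}")
            path = tmp_path / f"a{i}.xml"
            write_voc_xml(ann, path)
            back = read_voc_xml(path)
            assert np.array_equal(back.boxes, ann.boxes)
            assert np.array_equal(back.labels, ann.labels)
            assert (back.height, back.width) == (ann.height, ann.width)

    def test_specific_box_survives(self, tmp_path):
        ann = AnnotatedImage(image=np.zeros((50, 50, 3), np.uint8),
                             boxes=np.array([[10, 20, 30, 40]], np.float32))
        write_voc_xml(ann, tmp_path / "b.xml")
        assert read_voc_xml(tmp_path / "b.xml").boxes.tolist() == [[10, 20, 30, 40]]

    def test_voc_convention_map(self, tmp_path):
        """VOC (1, 1, W, H) inclusive == internal (0, 0, W, H) half-open."""
        ann = AnnotatedImage(image=np.zeros((20, 30, 3), np.uint8),
                             boxes=np.array([[0, 0, 30, 20]], np.float32))
        path = tmp_path / "c.xml"
        write_voc_xml(ann, path)
        text = path.read_text()
        assert "<xmin>1</xmin>" in text and "<ymin>1</ymin>" in text
        assert "<xmax>30</xmax>" in text and "<ymax>20</ymax>" in text
        assert read_voc_xml(path).boxes.tolist() == [[0, 0, 30, 20]]

    def test_malformed_xml_raises_with_path(self, tmp_path):
        bad = tmp_path / "bad.xml"
        bad.write_text("<annotation><object>")
        with pytest.raises(ValueError, match="bad.xml"):
            read_voc_xml(bad)


class TestCOCO:
    def test_structure_and_counts(self, rng):
        ds = [_random_ann(rng, n=2, sid="one")]
        doc = to_coco_json(ds)
        assert len(doc["images"]) == 1 and len(doc["annotations"]) == 2
        a = doc["annotations"][0]
        assert a["area"] == pytest.approx(a["bbox"][2] * a["bbox"][3])

    def test_empty_dataset(self):
        doc = to_coco_json([])
        assert doc["images"] == [] and doc["annotations"] == []

    def test_ids_unique_and_contiguous(self, rng):
        ds = [_random_ann(rng, n=3, sid=f"i{k}") for k in range(4)]
        doc = to_coco_json(ds)
        assert [im["id"] for im in doc["images"]] == [1, 2, 3, 4]
        assert [a["id"] for a in doc["annotations"]] == list(range(1, 13))

    def test_roundtrip_preserves_boxes(self, rng):
        ds = [_random_ann(rng, n=3, sid=f"r{k}") for k in range(3)]
        back = from_coco_json(to_coco_json(ds))
        for a, b in zip(ds, back):
            assert np.allclose(a.boxes, b.boxes)


class TestRotate:
    def test_zero_angle_is_identity(self, rng):
        ann = _random_ann(rng)
        out = augment_rotate(ann, rng, angle=0.0)
        assert np.array_equal(out.image, ann.image)
        assert np.allclose(out.boxes, ann.boxes)

    def test_90_degrees_on_square_image_analytic(self, rng):
        """A 90-degree turn maps box corners by the exact rotation about
        the image centre, and the transformed box tracks the rotated
        pixel content."""
        n = 40
        img = np.zeros((n, n, 3), np.uint8)
        img[10:18, 5:15] = 255
        ann = AnnotatedImage(image=img,
                             boxes=np.array([[5, 10, 15, 18]], np.float32))
        out = augment_rotate(ann, rng, angle=90.0)
        c = n / 2.0
        # corner-transform oracle: (x, y) -> (c + (y-c), c - (x-c))
        corners = np.array([[5, 10], [15, 10], [5, 18], [15, 18]], float)
        rot = np.stack([c + (corners[:, 1] - c), c - (corners[:, 0] - c)], axis=1)
        exp = [rot[:, 0].min(), rot[:, 1].min(), rot[:, 0].max(), rot[:, 1].max()]
        assert np.allclose(out.boxes[0], exp, atol=1e-4)
        ys, xs = np.nonzero(out.image[..., 0] > 127)
        content = [xs.min(), ys.min(), xs.max() + 1, ys.max() + 1]
        assert np.allclose(out.boxes[0], content, atol=1.0)

    def test_boxes_stay_in_bounds(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            ann = _random_ann(r)
            out = augment_rotate(ann, r)
            if len(out.boxes):
                assert (out.boxes[:, 0] >= 0).all() and (out.boxes[:, 1] >= 0).all()
                assert (out.boxes[:, 2] <= ann.width).all()
                assert (out.boxes[:, 3] <= ann.height).all()


class TestSaltPepper:
    def test_corruption_count_within_binomial_ci(self, rng):
        ann = AnnotatedImage(image=np.full((100, 100, 3), 128, np.uint8),
                             boxes=np.array([[1, 1, 9, 9]], np.float32))
        d = 0.02
        out = augment_salt_pepper(ann, rng, density=d)
        corrupted = int((out.image != 128).any(axis=2).sum())
        n = 100 * 100
        # 99% binomial interval
        lo = d * n - 2.576 * np.sqrt(n * d * (1 - d))
        hi = d * n + 2.576 * np.sqrt(n * d * (1 - d))
        assert lo <= corrupted <= hi
        vals = np.unique(out.image[(out.image != 128).any(axis=2)])
        assert set(vals.tolist()) <= {0, 255}

    def test_zero_density_is_identity_and_boxes_untouched(self, rng):
        ann = _random_ann(rng)
        out = augment_salt_pepper(ann, rng, density=0.0)
        assert np.array_equal(out.image, ann.image)
        out2 = augment_salt_pepper(ann, rng, density=0.03)
        assert np.array_equal(out2.boxes, ann.boxes)


class TestGammaHSV:
    def test_identity_parameters_within_one_lsb(self, rng):
        ann = _random_ann(rng)
        out = augment_gamma_hsv(ann, rng, gamma=1.0, v_shift=0.0)
        assert np.abs(out.image.astype(int) - ann.image.astype(int)).max() <= 1

    def test_scalar_pixel_oracle(self, rng):
        """Gray value 64 under gamma 0.5 -> 255*sqrt(64/255) = 127.7 -> 128."""
        ann = AnnotatedImage(image=np.full((8, 8, 3), 64, np.uint8),
                             boxes=np.array([[0, 0, 4, 4]], np.float32))
        out = augment_gamma_hsv(ann, rng, gamma=0.5, v_shift=0.0)
        assert abs(int(out.image[4, 4, 0]) - 128) <= 1

    def test_gamma_preserves_value_ordering(self, rng):
        vals = np.array([10, 60, 120, 200, 250], np.uint8)
        img = np.repeat(vals, 5).reshape(5, 5, 1).repeat(3, axis=2)
        ann = AnnotatedImage(image=img, boxes=np.array([[0, 0, 2, 2]], np.float32))
        out = augment_gamma_hsv(ann, rng, gamma=0.6, v_shift=0.0)
        got = out.image[:, 0, 0].astype(int)
        assert (np.diff(got) >= 0).all()


class TestAugmentedTrainset:
    def test_expansion_arithmetic(self, rng):
        originals = [_random_ann(rng, h=16, w=16, n=1, sid=f"o{i}") for i in range(800)]
        out = build_augmented_trainset(originals, 120, rng)
        assert len(out) == 920
        assert out[:800] is not originals and all(a is b for a, b in zip(out, originals))
        assert all(a.provenance for a in out[800:])

    def test_zero_extra_is_unchanged(self, rng):
        originals = [_random_ann(rng, sid="x")]
        assert len(build_augmented_trainset(originals, 0, rng)) == 1


class TestSplit:
    def test_1000_gives_800_100_100(self, rng):
        ds = [_random_ann(rng, h=16, w=16, n=1, sid=f"s{i}") for i in range(1000)]
        sp = split_dataset(ds, (8, 1, 1), seed=3)
        assert (len(sp["train"]), len(sp["val"]), len(sp["test"])) == (800, 100, 100)

    def test_ten_images_and_determinism(self, rng):
        ds = [_random_ann(rng, h=16, w=16, n=1, sid=f"t{i}") for i in range(10)]
        sp1 = split_dataset(ds, (8, 1, 1), seed=5)
        assert (len(sp1["train"]), len(sp1["val"]), len(sp1["test"])) == (8, 1, 1)
        sp2 = split_dataset(ds, (8, 1, 1), seed=5)
        for k in sp1:
            assert [a.source_id for a in sp1[k]] == [a.source_id for a in sp2[k]]


class TestGenerator:
    def test_seeded_scene_is_bitwise_reproducible(self):
        spec = FlockSceneSpec(stage="growing", n_faces=6, image_size=128, seed=11)
        a, b = generate_flock_scene(spec), generate_flock_scene(spec)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.boxes, b.boxes)

    def test_zero_occlusion_gives_disjoint_boxes(self):
        from flockdetr.losses import iou_corners
        spec = FlockSceneSpec(stage="growing", n_faces=5, image_size=192,
                              occlusion=0.0, seed=2)
        ann = generate_flock_scene(spec)
        assert len(ann.boxes) == 5
        iou = iou_corners(ann.boxes, ann.boxes)
        np.fill_diagonal(iou, 0.0)
        assert iou.max() == 0.0

    def test_stage_size_ordering_monte_carlo(self):
        """Mean face-box area: brooding < growing < finisher."""
        def mean_area(stage):
            areas = []
            for s in range(30):
                ann = generate_flock_scene(FlockSceneSpec(
                    stage=stage, n_faces=4, image_size=128, seed=1000 + s))
                wh = ann.boxes[:, 2:] - ann.boxes[:, :2]
                areas.extend((wh[:, 0] * wh[:, 1]).tolist())
            return np.mean(areas)
        a_b, a_g, a_f = (mean_area(s) for s in ("brooding", "growing", "finisher"))
        assert a_b < a_g < a_f

    def test_boxes_match_rendered_instance_masks_exactly(self):
        spec = FlockSceneSpec(stage="growing", n_faces=7, image_size=160,
                              occlusion=0.4, seed=9)
        ann, masks = generate_flock_scene(spec, return_masks=True)
        assert len(masks) == len(ann.boxes)
        for box, mask in zip(ann.boxes, masks):
            ys, xs = np.nonzero(mask)
            assert [xs.min(), ys.min(), xs.max() + 1, ys.max() + 1] == box.tolist()

    def test_infeasible_packing_warns_and_degrades_gracefully(self):
        spec = FlockSceneSpec(stage="finisher", n_faces=60, image_size=96,
                              occlusion=0.0, seed=0)
        with pytest.warns(UserWarning):
            ann = generate_flock_scene(spec)
        assert len(ann.boxes) < 60

    def test_dataset_generation_and_invalid_spec(self):
        ds = generate_flock_dataset(3, stage="brooding", base_seed=7, image_size=96)
        assert len(ds) == 3 and all(len(a.boxes) >= 1 for a in ds)
        with pytest.raises(ValueError):
            FlockSceneSpec(stage="adult")
        with pytest.raises(ValueError):
            FlockSceneSpec(n_faces=0)
        with pytest.raises(ValueError):
            FlockSceneSpec(occlusion=1.5)


def test_annotated_image_validation(rng):
    with pytest.raises(ValueError):
        AnnotatedImage(image=np.zeros((10, 10, 3), np.uint8),
                       boxes=np.array([[0, 0, 20, 5]], np.float32))
    with pytest.raises(ValueError):
        AnnotatedImage(image=np.zeros((10, 10, 3), np.uint8),
                       boxes=np.array([[3, 3, 3.5, 8]], np.float32))
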