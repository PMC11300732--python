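"""The copy-paste engine: occupancy map, placement rules, pasting, flips."""

import numpy as np
import pytest

from histocp.augment import (
    AugmentConfig,
    PlacementPoint,
    augment_dataset,
    augment_image,
    build_instance_pool,
    build_location_threshold,
    choose_instances,
    imbalance_ratio,
    is_footprint_free,
    is_location_free,
    missing_classes,
    paste_instance,
    paste_origin,
    propose_point,
    random_flip,
)
from histocp.errors import NoValidLocationError
from histocp.formats import (
    ImageRecord,
    class_counts,
    parse_three_channel_mask,
    render_three_channel_mask,
)
from histocp.synthetic import SceneSpec, generate_scene

from conftest import make_square_instance


class TestLocationThreshold:
    def test_empty_scene_all_free(self):
        lt = build_location_threshold([], 20, 30)
        assert lt.occupied_count == 0 and lt.grid.shape == (20, 30)

    def test_square_occupies_its_area(self, square_instance):
        lt = build_location_threshold([square_instance], 20, 20)
        assert lt.occupied_count == 25

    def test_random_scene_equals_direct_union_oracle(self):
        spec = SceneSpec(nuclei_count=(20, 30))
        _, _, instances = generate_scene(spec, np.random.default_rng(0))
        lt = build_location_threshold(instances, spec.height, spec.width)
        union = np.zeros((spec.height, spec.width), bool)
        for inst in instances:
            union |= inst.full_mask(spec.height, spec.width)
        assert np.array_equal(lt.grid, union)


class TestMissingClasses:
    def test_all_present_gives_empty_set(self, three_class_map):
        instances = [make_square_instance(instance_id=i + 1, label=l, category_id=i + 1,
                                          x=8 * i, y=8 * i)
                     for i, l in enumerate(three_class_map.labels)]
        assert missing_classes(instances, three_class_map.labels) == set()

    def test_empty_image_misses_everything(self):
        universe = [f"c{i}" for i in range(7)]
        assert missing_classes([], universe) == set(universe)

    def test_set_difference(self, three_class_map):
        instances = [make_square_instance(label="tumor")]
        assert missing_classes(instances, three_class_map.labels) == {
            "lymphocyte", "fibroblast",
        }

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            missing_classes([make_square_instance(label="alien")], ["tumor"])

    def test_minority_grouped_universe(self):
        # under the minority-merged grouping, an image holding only tumor and
        # fibroblast misses the remaining six grouped classes
        from histocp import nucls
        from histocp.formats import grouped_class_map
        universe = grouped_class_map(nucls.CONFIG2_GROUPING).labels
        instances = [make_square_instance(instance_id=1, label="tumor"),
                     make_square_instance(instance_id=2, label="fibroblast", x=10, y=10)]
        missing = missing_classes(instances, universe)
        assert missing == {"lymphocyte", "plasma_cell", "macrophage",
                           "vascular_endothelium", "other_nuclei", "ambiguous"}


class TestChooseInstances:
    def test_empty_missing_set(self):
        cfg = AugmentConfig(n_missing_classes=3)
        chins = choose_instances(set(), {}, cfg, np.random.default_rng(0))
        assert len(chins) == 0

    def test_k_items_of_single_class(self):
        pool = {"a": [make_square_instance(instance_id=i, label="a") for i in range(5)]}
        cfg = AugmentConfig(n_missing_classes=1, k_samples_per_class=2)
        chins = choose_instances({"a"}, pool, cfg, np.random.default_rng(0))
        assert len(chins) == 2 and set(chins.classes) == {"a"}
        assert len({i.instance_id for i in chins.items}) == 2  # without replacement

    def test_empty_pool_class_is_skipped_not_fatal(self):
        cfg = AugmentConfig(n_missing_classes=2, k_samples_per_class=1)
        pool = {"a": [make_square_instance(label="a")]}
        chins = choose_instances({"a", "b"}, pool, cfg, np.random.default_rng(1))
        assert chins.skipped_classes == ["b"]
        assert set(chins.classes) <= {"a"}

    def test_fixed_seed_reproducible(self):
        pool = {c: [make_square_instance(instance_id=i, label=c) for i in range(9)]
                for c in "abcde"}
        cfg = AugmentConfig(n_missing_classes=3, k_samples_per_class=4)
        runs = []
        for _ in range(2):
            chins = choose_instances(set("abcde"), pool, cfg, np.random.default_rng(42))
            runs.append([(c, i.instance_id) for c, i in zip(chins.classes, chins.items)])
        assert runs[0] == runs[1]


class TestProposePoint:
    def test_bounds_hold_over_many_draws(self):
        lt = build_location_threshold([], 100, 100)
        rng = np.random.default_rng(0)
        for _ in range(10_000):
            pt = propose_point(lt, 10, 10, rng)
            x, y = pt.p0
            assert 5 < x < 95 and 5 < y < 95

    def test_probe_offsets_match_half_sizes(self):
        lt = build_location_threshold([], 30, 30)

        class _Fixed:
            def integers(self, low, high):
                return 10
        pt = propose_point(lt, 4, 4, _Fixed())
        assert pt.p0 == (10, 10)
        assert set(pt.probe_points) == {
            (8, 8), (10, 8), (12, 8), (8, 10), (12, 10), (8, 12), (10, 12), (12, 12),
        }

    def test_always_eight_probes(self):
        lt = build_location_threshold([], 64, 64)
        rng = np.random.default_rng(1)
        for w, h in [(5, 5), (6, 9), (11, 4), (7, 7)]:
            pt = propose_point(lt, w, h, rng)
            assert len(pt.probe_points) == 8
            assert len(pt.all_points()) == 9

    def test_probes_in_bounds_for_odd_sizes(self):
        lt = build_location_threshold([], 20, 20)
        rng = np.random.default_rng(2)
        for _ in range(2000):
            pt = propose_point(lt, 9, 7, rng)
            for x, y in pt.all_points():
                assert 0 <= x < 20 and 0 <= y < 20

    def test_oversized_instance_rejected(self):
        lt = build_location_threshold([], 20, 20)
        with pytest.raises(NoValidLocationError):
            propose_point(lt, 25, 5, np.random.default_rng(0))


class TestNinePointCheck:
    def test_all_free_grid(self):
        lt = build_location_threshold([], 50, 50)
        rng = np.random.default_rng(0)
        assert all(is_location_free(lt, propose_point(lt, 8, 8, rng)) for _ in range(100))

    def test_fully_occupied_grid(self):
        lt = build_location_threshold([], 50, 50)
        lt.grid[:] = True
        rng = np.random.default_rng(0)
        assert not any(is_location_free(lt, propose_point(lt, 8, 8, rng)) for _ in range(100))

    def test_equals_direct_nine_pixel_oracle_on_random_grids(self):
        rng = np.random.default_rng(3)
        lt = build_location_threshold([], 64, 64)
        for _ in range(10_000):
            lt.grid[:] = rng.random((64, 64)) < 0.3
            pt = propose_point(lt, 10, 12, rng)
            # brute-force: look up each of the nine pixels independently
            (x, y) = pt.p0
            pixels = [lt.grid[y, x]] + [lt.grid[py, px] for px, py in pt.probe_points]
            assert is_location_free(lt, pt) == (not any(pixels))


class TestPasteInstance:
    def _setup(self):
        image = np.zeros((40, 40, 3), np.uint8)
        lt = build_location_threshold([], 40, 40)
        inst = make_square_instance(crop_value=200)
        pt = PlacementPoint(p0=(20, 20), probe_points=(
            (18, 18), (20, 18), (22, 18), (18, 20), (22, 20), (18, 22), (20, 22), (22, 22),
        ))
        return image, lt, inst, pt

    def test_paste_onto_empty_image(self):
        image, lt, inst, pt = self._setup()
        gt = []
        paste_instance(image, gt, lt, inst, pt)
        assert len(gt) == 1
        assert lt.occupied_count == inst.area

    def test_pixels_outside_mask_untouched(self):
        image, lt, inst, pt = self._setup()
        before = image.copy()
        paste_instance(image, [], lt, inst, pt)
        pasted_region = np.zeros((40, 40), bool)
        x, y, w, h = [20 - 2, 20 - 2, 5, 5]
        pasted_region[y:y + h, x:x + w] = inst.mask
        assert np.array_equal(image[~pasted_region], before[~pasted_region])
        assert (image[pasted_region] == 200).all()

    def test_occupied_location_is_a_contract_error(self):
        image, lt, inst, pt = self._setup()
        lt.grid[20, 20] = True
        with pytest.raises(RuntimeError):
            paste_instance(image, [], lt, inst, pt)

    def test_roundtrip_through_mask_triplet(self, three_class_map):
        image, lt, inst, pt = self._setup()
        gt = []
        paste_instance(image, gt, lt, inst, pt)
        triplet = render_three_channel_mask(gt, three_class_map, 40, 40)
        [back] = parse_three_channel_mask(triplet, three_class_map)
        assert back.bbox == gt[0].bbox
        assert np.array_equal(back.mask, gt[0].mask)


class TestAugmentImage:
    def _scene(self, seed=0):
        spec = SceneSpec(nuclei_count=(10, 14))
        image, _, instances = generate_scene(spec, np.random.default_rng(seed))
        pool = build_instance_pool([ImageRecord(1, image, instances)])
        return spec, image, instances, pool

    def test_n_zero_is_identity(self):
        spec, image, instances, pool = self._scene()
        cfg = AugmentConfig(n_missing_classes=0, seed=0)
        out, gt, log = augment_image(image, instances, pool, cfg, spec.class_map(),
                                     np.random.default_rng(0))
        assert np.array_equal(out, image) and len(gt) == len(instances) and log == []

    def test_no_missing_classes_no_pastes(self, three_class_map):
        instances = [make_square_instance(instance_id=i + 1, label=l, category_id=i + 1,
                                          x=10 * i + 2, y=2)
                     for i, l in enumerate(three_class_map.labels)]
        image = np.zeros((40, 40, 3), np.uint8)
        pool = build_instance_pool([ImageRecord(1, image, instances)])
        cfg = AugmentConfig(n_missing_classes=3, seed=1)
        _, gt, log = augment_image(image, instances, pool, cfg, three_class_map,
                                   np.random.default_rng(1))
        assert len(gt) == len(instances) and log == []

    def test_fully_occupied_grid_rejects_everything(self, three_class_map):
        big = make_square_instance(instance_id=1, label="tumor", x=0, y=0, side=40)
        image = np.zeros((40, 40, 3), np.uint8)
        pool = {"lymphocyte": [make_square_instance(instance_id=9, label="lymphocyte",
                                                    category_id=2)]}
        cfg = AugmentConfig(n_missing_classes=2, k_samples_per_class=3, seed=2)
        _, gt, log = augment_image(image, [big], pool, cfg, three_class_map,
                                   np.random.default_rng(2))
        assert len(gt) == 1
        assert all(r.outcome in ("rejected_occupied", "skipped_empty_pool") for r in log)

    def test_lt_equals_union_of_gt_after_every_paste(self):
        spec, image, instances, pool = self._scene(seed=3)
        # drop one class from the image so pasting happens
        keep = [i for i in instances if i.class_label != "tumor"]
        cfg = AugmentConfig(n_missing_classes=1, k_samples_per_class=6, seed=3)
        out, gt, log = augment_image(image, keep, pool, cfg, spec.class_map(),
                                     np.random.default_rng(3))
        assert any(r.outcome == "pasted" for r in log)
        union = np.zeros((spec.height, spec.width), bool)
        for inst in gt:
            overlap = union & inst.full_mask(spec.height, spec.width)
            union |= inst.full_mask(spec.height, spec.width)
        lt = build_location_threshold(gt, spec.height, spec.width)
        assert np.array_equal(lt.grid, union)

    def test_deterministic_under_fixed_seed(self):
        spec, image, instances, pool = self._scene(seed=4)
        keep = [i for i in instances if i.class_label == "tumor"]
        cfg = AugmentConfig(n_missing_classes=2, k_samples_per_class=5, seed=4)
        results = []
        for _ in range(2):
            out, gt, log = augment_image(image, keep, pool, cfg, spec.class_map(),
                                         np.random.default_rng(99))
            results.append((out.tobytes(), [(g.instance_id, g.bbox) for g in gt],
                            [(r.class_label, r.outcome, r.position) for r in log]))
        assert results[0] == results[1]

    def test_present_classes_never_disappear(self):
        spec, image, instances, pool = self._scene(seed=5)
        before = set(class_counts(instances))
        cfg = AugmentConfig(n_missing_classes=3, k_samples_per_class=3, seed=5)
        _, gt, _ = augment_image(image, instances, pool, cfg, spec.class_map(),
                                 np.random.default_rng(5))
        assert before <= set(class_counts(gt))


class TestAugmentDataset:
    def test_counts_conserved_when_nothing_missing(self, three_class_map):
        image = np.zeros((60, 60, 3), np.uint8)
        instances = [make_square_instance(instance_id=i + 1, label=l, category_id=i + 1,
                                          x=12 * i + 2, y=2)
                     for i, l in enumerate(three_class_map.labels)]
        records = [ImageRecord(1, image, instances)]
        out, summary = augment_dataset(records, AugmentConfig(seed=0), three_class_map)
        assert (summary.table["before"] == summary.table["after"]).all()

    def test_imbalance_strictly_decreases_on_severe_dataset(self, imbalanced_dataset):
        spec, records, _, _ = imbalanced_dataset
        cfg = AugmentConfig(n_missing_classes=3, k_samples_per_class=5, seed=17)
        _, summary = augment_dataset(records, cfg, spec.class_map())
        assert summary.n_pasted > 0
        assert summary.imbalance_after < summary.imbalance_before

    def test_before_counts_match_per_image_tallies(self, imbalanced_dataset):
        spec, records, _, _ = imbalanced_dataset
        cfg = AugmentConfig(seed=0)
        _, summary = augment_dataset(records, cfg, spec.class_map())
        manual = {}
        for record in records:
            for label, count in class_counts(record.instances).items():
                manual[label] = manual.get(label, 0) + count
        for label in spec.class_labels:
            assert summary.table.loc[label, "before"] == manual.get(label, 0)

    def test_strict_mode_yields_zero_mask_intersection(self, imbalanced_dataset):
        spec, records, _, _ = imbalanced_dataset
        cfg = AugmentConfig(n_missing_classes=3, k_samples_per_class=5, seed=23,
                            strict_occupancy=True)
        out, summary = augment_dataset(records, cfg, spec.class_map())
        assert summary.n_pasted > 0
        for record in out:
            acc = np.zeros((spec.height, spec.width), np.int32)
            for inst in record.instances:
                x, y, w, h = inst.bbox
                acc[y:y + h, x:x + w] += inst.mask
            assert (acc <= 1).all()


class TestStrictFootprint:
    def test_detects_overlap_the_nine_points_miss(self):
        # a thin occupied sliver between probe points
        lt = build_location_threshold([], 40, 40)
        lt.grid[20, 18] = True  # inside the would-be footprint, off all probes
        inst = make_square_instance(side=9)
        pt = PlacementPoint(p0=(20, 20), probe_points=tuple(
            (20 + kx, 20 + ky) for ky in (-4, 0, 4) for kx in (-4, 0, 4)
            if (kx, ky) != (0, 0)
        ))
        assert is_location_free(lt, pt)
        assert not is_footprint_free(lt, inst.mask, paste_origin(pt, 9, 9))


class TestRandomFlip:
    def _scene(self):
        spec = SceneSpec(nuclei_count=(8, 10))
        image, _, instances = generate_scene(spec, np.random.default_rng(6))
        return spec, image, instances

    def test_ratio_zero_is_identity(self):
        spec, image, instances = self._scene()
        out, gt = random_flip(image, instances, 0.0, np.random.default_rng(0))
        assert np.array_equal(out, image)
        assert [(g.instance_id, g.bbox) for g in gt] == \
               [(g.instance_id, g.bbox) for g in instances]

    def test_double_forced_flip_is_identity(self):
        spec, image, instances = self._scene()
        once_i, once_g = random_flip(image, instances, 1.0, np.random.default_rng(0),
                                     force=(True, True))
        twice_i, twice_g = random_flip(once_i, once_g, 1.0, np.random.default_rng(0),
                                       force=(True, True))
        assert np.array_equal(twice_i, image)
        for a, b in zip(twice_g, instances):
            assert a.bbox == b.bbox and np.array_equal(a.mask, b.mask)

    def test_flipped_bbox_is_tight_bound_of_flipped_mask(self):
        spec, image, instances = self._scene()
        out, gt = random_flip(image, instances, 1.0, np.random.default_rng(0),
                              force=(True, False))
        full_original = np.zeros((spec.height, spec.width), bool)
        for inst in instances:
            full_original |= inst.full_mask(spec.height, spec.width)
        for inst in gt:
            full = inst.full_mask(spec.height, spec.width)
            ys, xs = np.nonzero(full)
            x, y, w, h = inst.bbox
            assert (xs.min(), ys.min(), xs.max() - xs.min() + 1, ys.max() - ys.min() + 1) \
                   == (x, y, w, h)
            # the recomputed footprint is the mirrored original
            assert np.array_equal(full, full_original[:, ::-1] &
                                  inst.full_mask(spec.height, spec.width))

    def test_invalid_ratio_rejected(self):
        spec, image, instances = self._scene()
        with pytest.raises(ValueError):
            random_flip(image, instances, 1.5, np.random.default_rng(0))


def test_imbalance_ratio_edge_cases():
    assert imbalance_ratio({"a": 50, "b": 1}) == 50.0
    # zero-count classes are outside the reach of copy-paste and excluded
    assert imbalance_ratio({"a": 50, "b": 0, "c": 5}) == 10.0
    assert np.isnan(imbalance_ratio({"a": 3}))
    assert np.isnan(imbalance_ratio({}))
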