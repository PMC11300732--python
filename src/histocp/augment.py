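"""Occupancy-aware copy-paste augmentation for dense nuclei scenes.

Plain copy-paste pastes instances at random positions; in tissue images,
where nuclei are packed densely, that overlaps and occludes existing nuclei.
The engine here avoids overlap with a binary occupancy map (the *location
threshold*, LT) and targets class imbalance by pasting only instances of
classes *missing* from each image:

1. build the LT of an image (union of all instance footprints) and list its
   missing classes;
2. draw ``n`` of the missing classes at random;
3. for each drawn class, draw ``k`` candidate instances from the whole
   training pool (*ChIns*, the chosen instances);
4. for each candidate, draw a centre point whose margins keep the instance
   inside the image, and probe the LT at that point and the eight
   surrounding points offset by half the instance width/height — all nine
   must be free;
5. if free, composite the instance crop under its binary mask, append it to
   the ground truth and mark the LT; otherwise the candidate is simply not
   pasted.

The nine-point probe assumes instances of similar sizes; ``strict_occupancy``
swaps it for a full-footprint check, which guarantees zero overlap for any
size mix. A basic random horizontal/vertical flip augmentation is included
as well.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from math import ceil, floor
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import NoValidLocationError
from .formats import ClassMap, ImageRecord, NucleiInstance, class_counts

__all__ = [
    "LocationThreshold",
    "AugmentConfig",
    "ChosenInstances",
    "PlacementPoint",
    "PasteRecord",
    "AugmentSummary",
    "build_location_threshold",
    "missing_classes",
    "build_instance_pool",
    "choose_instances",
    "propose_point",
    "is_location_free",
    "is_footprint_free",
    "paste_origin",
    "paste_instance",
    "augment_image",
    "augment_dataset",
    "random_flip",
    "imbalance_ratio",
]

logger = logging.getLogger(__name__)


@dataclass
class LocationThreshold:
    """Binary occupancy grid: True/white = occupied by an instance."""

    grid: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValueError("occupancy grid must be 2-D")

    @property
    def height(self) -> int:
        return self.grid.shape[0]

    @property
    def width(self) -> int:
        return self.grid.shape[1]

    @property
    def occupied_count(self) -> int:
        return int(self.grid.sum())


@dataclass(frozen=True)
class AugmentConfig:
    """Knobs of one augmentation pass.

    ``n_missing_classes`` (n) missing classes are drawn per image and
    ``k_samples_per_class`` (k) candidate instances per drawn class.
    ``placement_attempts`` draws per candidate before giving up (1 = each
    candidate gets a single chance, the default behaviour).
    ``strict_occupancy`` replaces the nine-point probe with a full-footprint
    occupancy check.
    """

    n_missing_classes: int = 3
    k_samples_per_class: int = 5
    seed: int = 0
    placement_attempts: int = 1
    strict_occupancy: bool = False

    def __post_init__(self):
        if self.n_missing_classes < 0:
            raise ValueError("n_missing_classes must be >= 0")
        if self.k_samples_per_class < 1:
            raise ValueError("k_samples_per_class must be >= 1")
        if self.placement_attempts < 1:
            raise ValueError("placement_attempts must be >= 1")


@dataclass
class ChosenInstances:
    """The sampled candidates (ChIns) for one image, in draw order."""

    items: list[NucleiInstance]
    classes: list[str]
    skipped_classes: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class PlacementPoint:
    """Candidate paste centre ``p0`` with its eight surrounding probes."""

    p0: tuple[int, int]
    probe_points: tuple[tuple[int, int], ...]

    def all_points(self) -> tuple[tuple[int, int], ...]:
        return (self.p0,) + self.probe_points


@dataclass(frozen=True)
class PasteRecord:
    """Per-candidate outcome within one augmented image."""

    class_label: str
    source_image_id: object
    source_instance_id: int | None
    outcome: str  # "pasted" | "rejected_occupied" | "skipped_empty_pool"
    position: tuple[int, int] | None = None
    attempts: int = 0


def build_location_threshold(
    instances: Sequence[NucleiInstance], height: int, width: int
) -> LocationThreshold:
    """Occupancy grid = union of all instance footprints."""
    grid = np.zeros((height, width), dtype=bool)
    for inst in instances:
        x, y, w, h = inst.bbox
        grid[y:y + h, x:x + w] |= inst.mask
    return LocationThreshold(grid)


def missing_classes(instances: Sequence[NucleiInstance], all_classes: Sequence[str]) -> set[str]:
    """Classes of the universe absent from this image."""
    present = {inst.class_label for inst in instances}
    unknown = present - set(all_classes)
    if unknown:
        raise ValueError(f"instances carry classes outside the universe: {sorted(unknown)}")
    return set(all_classes) - present


def build_instance_pool(records: Sequence[ImageRecord]) -> dict[str, list[NucleiInstance]]:
    """Index every training instance by class, for cross-image sampling.

    Instances must carry crops (taken from the color-normalized images), as
    those pixels are what gets pasted.
    """
    pool: dict[str, list[NucleiInstance]] = {}
    for record in records:
        for inst in record.instances:
            if inst.crop is None:
                raise ValueError(
                    f"instance {inst.instance_id} of image {record.image_id} has no pixel crop"
                )
            pool.setdefault(inst.class_label, []).append(inst)
    return pool


def choose_instances(
    missing: set[str],
    pool: Mapping[str, Sequence[NucleiInstance]],
    cfg: AugmentConfig,
    rng: np.random.Generator,
) -> ChosenInstances:
    """Draw min(n, |missing|) classes, then min(k, pool) instances of each.

    Both draws are uniform without replacement; a drawn class with an empty
    pool is skipped with a warning (recorded, not an error). Deterministic
    for a fixed generator state: the missing set is sorted before sampling.
    """
    universe = sorted(missing)
    n = min(cfg.n_missing_classes, len(universe))
    chosen_classes = list(rng.choice(universe, size=n, replace=False)) if n else []
    items: list[NucleiInstance] = []
    classes: list[str] = []
    skipped: list[str] = []
    for label in chosen_classes:
        candidates = list(pool.get(label, []))
        if not candidates:
            logger.warning("class %r has no pool instances; skipped", label)
            skipped.append(label)
            continue
        k = min(cfg.k_samples_per_class, len(candidates))
        idx = rng.choice(len(candidates), size=k, replace=False)
        for i in idx:
            items.append(candidates[int(i)])
            classes.append(label)
    return ChosenInstances(items=items, classes=classes, skipped_classes=skipped)


def _margins(w_ins: int, h_ins: int) -> tuple[int, int]:
    # exclusion margins round up so the floor-offset probes stay in bounds
    # for odd instance sizes
    return ceil(w_ins / 2), ceil(h_ins / 2)


def propose_point(
    lt: LocationThreshold, w_ins: int, h_ins: int, rng: np.random.Generator
) -> PlacementPoint:
    """Draw a candidate centre with margins that keep the paste in bounds.

    ``x`` is uniform on the open interval (w_ins/2, w_LT - w_ins/2) and
    likewise ``y``; the eight probes sit at offsets ``{-w_ins//2, 0,
    w_ins//2} x {-h_ins//2, 0, h_ins//2}`` minus the centre itself.
    """
    mx, my = _margins(w_ins, h_ins)
    x_low, x_high = mx + 1, lt.width - mx   # inclusive, exclusive
    y_low, y_high = my + 1, lt.height - my
    if x_low >= x_high or y_low >= y_high:
        raise NoValidLocationError(
            f"instance {w_ins}x{h_ins} leaves no valid centre in a {lt.width}x{lt.height} grid"
        )
    x = int(rng.integers(x_low, x_high))
    y = int(rng.integers(y_low, y_high))
    ox, oy = floor(w_ins / 2), floor(h_ins / 2)
    # always eight probes, even when offsets coincide for 1-pixel instances
    probes = tuple(
        (x + kx, y + ky)
        for ky in (-oy, 0, oy)
        for kx in (-ox, 0, ox)
        if not (kx == 0 and ky == 0)
    )
    return PlacementPoint(p0=(x, y), probe_points=probes)


def is_location_free(lt: LocationThreshold, pt: PlacementPoint) -> bool:
    """True iff the centre and all eight probes hit free (black) pixels."""
    for x, y in pt.all_points():
        if lt.grid[y, x]:
            return False
    return True


def paste_origin(pt: PlacementPoint, w_ins: int, h_ins: int) -> tuple[int, int]:
    """Top-left corner of the pasted bbox for centre ``p0``."""
    x, y = pt.p0
    return x - floor(w_ins / 2), y - floor(h_ins / 2)


def is_footprint_free(lt: LocationThreshold, mask: np.ndarray, origin: tuple[int, int]) -> bool:
    """Strict check: no occupied pixel anywhere under the instance footprint."""
    x0, y0 = origin
    h, w = mask.shape
    window = lt.grid[y0:y0 + h, x0:x0 + w]
    return not (window & mask).any()


def paste_instance(
    image: np.ndarray,
    gt_instances: list[NucleiInstance],
    lt: LocationThreshold,
    instance: NucleiInstance,
    pt: PlacementPoint,
    new_id: int | None = None,
) -> tuple[np.ndarray, list[NucleiInstance], NucleiInstance]:
    """Composite one instance at ``pt`` and update ground truth and LT.

    The caller must have verified the location is free; this is enforced.
    Pixels outside the instance footprint are untouched. ``image``, ``lt``
    and ``gt_instances`` are updated in place; the new ground-truth entry is
    returned for convenience.
    """
    if not is_location_free(lt, pt):
        raise RuntimeError("paste_instance called on an occupied location (caller bug)")
    if instance.crop is None:
        raise ValueError("instance has no pixel crop to paste")
    _, _, w, h = instance.bbox
    x0, y0 = paste_origin(pt, w, h)
    if new_id is None:
        new_id = max((g.instance_id for g in gt_instances), default=0) + 1
    window = image[y0:y0 + h, x0:x0 + w]
    window[instance.mask] = instance.crop[instance.mask]
    lt.grid[y0:y0 + h, x0:x0 + w] |= instance.mask
    pasted = instance.translated((x0, y0), new_id=new_id)
    gt_instances.append(pasted)
    return image, gt_instances, pasted


def augment_image(
    image: np.ndarray,
    gt_instances: Sequence[NucleiInstance],
    pool: Mapping[str, Sequence[NucleiInstance]],
    cfg: AugmentConfig,
    class_map: ClassMap,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[NucleiInstance], list[PasteRecord]]:
    """Run one full copy-paste pass over a single image.

    Returns a new image, the extended ground truth and a per-candidate log.
    New instance ids continue from the largest existing id, so a re-rendered
    3-channel mask stays valid.
    """
    image = np.array(image, copy=True)
    gt = list(gt_instances)
    height, width = image.shape[:2]
    lt = build_location_threshold(gt, height, width)
    missing = missing_classes(gt, class_map.labels)
    chins = choose_instances(missing, pool, cfg, rng)
    log: list[PasteRecord] = [
        PasteRecord(class_label=label, source_image_id=None, source_instance_id=None,
                    outcome="skipped_empty_pool")
        for label in chins.skipped_classes
    ]
    next_id = max((g.instance_id for g in gt), default=0) + 1
    for inst, label in zip(chins.items, chins.classes):
        _, _, w, h = inst.bbox
        pasted = False
        attempts = 0
        for _ in range(cfg.placement_attempts):
            attempts += 1
            try:
                pt = propose_point(lt, w, h, rng)
            except NoValidLocationError:
                break
            if cfg.strict_occupancy:
                free = is_location_free(lt, pt) and is_footprint_free(
                    lt, inst.mask, paste_origin(pt, w, h)
                )
            else:
                free = is_location_free(lt, pt)
            if free:
                paste_instance(image, gt, lt, inst, pt, new_id=next_id)
                next_id += 1
                log.append(PasteRecord(
                    class_label=label,
                    source_image_id=inst.source_image_id,
                    source_instance_id=inst.instance_id,
                    outcome="pasted",
                    position=pt.p0,
                    attempts=attempts,
                ))
                pasted = True
                break
        if not pasted:
            log.append(PasteRecord(
                class_label=label,
                source_image_id=inst.source_image_id,
                source_instance_id=inst.instance_id,
                outcome="rejected_occupied",
                attempts=attempts,
            ))
    return image, gt, log


def imbalance_ratio(counts: Mapping[str, int]) -> float:
    """Most-frequent over least-frequent class count.

    Computed over classes with at least one instance: a class absent from
    the whole pool cannot be rebalanced by copy-paste (there is nothing to
    copy), so including it would pin the ratio at infinity regardless of
    what the augmentation achieves. NaN when fewer than two classes have
    instances.
    """
    values = [c for c in counts.values() if c > 0]
    if len(values) < 2:
        return float("nan")
    return max(values) / min(values)


@dataclass
class AugmentSummary:
    """Before/after census of one dataset-level augmentation pass."""

    table: pd.DataFrame
    imbalance_before: float
    imbalance_after: float
    n_pasted: int


def _image_rng(seed: int, image_id: object) -> np.random.Generator:
    # per-image streams keyed by (seed, id) so processing order or
    # parallelism cannot change results
    return np.random.default_rng([seed, zlib.crc32(str(image_id).encode())])


def augment_dataset(
    records: Sequence[ImageRecord],
    cfg: AugmentConfig,
    class_map: ClassMap,
    pool: Mapping[str, Sequence[NucleiInstance]] | None = None,
) -> tuple[list[ImageRecord], AugmentSummary]:
    """Augment every image independently and tally the class census.

    Each image gets its own random stream derived from ``(cfg.seed, image
    id)``. The summary table lists per-class counts before and after, and
    the imbalance ratio (max/min count) for both states.
    """
    if not records:
        raise ValueError("dataset is empty")
    if pool is None:
        pool = build_instance_pool(records)
    before = {label: 0 for label in class_map.labels}
    for record in records:
        for label, count in class_counts(record.instances).items():
            before[label] = before.get(label, 0) + count
    out: list[ImageRecord] = []
    n_pasted = 0
    for record in records:
        rng = _image_rng(cfg.seed, record.image_id)
        image, gt, log = augment_image(
            record.image, record.instances, pool, cfg, class_map, rng
        )
        n_pasted += sum(1 for r in log if r.outcome == "pasted")
        out.append(ImageRecord(image_id=record.image_id, image=image, instances=gt))
    after = {label: 0 for label in class_map.labels}
    for record in out:
        for label, count in class_counts(record.instances).items():
            after[label] = after.get(label, 0) + count
    table = pd.DataFrame(
        {"before": pd.Series(before), "after": pd.Series(after)},
    ).loc[list(class_map.labels)]
    summary = AugmentSummary(
        table=table,
        imbalance_before=imbalance_ratio(before),
        imbalance_after=imbalance_ratio(after),
        n_pasted=n_pasted,
    )
    return out, summary


def random_flip(
    image: np.ndarray,
    gt_instances: Sequence[NucleiInstance],
    ratio: float,
    rng: np.random.Generator,
    force: tuple[bool, bool] | None = None,
) -> tuple[np.ndarray, list[NucleiInstance]]:
    """Random horizontal and vertical flips, each applied with ``ratio``.

    Masks, crops and bboxes are transformed consistently. ``force`` pins the
    (horizontal, vertical) decisions, bypassing the draws (used to test the
    involution property).
    """
    if not 0.0 <= ratio <= 1.0:
        raise ValueError("ratio must lie in [0, 1]")
    if force is None:
        do_h = bool(rng.random() < ratio)
        do_v = bool(rng.random() < ratio)
    else:
        do_h, do_v = force
    height, width = image.shape[:2]
    out_image = image
    instances = list(gt_instances)
    if do_h:
        out_image = out_image[:, ::-1].copy()
        instances = [_flip_instance(i, width, axis="h") for i in instances]
    if do_v:
        out_image = out_image[::-1].copy()
        instances = [_flip_instance(i, height, axis="v") for i in instances]
    if out_image is image:
        out_image = image.copy()
    return out_image, instances


def _flip_instance(inst: NucleiInstance, extent: int, axis: str) -> NucleiInstance:
    x, y, w, h = inst.bbox
    if axis == "h":
        bbox = (extent - x - w, y, w, h)
        mask = inst.mask[:, ::-1].copy()
        crop = None if inst.crop is None else inst.crop[:, ::-1].copy()
    else:
        bbox = (x, extent - y - h, w, h)
        mask = inst.mask[::-1].copy()
        crop = None if inst.crop is None else inst.crop[::-1].copy()
    return NucleiInstance(
        instance_id=inst.instance_id,
        class_label=inst.class_label,
        category_id=inst.category_id,
        mask=mask,
        bbox=bbox,
        crop=crop,
        source_image_id=inst.source_image_id,
    )
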