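"""Synthetic nuclei scenes with known ground truth.

Generates the kind of input the augmentation pipeline consumes, with full
control over the statistics that matter to it: per-class instance
frequencies (imbalance), nucleus size range (the similar-size regime the
nine-point occupancy probe assumes), non-overlapping placement, and the
3-channel mask encoding. Nuclei are rendered as rotated ellipses with
per-axis size jitter and per-pixel color noise on an eosin-pink background —
deliberately schematic, since the algorithms under test depend on masks,
classes, sizes and colors, not on tissue texture.

A detector simulator (`perturb_to_detections`) degrades ground truth with
known miss/confusion/jitter rates, so metric implementations can be checked
against the rates that produced the detections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from .formats import (
    ClassMap,
    CocoDocument,
    ImageInfo,
    ImageRecord,
    MaskTriplet,
    NucleiInstance,
    annotations_to_coco,
    render_three_channel_mask,
)
from .metrics import Detection, GroundTruth

__all__ = [
    "SceneSpec",
    "generate_scene",
    "generate_dataset",
    "perturb_to_detections",
    "PerturbationTruth",
    "DEFAULT_CLASS_COLORS",
]

logger = logging.getLogger(__name__)

#: Hematoxylin-like palette: nuclei are blue-purple with per-class tints.
DEFAULT_CLASS_COLORS: tuple[tuple[int, int, int], ...] = (
    (64, 38, 110),
    (88, 48, 128),
    (52, 60, 130),
    (100, 40, 100),
    (70, 70, 140),
    (110, 60, 120),
    (45, 45, 95),
    (95, 75, 135),
    (60, 30, 85),
    (120, 80, 140),
    (80, 55, 105),
    (50, 80, 120),
    (105, 50, 90),
)

_EOSIN_BACKGROUND = (232, 205, 218)  # pale pink stroma
_MAX_REJECTIONS = 1000


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic field of view.

    ``class_probabilities`` is the sampling simplex over ``class_labels``
    (the imbalance control); ``radius_range`` bounds the ellipse semi-axes —
    the default 2:1 max/min spread keeps instances in the similar-size regime
    the nine-point probe is designed for.
    """

    height: int = 128
    width: int = 128
    class_labels: tuple[str, ...] = ("tumor", "lymphocyte", "fibroblast")
    class_probabilities: tuple[float, ...] | None = None
    nuclei_count: tuple[int, int] = (15, 25)
    radius_range: tuple[float, float] = (4.0, 8.0)
    class_colors: tuple[tuple[int, int, int], ...] | None = None
    background_color: tuple[int, int, int] = _EOSIN_BACKGROUND
    background_noise_sigma: float = 6.0
    color_noise_sigma: float = 8.0

    def __post_init__(self):
        probs = self.class_probabilities
        if probs is None:
            probs = tuple(1.0 / len(self.class_labels) for _ in self.class_labels)
            object.__setattr__(self, "class_probabilities", probs)
        if len(probs) != len(self.class_labels):
            raise ValueError("one probability per class is required")
        if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
            raise ValueError("class probabilities must be a simplex vector")
        lo, hi = self.radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("radius range must be positive and ordered")
        if self.nuclei_count[0] < 0 or self.nuclei_count[1] < self.nuclei_count[0]:
            raise ValueError("nuclei_count range must be ordered and non-negative")

    def class_map(self) -> ClassMap:
        return ClassMap.from_labels(self.class_labels)

    def colors(self) -> tuple[tuple[int, int, int], ...]:
        if self.class_colors is not None:
            return self.class_colors
        reps = -(-len(self.class_labels) // len(DEFAULT_CLASS_COLORS))
        return (DEFAULT_CLASS_COLORS * reps)[: len(self.class_labels)]


def generate_scene(
    spec: SceneSpec, rng: np.random.Generator
) -> tuple[np.ndarray, MaskTriplet, list[NucleiInstance]]:
    """One field of view: RGB image, 3-channel mask and instance list.

    Nuclei are placed by rejection sampling against an occupancy grid, so
    footprints never overlap; if the requested count cannot be placed within
    1000 rejections, the scene is returned with fewer nuclei and a warning.
    """
    class_map = spec.class_map()
    colors = spec.colors()
    image = np.clip(
        np.asarray(spec.background_color, dtype=float)
        + rng.normal(0.0, spec.background_noise_sigma, size=(spec.height, spec.width, 3)),
        0, 255,
    ).astype(np.uint8)
    occupancy = np.zeros((spec.height, spec.width), dtype=bool)
    target = int(rng.integers(spec.nuclei_count[0], spec.nuclei_count[1] + 1))
    instances: list[NucleiInstance] = []
    rejections = 0
    while len(instances) < target and rejections < _MAX_REJECTIONS:
        class_idx = int(rng.choice(len(spec.class_labels), p=spec.class_probabilities))
        a = rng.uniform(*spec.radius_range)
        b = rng.uniform(*spec.radius_range)
        angle = rng.uniform(0.0, np.pi)
        margin = int(np.ceil(max(a, b))) + 1
        if 2 * margin >= min(spec.height, spec.width):
            rejections += 1
            continue
        cy = int(rng.integers(margin, spec.height - margin))
        cx = int(rng.integers(margin, spec.width - margin))
        rr, cc = draw_ellipse(cy, cx, a, b, shape=occupancy.shape, rotation=angle)
        if len(rr) == 0 or occupancy[rr, cc].any():
            rejections += 1
            continue
        occupancy[rr, cc] = True
        footprint = np.zeros_like(occupancy)
        footprint[rr, cc] = True
        label = spec.class_labels[class_idx]
        color = np.asarray(colors[class_idx], dtype=float)
        noise = rng.normal(0.0, spec.color_noise_sigma, size=(len(rr), 3))
        image[rr, cc] = np.clip(color[None, :] + noise, 0, 255).astype(np.uint8)
        ys, xs = rr.min(), cc.min()
        ye, xe = rr.max() + 1, cc.max() + 1
        instances.append(
            NucleiInstance(
                instance_id=len(instances) + 1,
                class_label=label,
                category_id=class_map.category_id_for_label(label),
                mask=footprint[ys:ye, xs:xe],
                bbox=(int(xs), int(ys), int(xe - xs), int(ye - ys)),
                crop=image[ys:ye, xs:xe].copy(),
                source_image_id=None,
            )
        )
    if len(instances) < target:
        logger.warning(
            "placed %d of %d requested nuclei before exhausting rejections",
            len(instances), target,
        )
    triplet = render_three_channel_mask(instances, class_map, spec.height, spec.width)
    return image, triplet, instances


def generate_dataset(
    spec: SceneSpec, n_images: int, seed: int
) -> tuple[list[ImageRecord], list[MaskTriplet], CocoDocument]:
    """A dataset of scenes with per-image seeds derived from (seed, index)."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    records: list[ImageRecord] = []
    triplets: list[MaskTriplet] = []
    infos: list[ImageInfo] = []
    by_image: dict[object, list[NucleiInstance]] = {}
    for index in range(n_images):
        rng = np.random.default_rng([seed, index])
        image, triplet, instances = generate_scene(spec, rng)
        image_id = index + 1
        for inst in instances:
            inst.source_image_id = image_id
        records.append(ImageRecord(image_id=image_id, image=image, instances=instances))
        triplets.append(triplet)
        infos.append(ImageInfo(id=image_id, file_name=f"scene_{image_id:04d}.png",
                               height=spec.height, width=spec.width))
        by_image[image_id] = instances
    doc = annotations_to_coco(by_image, spec.class_map(), infos)
    return records, triplets, doc


@dataclass
class PerturbationTruth:
    """What the detector simulator actually did, for metric cross-checks."""

    n_gt: int
    n_detected: int
    n_missed: int
    n_class_swapped: int
    confusion: dict[tuple[str, str], int] = field(default_factory=dict)


def perturb_to_detections(
    records: Sequence[ImageRecord],
    class_map: ClassMap,
    rng: np.random.Generator,
    miss_rate: float = 0.0,
    class_confusion_rate: float = 0.0,
    bbox_jitter: float = 0.0,
    score_range: tuple[float, float] = (0.5, 1.0),
) -> tuple[list[Detection], list[GroundTruth], PerturbationTruth]:
    """Degrade ground truth into simulated detector output.

    Each ground-truth nucleus is dropped with probability ``miss_rate``;
    surviving detections have their class replaced by a uniformly different
    one with probability ``class_confusion_rate`` and their box translated by
    up to ``bbox_jitter`` of its width/height (keep it below ~0.2 so jittered
    boxes still clear IoU 0.5). Scores are uniform on ``score_range``. The
    returned tally is the exact truth behind the simulated output.
    """
    for name, rate in (("miss_rate", miss_rate), ("class_confusion_rate", class_confusion_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    labels = class_map.labels
    detections: list[Detection] = []
    gts: list[GroundTruth] = []
    truth = PerturbationTruth(n_gt=0, n_detected=0, n_missed=0, n_class_swapped=0)
    for record in records:
        for inst in record.instances:
            x, y, w, h = inst.bbox
            gts.append(GroundTruth(image_id=record.image_id,
                                   category_id=inst.category_id,
                                   bbox=(float(x), float(y), float(w), float(h))))
            truth.n_gt += 1
            if rng.random() < miss_rate:
                truth.n_missed += 1
                continue
            truth.n_detected += 1
            pred_label = inst.class_label
            if class_confusion_rate > 0 and rng.random() < class_confusion_rate and len(labels) > 1:
                others = [l for l in labels if l != inst.class_label]
                pred_label = others[int(rng.integers(len(others)))]
                truth.n_class_swapped += 1
            key = (inst.class_label, pred_label)
            truth.confusion[key] = truth.confusion.get(key, 0) + 1
            dx = rng.uniform(-bbox_jitter, bbox_jitter) * w if bbox_jitter else 0.0
            dy = rng.uniform(-bbox_jitter, bbox_jitter) * h if bbox_jitter else 0.0
            detections.append(Detection(
                image_id=record.image_id,
                category_id=class_map.category_id_for_label(pred_label),
                bbox=(float(x + dx), float(y + dy), float(w), float(h)),
                score=float(rng.uniform(*score_range)),
            ))
    return detections, gts, truth
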