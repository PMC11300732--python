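"""Annotation formats for nuclei instance segmentation.

Two dialects are supported and converted between:

* the 3-channel mask: a lossless RGB image whose red channel is a class
  intensity map (every nucleus of one class shares one pixel value), whose
  blue channel is an instance identity map (every nucleus has its own pixel
  value, 0 = background), and whose green channel carries no defined
  semantics and is preserved verbatim;
* COCO JSON: the ``images`` / ``annotations`` / ``categories`` document used
  by most object-detection tooling, with polygon segmentations.

Polygon segmentations are traced along pixel boundaries (vertices at integer
pixel-corner coordinates), so the mask -> polygon -> mask roundtrip is exact
for hole-free instances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from matplotlib.path import Path as MplPath
from scipy import ndimage

from .errors import (
    InconsistentMaskError,
    InstanceOverlapError,
    InvalidAnnotationError,
    MappingIncompleteError,
    ReferentialIntegrityError,
    UnknownClassIntensityError,
)

__all__ = [
    "ClassMap",
    "NucleiInstance",
    "MaskTriplet",
    "ImageInfo",
    "ImageRecord",
    "CocoDocument",
    "parse_three_channel_mask",
    "render_three_channel_mask",
    "annotations_to_coco",
    "coco_to_annotations",
    "group_classes",
    "grouped_class_map",
    "mask_to_polygons",
    "polygons_to_mask",
    "class_counts",
]


# ---------------------------------------------------------------------------
# class map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassMap:
    """Ordered association label <-> red-channel intensity <-> COCO category id.

    ``entries`` is a tuple of ``(label, intensity, category_id)``. Intensities,
    labels and category ids must each be unique; category ids must be
    contiguous from 1 (the COCO convention).
    """

    entries: tuple[tuple[str, int, int], ...]

    def __post_init__(self):
        labels = [e[0] for e in self.entries]
        intensities = [e[1] for e in self.entries]
        cids = [e[2] for e in self.entries]
        if len(set(labels)) != len(labels):
            raise ValueError("class labels must be unique")
        if len(set(intensities)) != len(intensities):
            raise ValueError("class intensities must be unique")
        if sorted(cids) != list(range(1, len(cids) + 1)):
            raise ValueError("category ids must be unique and contiguous from 1")

    @classmethod
    def from_labels(cls, labels: Sequence[str], intensities: Sequence[int] | None = None) -> "ClassMap":
        """Build a map assigning category ids 1..n in label order.

        When ``intensities`` is omitted, intensity ``i`` is used for the
        ``i``-th label (1-based), which is the common encoding for synthetic
        masks.
        """
        if intensities is None:
            intensities = range(1, len(labels) + 1)
        return cls(tuple((str(l), int(v), i + 1) for i, (l, v) in enumerate(zip(labels, intensities))))

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(e[0] for e in self.entries)

    def label_for_intensity(self, intensity: int) -> str:
        for label, inten, _ in self.entries:
            if inten == intensity:
                return label
        raise UnknownClassIntensityError(intensity)

    def intensity_for_label(self, label: str) -> int:
        for lab, inten, _ in self.entries:
            if lab == label:
                return inten
        raise KeyError(label)

    def category_id_for_label(self, label: str) -> int:
        for lab, _, cid in self.entries:
            if lab == label:
                return cid
        raise KeyError(label)

    def label_for_category_id(self, category_id: int) -> str:
        for lab, _, cid in self.entries:
            if cid == category_id:
                return lab
        raise KeyError(category_id)

    def coco_categories(self) -> list[dict]:
        return [{"id": cid, "name": lab} for lab, _, cid in sorted(self.entries, key=lambda e: e[2])]


# ---------------------------------------------------------------------------
# instances and mask triplets
# ---------------------------------------------------------------------------


@dataclass
class NucleiInstance:
    """One annotated nucleus.

    ``mask`` is the binary footprint cropped to ``bbox``; ``bbox`` is
    ``(x, y, w, h)`` in 0-based pixel coordinates (x = column, y = row) and is
    the tight axis-aligned bound of the footprint, which positions the local
    mask inside its image. ``crop`` is the RGB patch of the source image cut
    to the same bbox (pixels outside the footprint are carried along but are
    never composited).
    """

    instance_id: int
    class_label: str
    category_id: int
    mask: np.ndarray
    bbox: tuple[int, int, int, int]
    crop: np.ndarray | None = None
    source_image_id: object | None = None

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2 or not self.mask.any():
            raise InvalidAnnotationError(
                f"instance {self.instance_id}: mask must be a nonempty 2-D binary grid"
            )
        x, y, w, h = (int(v) for v in self.bbox)
        self.bbox = (x, y, w, h)
        if self.mask.shape != (h, w):
            raise InvalidAnnotationError(
                f"instance {self.instance_id}: mask shape {self.mask.shape} != bbox (h,w) {(h, w)}"
            )
        # tightness: the footprint must touch all four bbox edges
        if not (self.mask[0].any() and self.mask[-1].any()
                and self.mask[:, 0].any() and self.mask[:, -1].any()):
            raise InvalidAnnotationError(
                f"instance {self.instance_id}: bbox is not the tight bound of the mask"
            )
        if self.crop is not None:
            self.crop = np.asarray(self.crop)
            if self.crop.shape[:2] != (h, w):
                raise InvalidAnnotationError(
                    f"instance {self.instance_id}: crop shape {self.crop.shape[:2]} != bbox (h,w)"
                )

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    def full_mask(self, height: int, width: int) -> np.ndarray:
        """Footprint placed on an all-false (height, width) grid."""
        x, y, w, h = self.bbox
        out = np.zeros((height, width), dtype=bool)
        out[y:y + h, x:x + w] = self.mask
        return out

    def translated(self, new_bbox_xy: tuple[int, int], new_id: int | None = None) -> "NucleiInstance":
        x, y = new_bbox_xy
        _, _, w, h = self.bbox
        return replace(
            self,
            instance_id=self.instance_id if new_id is None else new_id,
            bbox=(int(x), int(y), w, h),
            mask=self.mask.copy(),
            crop=None if self.crop is None else self.crop.copy(),
        )


def _tight_instance(instance_id, label, category_id, full_mask, image=None, source_image_id=None):
    ys, xs = np.nonzero(full_mask)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    crop = None if image is None else np.asarray(image)[y0:y1, x0:x1].copy()
    return NucleiInstance(
        instance_id=int(instance_id),
        class_label=label,
        category_id=int(category_id),
        mask=full_mask[y0:y1, x0:x1],
        bbox=(int(x0), int(y0), int(x1 - x0), int(y1 - y0)),
        crop=crop,
        source_image_id=source_image_id,
    )


@dataclass
class MaskTriplet:
    """The 3-channel ground-truth mask: red = class map, blue = instance map.

    The green channel has no defined meaning and is carried through
    untouched.
    """

    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray

    def __post_init__(self):
        self.red = np.asarray(self.red)
        self.green = np.asarray(self.green)
        self.blue = np.asarray(self.blue)
        if not (self.red.shape == self.green.shape == self.blue.shape) or self.red.ndim != 2:
            raise ValueError("red/green/blue must be 2-D grids of one shape")

    @property
    def height(self) -> int:
        return self.red.shape[0]

    @property
    def width(self) -> int:
        return self.red.shape[1]

    def to_image(self) -> np.ndarray:
        """Stack to an (H, W, 3) uint8 RGB image for lossless PNG output."""
        return np.stack([self.red, self.green, self.blue], axis=-1).astype(np.uint8)

    @classmethod
    def from_image(cls, rgb: np.ndarray) -> "MaskTriplet":
        rgb = np.asarray(rgb)
        if rgb.ndim != 3 or rgb.shape[2] < 3:
            raise ValueError("expected an (H, W, 3) image")
        return cls(rgb[..., 0].astype(np.int64), rgb[..., 1].astype(np.int64), rgb[..., 2].astype(np.int64))


@dataclass(frozen=True)
class ImageInfo:
    """COCO image record."""

    id: object
    file_name: str
    height: int
    width: int


@dataclass
class ImageRecord:
    """In-memory dataset element: pixels plus ground-truth instances."""

    image_id: object
    image: np.ndarray
    instances: list[NucleiInstance] = field(default_factory=list)

    @property
    def height(self) -> int:
        return self.image.shape[0]

    @property
    def width(self) -> int:
        return self.image.shape[1]


# ---------------------------------------------------------------------------
# 3-channel mask <-> instances
# ---------------------------------------------------------------------------


def parse_three_channel_mask(
    mask: MaskTriplet,
    class_map: ClassMap,
    image: np.ndarray | None = None,
    source_image_id: object | None = None,
) -> list[NucleiInstance]:
    """Extract one :class:`NucleiInstance` per distinct nonzero blue value.

    The class of an instance is the single red intensity covering its pixels;
    instances spanning two intensities raise :class:`InconsistentMaskError`
    and unknown intensities raise :class:`UnknownClassIntensityError`.
    Instances are returned ordered by instance id. When ``image`` is given,
    each instance carries its RGB crop.
    """
    blue = mask.blue
    red = mask.red
    instances: list[NucleiInstance] = []
    values = np.unique(blue)
    for value in values[values > 0]:
        footprint = blue == value
        reds = np.unique(red[footprint])
        if len(reds) != 1:
            raise InconsistentMaskError(value, reds)
        intensity = int(reds[0])
        label = class_map.label_for_intensity(intensity)
        instances.append(
            _tight_instance(
                value, label, class_map.category_id_for_label(label),
                footprint, image=image, source_image_id=source_image_id,
            )
        )
    return instances


def render_three_channel_mask(
    instances: Sequence[NucleiInstance],
    class_map: ClassMap,
    height: int,
    width: int,
    green: np.ndarray | None = None,
) -> MaskTriplet:
    """Inverse of :func:`parse_three_channel_mask`.

    Raises :class:`InstanceOverlapError` if two footprints collide. ``green``
    defaults to zeros (the channel is never interpreted).
    """
    red = np.zeros((height, width), dtype=np.int64)
    blue = np.zeros((height, width), dtype=np.int64)
    if green is None:
        green = np.zeros((height, width), dtype=np.int64)
    for inst in instances:
        x, y, w, h = inst.bbox
        window = blue[y:y + h, x:x + w]
        clash = window[inst.mask]
        if (clash != 0).any():
            raise InstanceOverlapError(set(clash[clash != 0]) | {inst.instance_id})
        window[inst.mask] = inst.instance_id
        red[y:y + h, x:x + w][inst.mask] = class_map.intensity_for_label(inst.class_label)
    return MaskTriplet(red, np.asarray(green), blue)


# ---------------------------------------------------------------------------
# polygon tracing and rasterisation
# ---------------------------------------------------------------------------

# outgoing boundary edge per side of an inside pixel, oriented with the
# interior on the left: (start_corner, end_corner) in (x, y) corner coords
def _boundary_edges(mask: np.ndarray):
    padded = np.pad(mask, 1)
    inside = np.argwhere(padded)
    edges = {}
    for r, c in inside:
        # corners in unpadded coordinates
        x0, y0 = c - 1, r - 1
        if not padded[r - 1, c]:  # top
            edges.setdefault((x0, y0), []).append((x0 + 1, y0))
        if not padded[r, c + 1]:  # right
            edges.setdefault((x0 + 1, y0), []).append((x0 + 1, y0 + 1))
        if not padded[r + 1, c]:  # bottom
            edges.setdefault((x0 + 1, y0 + 1), []).append((x0, y0 + 1))
        if not padded[r, c - 1]:  # left
            edges.setdefault((x0, y0 + 1), []).append((x0, y0))
    return edges


def mask_to_polygons(mask: np.ndarray, offset: tuple[int, int] = (0, 0)) -> list[list[float]]:
    """Trace the external contours of a binary mask along pixel edges.

    Returns COCO-style flat ``[x0, y0, x1, y1, ...]`` lists, one per external
    contour, with vertices at integer pixel-corner coordinates (pixel
    ``(row, col)`` spans ``[col, col+1] x [row, row+1]``). Holes are filled
    before tracing; nuclei are simply connected, and COCO polygons cannot
    encode holes anyway.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InvalidAnnotationError("cannot trace an empty mask")
    mask = ndimage.binary_fill_holes(mask)
    edges = _boundary_edges(mask)
    ox, oy = offset
    polygons = []
    while edges:
        start = next(iter(edges))
        loop = [start]
        prev_dir = None
        current = start
        while True:
            candidates = edges[current]
            if len(candidates) == 1 or prev_dir is None:
                nxt = candidates[0]
            else:
                # diagonal pinch: prefer the sharpest left turn so each loop
                # stays simple (non self-intersecting)
                def turn(cand):
                    dx, dy = cand[0] - current[0], cand[1] - current[1]
                    return prev_dir[0] * dy - prev_dir[1] * dx
                nxt = max(candidates, key=turn)
            candidates.remove(nxt)
            if not candidates:
                del edges[current]
            prev_dir = (nxt[0] - current[0], nxt[1] - current[1])
            if nxt == start:
                break
            loop.append(nxt)
            current = nxt
        # drop collinear intermediate vertices to keep polygons small
        simplified = []
        n = len(loop)
        for i, (x, y) in enumerate(loop):
            px, py = loop[i - 1]
            nx_, ny_ = loop[(i + 1) % n]
            if (x - px) * (ny_ - y) != (y - py) * (nx_ - x):
                simplified.append((x, y))
        flat: list[float] = []
        for x, y in simplified:
            flat.extend((float(x + ox), float(y + oy)))
        polygons.append(flat)
    return polygons


def polygons_to_mask(polygons: Iterable[Sequence[float]], height: int, width: int) -> np.ndarray:
    """Rasterise COCO polygons back to a binary mask.

    A pixel is inside when its centre ``(col + 0.5, row + 0.5)`` falls inside
    any polygon; for the pixel-corner polygons this package writes, the
    roundtrip is exact.
    """
    out = np.zeros((height, width), dtype=bool)
    for flat in polygons:
        pts = np.asarray(flat, dtype=float).reshape(-1, 2)
        if len(pts) < 3:
            continue
        path = MplPath(pts)
        x0 = max(int(np.floor(pts[:, 0].min())), 0)
        x1 = min(int(np.ceil(pts[:, 0].max())), width)
        y0 = max(int(np.floor(pts[:, 1].min())), 0)
        y1 = min(int(np.ceil(pts[:, 1].max())), height)
        if x1 <= x0 or y1 <= y0:
            continue
        xs, ys = np.meshgrid(np.arange(x0, x1) + 0.5, np.arange(y0, y1) + 0.5)
        centres = np.column_stack([xs.ravel(), ys.ravel()])
        inside = path.contains_points(centres).reshape(y1 - y0, x1 - x0)
        out[y0:y1, x0:x1] |= inside
    return out


# ---------------------------------------------------------------------------
# COCO documents
# ---------------------------------------------------------------------------


@dataclass
class CocoDocument:
    """COCO ``images`` / ``annotations`` / ``categories`` container."""

    images: list[dict]
    annotations: list[dict]
    categories: list[dict]

    def validate(self) -> None:
        image_ids = {im["id"] for im in self.images}
        category_ids = {c["id"] for c in self.categories}
        ann_ids = [a["id"] for a in self.annotations]
        if len(set(ann_ids)) != len(ann_ids):
            raise ReferentialIntegrityError("annotation ids are not unique")
        for ann in self.annotations:
            if ann["image_id"] not in image_ids:
                raise ReferentialIntegrityError(
                    f"annotation {ann['id']} references missing image {ann['image_id']}"
                )
            if ann["category_id"] not in category_ids:
                raise ReferentialIntegrityError(
                    f"annotation {ann['id']} references missing category {ann['category_id']}"
                )
            if ann.get("area", 0) <= 0:
                raise InvalidAnnotationError(f"annotation {ann['id']} has non-positive area")

    def to_dict(self) -> dict:
        return {
            "images": self.images,
            "annotations": self.annotations,
            "categories": self.categories,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=False), encoding="utf-8")

    @classmethod
    def load(cls, path) -> "CocoDocument":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        doc = cls(
            images=list(data.get("images", [])),
            annotations=list(data.get("annotations", [])),
            categories=list(data.get("categories", [])),
        )
        doc.validate()
        return doc


def annotations_to_coco(
    instances_by_image: Mapping[object, Sequence[NucleiInstance]],
    class_map: ClassMap,
    image_infos: Sequence[ImageInfo],
) -> CocoDocument:
    """Convert grouped instances to a COCO document.

    One annotation per instance: polygon segmentation traced from the binary
    footprint, ``bbox = (x, y, w, h)``, ``area`` = footprint pixel count,
    ``iscrowd = 0``. Annotation ids are assigned serially from 1 in image
    order.
    """
    images = [
        {"id": info.id, "file_name": info.file_name, "height": int(info.height), "width": int(info.width)}
        for info in image_infos
    ]
    known = {info.id for info in image_infos}
    unknown = set(instances_by_image) - known
    if unknown:
        raise ReferentialIntegrityError(f"instances given for unknown images: {sorted(map(str, unknown))}")
    annotations = []
    next_id = 1
    for info in image_infos:
        for inst in instances_by_image.get(info.id, []):
            x, y, w, h = inst.bbox
            if x < 0 or y < 0 or x + w > info.width or y + h > info.height:
                raise InvalidAnnotationError(
                    f"instance {inst.instance_id} exceeds bounds of image {info.id}"
                )
            annotations.append({
                "id": next_id,
                "image_id": info.id,
                "category_id": inst.category_id,
                "segmentation": mask_to_polygons(inst.mask, offset=(x, y)),
                "bbox": [float(x), float(y), float(w), float(h)],
                "area": inst.area,
                "iscrowd": 0,
            })
            next_id += 1
    doc = CocoDocument(images=images, annotations=annotations, categories=class_map.coco_categories())
    doc.validate()
    return doc


def coco_to_annotations(doc: CocoDocument) -> dict[object, list[NucleiInstance]]:
    """Rasterise a COCO document back to per-image instance lists.

    Instance ids restart from 1 within each image (the blue-channel
    convention).
    """
    doc.validate()
    label_by_cid = {c["id"]: c["name"] for c in doc.categories}
    dims = {im["id"]: (im["height"], im["width"]) for im in doc.images}
    out: dict[object, list[NucleiInstance]] = {im["id"]: [] for im in doc.images}
    counters = {im["id"]: 0 for im in doc.images}
    for ann in doc.annotations:
        image_id = ann["image_id"]
        height, width = dims[image_id]
        full = polygons_to_mask(ann["segmentation"], height, width)
        if not full.any():
            raise InvalidAnnotationError(f"annotation {ann['id']} rasterises to an empty mask")
        counters[image_id] += 1
        out[image_id].append(
            _tight_instance(
                counters[image_id],
                label_by_cid[ann["category_id"]],
                ann["category_id"],
                full,
                source_image_id=image_id,
            )
        )
    return out


# ---------------------------------------------------------------------------
# class grouping
# ---------------------------------------------------------------------------


def grouped_class_map(grouping: Mapping[str, str]) -> ClassMap:
    """Class map over the grouped labels, ordered by first appearance."""
    seen: list[str] = []
    for target in grouping.values():
        if target not in seen:
            seen.append(target)
    return ClassMap.from_labels(seen)


def group_classes(counts_or_instances, grouping: Mapping[str, str]):
    """Merge classes according to ``grouping`` (original label -> group label).

    Accepts either a ``{label: count}`` mapping (counts are summed per group)
    or a sequence of :class:`NucleiInstance` (labels and category ids are
    rewritten against :func:`grouped_class_map`). The total is conserved in
    both cases. Labels without a grouping entry raise
    :class:`MappingIncompleteError`.
    """
    if isinstance(counts_or_instances, Mapping):
        counts = counts_or_instances
        missing = [l for l in counts if l not in grouping]
        if missing:
            raise MappingIncompleteError(missing)
        out: dict[str, int] = {}
        for target in dict.fromkeys(grouping.values()):
            out[target] = 0
        for label, count in counts.items():
            out[grouping[label]] += count
        return out
    instances = list(counts_or_instances)
    missing = sorted({i.class_label for i in instances if i.class_label not in grouping})
    if missing:
        raise MappingIncompleteError(missing)
    gmap = grouped_class_map(grouping)
    return [
        replace(
            inst,
            class_label=grouping[inst.class_label],
            category_id=gmap.category_id_for_label(grouping[inst.class_label]),
            mask=inst.mask,
            crop=inst.crop,
        )
        for inst in instances
    ]


def class_counts(instances: Iterable[NucleiInstance]) -> dict[str, int]:
    """Per-class instance tally."""
    out: dict[str, int] = {}
    for inst in instances:
        out[inst.class_label] = out.get(inst.class_label, 0) + 1
    return out
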