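"""Detection and classification metrics.

Implements the standard object-detection evaluation stack at a single IoU
threshold (0.5 by default): greedy score-ordered matching of detections to
ground truth, all-point interpolated average precision, mAP over classes, a
confusion matrix extended with a background row/column (undetected nuclei on
the ground-truth axis, spurious detections on the prediction axis), one-vs-
rest balanced accuracy, and plain detection sensitivity for the single-class
setting.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import InvalidBoxError, ZeroGroundTruthError

__all__ = [
    "Detection",
    "GroundTruth",
    "PRCurve",
    "ConfusionMatrix",
    "MatchResult",
    "iou",
    "mask_iou",
    "match_detections",
    "precision_recall_curve",
    "average_precision",
    "per_class_average_precision",
    "mean_ap",
    "confusion_with_background",
    "balanced_accuracy",
    "detection_sensitivity",
]

logger = logging.getLogger(__name__)

BACKGROUND = "background"


@dataclass(frozen=True)
class Detection:
    """One detector output: box, class, confidence, optional mask."""

    image_id: object
    category_id: int
    bbox: tuple[float, float, float, float]
    score: float
    mask: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")
        _check_box(self.bbox)


@dataclass(frozen=True)
class GroundTruth:
    """One annotated instance used as evaluation reference."""

    image_id: object
    category_id: int
    bbox: tuple[float, float, float, float]
    mask: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self):
        _check_box(self.bbox)


def _check_box(bbox) -> None:
    x, y, w, h = bbox
    if w <= 0 or h <= 0:
        raise InvalidBoxError(f"box {bbox} has non-positive area")


def iou(box_a, box_b) -> float:
    """Intersection-over-union of two ``(x, y, w, h)`` boxes."""
    _check_box(box_a)
    _check_box(box_b)
    ax, ay, aw, ah = box_a
    bx, by, bw, bh = box_b
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union


def mask_iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Jaccard index of two binary masks of one shape."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    union = (a | b).sum()
    if union == 0:
        raise InvalidBoxError("both masks are empty")
    return float((a & b).sum() / union)


@dataclass
class MatchResult:
    """Greedy matching outcome for one image/class pool.

    ``order`` are detection indices in descending-score order (stable);
    ``tp`` aligns with ``order``; ``matched_gt[i]`` is the matched ground
    truth index or -1; ``undetected_gt`` lists ground-truth indices no
    detection claimed.
    """

    order: np.ndarray
    tp: np.ndarray
    matched_gt: np.ndarray
    undetected_gt: list[int]

    @property
    def n_tp(self) -> int:
        return int(self.tp.sum())

    @property
    def n_fp(self) -> int:
        return int((~self.tp).sum())


def match_detections(detections, gt_boxes, iou_threshold: float = 0.5) -> MatchResult:
    """Greedily match detections to ground truth in descending score order.

    ``detections`` is a sequence of :class:`Detection` or ``(bbox, score)``
    pairs; ``gt_boxes`` a sequence of boxes (or :class:`GroundTruth`). Each
    ground truth is claimed at most once; a detection is a true positive when
    its best still-unclaimed IoU reaches the threshold, otherwise a false
    positive (duplicates on an already-claimed ground truth are false
    positives). Score ties break by input order (stable sort).
    """
    boxes, scores = [], []
    for det in detections:
        if isinstance(det, Detection):
            boxes.append(det.bbox)
            scores.append(det.score)
        else:
            boxes.append(det[0])
            scores.append(det[1])
    gts = [g.bbox if isinstance(g, GroundTruth) else g for g in gt_boxes]
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable") if scores else np.array([], dtype=int)
    tp = np.zeros(len(boxes), dtype=bool)
    matched_gt = np.full(len(boxes), -1, dtype=int)
    claimed = np.zeros(len(gts), dtype=bool)
    for rank, det_idx in enumerate(order):
        best_iou, best_gt = 0.0, -1
        for gt_idx, gt_box in enumerate(gts):
            if claimed[gt_idx]:
                continue
            value = iou(boxes[det_idx], gt_box)
            if value > best_iou:
                best_iou, best_gt = value, gt_idx
        if best_gt >= 0 and best_iou >= iou_threshold:
            tp[rank] = True
            matched_gt[rank] = best_gt
            claimed[best_gt] = True
    return MatchResult(
        order=order,
        tp=tp,
        matched_gt=matched_gt,
        undetected_gt=[i for i in range(len(gts)) if not claimed[i]],
    )


@dataclass
class PRCurve:
    """Precision-recall points in increasing-recall order."""

    recall: np.ndarray
    precision: np.ndarray

    def __post_init__(self):
        self.recall = np.asarray(self.recall, dtype=float)
        self.precision = np.asarray(self.precision, dtype=float)
        if self.recall.shape != self.precision.shape:
            raise ValueError("recall and precision must align")
        if (np.diff(self.recall) < 0).any():
            raise ValueError("recall must be non-decreasing")
        for arr in (self.recall, self.precision):
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError("precision/recall must lie in [0, 1]")


def precision_recall_curve(tp_flags, n_gt: int) -> PRCurve:
    """Cumulative precision/recall along the score-ranked detection list."""
    if n_gt <= 0:
        raise ZeroGroundTruthError("precision-recall needs at least one ground truth")
    flags = np.asarray(tp_flags, dtype=bool)
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    recall = tp_cum / n_gt
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1)
    return PRCurve(recall=recall, precision=precision)


def average_precision(tp_flags_or_curve, n_gt: int | None = None) -> float:
    """Area under the interpolated precision-recall curve (AP@alpha).

    Uses all-point interpolation: precision is made monotonically
    non-increasing in recall (each point takes the max precision at any
    equal-or-higher recall) and integrated over recall. Accepts either a
    :class:`PRCurve` or score-ordered TP flags plus the ground-truth count.
    """
    if isinstance(tp_flags_or_curve, PRCurve):
        curve = tp_flags_or_curve
    else:
        if n_gt is None:
            raise ValueError("n_gt is required when passing TP flags")
        curve = precision_recall_curve(tp_flags_or_curve, n_gt)
    if curve.recall.size == 0:
        return 0.0
    recall = np.concatenate([[0.0], curve.recall])
    precision = np.concatenate([[0.0], curve.precision])
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    return float(np.sum(np.diff(recall) * envelope[1:]))


def _by_image(items):
    grouped = defaultdict(list)
    for item in items:
        grouped[item.image_id].append(item)
    return grouped


def per_class_average_precision(
    detections: Sequence[Detection],
    ground_truth: Sequence[GroundTruth],
    category_ids: Sequence[int],
    iou_threshold: float = 0.5,
) -> dict[int, float | None]:
    """AP per class over a whole dataset.

    Matching is done per image and per class; TP flags are pooled across
    images in global score order. Classes with zero ground truth have
    undefined AP and map to ``None`` (logged, skipped by :func:`mean_ap`).
    """
    out: dict[int, float | None] = {}
    for cid in category_ids:
        class_dets = [d for d in detections if d.category_id == cid]
        class_gts = [g for g in ground_truth if g.category_id == cid]
        if not class_gts:
            logger.warning("category %s has no ground truth; AP undefined", cid)
            out[cid] = None
            continue
        gts_by_image = _by_image(class_gts)
        records = []  # (score, input rank, tp)
        for image_id, dets in _by_image(class_dets).items():
            result = match_detections(dets, gts_by_image.get(image_id, []), iou_threshold)
            for rank, det_idx in enumerate(result.order):
                records.append((dets[det_idx].score, result.tp[rank]))
        records.sort(key=lambda r: -r[0])
        flags = [tp for _, tp in records]
        out[cid] = average_precision(flags, n_gt=len(class_gts))
    return out


def mean_ap(per_class: Mapping[int, float | None] | Sequence[float]) -> float:
    """Unweighted mean over defined per-class AP values."""
    if isinstance(per_class, Mapping):
        values = [v for v in per_class.values() if v is not None]
    else:
        values = [v for v in per_class if v is not None]
    if not values:
        raise ZeroGroundTruthError("no class has a defined AP")
    return float(np.mean(values))


@dataclass
class ConfusionMatrix:
    """(M+1) x (M+1) counts; ground truth on rows, predictions on columns.

    The last row/column is the background tag: row = spurious detections,
    column = undetected ground truth.
    """

    counts: np.ndarray
    class_labels: tuple[str, ...]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        m = len(self.class_labels)
        if self.counts.shape != (m + 1, m + 1):
            raise ValueError("counts must be (M+1, M+1) for M classes plus background")
        if (self.counts < 0).any():
            raise ValueError("counts must be >= 0")

    @property
    def labels_with_background(self) -> tuple[str, ...]:
        return self.class_labels + (BACKGROUND,)

    def without_background(self) -> np.ndarray:
        return self.counts[:-1, :-1]


def confusion_with_background(
    detections: Sequence[Detection],
    ground_truth: Sequence[GroundTruth],
    class_labels: Sequence[str],
    iou_threshold: float = 0.5,
) -> ConfusionMatrix:
    """Confusion matrix with a background tag on both axes.

    Localization matching is class-agnostic (greedy by score within each
    image, IoU >= threshold) so class swaps land in off-diagonal cells; an
    undetected ground truth counts toward (its class, background) and an
    unmatched detection toward (background, its class). Category ids are
    1-based positions into ``class_labels``.
    """
    m = len(class_labels)
    counts = np.zeros((m + 1, m + 1), dtype=np.int64)
    gts_by_image = _by_image(ground_truth)
    dets_by_image = _by_image(detections)
    for image_id in set(gts_by_image) | set(dets_by_image):
        dets = dets_by_image.get(image_id, [])
        gts = gts_by_image.get(image_id, [])
        result = match_detections(dets, gts, iou_threshold)
        for rank, det_idx in enumerate(result.order):
            pred_col = dets[det_idx].category_id - 1
            if result.tp[rank]:
                gt_row = gts[result.matched_gt[rank]].category_id - 1
                counts[gt_row, pred_col] += 1
            else:
                counts[m, pred_col] += 1
        for gt_idx in result.undetected_gt:
            counts[gts[gt_idx].category_id - 1, m] += 1
    return ConfusionMatrix(counts=counts, class_labels=tuple(class_labels))


def balanced_accuracy(
    cm: ConfusionMatrix, include_background: bool = True
) -> tuple[dict[str, float], float]:
    """One-vs-rest balanced accuracy per class and its unweighted mean.

    For class ``c``: sensitivity ``TP/(TP+FN)`` over its ground-truth row,
    specificity ``TN/(TN+FP)`` over everything else; balanced accuracy is
    their mean. ``include_background=False`` removes the background
    row/column first, restricting the question to "how well are detected
    nuclei classified". Classes with no ground truth and no predictions are
    undefined and excluded (logged).
    """
    if include_background:
        counts = cm.counts
        labels = cm.labels_with_background
    else:
        counts = cm.without_background()
        labels = cm.class_labels
    total = counts.sum()
    per_class: dict[str, float] = {}
    for idx, label in enumerate(labels):
        tp = counts[idx, idx]
        fn = counts[idx, :].sum() - tp
        fp = counts[:, idx].sum() - tp
        tn = total - tp - fn - fp
        if tp + fn == 0 and tp + fp == 0:
            logger.warning("class %s has no ground truth and no predictions; excluded", label)
            continue
        sensitivity = tp / (tp + fn) if tp + fn > 0 else 0.0
        specificity = tn / (tn + fp) if tn + fp > 0 else 0.0
        per_class[label] = float((sensitivity + specificity) / 2)
    if not per_class:
        raise ZeroGroundTruthError("no class has a defined balanced accuracy")
    return per_class, float(np.mean(list(per_class.values())))


def detection_sensitivity(n_tp: int, n_gt: int) -> float:
    """Fraction of ground-truth nuclei detected (single merged class)."""
    if n_gt <= 0:
        raise ZeroGroundTruthError("sensitivity needs at least one ground truth")
    if not 0 <= n_tp <= n_gt:
        raise ValueError("TP count must lie in [0, n_gt]")
    return n_tp / n_gt
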