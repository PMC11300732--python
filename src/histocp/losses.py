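"""Class weighting and reference classification losses.

The rebalancing weight for class ``c`` is

    w_c = N / (M * alpha_c)

with ``N`` the total instance count, ``M`` the number of classes and
``alpha_c`` the count of class ``c``; balanced data yields unit weights and
``sum_c alpha_c * w_c = N`` always. The weighted cross-entropy and focal
losses here are pure numeric references — weight tables exported from them
can be dropped into any detector's classification head, but no gradient
machinery is provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import EmptyDatasetError

__all__ = [
    "ClassWeights",
    "compute_class_weights",
    "weighted_cross_entropy",
    "focal_loss",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass(frozen=True)
class ClassWeights:
    """Per-class loss weights with the counts they were derived from."""

    weights: tuple[float, ...]
    counts: tuple[float, ...]

    def __post_init__(self):
        if len(self.weights) != len(self.counts):
            raise ValueError("weights and counts must have one entry per class")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be >= 0")

    @property
    def total(self) -> float:
        return float(sum(self.counts))

    @property
    def n_classes(self) -> int:
        return len(self.weights)


def compute_class_weights(counts, zero_count: str = "zero_weight") -> ClassWeights:
    """Inverse-frequency weights ``w_c = N / (M * alpha_c)``.

    ``counts`` is the per-class instance tally. A class with zero count has
    an undefined weight (division by zero); by default it gets weight 0 and a
    logged warning — such a class never appears in the ground truth, so a
    zero weight simply excludes it from the loss. Pass
    ``zero_count="error"`` to raise instead. All-zero counts raise
    :class:`EmptyDatasetError`.
    """
    alpha = np.asarray(counts, dtype=float)
    if alpha.ndim != 1 or alpha.size < 1:
        raise ValueError("counts must be a 1-D vector with at least one class")
    if (alpha < 0).any():
        raise ValueError("counts must be >= 0")
    total = alpha.sum()
    if total == 0:
        raise EmptyDatasetError("all class counts are zero")
    zero = alpha == 0
    if zero.any():
        if zero_count == "error":
            raise EmptyDatasetError(
                f"classes {np.nonzero(zero)[0].tolist()} have zero instances"
            )
        logger.warning(
            "classes %s have zero instances; assigned weight 0 (excluded from the loss)",
            np.nonzero(zero)[0].tolist(),
        )
    weights = np.zeros_like(alpha)
    weights[~zero] = total / (alpha.size * alpha[~zero])
    return ClassWeights(weights=tuple(weights), counts=tuple(alpha))


def _as_batch(probs, onehot):
    p = np.asarray(probs, dtype=float)
    y = np.asarray(onehot, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"probs shape {p.shape} != onehot shape {y.shape}")
    if p.ndim == 1:
        p = p[None, :]
        y = y[None, :]
    if p.ndim != 2:
        raise ValueError("expected per-class vectors or an (observations, classes) batch")
    if not np.allclose(y.sum(axis=1), 1) or not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("onehot must have exactly one 1 per observation")
    return np.clip(p, _EPS, 1.0), y


def weighted_cross_entropy(probs, onehot, weights: ClassWeights | None = None) -> float:
    """Weighted cross-entropy ``-sum_c w_c * log(p_c) * y_c``.

    ``probs``/``onehot`` are per-class vectors or ``(observations, classes)``
    batches; the batch form returns the mean over observations. ``weights``
    defaults to unit weights (plain cross-entropy). Probabilities are clamped
    at 1e-12 so a confidently wrong prediction yields a large finite loss.
    """
    p, y = _as_batch(probs, onehot)
    if weights is None:
        w = np.ones(p.shape[1])
    else:
        w = np.asarray(weights.weights, dtype=float)
        if w.size != p.shape[1]:
            raise ValueError(f"{w.size} weights for {p.shape[1]} classes")
    per_obs = -(w[None, :] * np.log(p) * y).sum(axis=1)
    return float(per_obs.mean())


def focal_loss(probs, onehot, gamma: float = 2.0, alpha: float = 0.25) -> float:
    """Focal loss ``-alpha * (1 - p_t)^gamma * log(p_t)``.

    ``p_t`` is the probability assigned to the correct class. ``gamma=0,
    alpha=1`` reduces to unweighted cross-entropy. Batch form returns the
    mean over observations.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    p, y = _as_batch(probs, onehot)
    p_t = (p * y).sum(axis=1)
    per_obs = -alpha * np.power(1.0 - p_t, gamma) * np.log(p_t)
    return float(per_obs.mean())
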