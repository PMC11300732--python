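"""Reinhard color transfer for H&E images.

Stain appearance varies between slides and scanners; Reinhard normalization
removes that variation by matching each image's per-channel mean and
standard deviation, in a decorrelated opponent color space, to a reference.
The default space is the log-LMS-derived l-alpha-beta space of the original
color-transfer method (l = achromatic, alpha = yellow-blue, beta =
red-green); CIELAB is available as an option since many histology pipelines
use it instead.

RGB values are kept on their native 0-255 scale and 1 is added to the linear
LMS responses before the log transform, so black pixels are well defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from skimage import color as skcolor

from .errors import EmptyInputError

__all__ = [
    "ChannelStats",
    "rgb_to_opponent",
    "opponent_to_rgb",
    "compute_stats",
    "reinhard_normalize",
    "pooled_stats",
    "normalize_dataset",
]

logger = logging.getLogger(__name__)

# Ruderman/Reinhard matrices
_RGB2LMS = np.array([
    [0.3811, 0.5783, 0.0402],
    [0.1967, 0.7244, 0.0782],
    [0.0241, 0.1288, 0.8444],
])
_LMS2RGB = np.linalg.inv(_RGB2LMS)
_LOGLMS2LAB = np.diag([1 / np.sqrt(3), 1 / np.sqrt(6), 1 / np.sqrt(2)]) @ np.array([
    [1, 1, 1],
    [1, 1, -2],
    [1, -1, 0],
])
_LAB2LOGLMS = np.linalg.inv(_LOGLMS2LAB)

_SPACES = ("lalphabeta", "lab")


@dataclass(frozen=True)
class ChannelStats:
    """Per-channel mean and standard deviation in the opponent space."""

    mean: tuple[float, float, float]
    std: tuple[float, float, float]

    def __post_init__(self):
        mean = tuple(float(v) for v in self.mean)
        std = tuple(float(v) for v in self.std)
        if not all(np.isfinite(mean)) or not all(np.isfinite(std)):
            raise ValueError("channel statistics must be finite")
        if any(s < 0 for s in std):
            raise ValueError("channel standard deviations must be >= 0")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "std", std)


def _check_space(space: str) -> None:
    if space not in _SPACES:
        raise ValueError(f"unknown color space {space!r}; choose from {_SPACES}")


def rgb_to_opponent(image: np.ndarray, space: str = "lalphabeta") -> np.ndarray:
    """Forward transform RGB (uint8 or float, 0-255) to the opponent space."""
    _check_space(space)
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if space == "lab":
        return skcolor.rgb2lab(arr / 255.0)
    lms = arr @ _RGB2LMS.T
    log_lms = np.log10(lms + 1.0)
    return log_lms @ _LOGLMS2LAB.T


def opponent_to_rgb(arr: np.ndarray, space: str = "lalphabeta") -> np.ndarray:
    """Inverse transform back to float RGB on the 0-255 scale (unclipped)."""
    _check_space(space)
    arr = np.asarray(arr, dtype=np.float64)
    if space == "lab":
        return skcolor.lab2rgb(arr) * 255.0
    log_lms = arr @ _LAB2LOGLMS.T
    lms = np.power(10.0, log_lms) - 1.0
    return lms @ _LMS2RGB.T


def compute_stats(image: np.ndarray, space: str = "lalphabeta") -> ChannelStats:
    """Opponent-space per-channel mean and std of an RGB image."""
    arr = np.asarray(image)
    if arr.size == 0:
        raise EmptyInputError("cannot compute channel statistics of an empty image")
    opp = rgb_to_opponent(arr, space)
    flat = opp.reshape(-1, 3)
    return ChannelStats(mean=tuple(flat.mean(axis=0)), std=tuple(flat.std(axis=0)))


def reinhard_normalize(
    source: np.ndarray,
    target: ChannelStats | np.ndarray,
    space: str = "lalphabeta",
    as_uint8: bool = True,
) -> np.ndarray:
    """Match the source image's opponent-space statistics to the target's.

    Each opponent channel is mapped ``(v - mu_src) * (sigma_tgt / sigma_src)
    + mu_tgt``. A source channel with zero spread cannot be rescaled; its
    scale term is set to 0 so the channel lands exactly on the target mean
    (logged as a warning when the target spread is nonzero). The result is
    converted back to RGB, clipped to 0-255 and, by default, quantized to
    uint8; pass ``as_uint8=False`` for the float image (useful when verifying
    statistics free of quantization).
    """
    if not isinstance(target, ChannelStats):
        target = compute_stats(target, space)
    src = np.asarray(source)
    if src.size == 0:
        raise EmptyInputError("cannot normalize an empty image")
    opp = rgb_to_opponent(src, space)
    flat = opp.reshape(-1, 3)
    mu_s = flat.mean(axis=0)
    sd_s = flat.std(axis=0)
    mu_t = np.asarray(target.mean)
    sd_t = np.asarray(target.std)
    scale = np.zeros(3)
    nonzero = sd_s > 0
    scale[nonzero] = sd_t[nonzero] / sd_s[nonzero]
    degenerate = ~nonzero & (sd_t > 0)
    if degenerate.any():
        logger.warning(
            "source channel(s) %s have zero spread; pinned to the target mean",
            np.nonzero(degenerate)[0].tolist(),
        )
    out_opp = (opp - mu_s) * scale + mu_t
    rgb = np.clip(opponent_to_rgb(out_opp, space), 0.0, 255.0)
    if as_uint8:
        return np.round(rgb).astype(np.uint8)
    return rgb


def pooled_stats(images: Sequence[np.ndarray], space: str = "lalphabeta") -> ChannelStats:
    """Dataset-pooled target: the mean of per-image means and stds.

    Used as the default reference so normalization does not depend on an
    arbitrary image choice.
    """
    if len(images) == 0:
        raise EmptyInputError("cannot pool statistics over an empty dataset")
    stats = [compute_stats(im, space) for im in images]
    mean = np.mean([s.mean for s in stats], axis=0)
    std = np.mean([s.std for s in stats], axis=0)
    return ChannelStats(mean=tuple(mean), std=tuple(std))


def normalize_dataset(
    images: Sequence[np.ndarray],
    reference: ChannelStats | np.ndarray | None = None,
    space: str = "lalphabeta",
    as_uint8: bool = True,
) -> list[np.ndarray]:
    """Normalize every image against one shared target.

    ``reference`` may be precomputed :class:`ChannelStats`, a reference
    image, or ``None`` for the pooled default. Deterministic; an empty input
    list yields an empty output.
    """
    images = list(images)
    if not images:
        return []
    if reference is None:
        target = pooled_stats(images, space)
    elif isinstance(reference, ChannelStats):
        target = reference
    else:
        target = compute_stats(reference, space)
    out = []
    for idx, image in enumerate(images):
        try:
            out.append(reinhard_normalize(image, target, space, as_uint8=as_uint8))
        except Exception as exc:
            raise type(exc)(f"image #{idx}: {exc}") from exc
    return out
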