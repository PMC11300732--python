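"""Disk I/O helpers: lossless PNG images, mask triplets, grouping files."""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Mapping

import imageio.v3 as iio
import numpy as np
import yaml

from .formats import MaskTriplet

__all__ = [
    "read_image",
    "write_image",
    "read_mask_triplet",
    "write_mask_triplet",
    "load_grouping",
]

IMAGE_SUFFIXES = (".png", ".tif", ".tiff")


def read_image(path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return arr[..., :3]


def write_image(path, image: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def read_mask_triplet(path) -> MaskTriplet:
    return MaskTriplet.from_image(read_image(path))


def write_mask_triplet(path, triplet: MaskTriplet) -> None:
    write_image(path, triplet.to_image())


def load_grouping(name_or_path: str) -> Mapping[str, str]:
    """A grouping mapping: a built-in preset name or a YAML file path.

    Presets ``config1`` (everything -> nuclei) and ``config2`` (minority
    merging) ship with the package.
    """
    candidate = Path(name_or_path)
    if candidate.suffix in (".yml", ".yaml") and candidate.exists():
        text = candidate.read_text(encoding="utf-8")
    else:
        try:
            text = (resources.files("histocp") / "data" / f"{name_or_path}.yaml").read_text(
                encoding="utf-8"
            )
        except FileNotFoundError:
            raise FileNotFoundError(
                f"no grouping preset or file named {name_or_path!r}"
            ) from None
    mapping = yaml.safe_load(text)
    if not isinstance(mapping, dict):
        raise ValueError(f"grouping {name_or_path!r} is not a flat mapping")
    return {str(k): str(v) for k, v in mapping.items()}
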