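"""Image, mask and probability-map file I/O (PNG/JPEG via Pillow)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "read_image", "write_image", "read_mask", "write_mask",
    "write_probability_map", "read_probability_map", "to_float", "to_uint8",
]


def read_image(path) -> np.ndarray:
    """RGB image as (h, w, 3) uint8."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def write_image(path, image) -> None:
    image = np.asarray(image)
    if image.dtype != np.uint8:
        image = to_uint8(image)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(image).save(path)


def read_mask(path) -> np.ndarray:
    """Single-channel mask as (h, w) uint8 in {0, 1}; nonzero = lesion."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return (arr > 0).astype(np.uint8)


def write_mask(path, mask) -> None:
    mask = (np.asarray(mask) > 0).astype(np.uint8) * 255
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(mask, mode="L").save(path)


def write_probability_map(path, prob) -> None:
    """Probabilities in [0, 1] stored as 16-bit grayscale PNG."""
    prob = np.asarray(prob, dtype=np.float64)
    if prob.ndim == 3 and prob.shape[-1] == 1:
        prob = prob[..., 0]
    arr = np.round(np.clip(prob, 0.0, 1.0) * 65535).astype(np.uint16)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(arr).save(path)


def read_probability_map(path) -> np.ndarray:
    with Image.open(path) as im:
        arr = np.asarray(im, dtype=np.float64)
    return (arr / 65535.0).astype(np.float32)


def to_float(image) -> np.ndarray:
    """uint8 [0, 255] -> float32 [0, 1] (the network's input scaling)."""
    return np.asarray(image, dtype=np.float32) / 255.0


def to_uint8(image) -> np.ndarray:
    return np.round(np.clip(np.asarray(image, dtype=np.float32), 0.0, 1.0)
                    * 255).astype(np.uint8)
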