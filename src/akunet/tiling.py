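"""Wide-field inference: pad, tile, predict per tile, reassemble.

A full photograph is zero-padded to the smallest size that a grid of
model-sized tiles (stride = tile side minus overlap) covers exactly, the
model is run on every tile, the per-tile probability maps are placed back
at their origins (overlapping pixels averaged), and the padding is
removed so the output matches the input size pixel-for-pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import LesionRegionSet, extract_regions

__all__ = ["TilingPlan", "plan_tiling", "predict_wide", "detect_regions"]


@dataclass
class TilingPlan:
    pad: tuple          # (top, bottom, left, right)
    tiles: list         # (row, col) origins in the padded frame
    tile_side: int
    overlap: int
    padded_shape: tuple
    input_shape: tuple


def _axis_plan(n, tile, stride):
    """Padded length and tile count along one axis."""
    if n <= tile:
        return tile, 1
    k = int(np.ceil((n - tile) / stride))
    return tile + k * stride, k + 1


def plan_tiling(height: int, width: int, tile_side: int,
                overlap: int = 0) -> TilingPlan:
    """Minimal, symmetric-as-possible zero padding plus tile origins.

    When total padding along an axis is odd, the extra pixel goes to the
    bottom/right (documented convention; the aggregated output does not
    depend on it for a deterministic model).
    """
    if height <= 0 or width <= 0:
        raise ValueError(f"image size must be positive, got {height}x{width}")
    if not (tile_side > overlap >= 0):
        raise ValueError(
            f"need tile_side > overlap >= 0, got {tile_side}, {overlap}")
    stride = tile_side - overlap
    ph, nh = _axis_plan(height, tile_side, stride)
    pw, nw = _axis_plan(width, tile_side, stride)
    pad_h, pad_w = ph - height, pw - width
    pad = (pad_h // 2, pad_h - pad_h // 2, pad_w // 2, pad_w - pad_w // 2)
    tiles = [(i * stride, j * stride) for i in range(nh) for j in range(nw)]
    return TilingPlan(pad=pad, tiles=tiles, tile_side=tile_side,
                      overlap=overlap, padded_shape=(ph, pw),
                      input_shape=(height, width))


def predict_wide(image, model, plan: TilingPlan,
                 batch_size: int = 8) -> np.ndarray:
    """Tiled probability map for a full (h, w, 3) image in [0, 1].

    ``model`` is anything with a ``predict`` method (or a callable)
    mapping (n, t, t, 3) stacks to (n, t, t, 1) probabilities.
    """
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected (h, w, 3) image, got {image.shape}")
    if image.shape[:2] != plan.input_shape:
        raise ValueError(
            f"plan was made for {plan.input_shape}, image is {image.shape[:2]}")
    t = plan.tile_side
    top, bottom, left, right = plan.pad
    padded = np.pad(image, ((top, bottom), (left, right), (0, 0)))
    stack = np.stack([padded[r:r + t, c:c + t] for r, c in plan.tiles])
    predict = model.predict if hasattr(model, "predict") else model
    probs = np.empty((len(stack), t, t, 1), dtype=np.float32)
    for i in range(0, len(stack), batch_size):
        out = np.asarray(predict(stack[i:i + batch_size]), dtype=np.float32)
        if out.shape[1:3] != (t, t):
            raise ValueError(
                f"model returned {out.shape[1:3]} tiles, expected {(t, t)}")
        probs[i:i + len(out)] = out.reshape(len(out), t, t, 1)
    acc = np.zeros(plan.padded_shape, dtype=np.float64)
    weight = np.zeros(plan.padded_shape, dtype=np.float64)
    for (r, c), p in zip(plan.tiles, probs):
        acc[r:r + t, c:c + t] += p[..., 0]
        weight[r:r + t, c:c + t] += 1.0
    out = (acc / weight).astype(np.float32)
    h, w = plan.input_shape
    return out[top:top + h, left:left + w]


def detect_regions(prob, threshold: float = 0.5, min_area_px: int = 0,
                   connectivity: int = 8):
    """Binarise a probability map and drop small connected components.

    Returns (mask, LesionRegionSet of the surviving components).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    prob = np.asarray(prob, dtype=np.float32)
    if prob.ndim == 3 and prob.shape[-1] == 1:
        prob = prob[..., 0]
    mask = prob >= threshold
    regions = extract_regions(mask.astype(np.uint8), connectivity)
    keep = [px for px in regions.regions if len(px) >= min_area_px]
    filtered = LesionRegionSet(regions=keep, shape=mask.shape,
                               connectivity=connectivity)
    return filtered.to_mask().astype(np.uint8), filtered
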