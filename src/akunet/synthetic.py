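"""Seeded synthetic clinical-photograph fixtures with exact ground truth.

The generator emulates the appearance that makes actinic keratosis hard
to segment in wide-field photographs: low-contrast reddish-brown patches
with fuzzy boundaries on a textured skin-like background, alongside
distractors that must *not* be segmented — dark hair-like curves and
sharp, high-contrast benign spots (the seborrheic-keratosis / lentigo
confusers).  Every scene is deterministic given its seed, and the
ground-truth mask marks exactly the lesion supports before boundary
blurring (mirroring rough clinical annotations).

Scale is expressed in pixels per millimetre (default 5 px/mm) so lesion
diameters can be stated in millimetres (default 2-20 mm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import bezier_curve, disk

from .io import to_uint8, write_image, write_mask
from .patches import AnnotatedImage

logger = logging.getLogger(__name__)

__all__ = ["SceneConfig", "generate_scene", "generate_dataset", "write_dataset"]

_LUM = np.array([0.299, 0.587, 0.114])


@dataclass
class SceneConfig:
    """Knobs of the synthetic scene generator.

    All ranges are inclusive (low, high) pairs sampled uniformly per
    scene/lesion.  ``contrast`` is the absolute difference in mean gray
    intensity (on a 0-1 scale) between lesion and background pixels.
    """

    size: tuple = (256, 256)
    px_per_mm: float = 5.0
    lesion_count: tuple = (1, 4)
    lesion_diam_mm: tuple = (2.0, 20.0)
    contrast: tuple = (0.15, 0.35)
    boundary_softness_px: tuple = (1.5, 4.0)
    hair_count: tuple = (0, 4)
    spot_count: tuple = (0, 3)
    texture_amp: float = 0.04
    vignette: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("lesion_count", "lesion_diam_mm", "contrast",
                     "boundary_softness_px", "hair_count", "spot_count"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} range ({lo}, {hi}) is empty")
        if not (0.0 < self.contrast[0] and self.contrast[1] < 1.0):
            raise ValueError("contrast must lie in (0, 1)")
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be positive")

    def to_dict(self):
        d = dict(vars(self))
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


def _background(h, w, rng, base_tone, texture_amp, vignette):
    img = np.empty((h, w, 3), dtype=np.float64)
    img[...] = base_tone
    # multi-octave smooth noise, shared across channels (skin texture)
    texture = np.zeros((h, w))
    for scale, weight in ((8, 1.0), (16, 0.7), (32, 0.5)):
        grid = rng.standard_normal((h // scale + 2, w // scale + 2))
        zoomed = ndimage.zoom(grid, scale, order=3)[:h, :w]
        texture += weight * zoomed
    texture /= max(texture.std(), 1e-9)
    img += (texture_amp * texture)[..., None]
    # faint per-channel mottling (dyschromia)
    for c in range(3):
        grid = rng.standard_normal((h // 32 + 2, w // 32 + 2))
        zoomed = ndimage.zoom(grid, 32, order=3)[:h, :w]
        img[..., c] += 0.3 * texture_amp * zoomed / max(zoomed.std(), 1e-9)
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = ((yy - h / 2) / (h / 2)) ** 2 + ((xx - w / 2) / (w / 2)) ** 2
    img *= (1.0 - vignette * r2)[..., None]
    return img


def _superellipse_support(h, w, center, axes, exponent, theta):
    cy, cx = center
    a, b = axes
    yy, xx = np.mgrid[0:h, 0:w]
    y = yy - cy
    x = xx - cx
    xr = np.cos(theta) * x + np.sin(theta) * y
    yr = -np.sin(theta) * x + np.cos(theta) * y
    return (np.abs(xr / a) ** exponent + np.abs(yr / b) ** exponent) <= 1.0


def _add_lesion(img, mask, rng, cfg):
    """Paint one soft-edged super-ellipse lesion; returns its geometry
    (or None when placement failed)."""
    h, w = img.shape[:2]
    diam = rng.uniform(*cfg.lesion_diam_mm) * cfg.px_per_mm
    a = min(diam / 2.0, min(h, w) / 2.5)
    a = max(a, 2.5)
    b = a * rng.uniform(0.5, 1.0)
    margin_y = min(a, b)
    cy = rng.uniform(margin_y, h - margin_y)
    cx = rng.uniform(margin_y, w - margin_y)
    exponent = rng.uniform(1.5, 3.0)
    theta = rng.uniform(0.0, np.pi)
    support = _superellipse_support(h, w, (cy, cx), (a, b), exponent, theta)
    if not support.any():
        return None
    contrast = rng.uniform(*cfg.contrast)
    softness = rng.uniform(*cfg.boundary_softness_px)
    # reddish-brown shift whose luminance magnitude equals the contrast
    v = np.array([rng.uniform(0.1, 0.4), -1.0, rng.uniform(-0.9, -0.5)])
    v *= contrast / abs(float(v @ _LUM))
    soft = ndimage.gaussian_filter(support.astype(np.float64), softness)
    interior = max(soft[support].mean(), 0.5)  # compensate blur dilution
    img += (soft / interior)[..., None] * v
    mask |= support
    return {"center": (cy, cx), "axes": (a, b), "exponent": exponent,
            "theta": theta, "contrast": contrast, "softness": softness}


def _add_hair(img, mask, rng):
    h, w = img.shape[:2]
    pts = rng.uniform([0, 0], [h - 1, w - 1], size=(3, 2)).astype(int)
    rr, cc = bezier_curve(pts[0, 0], pts[0, 1], pts[1, 0], pts[1, 1],
                          pts[2, 0], pts[2, 1], weight=rng.uniform(0.5, 2.0),
                          shape=(h, w))
    canvas = np.zeros((h, w), dtype=bool)
    canvas[rr, cc] = True
    canvas = ndimage.binary_dilation(canvas, iterations=int(rng.integers(1, 3)))
    strength = rng.uniform(0.15, 0.35)
    soft = ndimage.gaussian_filter(canvas.astype(np.float64), 0.6)
    soft[mask] = 0.0  # distractors never paint over the lesion support
    img -= (strength * soft)[..., None] * np.array([0.9, 1.0, 1.0])


def _add_spot(img, mask, rng):
    """Sharp-edged dark disc (benign-lesion confuser) avoiding the mask."""
    h, w = img.shape[:2]
    for _ in range(20):
        radius = rng.uniform(2.0, 6.0)
        cy = rng.uniform(radius, h - radius)
        cx = rng.uniform(radius, w - radius)
        rr, cc = disk((cy, cx), radius, shape=(h, w))
        if mask[rr, cc].any():
            continue
        shade = rng.uniform(0.2, 0.4)
        img[rr, cc] -= shade * np.array([0.8, 1.0, 1.0])
        return True
    logger.warning("could not place benign spot away from lesions; skipped")
    return False


def generate_scene(config: SceneConfig, rng=None, patient_tone=None,
                   patient_id=None) -> AnnotatedImage:
    """One synthetic annotated photograph, deterministic given the seed."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    h, w = config.size
    tone = patient_tone if patient_tone is not None else _patient_tone(rng)
    img = _background(h, w, rng, tone, config.texture_amp, config.vignette)
    mask = np.zeros((h, w), dtype=bool)

    n_lesions = int(rng.integers(config.lesion_count[0],
                                 config.lesion_count[1] + 1))
    lesions = []
    for _ in range(n_lesions):
        info = _add_lesion(img, mask, rng, config)
        if info is not None:
            lesions.append(info)
    if len(lesions) < n_lesions:
        logger.warning("placed %d of %d requested lesions",
                       len(lesions), n_lesions)

    for _ in range(int(rng.integers(config.hair_count[0],
                                    config.hair_count[1] + 1))):
        _add_hair(img, mask, rng)
    for _ in range(int(rng.integers(config.spot_count[0],
                                    config.spot_count[1] + 1))):
        _add_spot(img, mask, rng)

    return AnnotatedImage(
        image=to_uint8(img),
        mask=mask.astype(np.uint8),
        patient_id=patient_id or f"synthetic-{config.seed:08d}",
        pixel_scale=config.px_per_mm,
        meta={"lesions": lesions},
    )


def _patient_tone(rng):
    base = np.array([0.78, 0.60, 0.50])
    return base + rng.uniform(-0.05, 0.05, size=3)


def generate_dataset(n_patients: int, images_per_patient: int,
                     config: SceneConfig):
    """Per-patient correlated scenes plus an index table.

    Each patient keeps one base skin tone (with small per-image jitter),
    so patient-level split leakage checks are meaningful.
    """
    if n_patients <= 0 or images_per_patient <= 0:
        raise ValueError("counts must be positive")
    master = np.random.default_rng(config.seed)
    images, rows = [], []
    for p in range(n_patients):
        patient_id = f"P{p:03d}"
        patient_rng = np.random.default_rng(master.integers(2 ** 31))
        tone = _patient_tone(patient_rng)
        for i in range(images_per_patient):
            scene_tone = tone + patient_rng.uniform(-0.01, 0.01, size=3)
            img = generate_scene(config, rng=patient_rng,
                                 patient_tone=scene_tone,
                                 patient_id=patient_id)
            stem = f"{patient_id}_img{i:03d}"
            images.append(img)
            rows.append({"stem": stem, "patient_id": patient_id})
    return images, pd.DataFrame(rows)


def write_dataset(images, index: pd.DataFrame, out_dir) -> None:
    """Write the images/ masks/ index.csv layout the crop pipeline reads."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    for img, stem in zip(images, index["stem"]):
        write_image(out_dir / "images" / f"{stem}.png", img.image)
        write_mask(out_dir / "masks" / f"{stem}.png", img.mask)
    index.to_csv(out_dir / "index.csv", index=False)
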