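"""Crop extraction and patient-level splitting.

Training crops are lesion-centred boxes (one per connected annotated
region) plus translation-augmented boxes whose origins are shifted by
seeded uniform offsets, so the same lesion is seen in varying
perilesional context.  Photographs are first rescaled by 0.5, boxes of
``side`` pixels (default 512) are cut, and each crop is rescaled by 0.5
again to the network input size (default 256).  Data splits assign whole
patients to train/validation/test so no lesion leaks across splits.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotatedImage", "CropSpec", "CropPair", "SplitManifest",
    "rescale_half", "lesion_boxes", "translation_augment", "extract_crops",
    "split_by_patient", "load_dataset", "build_crop_arrays",
]


@dataclass
class AnnotatedImage:
    """An RGB photograph with its binary lesion mask and patient identity."""

    image: np.ndarray          # (h, w, 3) uint8
    mask: np.ndarray           # (h, w) uint8 in {0, 1}
    patient_id: str
    pixel_scale: float | None = None  # pixels per millimetre
    meta: dict | None = None   # generator-side provenance (synthetic scenes)

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape[:2]} and mask {self.mask.shape} "
                "differ in size")
        if not self.patient_id:
            raise ValueError("patient_id must be nonempty")


@dataclass
class CropSpec:
    """A square window: origin (top-left row/col), side, and which
    translation offset produced it (0 = lesion-centred)."""

    origin: tuple
    side: int
    offset_index: int = 0
    region_label: int = 0


@dataclass
class CropPair:
    image: np.ndarray
    mask: np.ndarray
    spec: CropSpec
    patient_id: str = ""


def rescale_half(img: AnnotatedImage) -> AnnotatedImage:
    """Halve the resolution; the mask is resampled nearest-neighbour so
    it stays strictly binary, and the pixel scale is halved with it."""
    h, w = img.mask.shape
    nh, nw = h // 2, w // 2
    image = resize(img.image, (nh, nw), order=1, anti_aliasing=True,
                   preserve_range=True).astype(np.uint8)
    mask = resize(img.mask, (nh, nw), order=0, anti_aliasing=False,
                  preserve_range=True).astype(np.uint8)
    scale = img.pixel_scale / 2.0 if img.pixel_scale else None
    return AnnotatedImage(image=image, mask=mask, patient_id=img.patient_id,
                          pixel_scale=scale)


def _clamp_origin(center, side, shape):
    h, w = shape
    r = int(round(center[0] - side / 2.0))
    c = int(round(center[1] - side / 2.0))
    r = min(max(r, 0), max(h - side, 0))
    c = min(max(c, 0), max(w - side, 0))
    return (r, c)


def lesion_boxes(img: AnnotatedImage, side: int) -> list:
    """One lesion-centred box per connected annotated region.

    The box centre is the region centroid (or the nearest region pixel
    when the centroid falls outside a non-convex region), clamped so the
    window stays inside the image.  Regions are ordered by label, so the
    output is deterministic.
    """
    from .metrics import extract_regions

    h, w = img.mask.shape
    if side > min(h, w):
        raise ValueError(f"box side {side} exceeds image size {(h, w)}")
    regions = extract_regions(img.mask)
    specs = []
    for label, px in enumerate(regions.regions, start=1):
        centroid = px.mean(axis=0)
        cy, cx = int(round(centroid[0])), int(round(centroid[1]))
        if not img.mask[min(cy, img.mask.shape[0] - 1),
                        min(cx, img.mask.shape[1] - 1)]:
            d2 = ((px - centroid) ** 2).sum(axis=1)
            cy, cx = px[int(d2.argmin())]
        origin = _clamp_origin((cy + 0.5, cx + 0.5), side, img.mask.shape)
        specs.append(CropSpec(origin=origin, side=side, offset_index=0,
                              region_label=label))
    return specs


def translation_augment(spec: CropSpec, img: AnnotatedImage, n_offsets: int,
                        max_shift: int | None = None, seed: int = 0,
                        max_retries: int = 50) -> list:
    """Translation boxes around a lesion-centred box.

    Draws ``n_offsets`` seeded uniform shifts in [-max_shift, +max_shift]^2
    (default max_shift = side/4), clamps each shifted box into bounds and
    resamples until the box still intersects the source region; boxes that
    fail after bounded retries are skipped with a warning.
    """
    if n_offsets < 0:
        raise ValueError("n_offsets must be >= 0")
    if max_shift is None:
        max_shift = spec.side // 4
    rng = np.random.default_rng(seed)
    h, w = img.mask.shape
    from .metrics import extract_regions

    regions = extract_regions(img.mask)
    if spec.region_label < 1 or spec.region_label > regions.n:
        raise ValueError(f"spec references region {spec.region_label} "
                         f"but mask has {regions.n}")
    px = regions.regions[spec.region_label - 1]
    out = []
    for k in range(1, n_offsets + 1):
        for _ in range(max_retries):
            dy, dx = rng.integers(-max_shift, max_shift + 1, size=2)
            r = min(max(spec.origin[0] + int(dy), 0), max(h - spec.side, 0))
            c = min(max(spec.origin[1] + int(dx), 0), max(w - spec.side, 0))
            inside = ((px[:, 0] >= r) & (px[:, 0] < r + spec.side)
                      & (px[:, 1] >= c) & (px[:, 1] < c + spec.side))
            if inside.any():
                out.append(CropSpec(origin=(r, c), side=spec.side,
                                    offset_index=k,
                                    region_label=spec.region_label))
                break
        else:
            logger.warning("no valid translation box for region %d offset %d",
                           spec.region_label, k)
    return out


def extract_crops(img: AnnotatedImage, specs, final_side: int) -> list:
    """Cut the specified windows and rescale them to ``final_side``
    (bilinear for the image, nearest-neighbour for the mask)."""
    pairs = []
    h, w = img.mask.shape
    for spec in specs:
        r, c = spec.origin
        if r < 0 or c < 0 or r + spec.side > h or c + spec.side > w:
            raise ValueError(f"crop {spec} exceeds image bounds {(h, w)}")
        im = img.image[r:r + spec.side, c:c + spec.side]
        mk = img.mask[r:r + spec.side, c:c + spec.side]
        if final_side != spec.side:
            im = resize(im, (final_side, final_side), order=1,
                        anti_aliasing=True, preserve_range=True
                        ).astype(np.uint8)
            mk = resize(mk, (final_side, final_side), order=0,
                        anti_aliasing=False, preserve_range=True
                        ).astype(np.uint8)
        pairs.append(CropPair(image=im, mask=mk, spec=spec,
                              patient_id=img.patient_id))
    return pairs


@dataclass
class SplitManifest:
    """patient_id -> split assignment, plus bookkeeping counts."""

    assignment: dict
    seed: int
    counts: dict = field(default_factory=dict)

    def patients(self, split: str):
        return sorted(p for p, s in self.assignment.items() if s == split)

    def validate(self):
        splits = {}
        for p, s in self.assignment.items():
            splits.setdefault(s, set()).add(p)
        names = list(splits)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                common = splits[a] & splits[b]
                if common:
                    raise ValueError(f"patients {common} in both {a} and {b}")
        return True

    def to_json(self, path):
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump({"assignment": self.assignment, "seed": self.seed,
                       "counts": self.counts}, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            d = json.load(fh)
        return cls(assignment=d["assignment"], seed=d["seed"],
                   counts=d.get("counts", {}))


def split_by_patient(images, fractions=(0.8, 0.1, 0.1),
                     seed: int = 0) -> SplitManifest:
    """Seeded assignment of whole patients to train/val/test splits."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    patients = sorted({img.patient_id for img in images})
    names = ("train", "val", "test")[:len(fractions)]
    if len(patients) < len(fractions):
        raise ValueError(
            f"{len(patients)} patients cannot fill {len(fractions)} splits")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(patients))
    counts = [int(round(f * len(patients))) for f in fractions]
    counts[0] = len(patients) - sum(counts[1:])
    # every split gets at least one patient
    for i in range(1, len(counts)):
        if counts[i] == 0:
            counts[i] = 1
            counts[0] -= 1
    assignment = {}
    pos = 0
    for name, cnt in zip(names, counts):
        for p in order[pos:pos + cnt]:
            assignment[p] = name
        pos += cnt
    per_split_images = {
        name: sum(1 for img in images if assignment[img.patient_id] == name)
        for name in names}
    manifest = SplitManifest(assignment=assignment, seed=seed,
                             counts={"patients": dict(zip(names, counts)),
                                     "images": per_split_images})
    manifest.validate()
    return manifest


def load_dataset(root) -> list:
    """Read the images/ masks/ index.csv layout into AnnotatedImages."""
    from .io import read_image, read_mask

    root = Path(root)
    index = pd.read_csv(root / "index.csv", dtype=str)
    images = []
    for row in index.itertuples():
        images.append(AnnotatedImage(
            image=read_image(root / "images" / f"{row.stem}.png"),
            mask=read_mask(root / "masks" / f"{row.stem}.png"),
            patient_id=row.patient_id))
    return images


def build_crop_arrays(images, side, final_side, n_offsets=8, seed=0,
                      augment=True, prescale=True):
    """Run the full crop pipeline over a list of annotated photographs.

    Returns (X, Y, patient_ids): float32 images in [0, 1] of shape
    (n, final_side, final_side, 3) and binary masks (n, final_side,
    final_side, 1).  With ``augment`` off only lesion-centred crops are
    produced (the evaluation setting).
    """
    from .io import to_float

    xs, ys, pids = [], [], []
    for idx, img in enumerate(images):
        work = rescale_half(img) if prescale else img
        if not work.mask.any():
            continue
        specs = lesion_boxes(work, side)
        all_specs = list(specs)
        if augment:
            for spec in specs:
                all_specs.extend(translation_augment(
                    spec, work, n_offsets,
                    seed=seed + 1000 * idx + spec.region_label))
        for pair in extract_crops(work, all_specs, final_side):
            xs.append(to_float(pair.image))
            ys.append(pair.mask.astype(np.float32)[..., None])
            pids.append(img.patient_id)
    if not xs:
        raise ValueError("no crops produced (all masks empty?)")
    return np.stack(xs), np.stack(ys), pids
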