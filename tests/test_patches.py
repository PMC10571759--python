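"""Crop pipeline: rescaling, lesion boxes, translation augmentation,
co-registration, and patient-level splitting."""

import numpy as np
import pytest

from akunet.metrics import extract_regions
from akunet.patches import (AnnotatedImage, CropSpec, build_crop_arrays,
                            extract_crops, lesion_boxes, rescale_half,
                            split_by_patient, translation_augment)


def make_image(mask, patient="p0", scale=5.0):
    img = np.full(mask.shape + (3,), 128, dtype=np.uint8)
    img[mask > 0] = (200, 60, 60)  # unique lesion colour
    return AnnotatedImage(image=img, mask=mask.astype(np.uint8),
                          patient_id=patient, pixel_scale=scale)


def blob_mask(shape, blobs):
    m = np.zeros(shape, dtype=np.uint8)
    for (r, c, s) in blobs:
        m[r:r + s, c:c + s] = 1
    return m


# ---------------------------------------------------------------- rescale

def test_rescale_half_halves_everything():
    img = make_image(blob_mask((64, 96), [(10, 10, 8)]))
    half = rescale_half(img)
    assert half.image.shape == (32, 48, 3)
    assert half.mask.shape == (32, 48)
    assert half.pixel_scale == pytest.approx(2.5)
    assert set(np.unique(half.mask)) <= {0, 1}
    quarter = rescale_half(half)
    assert quarter.image.shape == (16, 24, 3)


def test_rescale_half_on_odd_full_resolution_shape():
    # full-frame photographs have even dimensions; halving is exact
    img = make_image(blob_mask((402, 602), [(100, 100, 40)]))
    half = rescale_half(img)
    assert half.image.shape[:2] == (201, 301)


# ------------------------------------------------------------ lesion boxes

def test_one_box_per_region_centred_on_blob():
    mask = blob_mask((100, 100), [(40, 40, 10)])
    boxes = lesion_boxes(make_image(mask), side=20)
    assert len(boxes) == 1
    (r, c) = boxes[0].origin
    # window centre within half a pixel of the blob centroid (44.5, 44.5)
    assert abs(r + 10 - 44.5) <= 0.5 and abs(c + 10 - 44.5) <= 0.5


@pytest.mark.parametrize("k", [1, 3, 5])
def test_box_count_matches_region_count(k, rng):
    blobs = [(10 + 20 * i, 10 + 15 * i, 4) for i in range(k)]
    mask = blob_mask((100, 100), blobs)
    img = make_image(mask)
    expected = extract_regions(mask).n
    boxes = lesion_boxes(img, side=16)
    assert len(boxes) == expected == k


def test_corner_blob_box_clamped_and_contains_blob():
    mask = blob_mask((60, 60), [(0, 0, 6)])
    boxes = lesion_boxes(make_image(mask), side=20)
    (r, c) = boxes[0].origin
    assert r == 0 and c == 0
    crop = extract_crops(make_image(mask), boxes, final_side=20)[0]
    assert crop.mask.sum() == mask.sum()  # blob fully inside


def test_oversized_box_rejected():
    with pytest.raises(ValueError):
        lesion_boxes(make_image(blob_mask((30, 30), [(5, 5, 4)])), side=64)


# ----------------------------------------------------------- augmentation

def test_translation_augment_deterministic_and_nonempty():
    mask = blob_mask((80, 80), [(30, 30, 8)])
    img = make_image(mask)
    spec = lesion_boxes(img, side=24)[0]
    a = translation_augment(spec, img, n_offsets=5, seed=3)
    b = translation_augment(spec, img, n_offsets=5, seed=3)
    assert [s.origin for s in a] == [s.origin for s in b]
    assert len(a) == 5
    assert translation_augment(spec, img, n_offsets=0, seed=1) == []


def test_every_augmented_crop_intersects_its_lesion():
    """1000 seeded draws: the shifted boxes always keep mask pixels."""
    mask = blob_mask((80, 80), [(10, 50, 6)])
    img = make_image(mask)
    spec = lesion_boxes(img, side=24)[0]
    specs = []
    for seed in range(100):
        specs.extend(translation_augment(spec, img, n_offsets=10, seed=seed))
    assert len(specs) == 1000
    for s in specs:
        crop = img.mask[s.origin[0]:s.origin[0] + 24,
                        s.origin[1]:s.origin[1] + 24]
        assert crop.any()


# ------------------------------------------------------------------ crops

def test_extract_crops_rescale_and_coregistration():
    mask = blob_mask((100, 100), [(40, 40, 12)])
    img = make_image(mask)
    specs = lesion_boxes(img, side=40)
    pairs = extract_crops(img, specs, final_side=20)
    crop = pairs[0]
    assert crop.image.shape == (20, 20, 3) and crop.mask.shape == (20, 20)
    # lesion pixels carry a unique colour: recompute the mask from colours
    recomputed = (crop.image[..., 0] > 180).astype(np.uint8)
    np.testing.assert_array_equal(recomputed, crop.mask)
    # final_side == side leaves the window untouched
    raw = extract_crops(img, specs, final_side=40)[0]
    np.testing.assert_array_equal(
        raw.image, img.image[specs[0].origin[0]:specs[0].origin[0] + 40,
                             specs[0].origin[1]:specs[0].origin[1] + 40])


def test_all_lesion_crop_has_all_ones_mask():
    mask = np.ones((32, 32), dtype=np.uint8)
    img = make_image(mask)
    pairs = extract_crops(img, [CropSpec(origin=(0, 0), side=32)], 16)
    assert pairs[0].mask.all()


# ------------------------------------------------------------------ split

def test_split_counts_determinism_and_no_leakage():
    images = [make_image(blob_mask((40, 40), [(10, 10, 4)]), patient=f"p{i}")
              for i in range(10) for _ in range(2)]
    m1 = split_by_patient(images, (0.8, 0.1, 0.1), seed=4)
    m2 = split_by_patient(images, (0.8, 0.1, 0.1), seed=4)
    assert m1.assignment == m2.assignment
    assert m1.counts["patients"] == {"train": 8, "val": 1, "test": 1}
    m1.validate()
    splits = [set(m1.patients(s)) for s in ("train", "val", "test")]
    assert not (splits[0] & splits[1] or splits[0] & splits[2]
                or splits[1] & splits[2])
    with pytest.raises(ValueError):
        split_by_patient(images[:2], (0.5, 0.25, 0.25), seed=0)


def test_manifest_round_trip(tmp_path):
    images = [make_image(blob_mask((40, 40), [(8, 8, 4)]), patient=f"p{i}")
              for i in range(5)]
    m = split_by_patient(images, (0.6, 0.2, 0.2), seed=1)
    m.to_json(tmp_path / "split.json")
    from akunet.patches import SplitManifest

    back = SplitManifest.from_json(tmp_path / "split.json")
    assert back.assignment == m.assignment


def test_build_crop_arrays_shapes_and_scaling():
    images = [make_image(blob_mask((128, 128), [(40, 40, 16), (90, 20, 10)]),
                         patient=f"p{i}") for i in range(2)]
    x, y, pids = build_crop_arrays(images, side=32, final_side=16,
                                   n_offsets=2, seed=0, augment=True)
    assert x.shape[1:] == (16, 16, 3) and y.shape[1:] == (16, 16, 1)
    assert x.dtype == np.float32 and x.max() <= 1.0
    assert len(pids) == len(x)
    # centred-only mode yields exactly one crop per region
    xc, _, _ = build_crop_arrays(images, side=32, final_side=16,
                                 augment=False)
    assert len(xc) == 4  # 2 regions per image (after 0.5x prescale)
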