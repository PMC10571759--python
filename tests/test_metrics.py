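"""Pixel metrics and region-tolerant scores, checked against a
brute-force pixel/region loop oracle and algebraic identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from akunet.metrics import (adapted_scores, af1, aggregate, dice,
                            evaluate_pair, extract_regions, iou)
from oracles import brute_force_scores


def random_mask(rng, shape=(32, 32), p=0.2):
    return (rng.uniform(size=shape) < p).astype(np.uint8)


# ------------------------------------------------------------- dice / iou

def test_dice_iou_worked_examples():
    a = np.zeros((6, 6), dtype=np.uint8)
    b = np.zeros((6, 6), dtype=np.uint8)
    a[1:3, 1:3] = 1               # 2x2 block
    b[1:3, 2:4] = 1               # shifted one column; overlap 2 px
    assert dice(a, b) == pytest.approx(0.5)
    assert iou(a, b) == pytest.approx(1 / 3)
    assert dice(a, a) == 1.0 and iou(a, a) == 1.0
    disjoint = np.zeros_like(a)
    disjoint[4:6, 4:6] = 1
    assert dice(a, disjoint) == 0.0
    empty = np.zeros_like(a)
    assert dice(empty, empty) == 1.0 and iou(empty, empty) == 1.0


def test_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        dice(np.zeros((3, 3), dtype=np.uint8), np.zeros((4, 4), dtype=np.uint8))


@settings(max_examples=50, deadline=None)
@given(seed=st.integers(0, 10_000), p=st.floats(0.05, 0.6))
def test_dice_iou_identity_and_order(seed, p):
    rng = np.random.default_rng(seed)
    a, b = random_mask(rng, p=p), random_mask(rng, p=p)
    d, j = dice(a, b), iou(a, b)
    assert d >= j
    assert d == pytest.approx(2 * j / (1 + j), abs=1e-12)


# ---------------------------------------------------------------- regions

def test_connectivity_of_diagonal_blobs():
    m = np.zeros((4, 4), dtype=np.uint8)
    m[0, 0] = m[1, 1] = 1          # touch only diagonally
    assert extract_regions(m, connectivity=8).n == 1
    assert extract_regions(m, connectivity=4).n == 2
    assert extract_regions(np.zeros((3, 3), dtype=np.uint8)).n == 0


def test_region_pixels_partition_foreground(rng):
    m = random_mask(rng)
    regions = extract_regions(m)
    assert sum(len(px) for px in regions.regions) == int(m.sum())
    np.testing.assert_array_equal(regions.to_mask(), m.astype(bool))


# ---------------------------------------------------------- adapted scores

def test_af1_harmonic_mean_conventions():
    assert af1(0.96, 0.67) == pytest.approx(2 * 0.96 * 0.67 / (0.96 + 0.67))
    assert af1(0.0, 0.0) == 0.0
    assert np.isnan(af1(float("nan"), 0.5))


def test_pred_covering_one_of_two_regions():
    gt = np.zeros((10, 10), dtype=np.uint8)
    gt[1:3, 1:3] = 1
    gt[6:8, 6:8] = 1
    pred = np.zeros_like(gt)
    pred[1:3, 1:3] = 1
    rep = adapted_scores(extract_regions(gt), pred, gt)
    assert rep.arec == pytest.approx(0.5)
    assert rep.aprec == pytest.approx(1.0)
    assert rep.af1 == pytest.approx(2 / 3)
    assert rep.tpc == 1 and rep.n_regions == 2


def test_single_pixel_hit_gives_full_region_credit():
    """One shared pixel counts the region as found even though the pixel
    overlap (Dice) stays near zero — the region-tolerant design."""
    gt = np.zeros((20, 20), dtype=np.uint8)
    gt[2:18, 2:18] = 1
    pred = np.zeros_like(gt)
    pred[2, 2] = 1
    rep = adapted_scores(extract_regions(gt), pred, gt)
    ref = brute_force_scores(pred, gt)
    assert rep.tpc == ref["tpc"] == 1
    assert rep.arec == 1.0
    assert rep.af1 >= rep.dice
    assert rep.dice < 0.05


def test_inconsistent_region_set_rejected(rng):
    gt = random_mask(rng)
    other = random_mask(rng)
    if np.array_equal(gt, other):
        other[0, 0] ^= 1
    with pytest.raises(ValueError):
        adapted_scores(extract_regions(other), gt, gt)


@pytest.mark.parametrize("connectivity", [4, 8])
def test_adapted_scores_match_brute_force(connectivity):
    rng = np.random.default_rng(99)
    for _ in range(100):
        gt = random_mask(rng, p=rng.uniform(0.05, 0.4))
        pred = random_mask(rng, p=rng.uniform(0.05, 0.4))
        rep = adapted_scores(extract_regions(gt, connectivity), pred, gt)
        ref = brute_force_scores(pred, gt, connectivity)
        assert (rep.tp, rep.fp, rep.fn) == (ref["tp"], ref["fp"], ref["fn"])
        assert rep.tpc == ref["tpc"] and rep.n_regions == ref["n"]
        for key in ("dice", "iou", "arec", "aprec"):
            mine, theirs = getattr(rep, key), ref[key]
            if np.isnan(theirs):
                assert np.isnan(mine)
            else:
                assert mine == pytest.approx(theirs, abs=1e-12)
        assert rep.dice >= rep.iou


def test_growing_prediction_inside_gt_is_monotone(rng):
    gt = random_mask(rng, p=0.3)
    regions = extract_regions(gt)
    pred = np.zeros_like(gt)
    prev_tp, prev_tpc = 0, 0
    fg = np.argwhere(gt)
    for i in range(0, len(fg), max(len(fg) // 10, 1)):
        pred[tuple(fg[i])] = 1
        rep = adapted_scores(regions, pred, gt)
        assert rep.tp >= prev_tp and rep.tpc >= prev_tpc
        prev_tp, prev_tpc = rep.tp, rep.tpc


# ------------------------------------------------------------- evaluation

def test_evaluate_pair_and_conventions(rng):
    gt = random_mask(rng, p=0.3)
    rep = evaluate_pair(gt.astype(np.float32), gt, threshold=0.5)
    assert rep.dice == rep.iou == 1.0
    if rep.n_regions:
        assert rep.af1 == 1.0
    zero = evaluate_pair(np.zeros_like(gt, dtype=np.float32), gt)
    assert zero.dice == 0.0 and zero.iou == 0.0
    assert zero.arec == 0.0 and np.isnan(zero.aprec)
    interior = np.full(gt.shape, 0.5, dtype=np.float32)
    assert evaluate_pair(interior, gt, threshold=0.0).tp + \
        evaluate_pair(interior, gt, threshold=0.0).fp == gt.size
    assert evaluate_pair(interior, gt, threshold=1.0).tp == 0
    with pytest.raises(ValueError):
        evaluate_pair(interior, gt, threshold=1.5)


def test_aggregate_excludes_undefined():
    gt = np.zeros((8, 8), dtype=np.uint8)
    gt[2:4, 2:4] = 1
    hit = evaluate_pair(gt.astype(np.float32), gt)
    miss = evaluate_pair(np.zeros_like(gt, dtype=np.float32), gt)
    agg = aggregate([hit, miss])
    assert agg["n_pairs"] == 2
    assert agg["aprec_undefined"] == 1
    assert agg["aprec"] == pytest.approx(1.0)   # only the defined pair
    assert agg["dice"] == pytest.approx(0.5)
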