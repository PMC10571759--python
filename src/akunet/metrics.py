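"""Segmentation metrics: Dice, IoU, and region-tolerant aRec/aPrec/aF1.

Pixel-overlap scores (Dice, IoU) treat the prediction and ground truth
symmetrically.  The adapted, region-tolerant scores are directional and
were designed for weakly annotated lesions: the ground-truth mask is
decomposed into its N connected annotated regions AK_1..AK_N, a region
counts as detected (TPC_i = 1) as soon as the prediction touches it in
at least one pixel, and

    aRec  = TPC / N
    aPrec = |AK_area intersect AK_pred| / |AK_pred|
    aF1   = 2 * aRec * aPrec / (aRec + aPrec)

so a roughly-outlined lesion that is found at all scores full recall
even when the pixel overlap is poor.  Metrics that would divide by zero
(aRec with no annotated region, aPrec with an empty prediction) are
reported as NaN and excluded from aggregation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "LesionRegionSet", "MetricsReport", "dice", "iou", "af1", "dice_from_iou",
    "extract_regions", "adapted_scores", "evaluate_pair", "aggregate",
    "score_directories",
]

_STRUCT = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


def _as_binary(mask, name="mask"):
    m = np.asarray(mask)
    if m.dtype != bool:
        vals = np.unique(m)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"{name} must be binary (0/1), got values {vals[:5]}")
        m = m.astype(bool)
    return m


def _check_shapes(a, b):
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")


def dice(a, b) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a, b = _as_binary(a, "a"), _as_binary(b, "b")
    _check_shapes(a, b)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def iou(a, b) -> float:
    """Jaccard index |A∩B| / |A∪B|; 1.0 when both masks are empty."""
    a, b = _as_binary(a, "a"), _as_binary(b, "b")
    _check_shapes(a, b)
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union


def dice_from_iou(iou_value: float) -> float:
    """Dice = 2*IoU / (1 + IoU) — the exact algebraic identity between
    the two overlap coefficients."""
    if not 0.0 <= iou_value <= 1.0:
        raise ValueError(f"IoU must lie in [0, 1], got {iou_value}")
    return 2.0 * iou_value / (1.0 + iou_value)


def af1(aprec: float, arec: float) -> float:
    """Harmonic mean of the adapted precision and recall.

    NaN inputs propagate; (0, 0) maps to 0.0 by convention.
    """
    if np.isnan(aprec) or np.isnan(arec):
        return float("nan")
    if aprec == 0.0 and arec == 0.0:
        return 0.0
    return 2.0 * arec * aprec / (arec + aprec)


@dataclass
class LesionRegionSet:
    """Connected annotated regions of a ground-truth mask."""

    regions: list  # list of (n_i, 2) pixel-coordinate arrays
    shape: tuple
    connectivity: int = 8

    @property
    def n(self) -> int:
        return len(self.regions)

    def to_mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        for px in self.regions:
            m[px[:, 0], px[:, 1]] = True
        return m

    def labelled(self) -> np.ndarray:
        lab = np.zeros(self.shape, dtype=np.int32)
        for i, px in enumerate(self.regions, start=1):
            lab[px[:, 0], px[:, 1]] = i
        return lab


def extract_regions(gt, connectivity: int = 8) -> LesionRegionSet:
    """Decompose a binary mask into connected components (deterministic
    raster-scan labelling)."""
    gt = _as_binary(gt, "gt")
    if connectivity not in _STRUCT:
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    lab, n = ndimage.label(gt, structure=_STRUCT[connectivity])
    regions = [np.argwhere(lab == i) for i in range(1, n + 1)]
    return LesionRegionSet(regions=regions, shape=gt.shape,
                           connectivity=connectivity)


@dataclass
class MetricsReport:
    dice: float
    iou: float
    aprec: float
    arec: float
    af1: float
    tp: int
    fp: int
    fn: int
    tpc: int
    n_regions: int

    def to_dict(self):
        return dict(vars(self))


def adapted_scores(gt_regions: LesionRegionSet, pred, gt) -> MetricsReport:
    """All metrics for one (prediction, ground truth) pair.

    ``gt_regions`` must be the connected-region decomposition of ``gt``
    (checked); the per-region hit rule is one shared pixel.
    """
    pred = _as_binary(pred, "pred")
    gt = _as_binary(gt, "gt")
    _check_shapes(pred, gt)
    if gt_regions.shape != gt.shape:
        raise ValueError("gt_regions shape does not match gt")
    region_mask = gt_regions.to_mask()
    if not np.array_equal(region_mask, gt):
        raise ValueError("gt_regions is not the region decomposition of gt")

    tp = int((pred & gt).sum())
    fp = int((pred & ~gt).sum())
    fn = int((~pred & gt).sum())

    tpc = sum(1 for px in gt_regions.regions if pred[px[:, 0], px[:, 1]].any())
    n = gt_regions.n
    pred_area = tp + fp
    arec = tpc / n if n else float("nan")
    aprec = tp / pred_area if pred_area else float("nan")
    return MetricsReport(
        dice=dice(pred, gt), iou=iou(pred, gt),
        aprec=aprec, arec=arec, af1=af1(aprec, arec),
        tp=tp, fp=fp, fn=fn, tpc=tpc, n_regions=n,
    )


def evaluate_pair(pred_prob, gt, threshold: float = 0.5,
                  connectivity: int = 8) -> MetricsReport:
    """Binarise a probability map at ``threshold`` and score it."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    prob = np.asarray(pred_prob, dtype=np.float32)
    if prob.ndim == 3 and prob.shape[-1] == 1:
        prob = prob[..., 0]
    gt = _as_binary(gt, "gt")
    _check_shapes(prob, gt)
    pred = prob >= threshold
    return adapted_scores(extract_regions(gt, connectivity), pred, gt)


def aggregate(reports) -> dict:
    """Unweighted means over pairs where each metric is defined.

    NaN (undefined) entries are excluded; the count of exclusions is
    reported per metric as ``<name>_undefined``.
    """
    out = {"n_pairs": len(reports)}
    for key in ("dice", "iou", "aprec", "arec", "af1"):
        vals = np.array([getattr(r, key) for r in reports], dtype=float)
        defined = ~np.isnan(vals)
        out[key] = float(vals[defined].mean()) if defined.any() else float("nan")
        out[f"{key}_undefined"] = int((~defined).sum())
    return out


def score_directories(pred_dir, gt_dir, threshold=0.5, connectivity=8,
                      out_csv=None, out_json=None):
    """Score matching PNG mask pairs (by filename stem) from two
    directories; returns (per-pair DataFrame, aggregate dict)."""
    from .io import read_mask

    pred_dir, gt_dir = Path(pred_dir), Path(gt_dir)
    rows, reports = [], []
    stems = sorted(p.stem for p in gt_dir.glob("*.png"))
    if not stems:
        raise FileNotFoundError(f"no PNG masks found in {gt_dir}")
    for stem in stems:
        pred_path = pred_dir / f"{stem}.png"
        if not pred_path.exists():
            continue
        pred = read_mask(pred_path)
        gt = read_mask(gt_dir / f"{stem}.png")
        rep = evaluate_pair(pred.astype(np.float32), gt, threshold, connectivity)
        reports.append(rep)
        rows.append({"stem": stem, **rep.to_dict()})
    df = pd.DataFrame(rows)
    agg = aggregate(reports)
    if out_csv:
        df.to_csv(out_csv, index=False)
    if out_json:
        with open(out_json, "w") as fh:
            json.dump(agg, fh, indent=2)
    return df, agg
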