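"""Independent reference implementations used only by tests.

Everything here is written as literal loops in float64, independent of
the package's vectorised code paths, so agreement is a meaningful check.
"""

import math

import numpy as np


def conv_same_literal(x, w):
    """Stride-1 same-padding 2-D convolution by explicit loops."""
    h, ww, cin = x.shape
    k, _, _, cout = w.shape
    p = k // 2
    out = np.zeros((h, ww, cout))
    for i in range(h):
        for j in range(ww):
            for co in range(cout):
                acc = 0.0
                for ki in range(k):
                    for kj in range(k):
                        ii, jj = i + ki - p, j + kj - p
                        if 0 <= ii < h and 0 <= jj < ww:
                            for ci in range(cin):
                                acc += x[ii, jj, ci] * w[ki, kj, ci, co]
                out[i, j, co] = acc
    return out


def _sig(z):
    return 1.0 / (1.0 + np.exp(-z))


def convlstm_step_literal(p, h_prev, c_prev, params):
    """One convLSTM update transcribed gate by gate.

    i = sig(Wxi*P + Whi*H + Wci.c_prev + b_i)
    f = sig(Wxf*P + Whf*H + Wcf.c_prev + b_f)
    c = f.c_prev + i.tanh(Wxc*P + Whc*H + b_c)
    o = sig(Wxo*P + Who*H + Wco.c + b_o)      # peephole on the NEW cell
    H = o.tanh(c)
    """
    i = _sig(conv_same_literal(p, params.w_xi)
             + conv_same_literal(h_prev, params.w_hi)
             + params.w_ci * c_prev + params.b_i)
    f = _sig(conv_same_literal(p, params.w_xf)
             + conv_same_literal(h_prev, params.w_hf)
             + params.w_cf * c_prev + params.b_f)
    c = f * c_prev + i * np.tanh(conv_same_literal(p, params.w_xc)
                                 + conv_same_literal(h_prev, params.w_hc)
                                 + params.b_c)
    o = _sig(conv_same_literal(p, params.w_xo)
             + conv_same_literal(h_prev, params.w_ho)
             + params.w_co * c + params.b_o)
    return o * np.tanh(c), c


def flood_regions(mask, connectivity=8):
    """Connected components by explicit stack-based flood fill."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(mask)
    regions = []
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                stack, px = [(r, c)], []
                seen[r, c] = True
                while stack:
                    y, x = stack.pop()
                    px.append((y, x))
                    for dy, dx in nbrs:
                        yy, xx = y + dy, x + dx
                        if (0 <= yy < h and 0 <= xx < w and mask[yy, xx]
                                and not seen[yy, xx]):
                            seen[yy, xx] = True
                            stack.append((yy, xx))
                regions.append(px)
    return regions


def brute_force_scores(pred, gt, connectivity=8):
    """Dice/IoU/TPC/aRec/aPrec by double loops over pixels and regions."""
    pred = np.asarray(pred, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    tp = fp = fn = 0
    for r in range(pred.shape[0]):
        for c in range(pred.shape[1]):
            if pred[r, c] and gt[r, c]:
                tp += 1
            elif pred[r, c]:
                fp += 1
            elif gt[r, c]:
                fn += 1
    regions = flood_regions(gt, connectivity)
    tpc = 0
    for px in regions:
        if any(pred[y, x] for y, x in px):
            tpc += 1
    n = len(regions)
    dice = 1.0 if (2 * tp + fp + fn) == 0 else 2 * tp / (2 * tp + fp + fn)
    iou = 1.0 if (tp + fp + fn) == 0 else tp / (tp + fp + fn)
    arec = tpc / n if n else float("nan")
    aprec = tp / (tp + fp) if (tp + fp) else float("nan")
    return {"tp": tp, "fp": fp, "fn": fn, "tpc": tpc, "n": n,
            "dice": dice, "iou": iou, "arec": arec, "aprec": aprec}


def superellipse_area(a, b, exponent):
    """Area of |x/a|^p + |y/b|^p <= 1 (closed form via Gamma functions)."""
    g = math.gamma
    return 4.0 * a * b * g(1 + 1 / exponent) ** 2 / g(1 + 2 / exponent)
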