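"""Differentiable array operations (NHWC layout throughout).

Convolutions are stride-1 with "same" zero padding and odd kernel sizes,
implemented by im2col + BLAS matmul; the input gradient is itself a
convolution with the spatially flipped, channel-transposed kernel, so
forward and backward share one code path.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor

__all__ = [
    "add", "sub", "mul", "sigmoid", "tanh", "relu", "concat",
    "slice_channels", "crop2d", "pad2d", "conv2d", "conv_transpose2d_2x2",
    "maxpool2x2", "batch_norm", "bce_mean", "mean",
]


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    g = grad
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b.accumulate_grad(_unbroadcast(g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data - b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b.accumulate_grad(-_unbroadcast(g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b.accumulate_grad(_unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        x.accumulate_grad(g * s * (1.0 - s))

    return Tensor(s, parents=(x,), backward=backward)


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)

    def backward(g):
        x.accumulate_grad(g * (1.0 - t * t))

    return Tensor(t, parents=(x,), backward=backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = np.where(mask, x.data, 0.0).astype(np.float32)

    def backward(g):
        x.accumulate_grad(g * mask)

    return Tensor(out_data, parents=(x,), backward=backward)


def concat(tensors, axis=-1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis if axis >= 0 else g.ndim + axis] = slice(a, b)
                t.accumulate_grad(g[tuple(idx)])

    return Tensor(out_data, parents=tuple(tensors), backward=backward)


def slice_channels(x: Tensor, start: int, stop: int) -> Tensor:
    out_data = x.data[..., start:stop]

    def backward(g):
        full = np.zeros_like(x.data)
        full[..., start:stop] = g
        x.accumulate_grad(full)

    return Tensor(out_data, parents=(x,), backward=backward)


def crop2d(x: Tensor, r0: int, r1: int, c0: int, c1: int) -> Tensor:
    """Spatial window of an NHWC tensor."""
    out_data = x.data[:, r0:r1, c0:c1, :]

    def backward(g):
        full = np.zeros_like(x.data)
        full[:, r0:r1, c0:c1, :] = g
        x.accumulate_grad(full)

    return Tensor(out_data, parents=(x,), backward=backward)


def pad2d(x: Tensor, pads) -> Tensor:
    """Zero-pad an NHWC tensor; pads = (top, bottom, left, right)."""
    top, bottom, left, right = pads
    out_data = np.pad(x.data, ((0, 0), (top, bottom), (left, right), (0, 0)))

    def backward(g):
        h, w = x.data.shape[1:3]
        x.accumulate_grad(g[:, top:top + h, left:left + w, :])

    return Tensor(out_data, parents=(x,), backward=backward)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B,H,W,C) -> (B*H*W, k*k*C) patches of the zero-padded input."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (B,H,W,C,k,k)
    cols = win.transpose(0, 1, 2, 4, 5, 3)              # (B,H,W,k,k,C)
    b, h, w = x.shape[:3]
    return np.ascontiguousarray(cols).reshape(b * h * w, k * k * x.shape[3])


def _conv_raw(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Stride-1 same-padding correlation; w is (k,k,Cin,Cout)."""
    k, _, cin, cout = w.shape
    if k == 1:
        return x @ w.reshape(cin, cout)
    b, h, ww = x.shape[:3]
    cols = _im2col(x, k)
    return (cols @ w.reshape(k * k * cin, cout)).reshape(b, h, ww, cout)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """2-D convolution, stride 1, same padding, odd square kernel."""
    k = w.data.shape[0]
    cin, cout = w.data.shape[2], w.data.shape[3]
    needs_grad = x.requires_grad or w.requires_grad
    cols = None
    if k == 1:
        out_flat = x.data.reshape(-1, cin) @ w.data.reshape(cin, cout)
    else:
        cols = _im2col(x.data, k)  # reused for the weight gradient
        out_flat = cols @ w.data.reshape(k * k * cin, cout)
        if not (needs_grad and w.requires_grad):
            cols = None
    out_data = out_flat.reshape(x.data.shape[:3] + (cout,))
    if b is not None:
        out_data += b.data

    def backward(g):
        if x.requires_grad:
            # input grad = correlation with flipped, channel-swapped kernel
            w_rot = w.data[::-1, ::-1].transpose(0, 1, 3, 2)
            x.accumulate_grad(_conv_raw(g, np.ascontiguousarray(w_rot)))
        if w.requires_grad:
            gf = g.reshape(-1, cout)
            if k == 1:
                dw = x.data.reshape(-1, cin).T @ gf
            else:
                dw = cols.T @ gf
            w.accumulate_grad(dw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b.accumulate_grad(g.sum(axis=(0, 1, 2)))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, parents=parents, backward=backward)


def conv_transpose2d_2x2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Transposed convolution, kernel 2, stride 2 (exact 2x upsampling).

    w has shape (Cin, 2, 2, Cout); each input pixel expands into a 2x2
    output block, so the op is a single matmul plus a reshape.
    """
    bsz, h, ww, cin = x.data.shape
    cout = w.data.shape[3]
    t = (x.data.reshape(-1, cin) @ w.data.reshape(cin, 4 * cout))
    t = t.reshape(bsz, h, ww, 2, 2, cout).transpose(0, 1, 3, 2, 4, 5)
    out_data = np.ascontiguousarray(t).reshape(bsz, 2 * h, 2 * ww, cout)
    if b is not None:
        out_data += b.data

    def backward(g):
        gr = g.reshape(bsz, h, 2, ww, 2, cout).transpose(0, 1, 3, 2, 4, 5)
        gr = np.ascontiguousarray(gr).reshape(-1, 4 * cout)
        if x.requires_grad:
            dx = gr @ w.data.reshape(cin, 4 * cout).T
            x.accumulate_grad(dx.reshape(x.data.shape))
        if w.requires_grad:
            dw = x.data.reshape(-1, cin).T @ gr
            w.accumulate_grad(dw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b.accumulate_grad(g.sum(axis=(0, 1, 2)))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, parents=parents, backward=backward)


def maxpool2x2(x: Tensor) -> Tensor:
    bsz, h, w, c = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 needs even spatial dims, got {h}x{w}")
    xr = x.data.reshape(bsz, h // 2, 2, w // 2, 2, c)
    xr = xr.transpose(0, 1, 3, 2, 4, 5).reshape(bsz, h // 2, w // 2, 4, c)
    idx = xr.argmax(axis=3)
    out_data = np.take_along_axis(xr, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(g):
        gr = np.zeros((bsz, h // 2, w // 2, 4, c), dtype=np.float32)
        np.put_along_axis(gr, idx[:, :, :, None, :], g[:, :, :, None, :], axis=3)
        gr = gr.reshape(bsz, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        x.accumulate_grad(np.ascontiguousarray(gr).reshape(x.data.shape))

    return Tensor(np.ascontiguousarray(out_data), parents=(x,), backward=backward)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, running_mean,
               running_var, training: bool, momentum: float = 0.1,
               eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalisation over (batch, height, width).

    ``running_mean``/``running_var`` are plain arrays updated in place
    during training and used verbatim at inference.
    """
    if training:
        mean = x.data.mean(axis=(0, 1, 2))
        var = x.data.var(axis=(0, 1, 2))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean) * invstd
    out_data = (gamma.data * xhat + beta.data).astype(np.float32)

    def backward(g):
        if gamma.requires_grad:
            gamma.accumulate_grad((g * xhat).sum(axis=(0, 1, 2)))
        if beta.requires_grad:
            beta.accumulate_grad(g.sum(axis=(0, 1, 2)))
        if x.requires_grad:
            gh = g * gamma.data
            if training:
                n = x.data.shape[0] * x.data.shape[1] * x.data.shape[2]
                s1 = gh.sum(axis=(0, 1, 2))
                s2 = (gh * xhat).sum(axis=(0, 1, 2))
                dx = invstd / n * (n * gh - s1 - xhat * s2)
            else:
                dx = gh * invstd
            x.accumulate_grad(dx.astype(np.float32))

    return Tensor(out_data, parents=(x, gamma, beta), backward=backward)


def mean(x: Tensor) -> Tensor:
    out_data = np.asarray(x.data.mean(), dtype=np.float32)
    n = x.data.size

    def backward(g):
        x.accumulate_grad(np.full_like(x.data, float(g) / n))

    return Tensor(out_data, parents=(x,), backward=backward)


def bce_mean(p: Tensor, y: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Pixel-averaged binary cross-entropy, L = -y log p - (1-y) log(1-p).

    Probabilities are clipped to [eps, 1-eps]; pixels clipped away get
    zero gradient (the loss is locally constant there).
    """
    y = np.asarray(y, dtype=np.float32)
    if y.shape != p.data.shape:
        raise ValueError(f"shape mismatch: pred {p.data.shape} vs target {y.shape}")
    pc = np.clip(p.data, eps, 1.0 - eps)
    losses = -(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc))
    out_data = np.asarray(losses.mean(), dtype=np.float32)
    n = y.size

    def backward(g):
        inside = (p.data > eps) & (p.data < 1.0 - eps)
        dp = np.where(inside, (pc - y) / (pc * (1.0 - pc)), 0.0)
        p.accumulate_grad((float(g) / n) * dp.astype(np.float32))

    return Tensor(out_data, parents=(p,), backward=backward)
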