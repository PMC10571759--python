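"""Reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps a float32 ``numpy.ndarray`` together with an
optional gradient and a closure that propagates gradients to its parents.
``Tensor.backward()`` runs the usual topological-order sweep.  The engine
is deliberately small: it supports exactly the operations needed by an
encoder-decoder segmentation network with convolutional-LSTM skip fusion
(convolutions, pooling, batch normalisation, gated recurrences and a
pixel-averaged cross-entropy loss).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter"]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        if not isinstance(data, np.ndarray):
            data = np.asarray(data, dtype=np.float32)
        elif data.dtype != np.float32:
            data = data.astype(np.float32)
        self.data = data
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = tuple(parents) if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def accumulate_grad(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.accumulate_grad(np.asarray(grad, dtype=np.float32))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None

    def detach(self):
        return Tensor(self.data)

    def item(self):
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # operator sugar (thin wrappers over functional ops; imported lazily to
    # avoid a circular module import)
    def __add__(self, other):
        from . import functional as F

        return F.add(self, _as_tensor(other))

    def __mul__(self, other):
        from . import functional as F

        return F.mul(self, _as_tensor(other))

    def __sub__(self, other):
        from . import functional as F

        return F.sub(self, _as_tensor(other))


class Parameter(Tensor):
    """A trainable tensor (always requires gradients)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)
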