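"""Minimal reverse-mode autodiff on NumPy arrays.

Tensors are (C, D, H, W) feature maps or scalars; operations build a
tape that :func:`backward` replays in reverse topological order.  Only
the primitives needed by the segmentation networks are provided.
"""

from __future__ import annotations

from itertools import product
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = ["Tensor", "conv3d", "relu", "sigmoid", "add", "mul", "concat",
           "upsample_nearest", "softmax_channels"]


class Tensor:
    """A node in the computation tape."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, data, parents: Sequence["Tensor"] = (),
                 backward: Optional[Callable[[np.ndarray], None]] = None,
                 requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: Optional[np.ndarray] = None
        self.parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Reverse-mode sweep from this (scalar) tensor."""
        topo: List[Tensor] = []
        seen = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t.parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self) -> None:
        self.grad = None


def _unbroadcast(g: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def conv3d(x: Tensor, w: Tensor, b: Optional[Tensor] = None,
           stride: int = 1, pad: int = 0) -> Tensor:
    """3D cross-correlation: x (Cin,D,H,W) * w (Cout,Cin,k,k,k) + b.

    Implemented as one matmul per kernel offset over shifted views;
    this keeps the working set small compared to a full im2col.
    """
    k = w.data.shape[2]
    cout, cin = w.data.shape[:2]
    s = stride
    xp = np.pad(x.data, ((0, 0),) + ((pad, pad),) * 3) if pad else x.data
    do = (xp.shape[1] - k) // s + 1
    ho = (xp.shape[2] - k) // s + 1
    wo = (xp.shape[3] - k) // s + 1
    n = do * ho * wo
    acc = np.zeros((n, cout), dtype=np.float32)
    offsets = list(product(range(k), repeat=3))
    for i, j, l in offsets:
        xs = xp[:, i:i + s * do:s, j:j + s * ho:s, l:l + s * wo:s]
        acc += xs.reshape(cin, n).T @ w.data[:, :, i, j, l].T
    out = acc.T.reshape(cout, do, ho, wo)
    if b is not None:
        out = out + b.data[:, None, None, None]

    def backward(g: np.ndarray) -> None:
        g2 = g.reshape(cout, n)            # (Cout, N)
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=(1, 2, 3)))
        gw = np.zeros_like(w.data) if w.requires_grad else None
        gxp = np.zeros_like(xp) if x.requires_grad else None
        for i, j, l in offsets:
            sl = (slice(None), slice(i, i + s * do, s),
                  slice(j, j + s * ho, s), slice(l, l + s * wo, s))
            if gw is not None:
                xs = xp[sl].reshape(cin, n)
                gw[:, :, i, j, l] = g2 @ xs.T
            if gxp is not None:
                gxp[sl] += (w.data[:, :, i, j, l].T @ g2).reshape(
                    cin, do, ho, wo)
        if gw is not None:
            w.accumulate(gw)
        if gxp is not None:
            x.accumulate(gxp[:, pad:xp.shape[1] - pad,
                             pad:xp.shape[2] - pad,
                             pad:xp.shape[3] - pad] if pad else gxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out, parents, backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = x.data * mask

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x.accumulate(g * mask)

    return Tensor(out, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x.accumulate(g * y * (1.0 - y))

    return Tensor(y, (x,), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.data.shape))

    return Tensor(out, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data * b.data

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * a.data, b.data.shape))

    return Tensor(out, (a, b), backward)


def concat(tensors: Sequence[Tensor]) -> Tensor:
    """Concatenate along the channel axis."""
    out = np.concatenate([t.data for t in tensors], axis=0)
    splits = np.cumsum([t.data.shape[0] for t in tensors])[:-1]

    def backward(g: np.ndarray) -> None:
        for t, gp in zip(tensors, np.split(g, splits, axis=0)):
            if t.requires_grad:
                t.accumulate(gp)

    return Tensor(out, tuple(tensors), backward)


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    f = factor
    out = (x.data.repeat(f, axis=1).repeat(f, axis=2).repeat(f, axis=3))

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            c, d, h, w = x.data.shape
            x.accumulate(
                g.reshape(c, d, f, h, f, w, f).sum(axis=(2, 4, 6)))

    return Tensor(out, (x,), backward)


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor,
                  eps: float = 1e-5) -> Tensor:
    """Per-channel normalization over the spatial axes with learnable
    scale/shift; stabilizes optimization of the deep 3D stacks."""
    mu = x.data.mean(axis=(1, 2, 3), keepdims=True)
    var = x.data.var(axis=(1, 2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = gamma.data[:, None, None, None] * xhat + beta.data[:, None, None, None]

    def backward(g: np.ndarray) -> None:
        if beta.requires_grad:
            beta.accumulate(g.sum(axis=(1, 2, 3)))
        if gamma.requires_grad:
            gamma.accumulate((g * xhat).sum(axis=(1, 2, 3)))
        if x.requires_grad:
            gy = g * gamma.data[:, None, None, None]
            m1 = gy.mean(axis=(1, 2, 3), keepdims=True)
            m2 = (gy * xhat).mean(axis=(1, 2, 3), keepdims=True)
            x.accumulate(inv * (gy - m1 - xhat * m2))

    return Tensor(out, (x, gamma, beta), backward)


def softmax_channels(x: Tensor) -> Tensor:
    """Softmax over the class/channel axis (axis 0)."""
    z = x.data - x.data.max(axis=0, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=0, keepdims=True)

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            dot = (g * y).sum(axis=0, keepdims=True)
            x.accumulate(y * (g - dot))

    return Tensor(y, (x,), backward)
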