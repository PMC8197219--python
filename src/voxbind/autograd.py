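"""Minimal reverse-mode autograd over numpy arrays.

Just enough machinery for a 3D fully-convolutional segmentation network:
stride-1 'same' convolutions (kernel 1 or 3) via im2col, MISH, channel
concatenation, factor-2 average pooling and nearest-neighbour upsampling,
spatial zero-padding/cropping and a numerically safe binary cross-entropy
on logits.  Arrays are channel-first ``(C, X, Y, Z)`` float32 and graphs
are built per forward pass.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

__all__ = [
    "Tensor", "conv3d", "mish", "sigmoid", "concat", "avg_pool3d",
    "upsample_nearest3d", "pad_spatial", "crop_spatial", "bce_with_logits",
]


class Tensor:
    """A numpy array plus its gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            order.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(order):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self) -> None:
        self.grad = None


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    out._parents = tuple(p for p in parents if isinstance(p, Tensor))
    out._backward = backward
    return out


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(C, X, Y, Z) -> (X*Y*Z, C*k^3) patches with zero 'same' padding."""
    if k == 1:
        c = x.shape[0]
        return x.reshape(c, -1).T
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))  # (C,X,Y,Z,k,k,k)
    c = x.shape[0]
    n = x.shape[1] * x.shape[2] * x.shape[3]
    return win.transpose(1, 2, 3, 0, 4, 5, 6).reshape(n, c * k**3)


def conv3d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """'Same' stride-1 convolution; ``w`` is (C_out, C_in, k, k, k)."""
    cout, cin, k, _, _ = w.shape
    if x.shape[0] != cin:
        raise ValueError(f"conv3d: input has {x.shape[0]} channels, weight expects {cin}")
    sx, sy, sz = x.shape[1:]
    cols = _im2col(x.data, k)  # (N, cin*k^3)
    wm = w.data.reshape(cout, -1)
    out = cols @ wm.T + b.data  # (N, cout)
    out = out.T.reshape(cout, sx, sy, sz)

    def backward(g: np.ndarray) -> None:
        gmat = g.reshape(cout, -1).T  # (N, cout)
        if w.requires_grad:
            # patches are recomputed rather than cached: with ~30 conv nodes
            # alive per graph, holding every im2col matrix would dominate
            # peak memory on larger grids
            w._accumulate((gmat.T @ _im2col(x.data, k)).reshape(w.shape))
        if b.requires_grad:
            b._accumulate(gmat.sum(axis=0))
        if x.requires_grad or x._parents:
            # full correlation of the output grad with the flipped kernel
            wf = np.flip(w.data, axis=(2, 3, 4)).transpose(1, 0, 2, 3, 4).reshape(cin, -1)
            gcols = _im2col(g.reshape(cout, sx, sy, sz), k)
            dx = (gcols @ wf.T).T.reshape(cin, sx, sy, sz)
            x._accumulate(dx)

    return _node(out, (x, w, b), backward)


def mish(x: Tensor) -> Tensor:
    """x * tanh(softplus(x)), evaluated stably."""
    xd = x.data
    sp = np.logaddexp(0.0, xd)  # softplus
    t = np.tanh(sp)
    out = xd * t

    def backward(g: np.ndarray) -> None:
        sig = expit(xd)
        grad = t + xd * (1.0 - t * t) * sig
        x._accumulate(g * grad)

    return _node(out, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    s = expit(x.data)

    def backward(g: np.ndarray) -> None:
        x._accumulate(g * s * (1.0 - s))

    return _node(s, (x,), backward)


def concat(tensors: list[Tensor]) -> Tensor:
    """Concatenate along the channel (first) axis."""
    sizes = [t.shape[0] for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=0)

    def backward(g: np.ndarray) -> None:
        off = 0
        for t, c in zip(tensors, sizes):
            t._accumulate(g[off:off + c])
            off += c

    return _node(out, tuple(tensors), backward)


def avg_pool3d(x: Tensor, f: int = 2) -> Tensor:
    c, sx, sy, sz = x.shape
    if sx % f or sy % f or sz % f:
        raise ValueError(f"avg_pool3d: spatial dims {x.shape[1:]} not divisible by {f}")
    xr = x.data.reshape(c, sx // f, f, sy // f, f, sz // f, f)
    out = xr.mean(axis=(2, 4, 6))

    def backward(g: np.ndarray) -> None:
        gx = np.repeat(np.repeat(np.repeat(g, f, axis=1), f, axis=2), f, axis=3)
        x._accumulate(gx / f**3)

    return _node(out, (x,), backward)


def upsample_nearest3d(x: Tensor, f: int = 2) -> Tensor:
    out = np.repeat(np.repeat(np.repeat(x.data, f, axis=1), f, axis=2), f, axis=3)

    def backward(g: np.ndarray) -> None:
        c, sx, sy, sz = x.shape
        gr = g.reshape(c, sx, f, sy, f, sz, f).sum(axis=(2, 4, 6))
        x._accumulate(gr)

    return _node(out, (x,), backward)


def pad_spatial(x: Tensor, target: tuple[int, int, int]) -> Tensor:
    """Zero-pad the spatial dims up to ``target`` (appended at the high end)."""
    c, sx, sy, sz = x.shape
    tx, ty, tz = target
    out = np.zeros((c, tx, ty, tz), dtype=np.float32)
    out[:, :sx, :sy, :sz] = x.data

    def backward(g: np.ndarray) -> None:
        x._accumulate(g[:, :sx, :sy, :sz])

    return _node(out, (x,), backward)


def crop_spatial(x: Tensor, target: tuple[int, int, int]) -> Tensor:
    tx, ty, tz = target
    out = x.data[:, :tx, :ty, :tz]

    def backward(g: np.ndarray) -> None:
        gx = np.zeros_like(x.data)
        gx[:, :tx, :ty, :tz] = g
        x._accumulate(gx)

    return _node(out.copy(), (x,), backward)


def bce_with_logits(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw logits (numerically stable)."""
    z = logits.data
    y = np.asarray(target, dtype=np.float32)
    if y.shape != z.shape:
        raise ValueError(f"bce: logits {z.shape} vs target {y.shape}")
    # log(1 + e^z) - z*y, the stable elementwise form
    loss = np.logaddexp(0.0, z) - z * y
    out = np.array(loss.mean(), dtype=np.float32)

    def backward(g: np.ndarray) -> None:
        p = expit(z)
        logits._accumulate(g * (p - y) / y.size)

    return _node(out, (logits,), backward)
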