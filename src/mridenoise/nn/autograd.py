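"""Minimal reverse-mode automatic differentiation over numpy arrays.

The denoising networks in this package are small (desk-scale U-Nets and
shift-convolution blindspot stacks), so a compact, fully-inspectable tape
of numpy operations is sufficient: every op stores a closure that maps the
output gradient back onto its parents, and :meth:`Tensor.backward` walks
the tape in reverse topological order.  All arithmetic is float64.

Only the operations the networks and losses need are implemented:
broadcast arithmetic, log/softplus/leaky-ReLU, reductions, valid 2-D
convolution, zero/reflect padding, 2x2 max-pooling, nearest-neighbour
upsampling, spatial rotation, channel concatenation and slicing.  Each op
is covered by a finite-difference gradient check in the test suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "cat",
    "conv2d",
    "leaky_relu",
    "log",
    "maxpool2x2",
    "pad2d",
    "rot90",
    "softplus",
    "upsample2x",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- tape -------------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (defaults to d(self)/d(self)=1)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor(-self.data, parents=(self,), backward=bwd)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __pow__(self, p: float):
        out_data = self.data**p

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other**-1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self**-1.0

    # -- reductions -------------------------------------------------------

    def sum(self):
        def bwd(g):
            if self.requires_grad:
                self._accumulate(np.broadcast_to(g, self.data.shape))

        return Tensor(self.data.sum(), parents=(self,), backward=bwd)

    def mean(self):
        n = self.data.size

        def bwd(g):
            if self.requires_grad:
                self._accumulate(np.broadcast_to(g / n, self.data.shape))

        return Tensor(self.data.mean(), parents=(self,), backward=bwd)

    def reshape(self, *shape):
        orig = self.data.shape

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(orig))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bwd)

    def __getitem__(self, key):
        out_data = self.data[key]

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accumulate(full)

        return Tensor(out_data, parents=(self,), backward=bwd)


# -- elementwise functions ------------------------------------------------


def log(x: Tensor) -> Tensor:
    def bwd(g):
        if x.requires_grad:
            x._accumulate(g / x.data)

    return Tensor(np.log(x.data), parents=(x,), backward=bwd)


def leaky_relu(x: Tensor, alpha: float = 0.1) -> Tensor:
    slope = np.where(x.data > 0, 1.0, alpha)

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * slope)

    return Tensor(x.data * slope, parents=(x,), backward=bwd)


def softplus(x: Tensor) -> Tensor:
    """log(1 + e^x), numerically stable; derivative is the sigmoid."""
    out_data = np.logaddexp(0.0, x.data)
    sig = 1.0 / (1.0 + np.exp(-x.data))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * sig)

    return Tensor(out_data, parents=(x,), backward=bwd)


# -- structural ops (NCHW layout) -----------------------------------------


def pad2d(x: Tensor, top: int, bottom: int, left: int, right: int, mode: str = "zero") -> Tensor:
    """Pad the two trailing (spatial) axes. mode: 'zero' or 'reflect'."""
    pads = [(0, 0)] * (x.data.ndim - 2) + [(top, bottom), (left, right)]
    if mode == "zero":
        out_data = np.pad(x.data, pads)

        def bwd(g):
            if x.requires_grad:
                sl = (Ellipsis,) + (
                    slice(top, g.shape[-2] - bottom),
                    slice(left, g.shape[-1] - right),
                )
                x._accumulate(g[sl])

    elif mode == "reflect":
        out_data = np.pad(x.data, pads, mode="reflect")
        h, w = x.data.shape[-2:]
        idx = np.arange(h * w).reshape(h, w)
        idx_pad = np.pad(idx, [(top, bottom), (left, right)], mode="reflect").ravel()

        def bwd(g):
            if x.requires_grad:
                lead = g.shape[:-2]
                acc = np.zeros(lead + (h * w,))
                np.add.at(acc, (Ellipsis, idx_pad), g.reshape(lead + (-1,)))
                x._accumulate(acc.reshape(x.data.shape))

    else:  # pragma: no cover - guarded by callers
        raise ValueError(f"unknown pad mode {mode!r}")
    return Tensor(out_data, parents=(x,), backward=bwd)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Valid cross-correlation: x (N,C,H,W) * weight (O,C,kh,kw) -> (N,O,H',W').

    Padding is the caller's job (see :func:`pad2d`), which is what lets the
    blindspot layers use asymmetric causal padding.
    """
    xd, wd = x.data, weight.data
    kh, kw = wd.shape[-2:]
    n, _, hin, win = xd.shape
    ho, wo = hin - kh + 1, win - kw + 1
    # one GEMM per kernel tap on plain array slices: much cheaper than
    # materializing the full (N,C,Ho,Wo,kh,kw) window tensor
    acc = None
    for i in range(kh):
        for j in range(kw):
            term = np.tensordot(
                xd[:, :, i : i + ho, j : j + wo], wd[:, :, i, j], axes=([1], [1])
            )  # N,Ho,Wo,O
            acc = term if acc is None else acc + term
    out_data = np.ascontiguousarray(acc.transpose(0, 3, 1, 2))
    if bias is not None:
        out_data += bias.data[None, :, None, None]

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bwd(g):
        if weight.requires_grad:
            dw = np.empty_like(wd)
            for i in range(kh):
                for j in range(kw):
                    dw[:, :, i, j] = np.tensordot(
                        g, xd[:, :, i : i + ho, j : j + wo], axes=([0, 2, 3], [0, 2, 3])
                    )
            weight._accumulate(dw)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dx = np.zeros_like(xd)
            for i in range(kh):
                for j in range(kw):
                    # dx slice gathers g spread back through tap (i, j)
                    dx[:, :, i : i + ho, j : j + wo] += np.tensordot(
                        g, wd[:, :, i, j], axes=([1], [0])
                    ).transpose(0, 3, 1, 2)
            x._accumulate(dx)

    return Tensor(out_data, parents=parents, backward=bwd)


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; spatial dims must be even."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 requires even spatial dimensions")
    blocks = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = blocks.reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        if x.requires_grad:
            dflat = np.zeros_like(flat)
            np.put_along_axis(dflat, idx[..., None], g[..., None], axis=-1)
            dx = dflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            x._accumulate(dx.reshape(n, c, h, w))

    return Tensor(out_data, parents=(x,), backward=bwd)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling of the spatial axes."""
    out_data = x.data.repeat(2, axis=-2).repeat(2, axis=-1)

    def bwd(g):
        if x.requires_grad:
            n, c, h2, w2 = g.shape
            gsum = g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
            x._accumulate(gsum)

    return Tensor(out_data, parents=(x,), backward=bwd)


def rot90(x: Tensor, k: int) -> Tensor:
    """Rotate the spatial axes by k*90 degrees."""
    out_data = np.rot90(x.data, k, axes=(-2, -1)).copy()

    def bwd(g):
        if x.requires_grad:
            x._accumulate(np.rot90(g, -k, axes=(-2, -1)))

    return Tensor(out_data, parents=(x,), backward=bwd)


def cat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    return Tensor(out_data, parents=tuple(tensors), backward=bwd)
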