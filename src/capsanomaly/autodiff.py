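"""Minimal reverse-mode automatic differentiation over numpy arrays.

The capsule network and the autoencoding baselines in this package are small
(a few thousand parameters, images of ~16x16), so they are trained with a
compact tape-based autodiff engine instead of a full deep-learning framework.
The engine supports exactly the operations the models need: broadcasting
arithmetic, two-operand einsum (which also powers the convolutions via
im2col), reductions, and a handful of pointwise nonlinearities.

Gradients are accumulated by topological traversal of the tape; every
primitive's backward rule is checked against central finite differences in
the test suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "einsum", "im2col", "conv2d", "softmax", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _prev: Sequence["Tensor"] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._prev = tuple(_prev)
        self._backward = _backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, self.requires_grad or other.requires_grad,
                     (self, other))

        def back(g):
            if self.requires_grad or self._prev:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad or other._prev:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = back
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, self.requires_grad or other.requires_grad,
                     (self, other))

        def back(g):
            if self.requires_grad or self._prev:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad or other._prev:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = back
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, self.requires_grad or other.requires_grad,
                     (self, other))

        def back(g):
            if self.requires_grad or self._prev:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad or other._prev:
                other._accumulate(_unbroadcast(-g * self.data / other.data ** 2, other.shape))

        out._backward = back
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, self.requires_grad or other.requires_grad,
                     (self, other))

        def back(g):
            if self.requires_grad or self._prev:
                self._accumulate(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape))
            if other.requires_grad or other._prev:
                other._accumulate(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape))

        out._backward = back
        return out

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.shape))
        return out

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def back(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        out._backward = back
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))

        def back(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = back
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ------------------------------------------------------------- pointwise
    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    def elu(self, alpha: float = 1.0):
        pos = self.data > 0
        neg_val = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        out = Tensor(np.where(pos, self.data, neg_val), self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(g * np.where(pos, 1.0, neg_val + alpha))
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(g * s * (1.0 - s))
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(g * e)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def sqrt(self):
        r = np.sqrt(self.data)
        out = Tensor(r, self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(g * 0.5 / r)
        return out


def einsum(spec: str, a: Tensor, b: Tensor) -> Tensor:
    """Two-operand einsum with autodiff.

    Valid for specs without repeated indices inside one operand and where
    every contracted index appears in both operands (all uses here qualify).
    """
    a, b = Tensor._lift(a), Tensor._lift(b)
    ins, out_sub = spec.replace(" ", "").split("->")
    sub_a, sub_b = ins.split(",")
    out = Tensor(np.einsum(spec, a.data, b.data), a.requires_grad or b.requires_grad, (a, b))

    def back(g):
        if a.requires_grad or a._prev:
            a._accumulate(np.einsum(f"{out_sub},{sub_b}->{sub_a}", g, b.data))
        if b.requires_grad or b._prev:
            b._accumulate(np.einsum(f"{out_sub},{sub_a}->{sub_b}", g, a.data))

    out._backward = back
    return out


def _im2col_index(c: int, h: int, w: int, kh: int, kw: int, sh: int, sw: int):
    oh = (h - kh) // sh + 1
    ow = (w - kw) // sw + 1
    i0 = np.repeat(np.arange(kh), kw)
    i0 = np.tile(i0, c)
    i1 = sh * np.repeat(np.arange(oh), ow)
    j0 = np.tile(np.arange(kw), kh * c)
    j1 = sw * np.tile(np.arange(ow), oh)
    i = i0.reshape(-1, 1) + i1.reshape(1, -1)  # (c*kh*kw, oh*ow)
    j = j0.reshape(-1, 1) + j1.reshape(1, -1)
    k = np.repeat(np.arange(c), kh * kw).reshape(-1, 1)
    return k, i, j, oh, ow


def im2col(x: Tensor, kernel: tuple[int, int], stride: tuple[int, int]) -> Tensor:
    """Unfold (B, C, H, W) into (B, C*kh*kw, oh*ow) patches (valid padding)."""
    b, c, h, w = x.shape
    kh, kw = kernel
    sh, sw = stride
    k, i, j, oh, ow = _im2col_index(c, h, w, kh, kw, sh, sw)
    cols = x.data[:, k, i, j]  # (B, C*kh*kw, oh*ow)
    out = Tensor(cols, x.requires_grad, (x,))

    def back(g):
        dx = np.zeros_like(x.data)
        np.add.at(dx, (slice(None), k, i, j), g)
        x._accumulate(dx)

    out._backward = back
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None,
           stride: tuple[int, int] = (1, 1)) -> Tensor:
    """Valid-padding 2D convolution. x: (B,C,H,W); weight: (F,C,kh,kw)."""
    f, c, kh, kw = weight.shape
    b, xc, h, w = x.shape
    if xc != c:
        raise ValueError(f"channel mismatch: input has {xc}, kernel expects {c}")
    sh, sw = stride
    oh = (h - kh) // sh + 1
    ow = (w - kw) // sw + 1
    if oh < 1 or ow < 1:
        raise ValueError(f"kernel {kh}x{kw} does not fit input {h}x{w}")
    cols = im2col(x, (kh, kw), stride)               # (B, C*kh*kw, L)
    wmat = weight.reshape(f, c * kh * kw)            # (F, K)
    out = einsum("fk,bkl->bfl", wmat, cols).reshape(b, f, oh, ow)
    if bias is not None:
        out = out + bias.reshape(1, f, 1, 1)
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x + Tensor(-x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))

    def back(g):
        pieces = np.split(g, len(tensors), axis=axis)
        for t, p in zip(tensors, pieces):
            if t.requires_grad or t._prev:
                t._accumulate(np.squeeze(p, axis=axis))

    out._backward = back
    return out


class Adam:
    """Adam optimizer over a list of Tensors."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
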