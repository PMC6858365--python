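"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for small convolutional networks trained on the
CPU: broadcasting elementwise arithmetic, matmul, reductions, shape ops,
the activations used by the models, and n-dimensional convolution /
transposed convolution primitives with hand-written backward passes
(validated against finite differences in the test suite).

Gradients are accumulated on leaf tensors created with
``requires_grad=True``; ``Tensor.backward()`` runs the tape in reverse
topological order.
"""

from __future__ import annotations

from itertools import product

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    # -- autodiff ------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor") -> None:
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self.grad = (
            np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=self.data.dtype)
        )
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * self.data / other.data**2, other.shape))

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape))

        out._backward = bw
        return out

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g.reshape(self.shape))
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


# ---------------------------------------------------------------------------
# Elementwise functions


def _unary(x: Tensor, value: np.ndarray, grad_fn) -> Tensor:
    out = Tensor(value, _parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * grad_fn(value))

    out._backward = bw
    return out


def exp(x: Tensor) -> Tensor:
    return _unary(x, np.exp(x.data), lambda v: v)


def log(x: Tensor) -> Tensor:
    out = Tensor(np.log(x.data), _parents=(x,))
    out._backward = lambda g: x.requires_grad and x._accumulate(g / x.data)
    return out


def sqrt(x: Tensor) -> Tensor:
    return _unary(x, np.sqrt(x.data), lambda v: 0.5 / v)


def tanh(x: Tensor) -> Tensor:
    return _unary(x, np.tanh(x.data), lambda v: 1.0 - v**2)


def sigmoid(x: Tensor) -> Tensor:
    return _unary(x, 1.0 / (1.0 + np.exp(-x.data)), lambda v: v * (1.0 - v))


def leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, slope * x.data), _parents=(x,))
    out._backward = lambda g: x.requires_grad and x._accumulate(
        g * np.where(mask, 1.0, slope)
    )
    return out


def absolute(x: Tensor) -> Tensor:
    out = Tensor(np.abs(x.data), _parents=(x,))
    out._backward = lambda g: x.requires_grad and x._accumulate(g * np.sign(x.data))
    return out


# ---------------------------------------------------------------------------
# Convolution primitives (channels-first: (N, C, *spatial))


def _pad_spatial(x: np.ndarray, pad: int) -> np.ndarray:
    if pad == 0:
        return x
    width = [(0, 0), (0, 0)] + [(pad, pad)] * (x.ndim - 2)
    return np.pad(x, width)


def _conv_forward_arrays(x: np.ndarray, w: np.ndarray, stride: int, pad: int):
    nd = x.ndim - 2
    kshape = w.shape[2:]
    xp = _pad_spatial(x, pad)
    sp = xp.shape[2:]
    out_sp = tuple((sp[i] - kshape[i]) // stride + 1 for i in range(nd))
    N, C = x.shape[:2]
    K = int(np.prod(kshape))
    P = int(np.prod(out_sp))
    cols = np.empty((N, C, K, P), dtype=x.dtype)
    for ki, offset in enumerate(product(*[range(k) for k in kshape])):
        sl = tuple(slice(offset[i], offset[i] + stride * out_sp[i], stride) for i in range(nd))
        cols[:, :, ki, :] = xp[(slice(None), slice(None)) + sl].reshape(N, C, P)
    cols2 = cols.reshape(N, C * K, P)
    W2 = w.reshape(w.shape[0], C * K)
    y = np.matmul(W2, cols2)  # (N, Cout, P)
    return y.reshape(N, w.shape[0], *out_sp), cols2, out_sp, kshape


def _col2im(gcols: np.ndarray, x_shape, kshape, stride: int, pad: int, dtype):
    nd = len(x_shape) - 2
    N, C = x_shape[:2]
    sp_padded = tuple(x_shape[2 + i] + 2 * pad for i in range(nd))
    out_sp = tuple((sp_padded[i] - kshape[i]) // stride + 1 for i in range(nd))
    gxp = np.zeros((N, C) + sp_padded, dtype=dtype)
    g = gcols.reshape(N, C, int(np.prod(kshape)), *out_sp)
    for ki, offset in enumerate(product(*[range(k) for k in kshape])):
        sl = tuple(slice(offset[i], offset[i] + stride * out_sp[i], stride) for i in range(nd))
        gxp[(slice(None), slice(None)) + sl] += g[:, :, ki]
    if pad:
        core = (slice(None), slice(None)) + tuple(slice(pad, pad + x_shape[2 + i]) for i in range(nd))
        gxp = gxp[core]
    return gxp


def conv_nd(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """n-D cross-correlation; w has shape (Cout, Cin, *kernel)."""
    y, cols2, out_sp, kshape = _conv_forward_arrays(x.data, w.data, stride, pad)
    if b is not None:
        y = y + b.data.reshape((1, -1) + (1,) * len(out_sp))
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, _parents=parents)
    N, Cout = y.shape[:2]

    def bw(g):
        g2 = g.reshape(N, Cout, -1)
        if b is not None and b.requires_grad:
            b._accumulate(g2.sum(axis=(0, 2)))
        if w.requires_grad:
            gW2 = np.matmul(g2, cols2.transpose(0, 2, 1)).sum(axis=0)
            w._accumulate(gW2.reshape(w.shape))
        if x.requires_grad:
            W2 = w.data.reshape(Cout, -1)
            gcols2 = np.matmul(W2.T, g2)
            x._accumulate(_col2im(gcols2, x.shape, kshape, stride, pad, x.data.dtype))

    out._backward = bw
    return out


def conv_transpose_nd(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 2) -> Tensor:
    """n-D transposed convolution; w has shape (Cin, Cout, *kernel), no padding.

    Output spatial size is ``(in - 1) * stride + kernel`` per axis; with
    kernel = stride it is an exact integer upscaling.
    """
    nd = x.ndim - 2
    kshape = w.shape[2:]
    N, Cin = x.shape[:2]
    Cout = w.shape[1]
    in_sp = x.shape[2:]
    out_sp = tuple((in_sp[i] - 1) * stride + kshape[i] for i in range(nd))
    x2 = x.data.reshape(N, Cin, -1)
    y = np.zeros((N, Cout) + out_sp, dtype=x.data.dtype)
    for offset in product(*[range(k) for k in kshape]):
        t = np.einsum("nip,io->nop", x2, w.data[(slice(None), slice(None)) + offset])
        sl = tuple(slice(offset[i], offset[i] + stride * in_sp[i], stride) for i in range(nd))
        y[(slice(None), slice(None)) + sl] += t.reshape((N, Cout) + in_sp)
    if b is not None:
        y += b.data.reshape((1, -1) + (1,) * nd)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, _parents=parents)

    def bw(g):
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0,) + tuple(range(2, 2 + nd))))
        for offset in product(*[range(k) for k in kshape]):
            sl = tuple(slice(offset[i], offset[i] + stride * in_sp[i], stride) for i in range(nd))
            gslice = g[(slice(None), slice(None)) + sl].reshape(N, Cout, -1)
            if w.requires_grad:
                gw = np.einsum("nip,nop->io", x2, gslice)
                if w.grad is None:
                    w.grad = np.zeros_like(w.data)
                w.grad[(slice(None), slice(None)) + offset] += gw
            if x.requires_grad:
                gx = np.einsum("nop,io->nip", gslice, w.data[(slice(None), slice(None)) + offset])
                x._accumulate(gx.reshape(x.shape))

    out._backward = bw
    return out
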