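"""Minimal reverse-mode automatic differentiation on numpy arrays.

The network in this package (1-D convolutions, LSTM cells, attention,
softmax heads) is small enough that a light tape-based engine over
vectorized numpy kernels trains it comfortably on one CPU, and keeping the
engine in-repo makes the analytic-vs-numerical gradient checks first-class
tests rather than trust in an external framework.

Every differentiable value is a :class:`Tensor` holding a float64 array, the
tensors it was computed from, and a closure that accumulates gradients into
those parents. ``Tensor.backward()`` topologically sorts the tape and runs
the closures once each. Gradients follow numpy broadcasting: a parent whose
shape was broadcast receives its gradient summed back to its own shape.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv1d",
    "dropout",
    "maxpool1d",
    "relu",
    "sigmoid",
    "softmax",
    "tanh",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # collapse leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node on the autodiff tape.

    Parameters
    ----------
    data
        Array (or scalar) value; stored as float64.
    parents
        Tensors this value was computed from.
    backward_fn
        Closure called with the output gradient; must accumulate into each
        parent's ``.grad``. ``None`` for leaves.
    requires_grad
        Leaves with ``requires_grad=False`` never receive gradients and are
        treated as constants.
    """

    __slots__ = ("data", "grad", "parents", "_backward_fn", "requires_grad")

    def __init__(
        self,
        data,
        parents: Sequence["Tensor"] = (),
        backward_fn: Callable[[np.ndarray], None] | None = None,
        requires_grad: bool = True,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.parents = tuple(parents)
        self._backward_fn = backward_fn
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in self.parents
        )

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, grad={'set' if self.grad is not None else 'unset'})"

    def _accumulate(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def backward(self) -> None:
        """Run reverse-mode accumulation from this (scalar) tensor."""
        if self.data.size != 1:
            raise ValueError("backward() expects a scalar loss tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can exceed the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward_fn is not None:
                node._backward_fn(node.grad)

    # -- arithmetic -------------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other, requires_grad=False)

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data + other.data, (self, other))
        out._backward_fn = lambda g: (self._accumulate(g), other._accumulate(g))
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, (self,))
        out._backward_fn = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data * other.data, (self, other))
        out._backward_fn = lambda g: (
            self._accumulate(g * other.data),
            other._accumulate(g * self.data),
        )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data / other.data, (self, other))
        out._backward_fn = lambda g: (
            self._accumulate(g / other.data),
            other._accumulate(-g * self.data / other.data**2),
        )
        return out

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data @ other.data, (self, other))

        def backward(g: np.ndarray) -> None:
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 2:
                self._accumulate(g @ b.T)
                other._accumulate(np.outer(a, g))
            elif a.ndim == 2 and b.ndim == 1:
                self._accumulate(np.outer(g, b))
                other._accumulate(a.T @ g)
            else:
                self._accumulate(g @ np.swapaxes(b, -1, -2))
                other._accumulate(np.swapaxes(a, -1, -2) @ g)

        out._backward_fn = backward
        return out

    def square(self) -> "Tensor":
        out = Tensor(self.data**2, (self,))
        out._backward_fn = lambda g: self._accumulate(2.0 * g * self.data)
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def backward(g: np.ndarray) -> None:
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        out._backward_fn = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), (self,))
        out._backward_fn = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes) -> "Tensor":
        axes = axes or None
        out = Tensor(self.data.transpose(axes), (self,))
        inv = np.argsort(axes) if axes else None
        out._backward_fn = lambda g: self._accumulate(g.transpose(inv))
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], (self,))

        def backward(g: np.ndarray) -> None:
            dx = np.zeros_like(self.data)
            np.add.at(dx, idx, g)  # fancy indices may repeat (embedding rows)
            self._accumulate(dx)

        out._backward_fn = backward
        return out


# -- nonlinearities and structured ops -------------------------------------


def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)
    out = Tensor(y, (x,))
    out._backward_fn = lambda g: x._accumulate(g * (1.0 - y**2))
    return out


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(y, (x,))
    out._backward_fn = lambda g: x._accumulate(g * y * (1.0 - y))
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(x.data * mask, (x,))
    out._backward_fn = lambda g: x._accumulate(g * mask)
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, (x,))

    def backward(g: np.ndarray) -> None:
        dot = (g * y).sum(axis=axis, keepdims=True)
        x._accumulate(y * (g - dot))

    out._backward_fn = backward
    return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    parts = list(tensors)
    out = Tensor(np.concatenate([t.data for t in parts], axis=axis), parts)
    sizes = [t.data.shape[axis] for t in parts]
    offsets = np.cumsum([0] + sizes)

    def backward(g: np.ndarray) -> None:
        for t, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    out._backward_fn = backward
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator, train: bool) -> Tensor:
    """Inverted dropout: identity in eval mode, mask/(1-p) scaling in train."""
    if not train or p <= 0.0:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    out = Tensor(x.data * mask, (x,))
    out._backward_fn = lambda g: x._accumulate(g * mask)
    return out


def _im2col(x: np.ndarray, kernel: int, stride: int) -> np.ndarray:
    """View (B, C, L) as (B, C, L_out, K) windows without copying."""
    b, c, length = x.shape
    l_out = (length - kernel) // stride + 1
    sb, sc, sl = x.strides
    return np.lib.stride_tricks.as_strided(
        x, (b, c, l_out, kernel), (sb, sc, sl * stride, sl), writeable=False
    )


def conv1d(x: Tensor, w: Tensor, b: Tensor, stride: int,
           pad: tuple[int, int] = (0, 0)) -> Tensor:
    """1-D cross-correlation with optional zero padding.

    ``x``: (batch, in_channels, length); ``w``: (out_channels, in_channels,
    kernel); ``b``: (out_channels,). Output (batch, out_channels, l_out) with
    ``l_out = (length + pad_lo + pad_hi - kernel)//stride + 1``.
    """
    kernel = w.shape[2]
    pad_lo, pad_hi = pad
    xdata = x.data
    if pad_lo or pad_hi:
        xdata = np.pad(xdata, ((0, 0), (0, 0), (pad_lo, pad_hi)))
    cols = _im2col(xdata, kernel, stride)  # (B, C_in, L_out, K)
    y = np.einsum("bclk,ock->bol", cols, w.data, optimize=True) + b.data[None, :, None]
    out = Tensor(y, (x, w, b))

    def backward(g: np.ndarray) -> None:
        w._accumulate(np.einsum("bol,bclk->ock", g, cols, optimize=True))
        b._accumulate(g.sum(axis=(0, 2)))
        if x.requires_grad:
            dcols = np.einsum("bol,ock->bclk", g, w.data, optimize=True)
            dx = np.zeros_like(xdata)
            l_out = g.shape[2]
            for k in range(kernel):  # fixed k → non-overlapping strided slice
                dx[:, :, k : k + stride * l_out : stride] += dcols[:, :, :, k]
            if pad_lo or pad_hi:
                dx = dx[:, :, pad_lo : dx.shape[2] - pad_hi]
            x._accumulate(dx)

    out._backward_fn = backward
    return out


def maxpool1d(x: Tensor, size: int) -> Tensor:
    """Non-overlapping max pooling over the last axis; trailing remainder dropped."""
    b, c, length = x.shape
    l_out = length // size
    windows = x.data[:, :, : l_out * size].reshape(b, c, l_out, size)
    arg = windows.argmax(axis=3)
    out = Tensor(windows.max(axis=3), (x,))

    def backward(g: np.ndarray) -> None:
        dx = np.zeros_like(x.data)
        dwin = dx[:, :, : l_out * size].reshape(b, c, l_out, size)
        bi, ci, li = np.ogrid[:b, :c, :l_out]
        dwin[bi, ci, li, arg] = g
        x._accumulate(dx)

    out._backward_fn = backward
    return out
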