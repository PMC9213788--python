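"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` together with an optional gradient and
a backward closure.  Calling :meth:`Tensor.backward` on a scalar output walks
the recorded graph in reverse topological order and accumulates gradients into
every reachable tensor with ``requires_grad``.  The op set is deliberately
small: exactly what the point-cloud and time-series branches of the VAE need
(dense algebra, max pooling, gathers for Chamfer losses, 1-D un/fold for
convolutions).  All heavy lifting is vectorised NumPy, so matmul-bound models
run at BLAS speed.

Gradient correctness is asserted against central differences in the test
suite; do not add an op without a matching check there.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np

__all__ = ["Tensor", "Parameter", "no_grad", "is_grad_enabled", "concat", "stack"]

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Disable graph recording (forward-only evaluation)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "_grad_sink")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and is_grad_enabled()
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- graph plumbing -------------------------------------------------------
    def _make(self, data: np.ndarray, parents: Iterable["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        parents = tuple(p for p in parents if isinstance(p, Tensor))
        out = Tensor(data)
        if is_grad_enabled() and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                node._backward_dispatch(g, grads)
            else:
                node._add_grad(g)

    def _backward_dispatch(self, g: np.ndarray, grads: dict[int, np.ndarray]) -> None:
        # Each op's backward closure stores per-parent grads via this hook.
        self._grad_sink = grads  # type: ignore[attr-defined]
        try:
            self._backward(g)  # type: ignore[misc]
        finally:
            del self._grad_sink  # type: ignore[attr-defined]

    def _send(self, parent: "Tensor", g: np.ndarray) -> None:
        if not parent.requires_grad:
            return
        if parent._backward is None and not parent._parents:
            parent._add_grad(g)
        else:
            sink = self._grad_sink  # type: ignore[attr-defined]
            key = id(parent)
            if key in sink:
                sink[key] = sink[key] + g
            else:
                sink[key] = g

    def _add_grad(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            out._send(self, _unbroadcast(g, self.data.shape))
            out._send(other, _unbroadcast(g, other.data.shape))

        out = self._make(out_data, (self, other), backward)
        return out

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            out._send(self, -g)

        out = self._make(-self.data, (self,), backward)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            out._send(self, _unbroadcast(g * other.data, self.data.shape))
            out._send(other, _unbroadcast(g * self.data, other.data.shape))

        out = self._make(out_data, (self, other), backward)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def backward(g):
            out._send(self, _unbroadcast(g / other.data, self.data.shape))
            out._send(other, _unbroadcast(-g * self.data / other.data**2,
                                          other.data.shape))

        out = self._make(out_data, (self, other), backward)
        return out

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            out._send(self, g * p * self.data ** (p - 1))

        out = self._make(out_data, (self,), backward)
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            a, b = self.data, other.data
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            out._send(self, _unbroadcast(ga, a.shape))
            out._send(other, _unbroadcast(gb, b.shape))

        out = self._make(out_data, (self, other), backward)
        return out

    # -- elementwise nonlinearities ------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            out._send(self, g * out_data)

        out = self._make(out_data, (self,), backward)
        return out

    def log(self):
        def backward(g):
            out._send(self, g / self.data)

        out = self._make(np.log(self.data), (self,), backward)
        return out

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            out._send(self, g / (2.0 * out_data))

        out = self._make(out_data, (self,), backward)
        return out

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            out._send(self, g * (1.0 - out_data**2))

        out = self._make(out_data, (self,), backward)
        return out

    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def backward(g):
            out._send(self, g * (out_data > 0))

        out = self._make(out_data, (self,), backward)
        return out

    def elu(self, alpha: float = 1.0):
        pos = self.data > 0
        neg_part = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        out_data = np.where(pos, self.data, neg_part)

        def backward(g):
            out._send(self, g * np.where(pos, 1.0, neg_part + alpha))

        out = self._make(out_data, (self,), backward)
        return out

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            out._send(self, np.broadcast_to(g, self.data.shape).copy())

        out = self._make(out_data, (self,), backward)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int):
        out_data = self.data.max(axis=axis)

        def backward(g):
            # ties (rare for float activations) split the gradient evenly
            mask = self.data == np.expand_dims(out_data, axis)
            counts = mask.sum(axis=axis, keepdims=True)
            full = mask * (np.expand_dims(g, axis) / counts)
            out._send(self, full.astype(self.data.dtype))

        out = self._make(out_data, (self,), backward)
        return out

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g):
            out._send(self, g.reshape(old))

        out = self._make(self.data.reshape(shape), (self,), backward)
        return out

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)

        def backward(g):
            out._send(self, g.transpose(inv))

        out = self._make(self.data.transpose(axes), (self,), backward)
        return out

    def __getitem__(self, key):
        fancy = isinstance(key, (np.ndarray, list)) or (
            isinstance(key, tuple) and any(isinstance(k, (np.ndarray, list)) for k in key))

        def backward(g):
            full = np.zeros_like(self.data)
            if fancy:
                np.add.at(full, key, g)
            else:
                full[key] += g
            out._send(self, full)

        out = self._make(self.data[key], (self,), backward)
        return out

    def take_rows(self, idx: np.ndarray):
        """Gather rows (axis 0); backward scatter-adds. ``idx`` is constant."""
        idx = np.asarray(idx)

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            out._send(self, full)

        out = self._make(self.data[idx], (self,), backward)
        return out

    # -- 1-D un/fold for convolutions ----------------------------------------
    def unfold1d(self, kernel: int, stride: int):
        """(B, C, L) -> (B, L_out, C*kernel) sliding windows."""
        b, c, l = self.data.shape
        l_out = (l - kernel) // stride + 1
        windows = np.lib.stride_tricks.sliding_window_view(self.data, kernel, axis=2)
        windows = windows[:, :, ::stride, :]              # (B, C, L_out, k)
        out_data = windows.transpose(0, 2, 1, 3).reshape(b, l_out, c * kernel)

        def backward(g):
            g4 = g.reshape(b, l_out, c, kernel).transpose(0, 2, 1, 3)
            full = np.zeros_like(self.data)
            for j in range(kernel):
                pos = np.arange(l_out) * stride + j
                np.add.at(full, (slice(None), slice(None), pos), g4[:, :, :, j])
            out._send(self, full)

        out = self._make(np.ascontiguousarray(out_data), (self,), backward)
        return out

    def fold1d(self, out_len: int, kernel: int, stride: int):
        """Overlap-add (B, L_in, C*kernel) -> (B, C, out_len); adjoint of unfold1d."""
        b, l_in, ck = self.data.shape
        c = ck // kernel
        g4 = self.data.reshape(b, l_in, c, kernel).transpose(0, 2, 1, 3)
        out_data = np.zeros((b, c, out_len), dtype=self.data.dtype)
        for j in range(kernel):
            pos = np.arange(l_in) * stride + j
            np.add.at(out_data, (slice(None), slice(None), pos), g4[:, :, :, j])

        def backward(g):
            windows = np.lib.stride_tricks.sliding_window_view(g, kernel, axis=2)
            windows = windows[:, :, ::stride, :]
            gi = windows.transpose(0, 2, 1, 3).reshape(b, l_in, ck)
            out._send(self, np.ascontiguousarray(gi))

        out = self._make(out_data, (self,), backward)
        return out

    def pad1d(self, left: int, right: int):
        """Zero-pad last axis of (B, C, L)."""
        def backward(g):
            out._send(self, g[:, :, left:g.shape[2] - right] if right else g[:, :, left:])

        padded = np.pad(self.data, ((0, 0), (0, 0), (left, right)))
        out = self._make(padded, (self,), backward)
        return out


class Parameter(Tensor):
    """A trainable tensor (always requires grad, even inside ``no_grad``)."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=False)
        self.requires_grad = True


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            out._send(t, p)

    anchor = tensors[0]
    out = anchor._make(out_data, tensors, backward)
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            out._send(t, np.take(g, i, axis=axis))

    anchor = tensors[0]
    out = anchor._make(out_data, tensors, backward)
    return out
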