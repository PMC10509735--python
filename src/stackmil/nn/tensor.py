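"""Reverse-mode automatic differentiation over NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; calling :meth:`Tensor.backward` on a scalar result accumulates gradients
into every upstream tensor created with ``requires_grad=True``.  The op set is
the minimum needed for small convolutional encoders, 1D z-integration,
attention pooling and Grad-CAM: elementwise arithmetic with broadcasting,
matmul, relu/tanh/exp/log, reductions, indexing, concat/stack, and 2D/1D
convolution (in :mod:`stackmil.nn.layers`).
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor", "stack", "concatenate", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "retains_grad")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None
        self.retains_grad = False

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64, copy=True)
        else:
            self.grad = self.grad + grad

    def retain_grad(self) -> "Tensor":
        self.retains_grad = True
        return self

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        grad = np.asarray(grad, dtype=np.float64)

        # topological order via iterative DFS
        order: list[Tensor] = []
        seen: set[int] = set()
        stack_: list[tuple[Tensor, bool]] = [(self, False)]
        while stack_:
            node, processed = stack_.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack_.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack_.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): grad}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            is_leaf = node._backward is None
            if is_leaf or node.retains_grad:
                node._accumulate(g)
            if node._backward is not None:
                node._backward_into(g, grads)

    def _backward_into(self, g: np.ndarray, grads: dict[int, np.ndarray]) -> None:
        parent_grads = self._backward(g)
        for p, pg in zip(self._parents, parent_grads):
            if not p.requires_grad or pg is None:
                continue
            key = id(p)
            if key in grads:
                grads[key] = grads[key] + pg
            else:
                grads[key] = pg

    def zero_grad(self) -> None:
        self.grad = None

    # -- basic properties ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data.item())

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return np.array(self.data, copy=True)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def backward(g):
            return (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def backward(g):
            return (_unbroadcast(g * b.data, a.data.shape),
                    _unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def backward(g):
            return (_unbroadcast(g / b.data, a.data.shape),
                    _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

        return Tensor._make(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        a = self
        e = float(exponent)

        def backward(g):
            return (g * e * a.data ** (e - 1.0),)

        return Tensor._make(a.data ** e, (a,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self, other
        a_vec, b_vec = a.data.ndim == 1, b.data.ndim == 1

        def backward(g):
            # promote 1-D operands to matrices so one rule covers all cases
            ad = a.data[None, :] if a_vec else a.data
            bd = b.data[:, None] if b_vec else b.data
            g2 = g
            if b_vec:
                g2 = np.expand_dims(g2, -1)
            if a_vec:
                g2 = np.expand_dims(g2, -2)
            ga = g2 @ np.swapaxes(bd, -1, -2)
            gb = np.swapaxes(ad, -1, -2) @ g2
            if a_vec:
                ga = np.squeeze(ga, -2)
            if b_vec:
                gb = np.squeeze(gb, -1)
            return (_unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape))

        return Tensor._make(a.data @ b.data, (a, b), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._make(a.data * mask, (a,), lambda g: (g * mask,))

    def tanh(self):
        a = self
        out = np.tanh(a.data)
        return Tensor._make(out, (a,), lambda g: (g * (1.0 - out ** 2),))

    def exp(self):
        a = self
        out = np.exp(a.data)
        return Tensor._make(out, (a,), lambda g: (g * out,))

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: (g / a.data,))

    def sqrt(self):
        return self ** 0.5

    # -- reductions ------------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, a.data.shape).copy(),)
            g2 = g
            if not keepdims:
                g2 = np.expand_dims(g, axis)
            return (np.broadcast_to(g2, a.data.shape).copy(),)

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Max over one axis; gradient flows to the first argmax (ties)."""
        a = self
        out = a.data.max(axis=axis, keepdims=True)
        mask = (a.data == out)
        # route gradient only to the first maximal entry along the axis
        first = np.cumsum(mask, axis=axis) == 1
        mask = mask & first

        def backward(g):
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (mask * g2,)

        data = out if keepdims else np.squeeze(out, axis=axis)
        return Tensor._make(data, (a,), backward)

    # -- shape ops ---------------------------------------------------------------
    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor._make(a.data.reshape(shape), (a,),
                            lambda g: (g.reshape(a.data.shape),))

    def transpose(self, *axes):
        a = self
        if not axes:
            axes = tuple(reversed(range(a.data.ndim)))
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._make(a.data.transpose(axes), (a,),
                            lambda g: (g.transpose(inv),))

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        a = self

        def backward(g):
            out = np.zeros_like(a.data)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor._make(a.data[idx], (a,), backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        pieces = np.split(g, len(tensors), axis=axis)
        return tuple(np.squeeze(p, axis=axis) for p in pieces)

    return Tensor._make(data, tensors, backward)


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(data, tensors, backward)
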