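"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the vector-quantized autoencoder: broadcasting
arithmetic, matmul (with batched operands), relu, exp/log, softmax and
log-softmax primitives, reductions, reshape/transpose, row gathering for
codebook lookup, and ``detach`` (the stop-gradient operator). Gradients are
accumulated into ``Tensor.grad`` by :meth:`Tensor.backward` via a topological
sort of the recorded tape.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` to undo numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the tape bookkeeping for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple["Tensor", ...] = (),
                 backward: Callable[[Array], None] | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Array | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- helpers ----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _accum(self, grad: Array) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)
        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, self.requires_grad, (self,))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accum(-g)
        out._backward = bwd
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data / other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / other.data ** 2)
        out._backward = bwd
        return out

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accum(g @ np.swapaxes(other.data, -1, -2))
            if other.requires_grad:
                other._accum(np.swapaxes(self.data, -1, -2) @ g)
        out._backward = bwd
        return out

    def square(self) -> "Tensor":
        return self * self

    # -- nonlinearities ---------------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad, (self,))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accum(g * mask)
        out._backward = bwd
        return out

    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), self.requires_grad, (self,))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accum(g * out.data)
        out._backward = bwd
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accum(g / self.data)
        out._backward = bwd
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, self.requires_grad, (self,))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                dot = (g * s).sum(axis=axis, keepdims=True)
                self._accum(s * (g - dot))
        out._backward = bwd
        return out

    def log_softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        ls = z - lse
        out = Tensor(ls, self.requires_grad, (self,))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accum(g - np.exp(ls) * g.sum(axis=axis, keepdims=True))
        out._backward = bwd
        return out

    # -- reductions & shaping ---------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bwd(g: Array) -> None:
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accum(np.asarray(g).reshape(self.data.shape))
        out._backward = bwd
        return out

    def transpose(self, axes: tuple[int, ...]) -> "Tensor":
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        inv = np.argsort(axes)

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accum(np.asarray(g).transpose(inv))
        out._backward = bwd
        return out

    def take_rows(self, idx: Array) -> "Tensor":
        """Gather rows (codebook lookup); backward scatter-adds."""
        idx = np.asarray(idx, dtype=np.intp)
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)
        out._backward = bwd
        return out

    # -- gradient control --------------------------------------------------
    def detach(self) -> "Tensor":
        """Stop-gradient: same value, no gradient flows to the parents."""
        return Tensor(self.data.copy())

    def backward(self) -> None:
        """Accumulate gradients of this (scalar) tensor into the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def straight_through(z_e: Tensor, z_q: Tensor) -> Tensor:
    """Straight-through estimator for the quantization step.

    The forward value equals ``z_q``; on the backward pass the quantization is
    treated as the identity, so the gradient with respect to ``z_e`` equals
    the gradient with respect to the output, and none reaches ``z_q``.
    """
    return z_e + (z_q - z_e).detach()


def parameters_zero_grad(params: Iterable[Tensor]) -> None:
    for p in params:
        p.grad = None
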