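"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The encoder is small (a few hundred thousand parameters at most) and its
layers reduce to a handful of tensor primitives: broadcast add/multiply,
two-operand einsum, ReLU/sigmoid, axis reductions, padding/slicing along
the time axis, channel concatenation, temporal max-pooling and a fused
softmax cross-entropy.  This module implements exactly those primitives
with hand-written vector-Jacobian products and a topological backward
pass.  Everything is deterministic: no threading, no in-place aliasing of
values that participate in the graph.

Gradient correctness is verified against central finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tensor", "parameter"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping an ndarray value."""

    __slots__ = ("value", "grad", "parents", "vjps", "requires_grad")

    def __init__(self, value, requires_grad: bool = False, parents=(), vjps=()):
        self.value = np.asarray(value)
        self.grad: np.ndarray | None = None
        self.parents: tuple[Tensor, ...] = tuple(parents)
        self.vjps = tuple(vjps)  # one callable g -> parent_grad per parent
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    # ------------------------------------------------------------------
    # graph construction helpers
    # ------------------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def __add__(self, other):
        if isinstance(other, (int, float)):
            # keep python scalars weakly typed so float32 graphs stay float32
            return Tensor(self.value + other, parents=(self,), vjps=(lambda g: g,))
        other = Tensor._lift(other)
        return Tensor(
            self.value + other.value,
            parents=(self, other),
            vjps=(
                lambda g: _unbroadcast(g, self.value.shape),
                lambda g: _unbroadcast(g, other.value.shape),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.value, parents=(self,), vjps=(lambda g: -g,))

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return Tensor(
                self.value * other, parents=(self,), vjps=(lambda g: g * other,)
            )
        other = Tensor._lift(other)
        return Tensor(
            self.value * other.value,
            parents=(self, other),
            vjps=(
                lambda g: _unbroadcast(g * other.value, self.value.shape),
                lambda g: _unbroadcast(g * self.value, other.value.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = Tensor._lift(other)
        return Tensor(
            self.value / other.value,
            parents=(self, other),
            vjps=(
                lambda g: _unbroadcast(g / other.value, self.value.shape),
                lambda g: _unbroadcast(
                    -g * self.value / (other.value**2), other.value.shape
                ),
            ),
        )

    def pow_const(self, p: float) -> "Tensor":
        val = self.value**p
        return Tensor(
            val,
            parents=(self,),
            vjps=(lambda g: g * p * self.value ** (p - 1),),
        )

    def relu(self) -> "Tensor":
        mask = self.value > 0
        return Tensor(
            np.where(mask, self.value, 0.0),
            parents=(self,),
            vjps=(lambda g: g * mask,),
        )

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.value))
        return Tensor(s, parents=(self,), vjps=(lambda g: g * s * (1.0 - s),))

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        val = self.value.sum(axis=axis, keepdims=keepdims)
        shape = self.value.shape

        def vjp(g):
            if axis is None:
                return np.broadcast_to(g, shape).copy()
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, tuple(a % len(shape) for a in axes))
            return np.broadcast_to(g, shape).copy()

        return Tensor(val, parents=(self,), vjps=(vjp,))

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.value.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.value.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        orig = self.value.shape
        return Tensor(
            self.value.reshape(*shape),
            parents=(self,),
            vjps=(lambda g: g.reshape(orig),),
        )

    # ------------------------------------------------------------------
    # time-axis (axis 2) structural ops for (N, C, T, V) feature maps
    # ------------------------------------------------------------------
    def pad_time(self, left: int, right: int, value: float = 0.0) -> "Tensor":
        if left == 0 and right == 0:
            return self
        pad = [(0, 0)] * self.value.ndim
        pad[2] = (left, right)
        T = self.value.shape[2]
        val = np.pad(self.value, pad, constant_values=value)

        def vjp(g):
            sl = [slice(None)] * g.ndim
            sl[2] = slice(left, left + T)
            return g[tuple(sl)]

        return Tensor(val, parents=(self,), vjps=(vjp,))

    def slice_time(self, start: int, stop: int, step: int = 1) -> "Tensor":
        sl = [slice(None)] * self.value.ndim
        sl[2] = slice(start, stop, step)
        sl = tuple(sl)
        shape = self.value.shape

        def vjp(g):
            out = np.zeros(shape, dtype=g.dtype)
            out[sl] = g
            return out

        return Tensor(self.value[sl], parents=(self,), vjps=(vjp,))

    def backward(self) -> None:
        """Accumulate gradients of this (scalar) node into the graph."""
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.value)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node.parents:
                node.grad = g if node.grad is None else node.grad + g
            for p, vjp in zip(node.parents, node.vjps):
                if not p.requires_grad:
                    continue
                pg = vjp(g)
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg
            # leaves with parents (shouldn't happen) fall through


def tensor(value, requires_grad: bool = False) -> Tensor:
    return Tensor(np.asarray(value), requires_grad=requires_grad)


def parameter(value) -> Tensor:
    return Tensor(np.asarray(value, dtype=np.float64), requires_grad=True)


# ----------------------------------------------------------------------
# free functions
# ----------------------------------------------------------------------

def einsum2(pattern: str, a: Tensor, b: Tensor) -> Tensor:
    """Two-operand einsum with automatic vector-Jacobian products.

    Constraint: every index of each operand must appear in the output or
    in the other operand (no unsummed marginalisation), which holds for
    all contractions the network uses.
    """
    ins, out = pattern.split("->")
    in1, in2 = ins.split(",")
    val = np.einsum(pattern, a.value, b.value, optimize=True)
    return Tensor(
        val,
        parents=(a, b),
        vjps=(
            lambda g: np.einsum(f"{out},{in2}->{in1}", g, b.value, optimize=True),
            lambda g: np.einsum(f"{in1},{out}->{in2}", a.value, g, optimize=True),
        ),
    )


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.value.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    val = np.concatenate([t.value for t in tensors], axis=axis)

    def make_vjp(i):
        def vjp(g):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(offsets[i], offsets[i + 1])
            return g[tuple(sl)]

        return vjp

    return Tensor(
        val, parents=tuple(tensors), vjps=tuple(make_vjp(i) for i in range(len(tensors)))
    )


def maxpool_time(x: Tensor, window: int = 3, stride: int = 1) -> Tensor:
    """Temporal max pooling with same padding on (N, C, T, V) maps."""
    N, C, T, V = x.value.shape
    out_len = -(-T // stride)  # ceil
    pad_total = window - 1
    left = pad_total // 2
    padded = np.pad(
        x.value,
        ((0, 0), (0, 0), (left, pad_total - left), (0, 0)),
        constant_values=-np.inf,
    )
    # windows: (N, C, out_len, window, V)
    idx = (np.arange(out_len) * stride)[:, None] + np.arange(window)[None, :]
    win = padded[:, :, idx, :]
    arg = win.argmax(axis=3)  # (N, C, out_len, V)
    val = np.take_along_axis(win, arg[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def vjp(g):
        gp = np.zeros_like(padded)
        # source time index in padded array for each output position
        src = (np.arange(out_len) * stride)[None, None, :, None] + arg
        n_i, c_i, _, v_i = np.indices(arg.shape)
        np.add.at(gp, (n_i, c_i, src, v_i), g)
        return gp[:, :, left : left + T, :]

    return Tensor(val, parents=(x,), vjps=(vjp,))


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> tuple[Tensor, np.ndarray]:
    """Mean cross-entropy over a batch; returns (loss, probabilities).

    Fused for numerical stability; the gradient is ``(softmax - onehot)/N``.
    """
    z = logits.value - logits.value.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.value.shape[0]
    ll = -np.log(np.clip(probs[np.arange(n), labels], 1e-300, None))
    loss_val = ll.mean()

    def vjp(g):
        grad = probs.copy()
        grad[np.arange(n), labels] -= 1.0
        return g * grad / n

    loss = Tensor(np.asarray(loss_val), parents=(logits,), vjps=(vjp,))
    return loss, probs
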