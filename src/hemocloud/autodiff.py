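"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the point-cloud feature extractor: broadcast-aware
elementwise arithmetic, batched matrix multiplication, ReLU, exponent/log,
axis reductions (sum, mean, max) and shape ops.  Gradients propagate through a
topologically sorted tape built on the fly; see ``tests/test_autodiff.py`` for
finite-difference checks of every primitive.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(float)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = _prev

    # -- helpers ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- elementwise ------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        return self * self._lift(other).pow(-1.0)

    def __rtruediv__(self, other):
        return self._lift(other) * self.pow(-1.0)

    def pow(self, p: float):
        out = Tensor(self.data**p, self.requires_grad, (self,))

        def backward():
            if self.requires_grad:
                self._accum(out.grad * p * self.data ** (p - 1))

        out._backward = backward
        return out

    def exp(self):
        out = Tensor(np.exp(self.data), self.requires_grad, (self,))

        def backward():
            if self.requires_grad:
                self._accum(out.grad * out.data)

        out._backward = backward
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def backward():
            if self.requires_grad:
                self._accum(out.grad / self.data)

        out._backward = backward
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad, (self,))

        def backward():
            if self.requires_grad:
                self._accum(out.grad * (self.data > 0.0))

        out._backward = backward
        return out

    # -- linear algebra ---------------------------------------------------
    def matmul(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def backward():
            g = out.grad
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        out._backward = backward
        return out

    __matmul__ = matmul

    def swapaxes(self, a: int, b: int):
        out = Tensor(np.swapaxes(self.data, a, b), self.requires_grad, (self,))

        def backward():
            if self.requires_grad:
                self._accum(np.swapaxes(out.grad, a, b))

        out._backward = backward
        return out

    def reshape(self, *shape):
        old = self.shape
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def backward():
            if self.requires_grad:
                self._accum(out.grad.reshape(old))

        out._backward = backward
        return out

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def backward():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Max along one axis; ties split their gradient equally."""
        data = self.data.max(axis=axis, keepdims=True)
        out = Tensor(data if keepdims else np.squeeze(data, axis),
                     self.requires_grad, (self,))

        def backward():
            if self.requires_grad:
                g = out.grad if keepdims else np.expand_dims(out.grad, axis)
                mask = self.data == data
                counts = mask.sum(axis=axis, keepdims=True)
                self._accum(mask * g / counts)

        out._backward = backward
        return out

    # -- graph ------------------------------------------------------------
    def backward(self) -> None:
        """Backpropagate from a scalar output."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: "Tensor") -> None:
            stack = [(node, iter(node._prev))]
            seen.add(id(node))
            while stack:
                cur, it = stack[-1]
                advanced = False
                for child in it:
                    if id(child) not in seen:
                        seen.add(id(child))
                        stack.append((child, iter(child._prev)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(cur)
                    stack.pop()

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()

    def detach(self) -> np.ndarray:
        return self.data.copy()


def relu(x: Tensor) -> Tensor:
    return x.relu()


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5):
    """Fused per-channel batch normalisation over all leading axes.

    Returns (out, batch_mean, batch_var) with mean/var as plain arrays for
    running-statistic updates.  The backward pass uses the closed-form
    batch-norm gradient instead of composing elementwise primitives.
    """
    c = x.data.shape[-1]
    flat = x.data.reshape(-1, c)
    m = flat.shape[0]
    mu = flat.mean(axis=0)
    var = flat.var(axis=0)
    inv_sd = 1.0 / np.sqrt(var + eps)
    x_hat = (flat - mu) * inv_sd
    out_data = (x_hat * gamma.data + beta.data).reshape(x.data.shape)
    out = Tensor(out_data, x.requires_grad or gamma.requires_grad or beta.requires_grad,
                 (x, gamma, beta))

    def backward():
        dy = out.grad.reshape(-1, c)
        if gamma.requires_grad:
            gamma._accum((dy * x_hat).sum(axis=0))
        if beta.requires_grad:
            beta._accum(dy.sum(axis=0))
        if x.requires_grad:
            dxh = dy * gamma.data
            dx = inv_sd * (
                dxh - dxh.mean(axis=0) - x_hat * (dxh * x_hat).mean(axis=0)
            )
            x._accum(dx.reshape(x.data.shape))

    out._backward = backward
    return out, mu, var


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate along one axis."""
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum(sizes)[:-1]

    def backward():
        pieces = np.split(out.grad, offsets, axis=axis)
        for t, g in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(g)

    out._backward = backward
    return out


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of (B, K) logits against integer labels (numerically stable)."""
    labels = np.asarray(labels, dtype=int)
    shift = Tensor(logits.data.max(axis=1, keepdims=True))  # constant shift
    z = logits - shift
    log_norm = z.exp().sum(axis=1, keepdims=True).log()
    logp = z - log_norm
    picked = logp * Tensor(np.eye(logits.shape[1])[labels])
    return -picked.sum() * (1.0 / len(labels))
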