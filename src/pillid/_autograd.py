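"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Provides exactly the operations the package's three models need: dense
layers, gated recurrent units, additive attention and the standard
classification losses.  Tensors record a tape of parent nodes; calling
:meth:`Tensor.backward` on a scalar loss walks the tape in reverse
topological order and accumulates gradients into ``.grad``.

Float32 throughout; gradients of broadcast operands are summed back to the
operand's shape.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

_DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(
        self,
        data,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
        requires_grad: bool = False,
    ):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.grad: np.ndarray | None = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph traversal ---------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
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
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data + other.data, (self, other))

        def back(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.data.shape)

        out._backward = back
        return out

    def __sub__(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data - other.data, (self, other))

        def back(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.data.shape)
            if other.requires_grad:
                other.grad -= _unbroadcast(g, other.data.shape)

        out._backward = back
        return out

    def __mul__(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data * other.data, (self, other))

        def back(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.data.shape)

        out._backward = back
        return out

    def scale(self, k: float) -> "Tensor":
        out = Tensor(self.data * k, (self,))

        def back(g):
            if self.requires_grad:
                self.grad += g * k

        out._backward = back
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, (self, other))

        def back(g):
            if self.requires_grad:
                self.grad += g @ other.data.T
            if other.requires_grad:
                other.grad += self.data.T @ g

        out._backward = back
        return out

    def __getitem__(self, key) -> "Tensor":
        out = Tensor(self.data[key], (self,))

        def back(g):
            if self.requires_grad:
                np.add.at(self.grad, key, g)

        out._backward = back
        return out

    # -- nonlinearities ----------------------------------------------------

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), (self,))

        def back(g):
            if self.requires_grad:
                self.grad += g * (out.data > 0)

        out._backward = back
        return out

    def tanh(self) -> "Tensor":
        out = Tensor(np.tanh(self.data), (self,))

        def back(g):
            if self.requires_grad:
                self.grad += g * (1.0 - out.data * out.data)

        out._backward = back
        return out

    def sigmoid(self) -> "Tensor":
        out = Tensor(_sigmoid(self.data), (self,))

        def back(g):
            if self.requires_grad:
                self.grad += g * out.data * (1.0 - out.data)

        out._backward = back
        return out

    def sum(self) -> "Tensor":
        out = Tensor(self.data.sum(), (self,))

        def back(g):
            if self.requires_grad:
                self.grad += np.full_like(self.data, float(g))

        out._backward = back
        return out


def _sigmoid(x: np.ndarray) -> np.ndarray:
    z = np.exp(-np.abs(x))
    return np.where(x >= 0, 1.0 / (1.0 + z), z / (1.0 + z))


def tensor(data) -> Tensor:
    return Tensor(data)


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t.grad += g[tuple(idx)]

    out._backward = back
    return out


def embedding(weight: Tensor, idx: np.ndarray) -> Tensor:
    """Row lookup weight[idx] with scatter-add gradient."""
    idx = np.asarray(idx)
    out = Tensor(weight.data[idx], (weight,))

    def back(g):
        if weight.requires_grad:
            np.add.at(weight.grad, idx, g)

    out._backward = back
    return out


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    m = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(m)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, (x,))

    def back(g):
        if x.requires_grad:
            dot = (g * s).sum(axis=axis, keepdims=True)
            x.grad += s * (g - dot)

    out._backward = back
    return out


def softmax_cross_entropy(
    logits: Tensor, targets: np.ndarray, weights: np.ndarray | None = None
) -> Tensor:
    """Mean cross-entropy over rows; `weights` masks/weights rows (sum-normalized)."""
    targets = np.asarray(targets, dtype=np.int64)
    n = logits.data.shape[0]
    if weights is None:
        w = np.full(n, 1.0 / n, dtype=_DTYPE)
    else:
        w = np.asarray(weights, dtype=_DTYPE)
        total = w.sum()
        w = w / total if total > 0 else w
    m = logits.data - logits.data.max(axis=1, keepdims=True)
    logz = np.log(np.exp(m).sum(axis=1, keepdims=True))
    logp = m - logz
    losses = -logp[np.arange(n), targets]
    out = Tensor((losses * w).sum(), (logits,))
    probs = np.exp(logp)

    def back(g):
        if logits.requires_grad:
            d = probs.copy()
            d[np.arange(n), targets] -= 1.0
            logits.grad += float(g) * d * w[:, None]

    out._backward = back
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray, weights: np.ndarray | None = None) -> Tensor:
    """Mean binary cross-entropy from logits, optional per-element weights."""
    t = np.asarray(targets, dtype=_DTYPE)
    if weights is None:
        w = np.full(logits.data.shape, 1.0 / logits.data.size, dtype=_DTYPE)
    else:
        w = np.asarray(weights, dtype=_DTYPE)
        total = w.sum()
        w = w / total if total > 0 else w
    x = logits.data
    # stable: max(x,0) - x*t + log(1+exp(-|x|))
    losses = np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))
    out = Tensor((losses * w).sum(), (logits,))
    p = _sigmoid(x)

    def back(g):
        if logits.requires_grad:
            logits.grad += float(g) * (p - t) * w

    out._backward = back
    return out


# -- optimizers ------------------------------------------------------------


class SGD:
    def __init__(self, params: Iterable[Tensor], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.vel = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self.vel):
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v -= self.lr * g
            p.data += v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = np.zeros_like(p.data)


class Adam:
    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = np.zeros_like(p.data)
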