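"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the primitives the graph-transformer encoder and the
contrastive losses need: broadcast-aware arithmetic, matmul, slicing,
concatenation, reductions, exp/log/relu/sqrt, and a numerically stable
masked log-sum-exp.  All data is float64; gradients accumulate into
``Tensor.grad`` after calling :meth:`Tensor.backward` on a scalar.

The engine is deliberately small: a ``Tensor`` records its parents and a
closure that routes the incoming gradient to them, and ``backward`` walks
the graph in reverse topological order.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "softmax", "masked_logsumexp", "layer_norm", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @classmethod
    def _child(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def T(self) -> "Tensor":
        def bw(g, out):
            return (g.T,)

        return Tensor._child(self.data.T, (self,), bw)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor._wrap(other)

        def bw(g, out):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor._child(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g, out):
            return (-g,)

        return Tensor._child(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)

        def bw(g, out):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._child(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._wrap(other)

        def bw(g, out):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor._child(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return Tensor._wrap(other) / self

    def __pow__(self, exponent: float):
        assert np.isscalar(exponent)

        def bw(g, out):
            return (g * exponent * self.data ** (exponent - 1),)

        return Tensor._child(self.data**exponent, (self,), bw)

    def __matmul__(self, other):
        other = Tensor._wrap(other)

        def bw(g, out):
            return (g @ other.data.T, self.data.T @ g)

        return Tensor._child(self.data @ other.data, (self, other), bw)

    def __getitem__(self, idx):
        def bw(g, out):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._child(self.data[idx], (self,), bw)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g, out):
            return (g * out.data,)

        return Tensor._child(out_data, (self,), bw)

    def log(self):
        def bw(g, out):
            return (g / self.data,)

        return Tensor._child(np.log(self.data), (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g, out):
            return (g * 0.5 / out.data,)

        return Tensor._child(out_data, (self,), bw)

    def relu(self):
        def bw(g, out):
            return (g * (self.data > 0),)

        return Tensor._child(np.maximum(self.data, 0.0), (self,), bw)

    # -- reductions / reshapes ------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bw(g, out):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return Tensor._child(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        def bw(g, out):
            return (g.reshape(self.shape),)

        return Tensor._child(self.data.reshape(*shape), (self,), bw)

    # -- autodiff driver ------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad, node)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g


# -- composite ops -------------------------------------------------------------

def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g, out):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._child(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, bw
    )


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # max-subtraction for stability; the shift is a constant w.r.t. autodiff,
    # which is exact because softmax is shift-invariant
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def masked_logsumexp(x: Tensor, mask: np.ndarray, axis: int = -1) -> Tensor:
    """log Σ_{mask=1} exp(x) along `axis`; excluded entries get zero gradient.

    `mask` is a constant {0,1} array broadcastable to x.shape. Rows whose mask
    is entirely zero yield -inf (caller's responsibility to avoid).
    """
    neg = np.where(mask > 0, 0.0, -np.inf)
    shifted_data = x.data + neg
    shift = shifted_data.max(axis=axis, keepdims=True)
    # constant offsets: -inf kills excluded exps exactly, grad is exp(-inf)=0
    e = (x - Tensor(shift - neg)).exp() * mask
    return e.sum(axis=axis, keepdims=True).log() + Tensor(shift)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize over the last (feature) axis, then scale and shift."""
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered / (var + eps).sqrt() * gamma + beta


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
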