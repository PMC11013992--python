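"""Minimal reverse-mode automatic differentiation on numpy arrays.

The segmentation head of the network is a stack of shared per-point maps
(linear layers, batch normalization, ReLU, outer products, max pooling),
so a small tape-based engine over dense float64 arrays is sufficient to
train it.  Gradients are accumulated by reverse topological traversal of
the operation graph; every operator's backward rule is exercised by
finite-difference tests.

Broadcasting follows numpy semantics; gradients flowing into a broadcast
operand are summed over the broadcast axes.  ``max`` routes its gradient
to the first (lowest-index) maximum, matching the deterministic tie rule
used throughout the package.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "softmax_cross_entropy",
    "Linear",
    "BatchNorm",
    "AdamW",
]


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: Tuple["Tensor", ...] = ()

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _make(data, parents: Tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64, copy=True)
        else:
            self.grad += grad

    def backward(self, grad=None) -> None:
        """Reverse-accumulate gradients from this node."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: List[Tensor] = []
        seen = set()

        def visit(node: "Tensor") -> None:
            stack = [(node, iter(node._parents))]
            seen.add(id(node))
            while stack:
                cur, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(cur)
                    stack.pop()

        visit(self)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- shape helpers ------------------------------------------------------

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out_data = self.data.reshape(shape)

        def bwd(g, self=self, old=old):
            self._accumulate(g.reshape(old))

        return Tensor._make(out_data, (self,), bwd)

    # -- arithmetic ---------------------------------------------------------

    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other) -> "Tensor":
        other = Tensor._coerce(other)
        out_data = self.data + other.data

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))

        return Tensor._make(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bwd(g, a=self):
            a._accumulate(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor._coerce(other)
        out_data = self.data * other.data

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        return self * Tensor._coerce(other).pow(-1.0)

    def __rtruediv__(self, other) -> "Tensor":
        return Tensor._coerce(other) * self.pow(-1.0)

    def pow(self, exponent: float) -> "Tensor":
        out_data = self.data ** exponent

        def bwd(g, a=self, p=exponent):
            a._accumulate(g * p * a.data ** (p - 1.0))

        return Tensor._make(out_data, (self,), bwd)

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    def __matmul__(self, other) -> "Tensor":
        other = Tensor._coerce(other)
        out_data = self.data @ other.data

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accumulate(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accumulate(_unbroadcast(gb, b.data.shape))

        return Tensor._make(out_data, (self, other), bwd)

    # -- nonlinearities and reductions --------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bwd(g, a=self, mask=mask):
            a._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), bwd)

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g, a=self, axis=axis, keepdims=keepdims):
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.data.shape))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(g, a.data.shape))

        return Tensor._make(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        """Maximum along one axis; gradient goes to the first maximum."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(
            self.data, np.expand_dims(idx, axis), axis=axis
        )
        if not keepdims:
            out_data = np.squeeze(out_data, axis=axis)

        def bwd(g, a=self, idx=idx, axis=axis, keepdims=keepdims):
            if not keepdims:
                g = np.expand_dims(g, axis)
            full = np.zeros_like(a.data)
            np.put_along_axis(full, np.expand_dims(idx, axis), g, axis=axis)
            a._accumulate(full)

        return Tensor._make(out_data, (self,), bwd)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along an axis."""
    tensors = [Tensor._coerce(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]

    def bwd(g, tensors=tensors, sizes=sizes, axis=axis):
        splits = np.cumsum(sizes)[:-1]
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    return Tensor._make(out_data, tuple(tensors), bwd)


def softmax_cross_entropy(logits: Tensor, targets, weights=None) -> Tensor:
    """Weighted mean softmax cross-entropy over rows of (M, C) logits.

    Fused forward/backward: grad of the mean loss w.r.t. logits is
    w * (softmax - onehot) / sum(w), numerically stable via max-shifted
    logsumexp.  ``weights`` (per-row, default all ones) lets callers
    up-weight rare classes.
    """
    targets = np.asarray(targets, dtype=np.int64).ravel()
    z = logits.data
    if weights is None:
        w = np.ones(z.shape[0])
    else:
        w = np.asarray(weights, dtype=np.float64).ravel()
    m = z.max(axis=1, keepdims=True)
    ez = np.exp(z - m)
    lse = m[:, 0] + np.log(ez.sum(axis=1))
    picked = z[np.arange(z.shape[0]), targets]
    wsum = w.sum()
    loss = float(np.sum(w * (lse - picked)) / wsum)
    softmax = ez / ez.sum(axis=1, keepdims=True)

    def bwd(g, a=logits, softmax=softmax, targets=targets, w=w, wsum=wsum):
        grad = softmax.copy()
        grad[np.arange(grad.shape[0]), targets] -= 1.0
        a._accumulate(g * (w[:, None] * grad) / wsum)

    return Tensor._make(np.float64(loss), (logits,), bwd)


# ---------------------------------------------------------------------------
# Layers


class Linear:
    """Shared per-point affine map, applied to the last axis."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        # He initialization: ReLU networks keep activation variance stable.
        scale = np.sqrt(2.0 / in_dim)
        self.weight = Tensor(rng.normal(0.0, scale, (in_dim, out_dim)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias

    def parameters(self) -> List[Tensor]:
        return [self.weight, self.bias]


class BatchNorm:
    """Batch normalization over all leading axes of a (..., dim) tensor.

    In training mode, statistics are computed from the current batch of
    points and running estimates are updated; in evaluation mode the
    running estimates are used.
    """

    def __init__(self, dim: int, eps: float = 1e-5, momentum: float = 0.9):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            flat = x if x.ndim == 2 else x.reshape(-1, x.shape[-1])
            mu = flat.mean(axis=0)
            var = ((flat - mu) * (flat - mu)).mean(axis=0)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu.data
            self.running_var = m * self.running_var + (1 - m) * var.data
            xhat = (x - mu) / (var + self.eps).sqrt()
        else:
            xhat = (x - Tensor(self.running_mean)) / Tensor(
                np.sqrt(self.running_var + self.eps)
            )
        return xhat * self.gamma + self.beta

    def parameters(self) -> List[Tensor]:
        return [self.gamma, self.beta]


# ---------------------------------------------------------------------------
# Optimizer


class AdamW:
    """Adam with decoupled weight decay.

    Defaults follow the training recipe used for the network: lr 1e-3,
    betas (0.9, 0.999), eps 1e-8, weight decay 1e-4.
    """

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas: Tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-4,
    ):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            p.data -= self.lr * self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
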