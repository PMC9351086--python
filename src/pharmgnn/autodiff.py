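"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The network in this package needs a small, predictable set of differentiable
operations — dense linear maps, pointwise nonlinearities, row gathers and
segment reductions over ragged graph batches — so a compact tape-based engine
is used rather than a full deep-learning framework.  All arithmetic is float64
for bit-reproducible runs and tight finite-difference agreement.

Tensors record their parents and a backward closure; ``Tensor.backward()``
topologically sorts the tape and accumulates gradients into ``.grad``.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

Array = np.ndarray


class Tensor:
    """A node in the computation tape wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[Array], None] | None = None,
        requires_grad: bool = False,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Array | None = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    # -- bookkeeping -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: Array, own: bool = False) -> None:
        """Add a gradient contribution.

        ``own=True`` promises the caller freshly allocated ``g`` (correct
        shape, float64) that nobody else references, letting it be adopted
        without a defensive copy.
        """
        if self.grad is None:
            if own:
                self.grad = g
            else:
                self.grad = np.array(np.broadcast_to(g, self.data.shape), dtype=np.float64)
        else:
            self.grad += g

    def backward(self, seed: Array | None = None) -> None:
        """Accumulate d(self)/d(leaf) into every reachable tensor's ``.grad``."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: molecule batches can produce deep tapes
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
        if seed is None:
            seed = np.ones_like(self.data)
        self._accumulate(np.asarray(seed, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    def __radd__(self, other):
        return add(_wrap(other), self)

    def __sub__(self, other):
        return add(self, neg(_wrap(other)))

    def __rsub__(self, other):
        return add(_wrap(other), neg(self))

    def __mul__(self, other):
        return mul(self, _wrap(other))

    def __rmul__(self, other):
        return mul(_wrap(other), self)

    def __truediv__(self, other):
        return div(self, _wrap(other))

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, other)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


def constant(data) -> Tensor:
    return Tensor(data)


def _unbroadcast(g: Array, shape: tuple[int, ...]) -> Array:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


# -- elementwise arithmetic ------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, (a, b))

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    out._backward = backward
    return out


def neg(a: Tensor) -> Tensor:
    out = Tensor(-a.data, (a,))
    out._backward = lambda g: a._accumulate(-g, own=True)
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, (a, b))

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape), own=True)
        b._accumulate(_unbroadcast(g * a.data, b.data.shape), own=True)

    out._backward = backward
    return out


def div(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data / b.data, (a, b))

    def backward(g):
        a._accumulate(_unbroadcast(g / b.data, a.data.shape), own=True)
        b._accumulate(_unbroadcast(-g * a.data / (b.data**2), b.data.shape), own=True)

    out._backward = backward
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, (a, b))

    def backward(g):
        a._accumulate(g @ b.data.T, own=True)
        b._accumulate(a.data.T @ g, own=True)

    out._backward = backward
    return out


# -- pointwise nonlinearities ----------------------------------------------

def exp(a: Tensor) -> Tensor:
    val = np.exp(a.data)
    out = Tensor(val, (a,))
    out._backward = lambda g: a._accumulate(g * val, own=True)
    return out


def log(a: Tensor) -> Tensor:
    out = Tensor(np.log(a.data), (a,))
    out._backward = lambda g: a._accumulate(g / a.data, own=True)
    return out


def tanh(a: Tensor) -> Tensor:
    val = np.tanh(a.data)
    out = Tensor(val, (a,))
    out._backward = lambda g: a._accumulate(g * (1.0 - val**2), own=True)
    return out


def sigmoid(a: Tensor) -> Tensor:
    val = 1.0 / (1.0 + np.exp(-a.data))
    out = Tensor(val, (a,))
    out._backward = lambda g: a._accumulate(g * val * (1.0 - val), own=True)
    return out


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = Tensor(a.data * mask, (a,))
    out._backward = lambda g: a._accumulate(g * mask, own=True)
    return out


def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    factor = np.where(a.data > 0, 1.0, slope)
    out = Tensor(a.data * factor, (a,))
    out._backward = lambda g: a._accumulate(g * factor, own=True)
    return out


def square(a: Tensor) -> Tensor:
    out = Tensor(a.data**2, (a,))
    out._backward = lambda g: a._accumulate(2.0 * g * a.data, own=True)
    return out


# -- reductions and structure ----------------------------------------------

def total(a: Tensor) -> Tensor:
    """Sum of all entries, as a 0-d tensor."""
    out = Tensor(a.data.sum(), (a,))
    out._backward = lambda g: a._accumulate(np.broadcast_to(g, a.data.shape).copy(), own=True)
    return out


def mean(a: Tensor) -> Tensor:
    n = a.data.size
    out = Tensor(a.data.mean(), (a,))
    out._backward = lambda g: a._accumulate(np.broadcast_to(g / n, a.data.shape).copy(), own=True)
    return out


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])

    out._backward = backward
    return out


def _scatter_rows(values: Array, index: Array, n_rows: int) -> Array:
    """out[index[i]] += values[i], via sort + reduceat (faster than ufunc.at)."""
    out = np.zeros((n_rows,) + values.shape[1:], dtype=np.float64)
    if len(index) == 0:
        return out
    order = np.argsort(index, kind="stable")
    sorted_idx = index[order]
    starts = np.flatnonzero(np.r_[True, sorted_idx[1:] != sorted_idx[:-1]])
    out[sorted_idx[starts]] = np.add.reduceat(values[order], starts, axis=0)
    return out


def gather_rows(a: Tensor, index: Array) -> Tensor:
    """out[i] = a[index[i]] — duplicate indices allowed."""
    index = np.asarray(index, dtype=np.intp)
    out = Tensor(a.data[index], (a,))
    out._backward = lambda g: a._accumulate(
        _scatter_rows(g, index, a.data.shape[0]), own=True
    )
    return out


def segment_sum(a: Tensor, segment_ids: Array, num_segments: int) -> Tensor:
    """Row-wise scatter-add: out[s] = sum of rows i with segment_ids[i] == s."""
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    out = Tensor(_scatter_rows(a.data, segment_ids, num_segments), (a,))
    out._backward = lambda g: a._accumulate(g[segment_ids], own=True)
    return out


def segment_softmax(scores: Tensor, segment_ids: Array, num_segments: int) -> Tensor:
    """Softmax of a column vector of scores within each segment.

    Shift-by-segment-max is applied on raw values only (a constant w.r.t. the
    tape), which leaves gradients exact while preventing overflow.
    """
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    if scores.data.ndim != 2 or scores.data.shape[1] != 1:
        raise ValueError("segment_softmax expects an (n, 1) score column")
    shift = np.full(num_segments, -np.inf)
    np.maximum.at(shift, segment_ids, scores.data[:, 0])
    shift[~np.isfinite(shift)] = 0.0  # empty segments
    e = exp(scores - constant(shift[segment_ids, None]))
    denom = segment_sum(e, segment_ids, num_segments)
    return e / gather_rows(denom, segment_ids)


def dropout(a: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; identity when rate == 0."""
    if rate <= 0.0:
        return a
    mask = (rng.random(a.data.shape) >= rate) / (1.0 - rate)
    return mul(a, constant(mask))


# -- optimisation ----------------------------------------------------------

class Adam:
    """Adam with optional L2 weight decay (added to the gradient)."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        weight_decay: float = 0.0,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        decay_mask: Iterable[bool] | None = None,
    ):
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.decay_mask = list(decay_mask) if decay_mask is not None else [True] * len(self.params)
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v, decay in zip(self.params, self.m, self.v, self.decay_mask):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.weight_decay and decay:
                g = g + self.weight_decay * p.data
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g**2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
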