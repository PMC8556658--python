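"""Minimal reverse-mode automatic differentiation on numpy arrays.

The model in this package is small (tens of parameters tensors, node counts
below ~20), so a compact tape-based engine over float64 numpy arrays is both
fast enough and easy to verify against finite differences.  Only the
operations the model needs are provided.

Conventions
-----------
* Every op takes/returns :class:`Tensor`; plain arrays and scalars are
  promoted with :func:`astensor`.
* Gradients accumulate into ``Tensor.grad`` during :meth:`Tensor.backward`.
* Broadcasting follows numpy; gradients are summed back over broadcast axes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "astensor",
    "add",
    "sub",
    "mul",
    "div",
    "neg",
    "matmul",
    "einsum",
    "relu",
    "sigmoid",
    "exp",
    "log",
    "absolute",
    "square",
    "tsum",
    "tmean",
    "reshape",
    "moveaxis",
    "concatenate",
    "getitem",
    "pad_last",
    "softmax",
    "log_softmax",
    "grad_reverse",
    "Adam",
]


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- conveniences -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    # -- autodiff ---------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
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
                if id(p) not in seen:
                    stack.append((p, False))

        self.grad = (
            np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64)
        )
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._backward(node.grad)):
                if g is None:
                    continue
                if not (parent.requires_grad or parent._backward is not None):
                    continue
                if parent.grad is None:
                    parent.grad = np.array(g, dtype=np.float64)
                else:
                    parent.grad = parent.grad + g


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, backward) -> Tensor:
    """Create a graph node; constant-only subtrees carry no tape."""
    track = any(p.requires_grad or p._backward is not None for p in parents)
    out = Tensor(data)
    if track:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` back down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# elementwise arithmetic
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    return _node(
        a.data + b.data,
        (a, b),
        lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
    )


def sub(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    return _node(
        a.data - b.data,
        (a, b),
        lambda g: (_unbroadcast(g, a.shape), _unbroadcast(-g, b.shape)),
    )


def mul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    return _node(
        a.data * b.data,
        (a, b),
        lambda g: (_unbroadcast(g * b.data, a.shape), _unbroadcast(g * a.data, b.shape)),
    )


def div(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    return _node(
        a.data / b.data,
        (a, b),
        lambda g: (
            _unbroadcast(g / b.data, a.shape),
            _unbroadcast(-g * a.data / (b.data**2), b.shape),
        ),
    )


def neg(a) -> Tensor:
    a = astensor(a)
    return _node(-a.data, (a,), lambda g: (-g,))


def relu(a) -> Tensor:
    a = astensor(a)
    mask = a.data > 0
    return _node(a.data * mask, (a,), lambda g: (g * mask,))


def leaky_relu(a, slope: float = 0.01) -> Tensor:
    a = astensor(a)
    mask = a.data > 0
    scale = np.where(mask, 1.0, slope)
    return _node(a.data * scale, (a,), lambda g: (g * scale,))


def sigmoid(a) -> Tensor:
    a = astensor(a)
    out = 0.5 * (1.0 + np.tanh(0.5 * a.data))  # numerically stable logistic
    return _node(out, (a,), lambda g: (g * out * (1.0 - out),))


def exp(a) -> Tensor:
    a = astensor(a)
    out = np.exp(a.data)
    return _node(out, (a,), lambda g: (g * out,))


def log(a) -> Tensor:
    a = astensor(a)
    return _node(np.log(a.data), (a,), lambda g: (g / a.data,))


def absolute(a) -> Tensor:
    a = astensor(a)
    return _node(np.abs(a.data), (a,), lambda g: (g * np.sign(a.data),))


def square(a) -> Tensor:
    a = astensor(a)
    return _node(a.data**2, (a,), lambda g: (2.0 * g * a.data,))


# ---------------------------------------------------------------------------
# contractions and reshaping
# ---------------------------------------------------------------------------

def matmul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)

    def backward(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

    return _node(np.matmul(a.data, b.data), (a, b), backward)


_EINSUM_PATHS: dict = {}


def _einsum(subscripts: str, *arrays) -> np.ndarray:
    """np.einsum with a memoised contraction path."""
    key = (subscripts, tuple(a.shape for a in arrays))
    path = _EINSUM_PATHS.get(key)
    if path is None:
        path = np.einsum_path(subscripts, *arrays, optimize="optimal")[0]
        _EINSUM_PATHS[key] = path
    return np.einsum(subscripts, *arrays, optimize=path)


def einsum(subscripts: str, *operands) -> Tensor:
    """Differentiable ``np.einsum``.

    Restriction: no repeated index within a single operand, and every
    contracted index must appear in at least one other operand or the
    output (plain reductions should use :func:`tsum`).
    """
    tensors = [astensor(op) for op in operands]
    lhs, rhs = subscripts.replace(" ", "").split("->")
    in_subs = lhs.split(",")
    if len(in_subs) != len(tensors):
        raise ValueError("operand count does not match subscripts")
    out = _einsum(subscripts, *[t.data for t in tensors])

    def backward(g):
        grads = []
        for i, target in enumerate(in_subs):
            others = [in_subs[j] for j in range(len(tensors)) if j != i]
            arrays = [tensors[j].data for j in range(len(tensors)) if j != i]
            avail = set(rhs) | set("".join(others))
            reduced = "".join(s for s in target if s in avail)
            spec = ",".join([rhs] + others) + "->" + reduced
            gi = _einsum(spec, g, *arrays)
            if reduced != target:
                # indices absent everywhere else were plain sums: broadcast back
                expand = [slice(None) if s in reduced else None for s in target]
                order = [reduced.index(s) for s in target if s in reduced]
                gi = np.transpose(gi, np.argsort(np.argsort(order))) if order else gi
                gi = np.broadcast_to(gi[tuple(expand)], tensors[i].shape).copy()
            grads.append(gi)
        return grads

    return _node(out, tuple(tensors), backward)


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = astensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            return (np.broadcast_to(g, a.shape).copy(),)
        g_exp = g if keepdims else np.expand_dims(g, axis)
        return (np.broadcast_to(g_exp, a.shape).copy(),)

    return _node(out, (a,), backward)


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = astensor(a)
    count = a.data.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(count))


def reshape(a, shape) -> Tensor:
    a = astensor(a)
    return _node(a.data.reshape(shape), (a,), lambda g: (g.reshape(a.shape),))


def moveaxis(a, source, destination) -> Tensor:
    a = astensor(a)
    return _node(
        np.moveaxis(a.data, source, destination),
        (a,),
        lambda g: (np.moveaxis(g, destination, source),),
    )


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


def getitem(a, idx) -> Tensor:
    a = astensor(a)

    def backward(g):
        buf = np.zeros_like(a.data)
        np.add.at(buf, idx, g)
        return (buf,)

    return _node(a.data[idx], (a,), backward)


def pad_last(a, before: int, after: int) -> Tensor:
    """Zero-pad the last axis (used for same-padded temporal convolution)."""
    a = astensor(a)
    width = [(0, 0)] * (a.ndim - 1) + [(before, after)]

    def backward(g):
        sl = [slice(None)] * (a.ndim - 1) + [slice(before, g.shape[-1] - after or None)]
        return (g[tuple(sl)],)

    return _node(np.pad(a.data, width), (a,), backward)


def softmax(a, axis: int = -1) -> Tensor:
    a = astensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out).sum(axis=axis, keepdims=True)
        return (out * (g - dot),)

    return _node(out, (a,), backward)


def log_softmax(a, axis: int = -1) -> Tensor:
    a = astensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    logz = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out = shifted - logz
    p = np.exp(out)

    def backward(g):
        return (g - p * g.sum(axis=axis, keepdims=True),)

    return _node(out, (a,), backward)


def grad_reverse(a, beta: float) -> Tensor:
    """Identity in the forward pass; multiplies the gradient by ``-beta``.

    The adversarial coupling between the domain classifier and the feature
    extractor: the classifier head minimises its own loss normally, while
    the features upstream of this layer receive the reversed (scaled)
    gradient and therefore *maximise* domain confusion.
    """
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    a = astensor(a)
    return _node(a.data.copy(), (a,), lambda g: ((-float(beta)) * g,))


# ---------------------------------------------------------------------------
# optimisation
# ---------------------------------------------------------------------------

class Adam:
    """Adaptive moment estimation over a list of parameter tensors."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
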