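"""Reverse-mode automatic differentiation on float64 numpy arrays.

A deliberately small tape: tensors wrap ``numpy`` arrays, operations record
their inputs and a backward rule, and :func:`grad` walks the tape in reverse
topological order.  Backward rules are themselves written in terms of tape
operations, so gradients stay differentiable — ``grad(..., create_graph=True)``
supports the gradient-through-a-gradient needed by second-order meta-learning.

Everything is float64; there is no broadcasting surprise beyond numpy's own
rules (un-broadcasting in backward passes is handled by summation).
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "grad",
    "add",
    "mul",
    "div",
    "matmul",
    "transpose",
    "reshape",
    "tsum",
    "broadcast_to",
    "exp",
    "log",
    "relu",
    "sigmoid",
    "gather",
    "concat1d",
]


class Tensor:
    """A node in the computation tape.

    Parameters
    ----------
    data:
        Array-like; stored as a float64 ``numpy`` array.
    parents:
        Input tensors of the producing operation (empty for leaves).
    bwd:
        Backward rule mapping the output cotangent to one cotangent (or
        ``None``) per parent, built from tape operations.
    requires_grad:
        Whether gradients should flow to / through this node.  Defaults to
        ``True`` iff any parent requires grad.
    """

    __slots__ = ("data", "parents", "_bwd", "requires_grad")

    def __init__(
        self,
        data,
        parents: tuple = (),
        bwd: Callable | None = None,
        requires_grad: bool | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.parents = parents
        self._bwd = bwd
        if requires_grad is None:
            requires_grad = any(p.requires_grad for p in parents)
        self.requires_grad = bool(requires_grad)

    # -- conveniences -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- operator sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __neg__(self):
        return mul(self, _wrap(-1.0))

    def __sub__(self, other):
        return add(self, -_wrap(other))

    def __rsub__(self, other):
        return add(_wrap(other), -self)

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, _wrap(other))

    def __rtruediv__(self, other):
        return div(_wrap(other), self)

    def __pow__(self, c):
        return power(self, float(c))

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    @property
    def T(self):
        return transpose(self)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in _axes_tuple(axis, self.data.ndim)]
        )
        return tsum(self, axis=axis, keepdims=keepdims) * (1.0 / float(n))


def tensor(data, requires_grad: bool = False) -> Tensor:
    """Create a leaf tensor."""
    return Tensor(data, requires_grad=requires_grad)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x, requires_grad=False)


def _axes_tuple(axis, ndim):
    if axis is None:
        return tuple(range(ndim))
    if isinstance(axis, int):
        return (axis % ndim,)
    return tuple(a % ndim for a in axis)


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------


def _sum_to(g: Tensor, shape: tuple) -> Tensor:
    """Un-broadcast ``g`` down to ``shape`` by summing the broadcast axes."""
    if g.data.shape == tuple(shape):
        return g
    extra = g.data.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    axes = tuple(
        i for i, (gs, s) in enumerate(zip(g.data.shape, shape)) if s == 1 and gs != 1
    )
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(
        a.data + b.data,
        parents=(a, b),
        bwd=lambda g: (_sum_to(g, a.data.shape), _sum_to(g, b.data.shape)),
    )


def mul(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(
        a.data * b.data,
        parents=(a, b),
        bwd=lambda g: (_sum_to(mul(g, b), a.data.shape), _sum_to(mul(g, a), b.data.shape)),
    )


def div(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(
        a.data / b.data,
        parents=(a, b),
        bwd=lambda g: (
            _sum_to(div(g, b), a.data.shape),
            _sum_to(-mul(g, div(a, mul(b, b))), b.data.shape),
        ),
    )


def power(a: Tensor, c: float) -> Tensor:
    return Tensor(
        a.data**c,
        parents=(a,),
        bwd=lambda g: (mul(g, mul(_wrap(c), power(a, c - 1.0))),),
    )


def matmul(a: Tensor, b: Tensor) -> Tensor:
    if a.data.ndim != 2 or b.data.ndim != 2:
        raise ValueError("matmul supports 2-D operands only")
    return Tensor(
        a.data @ b.data,
        parents=(a, b),
        bwd=lambda g: (matmul(g, transpose(b)), matmul(transpose(a), g)),
    )


def transpose(a: Tensor) -> Tensor:
    return Tensor(a.data.T, parents=(a,), bwd=lambda g: (transpose(g),))


def reshape(a: Tensor, shape) -> Tensor:
    old = a.data.shape
    return Tensor(
        a.data.reshape(shape), parents=(a,), bwd=lambda g: (reshape(g, old),)
    )


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    axes = _axes_tuple(axis, a.data.ndim)
    old = a.data.shape

    def bwd(g):
        if not keepdims:
            kshape = tuple(1 if i in axes else s for i, s in enumerate(old))
            g = reshape(g, kshape)
        return (broadcast_to(g, old),)

    return Tensor(a.data.sum(axis=axes, keepdims=keepdims), parents=(a,), bwd=bwd)


def broadcast_to(a: Tensor, shape) -> Tensor:
    old = a.data.shape
    return Tensor(
        np.broadcast_to(a.data, shape).copy(),
        parents=(a,),
        bwd=lambda g: (_sum_to(g, old),),
    )


def exp(a: Tensor) -> Tensor:
    out = Tensor(np.exp(a.data), parents=(a,))
    out._bwd = lambda g: (mul(g, out),)
    return out


def log(a: Tensor) -> Tensor:
    return Tensor(np.log(a.data), parents=(a,), bwd=lambda g: (div(g, a),))


def relu(a: Tensor) -> Tensor:
    mask = Tensor((a.data > 0).astype(np.float64))
    return Tensor(a.data * mask.data, parents=(a,), bwd=lambda g: (mul(g, mask),))


def sigmoid(a: Tensor) -> Tensor:
    out = Tensor(1.0 / (1.0 + np.exp(-a.data)), parents=(a,))
    out._bwd = lambda g: (mul(g, mul(out, add(_wrap(1.0), -out))),)
    return out


def gather(a: Tensor, idx: np.ndarray) -> Tensor:
    """Fancy-index a 1-D tensor with an integer array of any shape."""
    if a.data.ndim != 1:
        raise ValueError("gather expects a 1-D tensor")
    n = a.data.size
    return Tensor(a.data[idx], parents=(a,), bwd=lambda g: (_scatter(g, idx, n),))


def _scatter(g: Tensor, idx: np.ndarray, n: int) -> Tensor:
    data = np.bincount(idx.ravel(), weights=g.data.ravel(), minlength=n)
    return Tensor(data, parents=(g,), bwd=lambda c: (gather(c, idx),))


def concat1d(a: Tensor, b: Tensor) -> Tensor:
    na, nb = a.data.size, b.data.size
    ia = np.arange(na)
    ib = np.arange(na, na + nb)
    return Tensor(
        np.concatenate([a.data, b.data]),
        parents=(a, b),
        bwd=lambda g: (gather(g, ia), gather(g, ib)),
    )


# ---------------------------------------------------------------------------
# reverse pass
# ---------------------------------------------------------------------------


def _toposort(output: Tensor) -> list[Tensor]:
    order: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(output, False)]
    while stack:
        node, expanded = stack.pop()
        if expanded:
            order.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))
    return order


def grad(
    output: Tensor,
    inputs: Sequence[Tensor],
    grad_output: Tensor | None = None,
    create_graph: bool = False,
) -> list[Tensor]:
    """Cotangents of ``output`` with respect to each tensor in ``inputs``.

    With ``create_graph=True`` the returned tensors stay on the tape and can
    be differentiated again (second-order derivatives).  Inputs unreachable
    from ``output`` get zero cotangents.
    """
    if grad_output is None:
        grad_output = Tensor(np.ones_like(output.data))
    order = _toposort(output)
    cot: dict[int, Tensor] = {id(output): grad_output}
    for node in reversed(order):
        g = cot.get(id(node))
        if g is None or node._bwd is None:
            continue
        parts = node._bwd(g)
        for p, gp in zip(node.parents, parts):
            if gp is None or not p.requires_grad:
                continue
            if not create_graph:
                gp = Tensor(gp.data)
            prev = cot.get(id(p))
            if prev is None:
                cot[id(p)] = gp
            else:
                acc = add(prev, gp)
                cot[id(p)] = acc if create_graph else Tensor(acc.data)
        # pin parents so ids in `cot` stay unique while the walk is alive
    out = []
    for x in inputs:
        gx = cot.get(id(x))
        if gx is None:
            gx = Tensor(np.zeros_like(x.data))
        out.append(gx)
    return out
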