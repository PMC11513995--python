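"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Provides exactly the primitives the graph regressor needs: dense linear
algebra, elementwise nonlinearities, row gather, and segment (per-group)
sum / max / softmax reductions for message passing and graph readout.
Gradients are accumulated on a tape and released by :meth:`Tensor.backward`;
correctness is checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "reshape",
    "mul",
    "matmul",
    "relu",
    "leaky_relu",
    "gather",
    "segment_sum",
    "segment_max",
    "segment_softmax",
    "mean_abs_error",
    "mean_square_error",
]


class Tensor:
    """A NumPy array with a gradient slot and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)  # copy: g may alias a child's grad
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum *g* down to *shape* (inverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, _prev=(a, b))

    def backward():
        if a.requires_grad:
            a._accum(_unbroadcast(out.grad, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(out.grad, b.data.shape))

    out._backward = backward
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, _prev=(a, b))

    def backward():
        if a.requires_grad:
            a._accum(_unbroadcast(out.grad * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(out.grad * a.data, b.data.shape))

    out._backward = backward
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, _prev=(a, b))

    def backward():
        if a.requires_grad:
            a._accum(out.grad @ b.data.T)
        if b.requires_grad:
            b._accum(a.data.T @ out.grad)

    out._backward = backward
    return out


def reshape(a: Tensor, shape) -> Tensor:
    out = Tensor(a.data.reshape(shape), _prev=(a,))

    def backward():
        if a.requires_grad:
            a._accum(out.grad.reshape(a.data.shape))

    out._backward = backward
    return out


def relu(a: Tensor) -> Tensor:
    out = Tensor(np.maximum(a.data, 0.0), _prev=(a,))

    def backward():
        if a.requires_grad:
            a._accum(out.grad * (a.data > 0))

    out._backward = backward
    return out


def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    out = Tensor(np.where(a.data > 0, a.data, slope * a.data), _prev=(a,))

    def backward():
        if a.requires_grad:
            a._accum(out.grad * np.where(a.data > 0, 1.0, slope))

    out._backward = backward
    return out


def gather(a: Tensor, idx: np.ndarray, scatter=None) -> Tensor:
    """Select rows ``a[idx]`` (idx may repeat).

    *scatter* may be a precomputed sparse matrix S of shape
    ``(len(a), len(idx))`` with ``S[idx[e], e] = 1``; the backward scatter-add
    then becomes one sparse matmul instead of an unbuffered ``np.add.at``.
    """
    idx = np.asarray(idx, dtype=np.int64)
    out = Tensor(a.data[idx], _prev=(a,))

    def backward():
        if a.requires_grad:
            if scatter is not None:
                a._accum(scatter @ out.grad)
            else:
                g = np.zeros_like(a.data)
                np.add.at(g, idx, out.grad)
                a._accum(g)

    out._backward = backward
    return out


def segment_sum(a: Tensor, seg: np.ndarray, n_seg: int, scatter=None) -> Tensor:
    """Sum rows of *a* into *n_seg* groups given per-row group ids.

    *scatter* may be the sparse matrix S of shape ``(n_seg, len(a))`` with
    ``S[seg[r], r] = 1``, in which case the forward reduction is one sparse
    matmul.
    """
    seg = np.asarray(seg, dtype=np.int64)
    if scatter is not None:
        data = scatter @ a.data
    else:
        data = np.zeros((n_seg,) + a.data.shape[1:], dtype=np.float64)
        np.add.at(data, seg, a.data)
    out = Tensor(data, _prev=(a,))

    def backward():
        if a.requires_grad:
            a._accum(out.grad[seg])

    out._backward = backward
    return out


def segment_max(a: Tensor, seg: np.ndarray, n_seg: int) -> Tensor:
    """Per-group elementwise max over rows; gradient flows to the argmax row.

    Every group must be non-empty.  Ties route the gradient to the first
    maximal row (deterministic).
    """
    seg = np.asarray(seg, dtype=np.int64)
    if a.data.ndim != 2:
        raise ValueError("segment_max expects a 2-D tensor (rows x features)")
    n_rows, n_cols = a.data.shape
    data = np.full((n_seg, n_cols), -np.inf)
    np.maximum.at(data, seg, a.data)
    if np.isneginf(data).any():
        raise ValueError("segment_max: empty group")
    # first row attaining each group/column max (deterministic tie-break)
    rr, cc = np.nonzero(a.data == data[seg])
    winner = np.full((n_seg, n_cols), n_rows, dtype=np.int64)
    np.minimum.at(winner, (seg[rr], cc), rr)
    out = Tensor(data, _prev=(a,))

    def backward():
        if a.requires_grad:
            g = np.zeros_like(a.data)
            cols = np.tile(np.arange(n_cols), n_seg)
            np.add.at(g, (winner.ravel(), cols), out.grad.ravel())
            a._accum(g)

    out._backward = backward
    return out


def segment_softmax(e: Tensor, seg: np.ndarray, n_seg: int) -> Tensor:
    """Softmax of a 1-D score vector within each group (attention weights)."""
    seg = np.asarray(seg, dtype=np.int64)
    if e.data.ndim != 1:
        raise ValueError("segment_softmax expects a 1-D score tensor")
    mx = np.full(n_seg, -np.inf)
    np.maximum.at(mx, seg, e.data)
    z = np.exp(e.data - mx[seg])
    denom = np.zeros(n_seg)
    np.add.at(denom, seg, z)
    alpha = z / denom[seg]
    out = Tensor(alpha, _prev=(e,))

    def backward():
        if e.requires_grad:
            # d alpha_k / d e_j = alpha_k (delta_kj - alpha_j) within a group
            dot = np.zeros(n_seg)
            np.add.at(dot, seg, out.grad * alpha)
            e._accum(alpha * (out.grad - dot[seg]))

    out._backward = backward
    return out


def mean_abs_error(pred: Tensor, target: np.ndarray) -> Tensor:
    """L1 loss; subgradient 0 at exact zero residuals."""
    target = np.asarray(target, dtype=np.float64)
    resid = pred.data - target
    out = Tensor(np.mean(np.abs(resid)), _prev=(pred,))

    def backward():
        if pred.requires_grad:
            pred._accum(out.grad * np.sign(resid) / resid.size)

    out._backward = backward
    return out


def mean_square_error(pred: Tensor, target: np.ndarray) -> Tensor:
    target = np.asarray(target, dtype=np.float64)
    resid = pred.data - target
    out = Tensor(np.mean(resid**2), _prev=(pred,))

    def backward():
        if pred.requires_grad:
            pred._accum(out.grad * 2.0 * resid / resid.size)

    out._backward = backward
    return out
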