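"""Minimal reverse-mode automatic differentiation on numpy arrays.

The unrolled reconstruction networks in this package need gradients of a
scalar loss with respect to convolution kernels, batch-norm parameters and
the fusion step size, propagated through sparse projector applications and
the closed-form fusion.  This module provides a small tape-based autodiff
engine sufficient for that: elementwise arithmetic, reductions, reshapes,
sparse matrix products and an n-dimensional convolution primitive.

Every public op dispatches on its argument types: called with plain numpy
arrays it computes with numpy and returns an array, called with at least one
:class:`Tensor` it records the operation on the tape.  This lets the same
formula (e.g. the fusion closed form) serve both the classic reconstructors
and the trainable networks.

An activation ledger tracks how many array elements are retained on the tape
between a forward pass and the corresponding backward pass; sequential
training of unrolled chains keeps this peak independent of chain depth.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Tensor",
    "as_tensor",
    "no_grad",
    "ledger",
    "add", "mul", "div", "sqrt", "exp", "log", "power",
    "maximum", "relu", "absolute", "where", "softplus",
    "sum_", "reshape", "transpose", "spmm", "conv_nd",
    "grad_check",
]


class _GradState:
    enabled: bool = True


_state = _GradState()


@contextmanager
def no_grad():
    """Disable tape recording inside the context (inference / frozen prefix)."""
    prev = _state.enabled
    _state.enabled = False
    try:
        yield
    finally:
        _state.enabled = prev


class ActivationLedger:
    """Counts array elements retained on the autodiff tape.

    ``current`` rises as graph-bearing tensors are created and is reset at
    the start of each training step via :meth:`start_step`; ``peak`` holds
    the maximum over completed steps.
    """

    def __init__(self):
        self.current = 0
        self.peak = 0

    def reset(self):
        self.current = 0
        self.peak = 0

    def start_step(self):
        self.current = 0

    def _add(self, n: int):
        self.current += int(n)
        if self.current > self.peak:
            self.peak = self.current


ledger = ActivationLedger()


class Tensor:
    """Array node of the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjps")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._vjps: tuple = ()

    # -- graph construction -------------------------------------------------
    @staticmethod
    def _make(data, parents, vjps) -> "Tensor":
        out = Tensor(data)
        live = [(p, v) for p, v in zip(parents, vjps) if p.requires_grad]
        if _state.enabled and live:
            out.requires_grad = True
            out._parents = tuple(p for p, _ in live)
            out._vjps = tuple(v for _, v in live)
            ledger._add(out.data.size)
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._parents:
                node.grad = g if node.grad is None else node.grad + g
            for p, vjp in zip(node._parents, node._vjps):
                contrib = vjp(g)
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + contrib
                else:
                    grads[id(p)] = contrib
            # leaf with parents impossible; interior nodes keep no .grad

    # -- operator overloads --------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -_d(other))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __pow__(self, p):
        return power(self, p)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x, requires_grad: bool = False) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(x, requires_grad=requires_grad)


def _d(x):
    """Raw ndarray view of a Tensor or array-like."""
    return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)


def _is_t(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward op."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# -- elementwise ops ---------------------------------------------------------

def add(a, b):
    if not _is_t(a, b):
        return _d(a) + _d(b)
    ta, tb = as_tensor(a), as_tensor(b)
    out = ta.data + tb.data
    return Tensor._make(
        out,
        (ta, tb),
        (lambda g: _unbroadcast(g, ta.data.shape),
         lambda g: _unbroadcast(g, tb.data.shape)),
    )


def mul(a, b):
    if not _is_t(a, b):
        return _d(a) * _d(b)
    ta, tb = as_tensor(a), as_tensor(b)
    out = ta.data * tb.data
    return Tensor._make(
        out,
        (ta, tb),
        (lambda g: _unbroadcast(g * tb.data, ta.data.shape),
         lambda g: _unbroadcast(g * ta.data, tb.data.shape)),
    )


def div(a, b):
    if not _is_t(a, b):
        return _d(a) / _d(b)
    ta, tb = as_tensor(a), as_tensor(b)
    out = ta.data / tb.data
    return Tensor._make(
        out,
        (ta, tb),
        (lambda g: _unbroadcast(g / tb.data, ta.data.shape),
         lambda g: _unbroadcast(-g * ta.data / tb.data ** 2, tb.data.shape)),
    )


def power(a, p: float):
    if not _is_t(a):
        return _d(a) ** p
    ta = as_tensor(a)
    out = ta.data ** p
    return Tensor._make(out, (ta,), (lambda g: g * p * ta.data ** (p - 1),))


def sqrt(a):
    if not _is_t(a):
        return np.sqrt(_d(a))
    ta = as_tensor(a)
    out = np.sqrt(ta.data)
    return Tensor._make(out, (ta,), (lambda g: g * 0.5 / out,))


def exp(a):
    if not _is_t(a):
        return np.exp(_d(a))
    ta = as_tensor(a)
    out = np.exp(ta.data)
    return Tensor._make(out, (ta,), (lambda g: g * out,))


def log(a):
    if not _is_t(a):
        return np.log(_d(a))
    ta = as_tensor(a)
    out = np.log(ta.data)
    return Tensor._make(out, (ta,), (lambda g: g / ta.data,))


def softplus(a):
    """log(1 + e^a), numerically stable; derivative is the logistic sigmoid."""
    if not _is_t(a):
        return np.logaddexp(0.0, _d(a))
    ta = as_tensor(a)
    out = np.logaddexp(0.0, ta.data)
    sig = 1.0 / (1.0 + np.exp(-ta.data))
    return Tensor._make(out, (ta,), (lambda g: g * sig,))


def maximum(a, b):
    """Elementwise max; subgradient routes to the larger argument (ties to a)."""
    if not _is_t(a, b):
        return np.maximum(_d(a), _d(b))
    ta, tb = as_tensor(a), as_tensor(b)
    mask = ta.data >= tb.data
    out = np.where(mask, ta.data, tb.data)
    return Tensor._make(
        out,
        (ta, tb),
        (lambda g: _unbroadcast(g * mask, ta.data.shape),
         lambda g: _unbroadcast(g * (~mask), tb.data.shape)),
    )


def relu(a):
    return maximum(a, 0.0)


def absolute(a):
    if not _is_t(a):
        return np.abs(_d(a))
    ta = as_tensor(a)
    s = np.sign(ta.data)
    return Tensor._make(np.abs(ta.data), (ta,), (lambda g: g * s,))


def where(cond, a, b):
    """Select by a boolean array; `cond` is never differentiated."""
    c = np.asarray(_d(cond), dtype=bool)
    if not _is_t(a, b):
        return np.where(c, _d(a), _d(b))
    ta, tb = as_tensor(a), as_tensor(b)
    out = np.where(c, ta.data, tb.data)
    return Tensor._make(
        out,
        (ta, tb),
        (lambda g: _unbroadcast(np.where(c, g, 0.0), ta.data.shape),
         lambda g: _unbroadcast(np.where(c, 0.0, g), tb.data.shape)),
    )


# -- reductions and shape ops ------------------------------------------------

def sum_(a, axis=None, keepdims: bool = False):
    if not _is_t(a):
        return _d(a).sum(axis=axis, keepdims=keepdims)
    ta = as_tensor(a)
    out = ta.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        g = np.asarray(g)
        if axis is None:
            return np.broadcast_to(g, ta.data.shape).copy()
        ax = axis if isinstance(axis, tuple) else (axis,)
        if not keepdims:
            g = np.expand_dims(g, ax)
        return np.broadcast_to(g, ta.data.shape).copy()

    return Tensor._make(out, (ta,), (vjp,))


def mean_(a, axis=None, keepdims: bool = False):
    n = _d(a).size if axis is None else np.prod(
        [_d(a).shape[i] for i in (axis if isinstance(axis, tuple) else (axis,))])
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def reshape(a, shape):
    if not _is_t(a):
        return _d(a).reshape(shape)
    ta = as_tensor(a)
    old = ta.data.shape
    return Tensor._make(ta.data.reshape(shape), (ta,),
                        (lambda g: g.reshape(old),))


def transpose(a, axes=None):
    if not _is_t(a):
        return _d(a).transpose(axes)
    ta = as_tensor(a)
    if axes is None:
        axes = tuple(reversed(range(ta.data.ndim)))
    inv = np.argsort(axes)
    return Tensor._make(ta.data.transpose(axes), (ta,),
                        (lambda g: g.transpose(inv),))


# -- sparse matrix product ---------------------------------------------------

def spmm(A: sp.spmatrix, x, AT: sp.spmatrix | None = None):
    """A @ x for a constant sparse A; x is (N,) or (N, B).

    The adjoint used in the backward pass is ``AT`` when given (pass a
    precomputed CSR transpose for speed), else ``A.T``.
    """
    if not _is_t(x):
        return A @ _d(x)
    tx = as_tensor(x)
    At = AT if AT is not None else A.T.tocsr()
    return Tensor._make(A @ tx.data, (tx,), (lambda g: At @ g,))


# -- n-dimensional convolution ------------------------------------------------

def _conv_raw(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Cross-correlation, stride 1, zero 'same' padding.

    x: (B, C, *spatial); w: (O, C, *k) with odd kernel sizes.
    """
    d = x.ndim - 2
    k = w.shape[2:]
    pad = [(0, 0), (0, 0)] + [(ki // 2, ki // 2) for ki in k]
    xp = np.pad(x, pad)
    cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=tuple(range(2, 2 + d)))
    # cols: (B, C, *S, *k) -> (B, *S, C, *k)
    perm = (0,) + tuple(range(2, 2 + d)) + (1,) + tuple(range(2 + d, 2 + 2 * d))
    cols = cols.transpose(perm)
    B = x.shape[0]
    S = cols.shape[1:1 + d]
    CK = int(np.prod(cols.shape[1 + d:]))
    out = cols.reshape(B * int(np.prod(S)), CK) @ w.reshape(w.shape[0], CK).T
    out = out.reshape((B,) + S + (w.shape[0],))
    return np.moveaxis(out, -1, 1)


def _conv_vjp_w(x: np.ndarray, gout: np.ndarray, kshape: tuple) -> np.ndarray:
    d = x.ndim - 2
    pad = [(0, 0), (0, 0)] + [(ki // 2, ki // 2) for ki in kshape]
    xp = np.pad(x, pad)
    cols = np.lib.stride_tricks.sliding_window_view(xp, kshape, axis=tuple(range(2, 2 + d)))
    perm = (0,) + tuple(range(2, 2 + d)) + (1,) + tuple(range(2 + d, 2 + 2 * d))
    cols = cols.transpose(perm)
    B = x.shape[0]
    S = cols.shape[1:1 + d]
    CK = int(np.prod(cols.shape[1 + d:]))
    g = np.moveaxis(gout, 1, -1).reshape(B * int(np.prod(S)), gout.shape[1])
    gw = g.T @ cols.reshape(B * int(np.prod(S)), CK)
    return gw.reshape((gout.shape[1], x.shape[1]) + kshape)


def conv_nd(x, w, b=None):
    """Convolutional layer primitive (cross-correlation, same padding).

    Works for 2D (B, C, H, W) and 3D (B, C, D, H, W) inputs with odd kernels.
    """
    if not _is_t(x, w, b if b is not None else x):
        out = _conv_raw(_d(x), _d(w))
        if b is not None:
            out = out + _d(b).reshape((1, -1) + (1,) * (out.ndim - 2))
        return out
    tx, tw = as_tensor(x), as_tensor(w)
    out = _conv_raw(tx.data, tw.data)
    kshape = tw.data.shape[2:]
    d = tx.data.ndim - 2

    def vjp_x(g):
        wt = np.flip(tw.data, axis=tuple(range(2, 2 + d))).swapaxes(0, 1)
        return _conv_raw(g, wt)

    def vjp_w(g):
        return _conv_vjp_w(tx.data, g, kshape)

    parents = [tx, tw]
    vjps = [vjp_x, vjp_w]
    if b is not None:
        tb = as_tensor(b)
        out = out + tb.data.reshape((1, -1) + (1,) * (out.ndim - 2))
        parents.append(tb)
        axes = (0,) + tuple(range(2, 2 + d))
        vjps.append(lambda g: g.sum(axis=axes))
    return Tensor._make(out, tuple(parents), tuple(vjps))


# -- finite-difference gradient check -----------------------------------------

def grad_check(fn, params: list[Tensor], eps: float = 1e-6, n_entries: int = 5,
               rng: np.random.Generator | None = None,
               atol: float = 1e-4) -> float:
    """Max relative error between autodiff and central finite differences.

    ``fn()`` must rebuild the graph from ``params`` and return a scalar Tensor.
    Only ``n_entries`` randomly chosen entries per parameter are probed.
    ``atol`` floors the denominator: entries whose true gradient is below the
    finite-difference round-off noise are not scored as relative errors.
    """
    rng = rng or np.random.default_rng(0)
    for p in params:
        p.zero_grad()
    loss = fn()
    loss.backward()
    worst = 0.0
    for p in params:
        g = p.grad if p.grad is not None else np.zeros_like(p.data)
        flat = p.data.reshape(-1)
        idxs = rng.choice(flat.size, size=min(n_entries, flat.size), replace=False)
        for i in idxs:
            orig = flat[i]
            flat[i] = orig + eps
            fp = fn().item()
            flat[i] = orig - eps
            fm = fn().item()
            flat[i] = orig
            fd = (fp - fm) / (2 * eps)
            ad = g.reshape(-1)[i]
            denom = max(abs(fd), abs(ad), atol)
            worst = max(worst, abs(fd - ad) / denom)
    return worst
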