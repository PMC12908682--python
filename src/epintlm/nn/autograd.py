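"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations that
produced it; :meth:`Tensor.backward` walks the tape in reverse
topological order and accumulates gradients into every tensor with
``requires_grad=True``.  Only the primitives the network needs are
implemented (elementwise arithmetic, broadcasting, batched matmul,
slicing, concatenation, reductions, the usual nonlinearities, softmax,
embedding gather, 1-D convolution and max-pooling); every primitive's
gradient is exercised by finite-difference checks in the test suite.

Graph recording can be suspended with :func:`no_grad` (used for
validation/test passes, where only the forward values are needed).
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_grad_enabled = True


@contextmanager
def no_grad():
    """Context manager that disables tape recording."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def is_grad_enabled() -> bool:
    return _grad_enabled


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, dtype=None, name: str = ""):
        self.data = np.asarray(data, dtype=dtype)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = ()
        self._backward = None
        self.name = name

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo = _postorder(self)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node.grad = None  # intermediate grads are not retained

    # -- operator sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other, self.dtype))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _as_tensor(other, self.dtype))

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other, self.dtype), -1.0))

    def __rsub__(self, other):
        return add(_as_tensor(other, self.dtype), mul(self, -1.0))

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / other)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, item):
        return getitem(self, item)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean_(self, axis=axis, keepdims=keepdims)


def _postorder(root: Tensor):
    order, state = [], {}
    stack = [root]
    while stack:
        node = stack[-1]
        st = state.get(id(node), 0)
        if st == 0:
            state[id(node)] = 1
            for p in node._parents:
                if state.get(id(p), 0) == 0:
                    stack.append(p)
        else:
            stack.pop()
            if st == 1:
                state[id(node)] = 2
                order.append(node)
    return order


def _as_tensor(x, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))


def _node(data, parents, backward) -> Tensor:
    req = _grad_enabled and any(p.requires_grad or p._parents for p in parents)
    out = Tensor(data)
    if req:
        out.requires_grad = False  # only leaves marked by the user carry True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == tuple(shape):
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _wants(t: Tensor) -> bool:
    return t.requires_grad or t._parents


# -- primitives -----------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data

    def backward(g):
        if _wants(a):
            a._accumulate(_unbroadcast(g, a.shape))
        if _wants(b):
            b._accumulate(_unbroadcast(g, b.shape))

    return _node(data, (a, b), backward)


def mul(a: Tensor, b) -> Tensor:
    b = _as_tensor(b, a.dtype)
    data = a.data * b.data

    def backward(g):
        if _wants(a):
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if _wants(b):
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _node(data, (a, b), backward)


def power(a: Tensor, p: float) -> Tensor:
    data = a.data ** p

    def backward(g):
        if _wants(a):
            a._accumulate(g * p * a.data ** (p - 1.0))

    return _node(data, (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product with numpy broadcasting over leading axes."""
    data = np.matmul(a.data, b.data)

    def backward(g):
        if _wants(a):
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accumulate(_unbroadcast(ga, a.shape))
        if _wants(b):
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accumulate(_unbroadcast(gb, b.shape))

    return _node(data, (a, b), backward)


def reshape(a: Tensor, shape) -> Tensor:
    data = a.data.reshape(shape)

    def backward(g):
        if _wants(a):
            a._accumulate(g.reshape(a.shape))

    return _node(data, (a,), backward)


def transpose(a: Tensor, axes) -> Tensor:
    axes = tuple(axes)
    data = a.data.transpose(axes)
    inv = tuple(np.argsort(axes))

    def backward(g):
        if _wants(a):
            a._accumulate(g.transpose(inv))

    return _node(data, (a,), backward)


def _has_fancy_index(item) -> bool:
    parts = item if isinstance(item, tuple) else (item,)
    return any(isinstance(p, (np.ndarray, list)) for p in parts)


def getitem(a: Tensor, item) -> Tensor:
    data = a.data[item]
    fancy = _has_fancy_index(item)

    def backward(g):
        if _wants(a):
            if a.grad is None:
                a.grad = np.zeros_like(a.data)
            if fancy:
                np.add.at(a.grad, item, g)
            else:
                a.grad[item] += g

    return _node(data, (a,), backward)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = list(tensors)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if _wants(t):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return _node(data, tuple(tensors), backward)


def sum_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if not _wants(a):
            return
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.shape))
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.shape))

    return _node(data, (a,), backward)


def mean_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = a.data.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def relu(a: Tensor) -> Tensor:
    data = np.maximum(a.data, 0)

    def backward(g):
        if _wants(a):
            a._accumulate(g * (a.data > 0))

    return _node(data, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    data = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))

    def backward(g):
        if _wants(a):
            a._accumulate(g * data * (1.0 - data))

    return _node(data, (a,), backward)


def tanh(a: Tensor) -> Tensor:
    data = np.tanh(a.data)

    def backward(g):
        if _wants(a):
            a._accumulate(g * (1.0 - data * data))

    return _node(data, (a,), backward)


def exp(a: Tensor) -> Tensor:
    data = np.exp(a.data)

    def backward(g):
        if _wants(a):
            a._accumulate(g * data)

    return _node(data, (a,), backward)


def log(a: Tensor) -> Tensor:
    data = np.log(a.data)

    def backward(g):
        if _wants(a):
            a._accumulate(g / a.data)

    return _node(data, (a,), backward)


def sqrt(a: Tensor) -> Tensor:
    data = np.sqrt(a.data)

    def backward(g):
        if _wants(a):
            a._accumulate(g * 0.5 / data)

    return _node(data, (a,), backward)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    x = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(x)
    data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if _wants(a):
            dot = (g * data).sum(axis=axis, keepdims=True)
            a._accumulate(data * (g - dot))

    return _node(data, (a,), backward)


def embedding(table: Tensor, indices: np.ndarray) -> Tensor:
    """Row gather ``table[indices]`` with scatter-add backward."""
    idx = np.asarray(indices)
    data = table.data[idx]

    def backward(g):
        if _wants(table):
            V, d = table.shape
            flat_idx = idx.ravel()
            gflat = g.reshape(-1, d)
            full = np.empty_like(table.data)
            for c in range(d):  # bincount per column beats scatter-add here
                full[:, c] = np.bincount(flat_idx, weights=gflat[:, c],
                                         minlength=V)
            table._accumulate(full)

    return _node(data, (table,), backward)


def conv1d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Valid 1-D convolution, stride 1, over the middle (length) axis.

    ``x``: (B, L, C_in); ``weight``: (K, C_in, C_out); ``bias``: (C_out,).
    Returns (B, L-K+1, C_out).  The im2col buffer is recomputed in the
    backward pass rather than stored.
    """
    B, L, Cin = x.shape
    K, _, Cout = weight.shape
    if L < K:
        raise ValueError(f"input length {L} shorter than kernel {K}")
    Lp = L - K + 1
    wmat = weight.data.reshape(K * Cin, Cout)

    def im2col(arr):
        win = np.lib.stride_tricks.sliding_window_view(arr, K, axis=1)
        # win: (B, Lp, Cin, K) -> (B, Lp, K, Cin) -> (B*Lp, K*Cin)
        return np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B * Lp, K * Cin)

    col = im2col(x.data)
    data = (col @ wmat + bias.data).reshape(B, Lp, Cout)
    saved = [col] if (_grad_enabled and (_wants(weight) or _wants(x))) else []
    del col

    def backward(g):
        gflat = g.reshape(B * Lp, Cout)
        col_b = saved[0]
        if _wants(weight):
            weight._accumulate((col_b.T @ gflat).reshape(K, Cin, Cout))
        if _wants(bias):
            bias._accumulate(gflat.sum(axis=0))
        if _wants(x):
            dcol = (gflat @ wmat.T).reshape(B, Lp, K, Cin)
            dx = np.zeros_like(x.data)
            for j in range(K):
                dx[:, j:j + Lp, :] += dcol[:, :, j, :]
            x._accumulate(dx)
        saved.clear()

    return _node(data, (x, weight, bias), backward)


def maxpool1d(x: Tensor, kernel: int) -> Tensor:
    """Non-overlapping max pooling over the middle axis; remainder dropped.

    ``x``: (B, L, C) -> (B, floor(L/kernel), C).
    """
    B, L, C = x.shape
    Lp = L // kernel
    if Lp < 1:
        raise ValueError(f"length {L} shorter than pooling kernel {kernel}")
    blocks = x.data[:, :Lp * kernel, :].reshape(B, Lp, kernel, C)
    arg = blocks.argmax(axis=2)
    data = np.take_along_axis(blocks, arg[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(g):
        if _wants(x):
            dblocks = np.zeros((B, Lp, kernel, C), dtype=x.dtype)
            np.put_along_axis(dblocks, arg[:, :, None, :], g[:, :, None, :], axis=2)
            dx = np.zeros_like(x.data)
            dx[:, :Lp * kernel, :] = dblocks.reshape(B, Lp * kernel, C)
            x._accumulate(dx)

    return _node(data, (x,), backward)


def gru_sequence(xp: Tensor, w_hh: Tensor, b_hh: Tensor,
                 reverse: bool = False) -> Tensor:
    """One GRU direction over a whole sequence, as a single fused op.

    ``xp``: the precomputed input projections ``x @ W_ih + b_ih`` with
    shape (B, L, 3h), gate order (reset, update, candidate);
    ``w_hh``: (h, 3h); ``b_hh``: (3h,).  Initial state is zero.
    Backpropagation through time is hand-written, which keeps the tape
    to one node for the entire recurrence.
    """
    B, L, H3 = xp.shape
    h = H3 // 3
    whh = w_hh.data
    bhh = b_hh.data
    steps = range(L - 1, -1, -1) if reverse else range(L)

    out = np.empty((B, L, h), dtype=xp.dtype)
    R = np.empty((L, B, h), dtype=xp.dtype)
    Z = np.empty((L, B, h), dtype=xp.dtype)
    N = np.empty((L, B, h), dtype=xp.dtype)
    GHN = np.empty((L, B, h), dtype=xp.dtype)
    HPREV = np.empty((L, B, h), dtype=xp.dtype)

    state = np.zeros((B, h), dtype=xp.dtype)
    xpd = xp.data
    for t in steps:
        gh = state @ whh + bhh
        gi = xpd[:, t, :]
        r = _sig(gi[:, :h] + gh[:, :h])
        z = _sig(gi[:, h:2 * h] + gh[:, h:2 * h])
        ghn = gh[:, 2 * h:]
        n = np.tanh(gi[:, 2 * h:] + r * ghn)
        HPREV[t] = state
        R[t], Z[t], N[t], GHN[t] = r, z, n, ghn
        state = (1.0 - z) * n + z * state
        out[:, t, :] = state

    def backward(g):
        dxp = np.zeros_like(xpd) if _wants(xp) else None
        dwhh = np.zeros_like(whh)
        dbhh = np.zeros_like(bhh)
        carry = np.zeros((B, h), dtype=xp.dtype)
        dgh = np.empty((B, 3 * h), dtype=xp.dtype)
        for t in reversed(list(steps)):
            dh = g[:, t, :] + carry
            r, z, n, ghn, hprev = R[t], Z[t], N[t], GHN[t], HPREV[t]
            dn_pre = dh * (1.0 - z) * (1.0 - n * n)
            dz_pre = dh * (hprev - n) * z * (1.0 - z)
            dr_pre = dn_pre * ghn * r * (1.0 - r)
            dgh[:, :h] = dr_pre
            dgh[:, h:2 * h] = dz_pre
            dgh[:, 2 * h:] = dn_pre * r
            if dxp is not None:
                dxp[:, t, :h] = dr_pre
                dxp[:, t, h:2 * h] = dz_pre
                dxp[:, t, 2 * h:] = dn_pre
            dwhh += hprev.T @ dgh
            dbhh += dgh.sum(axis=0)
            carry = dh * z + dgh @ whh.T
        if dxp is not None:
            xp._accumulate(dxp)
        if _wants(w_hh):
            w_hh._accumulate(dwhh)
        if _wants(b_hh):
            b_hh._accumulate(dbhh)

    return _node(out, (xp, w_hh, b_hh), backward)


def _sig(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
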