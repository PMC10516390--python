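"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numeric core of the package: a tape-based autodiff engine
providing exactly the operations the forecasting networks need — 2D
convolution with same-padding, elementwise arithmetic and activations,
channel concatenation/slicing, reductions and group normalization.
Gradients are accumulated by a reverse topological sweep over the graph.

Convolutions are stride-1, zero-padded to preserve spatial shape (odd
kernels only), with channels-last (N, H, W, C) activations so the im2col
buffers feed matrix multiplication without transposes.  The backward
pass propagates the input gradient by col2im (project the output
gradient through the kernel matrix, then scatter-add the kh*kw shifted
copies) and the kernel gradient by an im2col/output-gradient product.
The recurrent gate algebra is additionally available as a fused node
(:func:`lstm_cell`) whose hand-derived backward is verified against both
the primitive-op composition and finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "sub",
    "mul",
    "concat",
    "narrow",
    "sigmoid",
    "tanh",
    "leaky_relu",
    "conv2d",
    "group_norm",
    "permute",
    "reduce_sum",
    "powc",
    "mse",
    "zeros_like",
]


class Tensor:
    """A node in the computation graph wrapping a numpy array.

    ``requires_grad`` tensors accumulate into ``.grad`` during
    :meth:`backward`.  Graphs are single-use: call ``backward`` once per
    forward pass.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # operator sugar
    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def detach(self):
        return Tensor(self.data, requires_grad=False)

    def backward(self, grad=None):
        """Backpropagate ``grad`` (defaults to 1 for scalars) through the graph."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=self.data.dtype)

        order = []
        seen = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))

        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if not node.requires_grad and node._backward is not None:
                node.grad = None  # free intermediate gradients eagerly


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _tracked(*tensors):
    return any(t.requires_grad or t._backward is not None for t in tensors)


def _make(data, parents, backward_fn):
    out = Tensor(data)
    if _tracked(*parents):
        out._parents = tuple(parents)
        out._backward = backward_fn
    return out


def _accumulate(t, g):
    if not (t.requires_grad or t._backward is not None):
        return
    if t.grad is None:
        # views and read-only arrays are copied so the stored grad is owned
        t.grad = g.copy() if g.base is not None or g.flags.writeable is False else g
    else:
        np.add(t.grad, g, out=t.grad)


def _unbroadcast(g, shape):
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def zeros_like(t):
    return Tensor(np.zeros_like(t.data))


def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g, a.shape))
        _accumulate(b, _unbroadcast(g, b.shape))

    return _make(out_data, (a, b), backward)


def sub(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data - b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g, a.shape))
        _accumulate(b, _unbroadcast(-g, b.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g * b.data, a.shape))
        _accumulate(b, _unbroadcast(g * a.data, b.shape))

    return _make(out_data, (a, b), backward)


def concat(tensors, axis):
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]

    def backward(g):
        splits = np.split(g, np.cumsum(sizes)[:-1], axis=axis)
        for t, piece in zip(tensors, splits):
            _accumulate(t, piece)

    return _make(out_data, tensors, backward)


def narrow(t, axis, start, length):
    """Contiguous slice ``[start, start+length)`` along ``axis``."""
    t = _as_tensor(t)
    index = [slice(None)] * t.data.ndim
    index[axis] = slice(start, start + length)
    index = tuple(index)
    out_data = t.data[index]

    def backward(g):
        full = np.zeros_like(t.data)
        full[index] = g
        _accumulate(t, full)

    return _make(out_data, (t,), backward)


def sigmoid(t):
    t = _as_tensor(t)
    # stable logistic via tanh: sigma(x) = (tanh(x/2) + 1) / 2
    out_data = 0.5 * (np.tanh(0.5 * t.data) + 1.0)

    def backward(g):
        _accumulate(t, g * out_data * (1.0 - out_data))

    return _make(out_data, (t,), backward)


def tanh(t):
    t = _as_tensor(t)
    out_data = np.tanh(t.data)

    def backward(g):
        _accumulate(t, g * (1.0 - out_data * out_data))

    return _make(out_data, (t,), backward)


def leaky_relu(t, slope=0.2):
    t = _as_tensor(t)
    out_data = np.where(t.data >= 0, t.data, slope * t.data)

    def backward(g):
        _accumulate(t, np.where(t.data >= 0, g, slope * g))

    return _make(out_data, (t,), backward)


def permute(t, axes):
    """Axis permutation (materialized, so downstream matmuls stay fast)."""
    t = _as_tensor(t)
    out_data = np.ascontiguousarray(t.data.transpose(axes))
    inverse = np.argsort(axes)

    def backward(g):
        _accumulate(t, np.ascontiguousarray(g.transpose(inverse)))

    return _make(out_data, (t,), backward)


# im2col buffers above this size are recomputed in the backward pass
# instead of being cached on the graph
_COLS_CACHE_LIMIT = 8 << 20


def _im2col(x, kh, kw):
    """Channels-last im2col: x (N, H, W, C) -> (N*H*W, kh*kw*C), zero padded."""
    n, h, w, c = x.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    cols = np.empty((n, h, w, kh * kw * c), dtype=x.dtype)
    for di in range(kh):
        for dj in range(kw):
            k = di * kw + dj
            cols[..., k * c:(k + 1) * c] = xp[:, di:di + h, dj:dj + w, :]
    return cols.reshape(n * h * w, kh * kw * c)


def _corr2d(x, w):
    """Same-padding cross-correlation of x:(N,H,W,C) with w:(O,C,kh,kw)."""
    o, c, kh, kw = w.shape
    n, h, wd, _ = x.shape
    cols = _im2col(x, kh, kw)
    wmat = w.transpose(2, 3, 1, 0).reshape(kh * kw * c, o)
    return (cols @ np.ascontiguousarray(wmat)).reshape(n, h, wd, o), cols


def conv2d(x, w, b=None):
    """Same-padding stride-1 2D convolution (cross-correlation convention).

    Channels-last activations: x is (N, H, W, C); the kernel keeps the
    conventional (O, C, kh, kw) layout with odd kh, kw; b is (O,) or None.
    """
    x, w = _as_tensor(x), _as_tensor(w)
    o, cin, kh, kw = w.data.shape
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("conv2d requires odd kernel dimensions for same padding")
    if x.data.ndim != 4 or x.data.shape[3] != cin:
        raise ValueError(
            f"conv2d shape mismatch: input {x.data.shape} (N,H,W,C) vs kernel {w.data.shape}"
        )
    out_data, cols = _corr2d(x.data, w.data)
    cached_cols = cols if cols.nbytes <= _COLS_CACHE_LIMIT else None
    parents = [x, w]
    if b is not None:
        b = _as_tensor(b)
        out_data = out_data + b.data
        parents.append(b)

    def backward(g):
        g = np.ascontiguousarray(g)
        n, h, wd = g.shape[:3]
        gmat = g.reshape(-1, o)
        # dL/dx by col2im: project g back through the kernel matrix, then
        # scatter-add the kh*kw shifted copies into the padded input grad
        wmat = w.data.transpose(2, 3, 1, 0).reshape(kh * kw * cin, o)
        gcols = (gmat @ wmat.T).reshape(n, h, wd, kh * kw * cin)
        ph, pw = kh // 2, kw // 2
        gxp = np.zeros((n, h + 2 * ph, wd + 2 * pw, cin), dtype=g.dtype)
        for di in range(kh):
            for dj in range(kw):
                k = di * kw + dj
                gxp[:, di:di + h, dj:dj + wd, :] += gcols[..., k * cin:(k + 1) * cin]
        _accumulate(x, gxp[:, ph:ph + h, pw:pw + wd, :])
        cols_b = cached_cols if cached_cols is not None else _im2col(x.data, kh, kw)
        gw = cols_b.T @ gmat  # (kh*kw*C, O)
        _accumulate(w, np.ascontiguousarray(
            gw.reshape(kh, kw, cin, o).transpose(3, 2, 0, 1)))
        if b is not None:
            _accumulate(b, gmat.sum(axis=0))

    return _make(out_data, parents, backward)


def group_norm(x, n_groups, gamma, beta, eps=1e-5):
    """Group normalization over (H, W, channel-group) with affine parameters.

    x: (N, H, W, C) channels-last; gamma, beta: (C,).
    """
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    n, h, w, c = x.data.shape
    if c % n_groups:
        raise ValueError(f"channels {c} not divisible by {n_groups} groups")
    cg = c // n_groups
    xg = x.data.reshape(n, h * w, n_groups, cg)
    mean = xg.mean(axis=(1, 3), keepdims=True)
    var = xg.var(axis=(1, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = ((xg - mean) * inv).reshape(n, h, w, c)
    out_data = xhat * gamma.data + beta.data

    def backward(g):
        _accumulate(gamma, (g * xhat).sum(axis=(0, 1, 2)))
        _accumulate(beta, g.sum(axis=(0, 1, 2)))
        gx = (g * gamma.data).reshape(n, h * w, n_groups, cg)
        xh = xhat.reshape(n, h * w, n_groups, cg)
        dx = inv * (gx - gx.mean(axis=(1, 3), keepdims=True)
                    - xh * (gx * xh).mean(axis=(1, 3), keepdims=True))
        _accumulate(x, dx.reshape(n, h, w, c))

    return _make(out_data, (x, gamma, beta), backward)


def reduce_sum(t, axes, keepdims=False):
    t = _as_tensor(t)
    axes = tuple(axes)
    out_data = t.data.sum(axis=axes, keepdims=keepdims)

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axes)
        _accumulate(t, np.broadcast_to(g, t.data.shape))

    return _make(out_data, (t,), backward)


def powc(t, p):
    """Elementwise power with a constant exponent (data must keep x**p finite)."""
    t = _as_tensor(t)
    out_data = t.data ** p

    def backward(g):
        _accumulate(t, g * p * t.data ** (p - 1.0))

    return _make(out_data, (t,), backward)


def lstm_cell(gates, c_prev, w_ci=None, w_cf=None, w_co=None):
    """Fused LSTM elementwise block: gate activations through H_t in one node.

    ``gates`` holds the pre-activations of i, f, g (cell candidate) and o,
    stacked along the last axis in that order; ``w_ci``/``w_cf``/``w_co``
    are optional Hadamard peephole weights (broadcast against the cell
    state).  Returns (H_t, C_t).  Mathematically identical to composing
    the primitive ops; fused for speed with a hand-derived backward.
    """
    gates, c_prev = _as_tensor(gates), _as_tensor(c_prev)
    nh = gates.data.shape[-1]
    if nh % 4:
        raise ValueError("gates tensor must stack 4 gate blocks on the last axis")
    h = nh // 4
    gi, gf, gg, go = (gates.data[..., k * h:(k + 1) * h] for k in range(4))
    if w_ci is not None:
        w_ci, w_cf, w_co = _as_tensor(w_ci), _as_tensor(w_cf), _as_tensor(w_co)
        gi = gi + w_ci.data * c_prev.data
        gf = gf + w_cf.data * c_prev.data
    i = 0.5 * (np.tanh(0.5 * gi) + 1.0)
    f = 0.5 * (np.tanh(0.5 * gf) + 1.0)
    g = np.tanh(gg)
    c = f * c_prev.data + i * g
    if w_co is not None:
        go = go + w_co.data * c
    o = 0.5 * (np.tanh(0.5 * go) + 1.0)
    tc = np.tanh(c)
    h_data = o * tc

    peeps = [p for p in (w_ci, w_cf, w_co) if p is not None]
    c_node = _make(c, (gates, c_prev, *peeps), None)
    stash = {}

    def backward_h(gh):
        dpre_o = gh * tc * o * (1.0 - o)
        stash["dpre_o"] = dpre_o
        dc = gh * o * (1.0 - tc * tc)
        if w_co is not None:
            dc = dc + dpre_o * w_co.data
            _accumulate(w_co, _unbroadcast(dpre_o * c, w_co.shape))
        _accumulate(c_node, dc)

    def backward_c(gc):
        dpre_i = gc * g * i * (1.0 - i)
        dpre_f = gc * c_prev.data * f * (1.0 - f)
        dg = gc * i * (1.0 - g * g)
        dgates = np.empty_like(gates.data)
        dgates[..., 0:h] = dpre_i
        dgates[..., h:2 * h] = dpre_f
        dgates[..., 2 * h:3 * h] = dg
        dgates[..., 3 * h:4 * h] = stash.pop("dpre_o", 0.0)
        _accumulate(gates, dgates)
        dc_prev = gc * f
        if w_ci is not None:
            dc_prev = dc_prev + dpre_i * w_ci.data + dpre_f * w_cf.data
            _accumulate(w_ci, _unbroadcast(dpre_i * c_prev.data, w_ci.shape))
            _accumulate(w_cf, _unbroadcast(dpre_f * c_prev.data, w_cf.shape))
        _accumulate(c_prev, dc_prev)

    if c_node._parents:
        c_node._backward = backward_c
    h_node = _make(h_data, (c_node,), backward_h)
    return h_node, c_node


def mse(pred, target):
    """Mean squared error; target is treated as a constant."""
    pred = _as_tensor(pred)
    tgt = target.data if isinstance(target, Tensor) else np.asarray(target)
    diff = pred.data - tgt
    out_data = np.asarray((diff * diff).mean(), dtype=pred.data.dtype)

    def backward(g):
        _accumulate(pred, (2.0 / diff.size) * g * diff)

    return _make(out_data, (pred,), backward)
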