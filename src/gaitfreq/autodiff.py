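"""Minimal reverse-mode automatic differentiation over numpy arrays.

The network in this package is small (a handful of graph-mixing, pointwise
and FFT-filter operations), so instead of a full framework we use a compact
tape-based engine: each operation builds a :class:`Tensor` holding the result
and a closure that propagates the upstream gradient to its parents.
``Tensor.backward`` walks the tape in reverse topological order.

All custom vector-Jacobian products (notably the frequency-domain filter,
which is a real symmetric linear operator and therefore self-adjoint) are
validated against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "add",
    "mul",
    "leaky_relu",
    "relu",
    "mean",
    "reshape",
    "concat",
    "take",
    "channel_linear",
    "joint_mix",
    "linear",
    "spectral_filter",
    "temporal_conv",
    "label_smoothed_ce",
]


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad=False, parents=(), vjp=None):
        data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float64)
        self.data = data  # dtype is preserved (float32 models stay float32)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._vjp = vjp

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph traversal ---------------------------------------------------
    def backward(self, grad=None):
        """Accumulate gradients of a scalar (or given seed) into the tape."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without seed requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad)
        for node in reversed(topo):
            if node._vjp is not None and node.grad is not None:
                node._vjp(node.grad)

    def _accum(self, grad):
        # vjp outputs are fresh arrays and never mutated afterwards, so no copy
        self.grad = grad if self.grad is None else self.grad + grad

    def zero_grad(self):
        self.grad = None

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), -1.0))


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad, shape):
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# -- elementwise ----------------------------------------------------------


def add(a, b):
    if isinstance(b, (int, float)) and isinstance(a, Tensor):
        # scalar fast path: numpy weak promotion keeps a's dtype
        out = Tensor(a.data + b, parents=(a,))

        def vjp_s(g):
            if a.requires_grad:
                a._accum(g)

        out._vjp = vjp_s
        return out
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data + b.data, parents=(a, b))

    def vjp(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    out._vjp = vjp
    return out


def mul(a, b):
    if isinstance(b, (int, float)) and isinstance(a, Tensor):
        out = Tensor(a.data * b, parents=(a,))

        def vjp_s(g):
            if a.requires_grad:
                a._accum(g * b)

        out._vjp = vjp_s
        return out
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data * b.data, parents=(a, b))

    def vjp(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    out._vjp = vjp
    return out


def leaky_relu(x, slope=0.01):
    x = as_tensor(x)
    factor = np.where(x.data >= 0, 1.0, slope).astype(x.data.dtype)
    out = Tensor(x.data * factor, parents=(x,))

    def vjp(g):
        if x.requires_grad:
            x._accum(g * factor)

    out._vjp = vjp
    return out


def relu(x):
    return leaky_relu(x, slope=0.0)


def mean(x, axes=None, keepdims=False):
    x = as_tensor(x)
    out_data = x.data.mean(axis=axes, keepdims=keepdims)
    out = Tensor(out_data, parents=(x,))
    count = x.data.size / max(out_data.size, 1)

    def vjp(g):
        if not x.requires_grad:
            return
        g = np.asarray(g)
        if axes is not None and not keepdims:
            ax = (axes,) if np.isscalar(axes) else tuple(axes)
            g = np.expand_dims(g, tuple(a % x.data.ndim for a in ax))
        x._accum(np.broadcast_to(g, x.data.shape) / count)

    out._vjp = vjp
    return out


def reshape(x, shape):
    x = as_tensor(x)
    out = Tensor(x.data.reshape(shape), parents=(x,))

    def vjp(g):
        if x.requires_grad:
            x._accum(g.reshape(x.data.shape))

    out._vjp = vjp
    return out


def concat(xs, axis=0):
    xs = [as_tensor(x) for x in xs]
    out = Tensor(np.concatenate([x.data for x in xs], axis=axis), parents=tuple(xs))
    sizes = [x.data.shape[axis] for x in xs]
    offsets = np.cumsum([0] + sizes)

    def vjp(g):
        for x, lo, hi in zip(xs, offsets[:-1], offsets[1:]):
            if x.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                x._accum(g[tuple(sl)])

    out._vjp = vjp
    return out


def take(x, indices):
    """Gather along the leading axis; the adjoint is scatter-add."""
    x = as_tensor(x)
    indices = np.asarray(indices, dtype=np.intp)
    out = Tensor(x.data[indices], parents=(x,))

    def vjp(g):
        if x.requires_grad:
            acc = np.zeros_like(x.data)
            np.add.at(acc, indices, g)
            x._accum(acc)

    out._vjp = vjp
    return out


# -- linear maps -----------------------------------------------------------


def channel_linear(x, w, b=None):
    """Pointwise channel mixing on a (N, C, V, T) feature tensor.

    ``y[n, o] = sum_c w[o, c] x[n, c] (+ b[o])`` applied at every joint/frame.
    """
    x, w = as_tensor(x), as_tensor(w)
    # route the contraction through BLAS: mix channels on the second axis
    y = np.moveaxis(np.tensordot(w.data, x.data, axes=([1], [1])), 0, 1)
    parents = [x, w]
    if b is not None:
        b = as_tensor(b)
        y = y + b.data[None, :, None, None]
        parents.append(b)
    out = Tensor(np.ascontiguousarray(y), parents=tuple(parents))

    def vjp(g):
        if x.requires_grad:
            dx = np.moveaxis(np.tensordot(w.data.T, g, axes=([1], [1])), 0, 1)
            x._accum(np.ascontiguousarray(dx))
        if w.requires_grad:
            w._accum(np.tensordot(g, x.data, axes=([0, 2, 3], [0, 2, 3])))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))

    out._vjp = vjp
    return out


def joint_mix(x, m):
    """Mix the joint axis of a (N, C, V, T) tensor: ``y[..., i, :] = sum_j m[i, j] x[..., j, :]``.

    The time axis is kept last throughout the network so this is a single
    broadcast matmul and the FFT filter's spatial flattening is a free
    reshape.
    """
    x, m = as_tensor(x), as_tensor(m)
    out = Tensor(np.matmul(m.data, x.data), parents=(x, m))

    def vjp(g):
        if x.requires_grad:
            x._accum(np.matmul(m.data.T, g))
        if m.requires_grad:
            m._accum(np.tensordot(g, x.data, axes=([0, 1, 3], [0, 1, 3])))

    out._vjp = vjp
    return out


def linear(x, w, b=None):
    """Dense layer on (N, D): ``y = x @ w.T + b`` with w of shape (K, D)."""
    x, w = as_tensor(x), as_tensor(w)
    y = x.data @ w.data.T
    parents = [x, w]
    if b is not None:
        b = as_tensor(b)
        y = y + b.data[None, :]
        parents.append(b)
    out = Tensor(y, parents=tuple(parents))

    def vjp(g):
        if x.requires_grad:
            x._accum(g @ w.data)
        if w.requires_grad:
            w._accum(g.T @ x.data)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=0))

    out._vjp = vjp
    return out


# -- frequency-domain filter ----------------------------------------------


def _spectral_transform(xs):
    """Orthonormal 2D transform: real FFT along time, full FFT along space."""
    return np.fft.rfft2(xs, axes=(1, 2), norm="ortho")


def _spectral_inverse(yf, n_time):
    return np.fft.irfft2(yf, s=(yf.shape[1], n_time), axes=(1, 2), norm="ortho")


def spectral_filter(x, a_sym, b):
    """Apply a separable real mask in the 2D frequency domain of (N, C, V, T).

    The (C, V) axes are flattened into a spatial axis of length S = C*V; the
    transform is an orthonormal FFT over space and a real FFT over time.  The
    spatial factor ``a_sym`` (length S) must be symmetric under s -> (S-s) mod S
    so that the filtered operator maps real signals to real signals; the
    temporal factor ``b`` has length floor(T/2)+1 (real-FFT bins).

    With a real symmetric mask the whole operator is a real symmetric matrix,
    so the adjoint needed in the backward pass is the operator itself.
    """
    x, a_sym, b = as_tensor(x), as_tensor(a_sym), as_tensor(b)
    n, c, v, t = x.data.shape
    s = c * v
    f = t // 2 + 1
    if a_sym.data.shape != (s,) or b.data.shape != (f,):
        raise ValueError(
            f"mask shapes {a_sym.data.shape}/{b.data.shape} do not match S={s}, F={f}"
        )
    xs = x.data.reshape(n, s, t)
    xh = _spectral_transform(xs)
    mask = (a_sym.data[:, None] * b.data[None, :]).astype(x.data.dtype)
    ys = _spectral_inverse(mask[None] * xh, t)
    out = Tensor(ys.reshape(n, c, v, t), parents=(x, a_sym, b))

    # weight of each stored real-FFT bin in the full spectrum
    dup = np.full(f, 2.0, dtype=x.data.dtype)
    dup[0] = 1.0
    if t % 2 == 0:
        dup[-1] = 1.0

    def vjp(g):
        gh = _spectral_transform(g.reshape(n, s, t))
        if x.requires_grad:
            x._accum(_spectral_inverse(mask[None] * gh, t).reshape(n, c, v, t))
        if a_sym.requires_grad or b.requires_grad:
            r = (np.conj(gh) * xh).real.sum(axis=0) * dup[None, :]
            if a_sym.requires_grad:
                a_sym._accum(r @ b.data)
            if b.requires_grad:
                b._accum(a_sym.data @ r)

    out._vjp = vjp
    return out


# -- temporal convolution (TCN baseline) ----------------------------------


def temporal_conv(x, w):
    """Depthwise forward-window temporal convolution on (N, C, V, T).

    ``y[n, c, v, t] = sum_tau w[c, tau] * x[n, c, v, t + tau]`` with zero
    padding past the end of the sequence (window length s_d = w.shape[1]).
    """
    x, w = as_tensor(x), as_tensor(w)
    n, c, v, t = x.data.shape
    cw, sd = w.data.shape
    if cw != c:
        raise ValueError(f"kernel channels {cw} != input channels {c}")
    if sd > t:
        raise ValueError(f"window s_d={sd} exceeds T={t}")
    y = np.zeros_like(x.data)
    for tau in range(sd):
        y[..., : t - tau] += w.data[None, :, None, tau : tau + 1] * x.data[..., tau:]
    out = Tensor(y, parents=(x, w))

    def vjp(g):
        if x.requires_grad:
            dx = np.zeros_like(x.data)
            for tau in range(sd):
                dx[..., tau:] += w.data[None, :, None, tau : tau + 1] * g[..., : t - tau]
            x._accum(dx)
        if w.requires_grad:
            dw = np.zeros_like(w.data)
            for tau in range(sd):
                dw[:, tau] = (g[..., : t - tau] * x.data[..., tau:]).sum(axis=(0, 2, 3))
            w._accum(dw)

    out._vjp = vjp
    return out


# -- loss ------------------------------------------------------------------


def label_smoothed_ce(scores, labels, epsilon):
    """Label-smoothed cross-entropy, averaged over the batch.

    The smoothed target puts 1 - epsilon on the true class and
    epsilon / (K - 1) on each of the others.
    """
    scores = as_tensor(scores)
    labels = np.asarray(labels, dtype=np.intp)
    n, k = scores.data.shape
    if not 0.0 <= epsilon < 1.0:
        raise ValueError(f"label smoothing epsilon must be in [0, 1), got {epsilon}")
    if labels.min(initial=0) < 0 or labels.max(initial=0) >= k:
        raise ValueError("labels out of range")
    z = scores.data - scores.data.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    target = np.full((n, k), epsilon / (k - 1) if k > 1 else 0.0)
    target[np.arange(n), labels] = 1.0 - epsilon
    loss = -(target * logp).sum(axis=1).mean()
    out = Tensor(loss, parents=(scores,))

    def vjp(g):
        if scores.requires_grad:
            p = np.exp(logp)
            scores._accum((g * (p - target) / n).astype(scores.data.dtype))

    out._vjp = vjp
    return out
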