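"""Compact reverse-mode automatic differentiation over numpy arrays.

Only the operations the spatiotemporal graph network needs are provided:
broadcast-aware arithmetic, batched matmul, reductions, the activations, a
1x1 channel convolution, a strided temporal convolution, and cross-entropy.
Gradients are accumulated by topological-order backpropagation; everything is
float64 so finite-difference checks are meaningful.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode); nests safely."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction -----------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = parents
            out._backward = backward
        return out

    # -- introspection ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd ---------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: Tensor) -> None:
            stack = [(node, False)]
            while stack:
                n, done = stack.pop()
                if done:
                    topo.append(n)
                    continue
                if id(n) in seen or not n.requires_grad:
                    continue
                seen.add(id(n))
                stack.append((n, True))
                for p in n._parents:
                    stack.append((p, False))

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.grad is None:
                node.grad = np.zeros_like(node.data)
            node.grad = node.grad + g
            if node._backward is None:
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad or pg is None:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg
            # the node's contribution is propagated; release its closure so
            # activation memory is freed as backprop walks down the graph
            node._parents = ()
            node._backward = None

    def zero_grad(self) -> None:
        self.grad = None

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return div(self, other)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)


# ---------------------------------------------------------------------------
# primitive ops

def add(a, b) -> Tensor:
    a, b = Tensor._wrap(a), Tensor._wrap(b)
    return Tensor._make(
        a.data + b.data, (a, b),
        lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)))


def mul(a, b) -> Tensor:
    a, b = Tensor._wrap(a), Tensor._wrap(b)
    return Tensor._make(
        a.data * b.data, (a, b),
        lambda g: (_unbroadcast(g * b.data, a.data.shape),
                   _unbroadcast(g * a.data, b.data.shape)))


def div(a, b) -> Tensor:
    a, b = Tensor._wrap(a), Tensor._wrap(b)
    return Tensor._make(
        a.data / b.data, (a, b),
        lambda g: (_unbroadcast(g / b.data, a.data.shape),
                   _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape)))


def power(a, p: float) -> Tensor:
    a = Tensor._wrap(a)
    return Tensor._make(
        a.data ** p, (a,),
        lambda g: (g * p * a.data ** (p - 1),))


def exp(a) -> Tensor:
    a = Tensor._wrap(a)
    out_data = np.exp(a.data)
    return Tensor._make(out_data, (a,), lambda g: (g * out_data,))


def log(a) -> Tensor:
    a = Tensor._wrap(a)
    return Tensor._make(np.log(a.data), (a,), lambda g: (g / a.data,))


def matmul(a, b) -> Tensor:
    """Batched matrix product with numpy broadcasting on leading axes."""
    a, b = Tensor._wrap(a), Tensor._wrap(b)

    def backward(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        return (_unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape))

    return Tensor._make(np.matmul(a.data, b.data), (a, b), backward)


def relu(a) -> Tensor:
    a = Tensor._wrap(a)
    mask = a.data > 0
    return Tensor._make(np.where(mask, a.data, 0.0), (a,),
                        lambda g: (g * mask,))


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = Tensor._wrap(a)
    mask = a.data > 0
    scale = np.where(mask, 1.0, slope)
    return Tensor._make(a.data * scale, (a,), lambda g: (g * scale,))


def threshold(a, lam: float) -> Tensor:
    """Keep entries strictly above ``lam``, zero the rest (hard threshold)."""
    a = Tensor._wrap(a)
    mask = a.data > lam
    return Tensor._make(np.where(mask, a.data, 0.0), (a,),
                        lambda g: (g * mask,))


def reshape(a, shape) -> Tensor:
    a = Tensor._wrap(a)
    old = a.data.shape
    return Tensor._make(a.data.reshape(shape), (a,),
                        lambda g: (g.reshape(old),))


def transpose(a, axes) -> Tensor:
    a = Tensor._wrap(a)
    inv = np.argsort(axes)
    return Tensor._make(np.transpose(a.data, axes), (a,),
                        lambda g: (np.transpose(g, inv),))


def reduce_sum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = Tensor._wrap(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            return (np.broadcast_to(g, a.data.shape).copy(),)
        if not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, a.data.shape).copy(),)

    return Tensor._make(out_data, (a,), backward)


def reduce_mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = Tensor._wrap(a)
    if axis is None:
        count = a.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        count = int(np.prod([a.data.shape[ax] for ax in axes]))
    return mul(reduce_sum(a, axis=axis, keepdims=keepdims), 1.0 / count)


def softmax_rows(a) -> Tensor:
    """Softmax over the last axis (numerically shifted by a constant max)."""
    a = Tensor._wrap(a)
    shift = Tensor(a.data.max(axis=-1, keepdims=True))  # constant detach
    e = exp(a - shift)
    return div(e, reduce_sum(e, axis=-1, keepdims=True))


def batch_norm(x, gamma, beta, eps: float = 1e-5,
               mu=None, var=None) -> Tensor:
    """Fused train-mode batch normalization over all axes but the channel
    axis (axis 1), with affine parameters gamma/beta of shape (C,).

    A single op keeps only the normalized activations for backward, which
    matters for the wide layers of the backbone.  Precomputed batch ``mu``
    and ``var`` (keepdims ndarrays) may be passed to avoid a second pass.
    """
    x, gamma, beta = Tensor._wrap(x), Tensor._wrap(gamma), Tensor._wrap(beta)
    axes = tuple(i for i in range(x.ndim) if i != 1)
    bshape = tuple(x.shape[1] if i == 1 else 1 for i in range(x.ndim))
    m = x.size // x.shape[1]
    if mu is None:
        mu = x.data.mean(axis=axes, keepdims=True)
    xc = x.data - mu
    if var is None:
        var = (xc * xc).mean(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    del xc
    g_b = gamma.data.reshape(bshape)
    out_data = xhat * g_b + beta.data.reshape(bshape)

    def backward(g):
        dxhat = g * g_b
        s1 = dxhat.sum(axis=axes, keepdims=True)
        s2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
        dx = inv * (dxhat - s1 / m - xhat * s2 / m)
        dgamma = (g * xhat).sum(axis=axes).reshape(gamma.data.shape)
        dbeta = g.sum(axis=axes).reshape(beta.data.shape)
        return (dx, dgamma, dbeta)

    return Tensor._make(out_data, (x, gamma, beta), backward)


def conv1x1(x, w, b=None) -> Tensor:
    """Per-(frame, joint) channel map: x (N,C,T,V), w (C_out,C_in), b (C_out,)."""
    x, w = Tensor._wrap(x), Tensor._wrap(w)
    out_data = np.einsum("oc,nctv->notv", w.data, x.data, optimize=True)
    parents = [x, w]
    if b is not None:
        b = Tensor._wrap(b)
        out_data = out_data + b.data[None, :, None, None]
        parents.append(b)

    def backward(g):
        gx = np.einsum("oc,notv->nctv", w.data, g, optimize=True)
        gw = np.einsum("notv,nctv->oc", g, x.data, optimize=True)
        if b is not None:
            return (gx, gw, g.sum(axis=(0, 2, 3)))
        return (gx, gw)

    return Tensor._make(out_data, tuple(parents), backward)


def temporal_conv(x, w, b=None, stride: int = 1, pad: int = 4) -> Tensor:
    """Convolution along the frame axis: x (N,C,T,V), w (C_out,C_in,kt).

    Zero padding of ``pad`` frames on both sides; output length
    (T + 2*pad - kt)//stride + 1 (= ceil(T/stride) for kt odd, pad=(kt-1)/2).
    """
    x, w = Tensor._wrap(x), Tensor._wrap(w)
    N, C, T, V = x.data.shape
    kt = w.data.shape[2]
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (0, 0)))
    T_out = (T + 2 * pad - kt) // stride + 1
    idx = np.arange(T_out)[:, None] * stride + np.arange(kt)[None, :]
    # accumulate tap by tap so the (N, C, T_out, kt, V) im2col tensor is
    # never materialized (it dominates memory for wide layers)
    out_data = np.einsum("oc,nctv->notv", w.data[:, :, 0],
                         xp[:, :, idx[:, 0], :], optimize=True)
    for tap in range(1, kt):
        out_data += np.einsum("oc,nctv->notv", w.data[:, :, tap],
                              xp[:, :, idx[:, tap], :], optimize=True)
    parents = [x, w]
    if b is not None:
        b = Tensor._wrap(b)
        out_data = out_data + b.data[None, :, None, None]
        parents.append(b)

    def backward(g):
        gw = np.empty_like(w.data)
        gxp = np.zeros_like(xp)
        for tap in range(kt):
            cols_tap = xp[:, :, idx[:, tap], :]          # (N, C, T_out, V)
            gw[:, :, tap] = np.einsum("notv,nctv->oc", g, cols_tap,
                                      optimize=True)
            gcols_tap = np.einsum("oc,notv->nctv", w.data[:, :, tap],
                                  g, optimize=True)
            # idx[:, tap] is strictly increasing, so indices never repeat
            gxp[:, :, idx[:, tap], :] += gcols_tap
        gx = gxp[:, :, pad:pad + T, :]
        if b is not None:
            return (gx, gw, g.sum(axis=(0, 2, 3)))
        return (gx, gw)

    return Tensor._make(out_data, tuple(parents), backward)


def dropout(x, mask: np.ndarray, keep: float) -> Tensor:
    """Inverted dropout with a boolean mask (kept compact for backward)."""
    x = Tensor._wrap(x)
    scale = 1.0 / keep
    return Tensor._make(np.where(mask, x.data * scale, 0.0), (x,),
                        lambda g: (np.where(mask, g * scale, 0.0),))


def graph_conv(x, mixes, weights) -> Tensor:
    """Fused partitioned spatial graph convolution.

    out = sum_k W_k (x @ mix_k) with x (N, C_in, T, V), mix_k (V, V) or
    (N, 1, V, V), W_k (C_out, C_in).  One op instead of a 3K-op chain: only
    the input and the (small) mixing matrices are retained for backward; the
    per-partition mixed activations are recomputed there.
    """
    x = Tensor._wrap(x)
    mixes = [Tensor._wrap(m) for m in mixes]
    weights = [Tensor._wrap(w) for w in weights]
    out_data = None
    for m, w in zip(mixes, weights):
        mixed = np.matmul(x.data, m.data)
        term = np.einsum("oc,nctv->notv", w.data, mixed, optimize=True)
        out_data = term if out_data is None else out_data + term

    def backward(g):
        gx = np.zeros_like(x.data)
        grads_m, grads_w = [], []
        for m, w in zip(mixes, weights):
            gmixed = np.einsum("oc,notv->nctv", w.data, g, optimize=True)
            gx += np.matmul(gmixed, np.swapaxes(m.data, -1, -2))
            mixed = np.matmul(x.data, m.data)
            grads_w.append(np.einsum("notv,nctv->oc", g, mixed,
                                     optimize=True))
            if m.data.ndim == 2:
                gm = np.einsum("nctv,nctw->vw", x.data, gmixed,
                               optimize=True)
            else:
                gm = np.einsum("nctv,nctw->nvw", x.data, gmixed,
                               optimize=True)[:, None, :, :]
            grads_m.append(gm)
        return (gx, *grads_m, *grads_w)

    return Tensor._make(out_data, (x, *mixes, *weights), backward)


def cross_entropy(logits, labels) -> Tensor:
    """Mean cross-entropy of (N, K) logits against integer labels."""
    logits = Tensor._wrap(logits)
    z = logits.data
    labels = np.asarray(labels, dtype=int)
    n = z.shape[0]
    zmax = z.max(axis=1, keepdims=True)
    lse = zmax[:, 0] + np.log(np.exp(z - zmax).sum(axis=1))
    loss = (lse - z[np.arange(n), labels]).mean()

    def backward(g):
        p = np.exp(z - zmax)
        p /= p.sum(axis=1, keepdims=True)
        p[np.arange(n), labels] -= 1.0
        return (g * p / n,)

    return Tensor._make(loss, (logits,), backward)
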