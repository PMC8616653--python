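"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine in the micrograd style, sized for the
convolutional architectures in this package: every operation builds a
:class:`Tensor` node holding its forward value and a closure that
accumulates gradients into its parents. Convolutions are evaluated as a
loop over kernel taps, each tap a BLAS-backed ``tensordot``, which keeps
memory flat (no im2col buffer) while staying fast at the feature-map
sizes used here.

All operations preserve the dtype of their inputs, so float64 can be
used for numerical gradient checking while training runs in float32.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "mul",
    "relu",
    "sigmoid",
    "reshape",
    "concat",
    "matmul",
    "global_avg_pool",
    "conv2d",
    "depthwise_conv2d",
    "conv_transpose2x2",
    "maxpool2x2",
    "bilinear_up2x",
    "batchnorm2d",
    "softmax_cross_entropy",
]


class Tensor:
    """A node in the computation graph: an ndarray plus gradient plumbing."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self):
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def detach(self):
        return Tensor(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad, shape):
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def mul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def relu(x):
    x = _as_tensor(x)
    mask = x.data > 0
    out_data = x.data * mask

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor(out_data, parents=(x,), backward=backward)


def sigmoid(x):
    x = _as_tensor(x)
    s = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * s * (1.0 - s))

    return Tensor(s, parents=(x,), backward=backward)


def reshape(x, shape):
    x = _as_tensor(x)
    out_data = x.data.reshape(shape)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g.reshape(x.data.shape))

    return Tensor(out_data, parents=(x,), backward=backward)


def concat(tensors, axis=1):
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor(out_data, parents=tuple(tensors), backward=backward)


def matmul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return Tensor(out_data, parents=(a, b), backward=backward)


def global_avg_pool(x):
    """(N, C, H, W) -> (N, C) spatial mean."""
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    out_data = x.data.mean(axis=(2, 3))

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.broadcast_to(g[:, :, None, None] / (h * w), x.data.shape))

    return Tensor(out_data, parents=(x,), backward=backward)


def _pad_pair(pad):
    return (pad, pad) if isinstance(pad, int) else tuple(pad)


def _pad_hw(x, pad):
    ph, pw = _pad_pair(pad)
    if ph == 0 and pw == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))


def conv2d(x, w, b=None, stride=1, padding=0):
    """Cross-correlation of (N,C,H,W) with (O,C,kh,kw), optional bias (O,)."""
    x = _as_tensor(x)
    w = _as_tensor(w)
    b = _as_tensor(b) if b is not None else None
    n, c, h, ww_ = x.data.shape
    o, c2, kh, kw = w.data.shape
    if c != c2:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {c2}")
    s = stride
    ph, pw = _pad_pair(padding)
    ho = (h + 2 * ph - kh) // s + 1
    wo = (ww_ + 2 * pw - kw) // s + 1
    xp = _pad_hw(x.data, padding)
    out_data = np.zeros((n, o, ho, wo), dtype=x.data.dtype)
    for i in range(kh):
        for j in range(kw):
            xs = xp[:, :, i : i + s * ho : s, j : j + s * wo : s]
            # (O,C) . (N,C,Ho,Wo) over C -> (O,N,Ho,Wo)
            out_data += np.tensordot(w.data[:, :, i, j], xs, axes=([1], [1])).transpose(
                1, 0, 2, 3
            )
    if b is not None:
        out_data += b.data[None, :, None, None]

    def backward(g):
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        need_dx = x.requires_grad
        dxp = np.zeros_like(xp) if need_dx else None
        dw = np.zeros_like(w.data) if w.requires_grad else None
        for i in range(kh):
            for j in range(kw):
                xs = xp[:, :, i : i + s * ho : s, j : j + s * wo : s]
                if dw is not None:
                    dw[:, :, i, j] = np.tensordot(g, xs, axes=([0, 2, 3], [0, 2, 3]))
                if need_dx:
                    # (C,O) . (N,O,Ho,Wo) over O -> (C,N,Ho,Wo)
                    dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += np.tensordot(
                        w.data[:, :, i, j], g, axes=([0], [1])
                    ).transpose(1, 0, 2, 3)
        if dw is not None:
            w._accumulate(dw)
        if need_dx:
            if ph or pw:
                dxp = dxp[:, :, ph : ph + h, pw : pw + ww_]
            x._accumulate(dxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, parents=parents, backward=backward)


def depthwise_conv2d(x, w, b=None, padding=0):
    """Per-channel spatial convolution: (N,C,H,W) with weight (C,kh,kw)."""
    x = _as_tensor(x)
    w = _as_tensor(w)
    b = _as_tensor(b) if b is not None else None
    n, c, h, ww_ = x.data.shape
    c2, kh, kw = w.data.shape
    if c != c2:
        raise ValueError(f"depthwise_conv2d channel mismatch: input {c}, weight {c2}")
    ph, pw = _pad_pair(padding)
    ho = h + 2 * ph - kh + 1
    wo = ww_ + 2 * pw - kw + 1
    xp = _pad_hw(x.data, padding)
    out_data = np.zeros((n, c, ho, wo), dtype=x.data.dtype)
    for i in range(kh):
        for j in range(kw):
            out_data += xp[:, :, i : i + ho, j : j + wo] * w.data[None, :, i, j, None, None]
    if b is not None:
        out_data += b.data[None, :, None, None]

    def backward(g):
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        dxp = np.zeros_like(xp) if x.requires_grad else None
        dw = np.zeros_like(w.data) if w.requires_grad else None
        for i in range(kh):
            for j in range(kw):
                xs = xp[:, :, i : i + ho, j : j + wo]
                if dw is not None:
                    dw[:, i, j] = (g * xs).sum(axis=(0, 2, 3))
                if dxp is not None:
                    dxp[:, :, i : i + ho, j : j + wo] += g * w.data[None, :, i, j, None, None]
        if dw is not None:
            w._accumulate(dw)
        if dxp is not None:
            dcrop = dxp[:, :, ph : ph + h, pw : pw + ww_] if (ph or pw) else dxp
            x._accumulate(dcrop)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, parents=parents, backward=backward)


def conv_transpose2x2(x, w, b=None):
    """Transposed convolution, kernel 2, stride 2 (exact x2 upsampling).

    Weight shape (C_in, C_out, 2, 2). Output (N, C_out, 2H, 2W). Because
    stride equals kernel size the output taps never overlap, so each of
    the four kernel positions fills a disjoint interleaved sub-grid.
    """
    x = _as_tensor(x)
    w = _as_tensor(w)
    b = _as_tensor(b) if b is not None else None
    n, c, h, ww_ = x.data.shape
    c2, o, kh, kw = w.data.shape
    if c != c2 or (kh, kw) != (2, 2):
        raise ValueError("conv_transpose2x2 expects weight (C_in, C_out, 2, 2)")
    out_data = np.empty((n, o, 2 * h, 2 * ww_), dtype=x.data.dtype)
    for i in range(2):
        for j in range(2):
            # (O,C) . (N,C,H,W) over C -> (O,N,H,W)
            out_data[:, :, i::2, j::2] = np.tensordot(
                w.data[:, :, i, j], x.data, axes=([0], [1])
            ).transpose(1, 0, 2, 3)
    if b is not None:
        out_data += b.data[None, :, None, None]

    def backward(g):
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            dw = np.zeros_like(w.data)
            for i in range(2):
                for j in range(2):
                    gs = g[:, :, i::2, j::2]
                    dw[:, :, i, j] = np.tensordot(x.data, gs, axes=([0, 2, 3], [0, 2, 3]))
            w._accumulate(dw)
        if x.requires_grad:
            dx = np.zeros_like(x.data)
            for i in range(2):
                for j in range(2):
                    gs = g[:, :, i::2, j::2]
                    dx += np.tensordot(w.data[:, :, i, j], gs, axes=([1], [1])).transpose(
                        1, 0, 2, 3
                    )
            x._accumulate(dx)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, parents=parents, backward=backward)


def maxpool2x2(x):
    """2x2 max pooling, stride 2; requires even spatial dims."""
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 requires even spatial dimensions")
    windows = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = windows.reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, idx[..., None], g[..., None], axis=-1)
        dx = (
            dflat.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )
        x._accumulate(dx)

    return Tensor(out_data, parents=(x,), backward=backward)


# Fixed 4-tap bilinear kernel for 2x upsampling (align_corners=False style):
# the transpose of average-pooling composed with the standard [1,3,3,1]/4 filter.
_BILIN_1D = np.array([1.0, 3.0, 3.0, 1.0]) / 4.0
_BILIN_2D = np.outer(_BILIN_1D, _BILIN_1D) / 4.0  # sums to 4 => mean-preserving x2


def _bilinear_up2x_array(a):
    n, c, h, w = a.shape
    # zero-stuff to (2H, 2W) then correlate with the fixed 4x4 kernel, pad 1
    z = np.zeros((n, c, 2 * h + 3, 2 * w + 3), dtype=a.dtype)
    z[:, :, 1:-2:2, 1:-2:2] = a
    out = np.zeros((n, c, 2 * h, 2 * w), dtype=a.dtype)
    for i in range(4):
        for j in range(4):
            out += _BILIN_2D[i, j] * z[:, :, i : i + 2 * h, j : j + 2 * w]
    return out


def _bilinear_up2x_adjoint(g):
    n, c, h2, w2 = g.shape
    h, w = h2 // 2, w2 // 2
    acc = np.zeros((n, c, h2 + 3, w2 + 3), dtype=g.dtype)
    for i in range(4):
        for j in range(4):
            acc[:, :, i : i + h2, j : j + w2] += _BILIN_2D[i, j] * g
    return acc[:, :, 1:-2:2, 1:-2:2]


def bilinear_up2x(x):
    """Fixed-weight bilinear x2 upsampling (non-learnable alternative to deconv)."""
    x = _as_tensor(x)
    out_data = _bilinear_up2x_array(x.data)

    def backward(g):
        if x.requires_grad:
            x._accumulate(_bilinear_up2x_adjoint(g))

    return Tensor(out_data, parents=(x,), backward=backward)


def batchnorm2d(x, gamma, beta, running_mean, running_var, momentum=0.1, eps=1e-5, training=True):
    """Batch normalization over (N, H, W) per channel.

    `running_mean`/`running_var` are plain ndarrays updated in place during
    training; they are state, not graph nodes.
    """
    x = _as_tensor(x)
    gamma = _as_tensor(gamma)
    beta = _as_tensor(beta)
    n, c, h, w = x.data.shape
    m = n * h * w
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        unbiased = var * (m / max(m - 1, 1))
        running_var *= 1.0 - momentum
        running_var += momentum * unbiased
    else:
        mu = running_mean
        var = running_var
    ivar = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * ivar[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if not x.requires_grad:
            return
        gw = gamma.data[None, :, None, None]
        if not training:
            x._accumulate(g * gw * ivar[None, :, None, None])
            return
        dxhat = g * gw
        sum_dxhat = dxhat.sum(axis=(0, 2, 3))
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3))
        dx = (
            ivar[None, :, None, None]
            / m
            * (m * dxhat - sum_dxhat[None, :, None, None] - xhat * sum_dxhat_xhat[None, :, None, None])
        )
        x._accumulate(dx)

    return Tensor(out_data, parents=(x, gamma, beta), backward=backward)


def softmax_cross_entropy(scores, labels, class_weights=None):
    """Mean per-pixel negative log softmax probability of the true class.

    scores: Tensor (N, C, H, W); labels: int ndarray (N, H, W).
    With `class_weights` (length C) the mean is weighted and normalized by
    the total weight, so uniform weights reduce to the plain mean.
    """
    scores = _as_tensor(scores)
    labels = np.asarray(labels)
    n, c, h, w = scores.data.shape
    if labels.shape != (n, h, w):
        raise ValueError(f"labels shape {labels.shape} != {(n, h, w)}")
    if labels.min() < 0 or labels.max() >= c:
        raise ValueError(f"labels must lie in [0, {c})")
    shifted = scores.data - scores.data.max(axis=1, keepdims=True)
    exp = np.exp(shifted)
    probs = exp / exp.sum(axis=1, keepdims=True)
    logp = shifted - np.log(exp.sum(axis=1, keepdims=True))
    nll = -np.take_along_axis(logp, labels[:, None], axis=1)[:, 0]
    if class_weights is None:
        weights = None
        total = float(nll.size)
        loss = nll.mean()
    else:
        cw = np.asarray(class_weights, dtype=scores.data.dtype)
        if cw.shape != (c,):
            raise ValueError(f"class_weights must have shape ({c},)")
        weights = cw[labels]
        total = float(weights.sum())
        loss = float((weights * nll).sum()) / total
    onehot = np.zeros_like(scores.data)
    np.put_along_axis(onehot, labels[:, None], 1.0, axis=1)

    def backward(g):
        if not scores.requires_grad:
            return
        d = (probs - onehot) / total
        if weights is not None:
            d = d * weights[:, None]
        scores._accumulate(g * d)

    return Tensor(np.asarray(loss, dtype=scores.data.dtype), parents=(scores,), backward=backward)
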