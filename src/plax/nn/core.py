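"""Minimal reverse-mode autodiff on numpy arrays, NCHW layout.

Supports exactly the operations the placenta network needs: strided
convolution, 2x transposed convolution, batch normalization, ReLU, 2x2
max pooling, linear layers, channel concatenation, residual addition,
channel softmax, and the training losses.  Gradients flow through a
recorded DAG of :class:`Tensor` nodes; ``Tensor.backward()`` runs a
topological sweep.

Arrays keep whatever float dtype they come in with (float32 for
training speed, float64 for gradient checks in tests).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter"]


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient needs a scalar")
            grad = np.ones_like(self.data)
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


# ---------------------------------------------------------------------------
# convolution plumbing


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    N, C, H, W = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Ho = (H + 2 * pad - kh) // stride + 1
    Wo = (W + 2 * pad - kw) // stride + 1
    cols = np.empty((N, C, kh, kw, Ho, Wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i:i + stride * Ho:stride,
                                 j:j + stride * Wo:stride]
    return cols.reshape(N, C * kh * kw, Ho * Wo), (Ho, Wo)


def _col2im(cols: np.ndarray, xshape, kh: int, kw: int, stride: int, pad: int):
    N, C, H, W = xshape
    Ho = (H + 2 * pad - kh) // stride + 1
    Wo = (W + 2 * pad - kw) // stride + 1
    dx = np.zeros((N, C, H + 2 * pad, W + 2 * pad), dtype=cols.dtype)
    cols6 = cols.reshape(N, C, kh, kw, Ho, Wo)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] \
                += cols6[:, :, i, j]
    if pad:
        dx = dx[:, :, pad:-pad, pad:-pad]
    return dx


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           pad: int = 0) -> Tensor:
    """w: (F, C, kh, kw); x: (N, C, H, W)."""
    F, C, kh, kw = w.data.shape
    cols, (Ho, Wo) = _im2col(x.data, kh, kw, stride, pad)
    wmat = w.data.reshape(F, C * kh * kw)
    out = np.matmul(wmat[None], cols).reshape(x.data.shape[0], F, Ho, Wo)
    if b is not None:
        out += b.data.reshape(1, F, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        N = g.shape[0]
        gmat = g.reshape(N, F, Ho * Wo)
        # dw: fold batch into the contraction axis for a single BLAS call
        g2 = np.ascontiguousarray(gmat.transpose(1, 0, 2)).reshape(F, N * Ho * Wo)
        c2 = np.ascontiguousarray(cols.transpose(1, 0, 2)).reshape(
            C * kh * kw, N * Ho * Wo)
        w._accum((g2 @ c2.T).reshape(w.data.shape))
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.matmul(wmat.T[None], gmat)
            x._accum(_col2im(dcols, x.data.shape, kh, kw, stride, pad))

    return Tensor(out, parents=parents, backward=backward)


def conv_transpose2x(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """2x upsampling transposed convolution, kernel 2, stride 2.

    w: (C, F, 2, 2); output spatial size is exactly doubled.
    """
    N, C, H, W = x.data.shape
    Cw, F, _, _ = w.data.shape
    wmat = w.data.reshape(C, F * 4)
    xmat = x.data.reshape(N, C, H * W)
    out = np.matmul(wmat.T[None], xmat)          # (N, F*4, H*W)
    out = out.reshape(N, F, 2, 2, H, W).transpose(0, 1, 4, 2, 5, 3)
    out = out.reshape(N, F, 2 * H, 2 * W).copy()
    if b is not None:
        out += b.data.reshape(1, F, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        g6 = g.reshape(N, F, H, 2, W, 2).transpose(0, 1, 3, 5, 2, 4)
        gmat = g6.reshape(N, F * 4, H * W)
        w._accum(np.einsum("ncl,nfl->cf", xmat, gmat,
                           optimize=True).reshape(w.data.shape))
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            x._accum(np.matmul(wmat[None], gmat).reshape(N, C, H, W))

    return Tensor(out, parents=parents, backward=backward)


# ---------------------------------------------------------------------------
# pointwise / structural ops


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = x.data * mask

    def backward(g):
        x._accum(g * mask)

    return Tensor(out, parents=(x,), backward=backward)


def maxpool2x(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2, floor division on odd sizes."""
    N, C, H, W = x.data.shape
    Ho, Wo = H // 2, W // 2
    xc = x.data[:, :, :2 * Ho, :2 * Wo]
    win = xc.reshape(N, C, Ho, 2, Wo, 2)
    out = win.max(axis=(3, 5))

    def backward(g):
        mask = win == out[:, :, :, None, :, None]
        dx = np.zeros_like(x.data)
        dx[:, :, :2 * Ho, :2 * Wo] = (mask * g[:, :, :, None, :, None]
                                      ).reshape(N, C, 2 * Ho, 2 * Wo)
        x._accum(dx)

    return Tensor(out, parents=(x,), backward=backward)


def linear(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """x: (N, D); w: (D, K)."""
    out = x.data @ w.data
    if b is not None:
        out = out + b.data

    def backward(g):
        w._accum(x.data.T @ g)
        if b is not None:
            b._accum(g.sum(axis=0))
        if x.requires_grad:
            x._accum(g @ w.data.T)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out, parents=parents, backward=backward)


def flatten(x: Tensor) -> Tensor:
    N = x.data.shape[0]
    out = x.data.reshape(N, -1)

    def backward(g):
        x._accum(g.reshape(x.data.shape))

    return Tensor(out, parents=(x,), backward=backward)


def concat(xs: list[Tensor], axis: int = 1) -> Tensor:
    out = np.concatenate([t.data for t in xs], axis=axis)
    sizes = [t.data.shape[axis] for t in xs]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(xs, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor(out, parents=tuple(xs), backward=backward)


def add(x: Tensor, y: Tensor) -> Tensor:
    out = x.data + y.data

    def backward(g):
        x._accum(g)
        y._accum(g)

    return Tensor(out, parents=(x, y), backward=backward)


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor, running: dict,
                training: bool, momentum: float = 0.1,
                eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over (N, H, W)."""
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running["mean"] = (1 - momentum) * running["mean"] + momentum * mu
        running["var"] = (1 - momentum) * running["var"] + momentum * var
    else:
        mu, var = running["mean"], running["var"]
    ivstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * ivstd[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def backward(g):
        gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        beta._accum(g.sum(axis=(0, 2, 3)))
        if not x.requires_grad:
            return
        gxhat = g * gamma.data[None, :, None, None]
        if training:
            s1 = gxhat.sum(axis=(0, 2, 3), keepdims=True)
            s2 = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            dx = (gxhat - s1 / m - xhat * s2 / m) * ivstd[None, :, None, None]
        else:
            dx = gxhat * ivstd[None, :, None, None]
        x._accum(dx)

    return Tensor(out, parents=(x, gamma, beta), backward=backward)


def softmax_channels(x: Tensor) -> Tensor:
    """Softmax over axis 1 (classes) of an (N, K, ...) tensor."""
    z = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)

    def backward(g):
        dot = (g * p).sum(axis=1, keepdims=True)
        x._accum(p * (g - dot))

    return Tensor(p, parents=(x,), backward=backward)


# ---------------------------------------------------------------------------
# losses


def dice_loss(p: Tensor, onehot: np.ndarray, variant: str = "as_printed") -> Tensor:
    """Multi-class dice loss; ``p`` are per-pixel probabilities (N,K,H,W)."""
    g = np.asarray(onehot, dtype=p.data.dtype)
    c = 2.0 if variant == "doubled" else 1.0
    S = float((p.data * g).sum())
    Q = float((p.data * p.data + g * g).sum())
    out = np.asarray(1.0 - c * S / Q, dtype=p.data.dtype)

    def backward(grad):
        p._accum(grad * (-c) * (g * Q - 2.0 * p.data * S) / (Q * Q))

    return Tensor(out, parents=(p,), backward=backward)


def mse_sum(pred: Tensor, target: np.ndarray) -> Tensor:
    t = np.asarray(target, dtype=pred.data.dtype)
    diff = pred.data - t
    out = np.asarray((diff * diff).sum(), dtype=pred.data.dtype)

    def backward(g):
        pred._accum(g * 2.0 * diff)

    return Tensor(out, parents=(pred,), backward=backward)


def mse_mean(pred: Tensor, target: np.ndarray) -> Tensor:
    """Pixel-averaged squared error: the summed form rescaled by 1/N so
    SGD step sizes are resolution-independent."""
    t = np.asarray(target, dtype=pred.data.dtype)
    diff = pred.data - t
    n = diff.size
    out = np.asarray((diff * diff).sum() / n, dtype=pred.data.dtype)

    def backward(g):
        pred._accum(g * 2.0 * diff / n)

    return Tensor(out, parents=(pred,), backward=backward)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy over the batch; logits (N, K), labels (N,)."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    n = logits.data.shape[0]
    out = np.asarray(-logp[np.arange(n), labels].mean(),
                     dtype=logits.data.dtype)

    def backward(g):
        p = np.exp(logp)
        p[np.arange(n), labels] -= 1.0
        logits._accum(g * p / n)

    return Tensor(out, parents=(logits,), backward=backward)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        x._accum(g * s * (1.0 - s))

    return Tensor(s, parents=(x,), backward=backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy; logits and 0/1 targets of shape (N,)."""
    t = np.asarray(targets, dtype=logits.data.dtype).reshape(logits.data.shape)
    z = logits.data
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    out = np.asarray(loss.mean(), dtype=z.dtype)

    def backward(g):
        s = 1.0 / (1.0 + np.exp(-z))
        logits._accum(g * (s - t) / z.size)

    return Tensor(out, parents=(logits,), backward=backward)
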