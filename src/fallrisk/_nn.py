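"""Minimal numpy neural-network primitives with explicit backpropagation.

Only what the attention encoder needs: 2-D "same" convolution via
im2col, ReLU, a numerically stable row softmax, and Adam.  All arrays
are float64; every forward returns the cache its backward consumes.
"""

from __future__ import annotations

import numpy as np


def _pad_amounts(k: int) -> tuple[int, int]:
    # "same" padding; asymmetric for even kernels
    return (k - 1) // 2, k // 2


def im2col(x: np.ndarray, k: int) -> np.ndarray:
    """Unfold ``x`` (N, C, H, W) into (N, C*k*k, H*W) patch columns."""
    n, c, h, w = x.shape
    pl, pr = _pad_amounts(k)
    xp = np.pad(x, ((0, 0), (0, 0), (pl, pr), (pl, pr)))
    cols = np.empty((n, c, k, k, h, w), dtype=x.dtype)
    for di in range(k):
        for dj in range(k):
            cols[:, :, di, dj] = xp[:, :, di:di + h, dj:dj + w]
    return cols.reshape(n, c * k * k, h * w)


def col2im(dcols: np.ndarray, x_shape: tuple, k: int) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add patch gradients back."""
    n, c, h, w = x_shape
    pl, pr = _pad_amounts(k)
    dxp = np.zeros((n, c, h + pl + pr, w + pl + pr))
    dcols = dcols.reshape(n, c, k, k, h, w)
    for di in range(k):
        for dj in range(k):
            dxp[:, :, di:di + h, dj:dj + w] += dcols[:, :, di, dj]
    return dxp[:, :, pl:pl + h, pl:pl + w]


def conv2d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Same-padded 2-D convolution.  W is (Cout, Cin, k, k)."""
    n, c, h, w = x.shape
    cout, cin, k, _ = W.shape
    if k == 1:
        # fast path: a 1x1 convolution is a per-position linear map
        y = np.einsum("oc,nchw->nohw", W[:, :, 0, 0], x, optimize=True)
        y += b[None, :, None, None]
        return y, (x, None, k)
    cols = im2col(x, k)
    y = np.einsum("of,nfs->nos", W.reshape(cout, -1), cols, optimize=True)
    y = y.reshape(n, cout, h, w) + b[None, :, None, None]
    return y, (x, cols, k)


def conv2d_backward(dy: np.ndarray, W: np.ndarray, cache):
    x, cols, k = cache
    n, c, h, w = x.shape
    cout = W.shape[0]
    db = dy.sum(axis=(0, 2, 3))
    if k == 1:
        dW = np.einsum("nohw,nchw->oc", dy, x, optimize=True).reshape(W.shape)
        dx = np.einsum("oc,nohw->nchw", W[:, :, 0, 0], dy, optimize=True)
        return dx, dW, db
    dyf = dy.reshape(n, cout, h * w)
    dW = np.einsum("nos,nfs->of", dyf, cols, optimize=True).reshape(W.shape)
    dcols = np.einsum("of,nos->nfs", W.reshape(cout, -1), dyf, optimize=True)
    dx = col2im(dcols, x.shape, k)
    return dx, dW, db


def softmax_lastaxis(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_backward(attn: np.ndarray, dattn: np.ndarray) -> np.ndarray:
    inner = (attn * dattn).sum(axis=-1, keepdims=True)
    return attn * (dattn - inner)


class Adam:
    """Adam optimizer over a dict of named parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1c = 1 - self.beta1 ** self.t
        b2c = 1 - self.beta2 ** self.t
        for key, g in grads.items():
            p = self.params[key]
            m = self.m[key]
            v = self.v[key]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
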