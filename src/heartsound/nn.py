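"""Minimal NumPy layers for the heart-sound CNN.

Implements exactly what the classifier architecture needs — valid 2-D
convolution (im2col), ReLU, 2x2 max pooling, dense layers, softmax
cross-entropy, and Adam — with explicit forward/backward passes. All
computation is float32 and fully deterministic given the parameter values
and input order.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["conv2d_forward", "conv2d_backward", "maxpool2_forward", "maxpool2_backward",
           "relu", "relu_backward", "softmax", "cross_entropy", "AdamState"]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N, out_h*out_w, C*k*k) patches for a valid conv."""
    patches = sliding_window_view(x, (k, k), axis=(2, 3))  # (N,C,oh,ow,k,k)
    n, c, oh, ow, _, _ = patches.shape
    return patches.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * k * k), oh, ow


def conv2d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Valid convolution. x:(N,C,H,W), w:(F,C,k,k), b:(F,) -> (N,F,oh,ow).

    Returns the output plus a cache for the backward pass. The batched
    matmul is flattened to one 2-D GEMM for speed.
    """
    k = w.shape[-1]
    cols, oh, ow = _im2col(x, k)
    n = x.shape[0]
    wmat = w.reshape(w.shape[0], -1)  # (F, C*k*k)
    out = cols.reshape(n * oh * ow, -1) @ wmat.T + b  # (N*oh*ow, F)
    out = out.reshape(n, oh * ow, -1).transpose(0, 2, 1).reshape(n, w.shape[0], oh, ow)
    return out, (x.shape, cols, w)


def conv2d_backward(dout: np.ndarray, cache, need_dx: bool = True):
    """Gradients of a valid conv. dout:(N,F,oh,ow) -> (dx, dw, db).

    ``need_dx=False`` (first layer) skips the input gradient.
    """
    x_shape, cols, w = cache
    n, f, oh, ow = dout.shape
    k = w.shape[-1]
    dmat = dout.reshape(n, f, oh * ow).transpose(0, 2, 1)  # (N, oh*ow, F)
    dw = (dmat.reshape(n * oh * ow, f).T @ cols.reshape(n * oh * ow, -1)).reshape(w.shape)
    db = dout.sum(axis=(0, 2, 3))
    if not need_dx:
        return None, dw, db
    # dx = full-correlation of dout with the flipped kernels
    pad = k - 1
    dpad = np.pad(dout, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    wflip = w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C, F, k, k)
    cols_d, ih, iw = _im2col(dpad, k)
    dx = cols_d.reshape(n * ih * iw, -1) @ wflip.reshape(wflip.shape[0], -1).T
    dx = dx.reshape(n, ih * iw, -1).transpose(0, 2, 1).reshape(x_shape)
    return dx, dw, db


def maxpool2_forward(x: np.ndarray):
    """2x2 max pooling, stride 2. Trailing odd rows/cols are dropped."""
    n, c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    xv = x[:, :, : h2 * 2, : w2 * 2].reshape(n, c, h2, 2, w2, 2)
    xf = xv.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
    idx = xf.argmax(axis=-1)
    out = np.take_along_axis(xf, idx[..., None], axis=-1)[..., 0]
    return out, (x.shape, idx)


def maxpool2_backward(dout: np.ndarray, cache):
    x_shape, idx = cache
    n, c, h, w = x_shape
    h2, w2 = h // 2, w // 2
    dxf = np.zeros((n, c, h2, w2, 4), dtype=dout.dtype)
    np.put_along_axis(dxf, idx[..., None], dout[..., None], axis=-1)
    dx = np.zeros(x_shape, dtype=dout.dtype)
    dx[:, :, : h2 * 2, : w2 * 2] = (
        dxf.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, h2 * 2, w2 * 2)
    )
    return dx


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0)


def relu_backward(dout: np.ndarray, x: np.ndarray) -> np.ndarray:
    return dout * (x > 0)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, onehot: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(np.sum(onehot * np.log(probs + eps), axis=-1)))


class AdamState:
    """Adam optimizer state over a dict of named parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
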