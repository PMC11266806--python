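"""Minimal NumPy layers for the 1-D CNN (float32, batch layout (N, L, C))."""

from __future__ import annotations

import numpy as np


def he_init(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


def conv1d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray, kernel: int):
    """Same-padding 1-D convolution.

    x: (N, L, C); w: (C * kernel, F) with C-major / tap-minor flattening;
    returns (out (N, L, F), cache).
    """
    n, length, c = x.shape
    pad = kernel // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, kernel, axis=1)  # (N, L, C, k)
    cols = win.transpose(0, 1, 2, 3).reshape(n, length, c * kernel)
    out = cols @ w + b
    return out, (cols, x.shape, w, kernel)


def conv1d_backward(dout: np.ndarray, cache):
    cols, x_shape, w, kernel = cache
    n, length, c = x_shape
    f = w.shape[1]
    pad = kernel // 2
    dw = cols.reshape(n * length, c * kernel).T @ dout.reshape(n * length, f)
    db = dout.sum(axis=(0, 1))
    w3 = w.reshape(c, kernel, f)
    dxp = np.zeros((n, length + 2 * pad, c), dtype=dout.dtype)
    flat = dout.reshape(n * length, f)
    for j in range(kernel):
        dxp[:, j : j + length, :] += (flat @ w3[:, j, :].T).reshape(n, length, c)
    dx = dxp[:, pad : pad + length, :]
    return dx, dw, db


def relu_forward(x):
    out = np.maximum(x, 0.0)
    return out, (x > 0)


def relu_backward(dout, mask):
    return dout * mask


def maxpool_forward(x: np.ndarray):
    """Max pooling, window 2, stride 2 (odd tail sample dropped)."""
    n, length, c = x.shape
    l2 = length // 2
    xt = x[:, : 2 * l2, :].reshape(n, l2, 2, c)
    arg = xt.argmax(axis=2)
    out = np.take_along_axis(xt, arg[:, :, None, :], axis=2)[:, :, 0, :]
    return out, (arg, x.shape)


def maxpool_backward(dout: np.ndarray, cache):
    arg, x_shape = cache
    n, length, c = x_shape
    l2 = length // 2
    dxt = np.zeros((n, l2, 2, c), dtype=dout.dtype)
    np.put_along_axis(dxt, arg[:, :, None, :], dout[:, :, None, :], axis=2)
    dx = np.zeros((n, length, c), dtype=dout.dtype)
    dx[:, : 2 * l2, :] = dxt.reshape(n, 2 * l2, c)
    return dx


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def se_forward(x: np.ndarray, w1, b1, w2, b2):
    """Squeeze-excitation channel attention: y = x * sigmoid(MLP(mean_t x))."""
    z = x.mean(axis=1)  # (N, C)
    h_pre = z @ w1 + b1
    h = np.maximum(h_pre, 0.0)
    s = _sigmoid(h @ w2 + b2)
    y = x * s[:, None, :]
    return y, (x, z, h_pre, h, s, w1, w2)


def se_backward(dy: np.ndarray, cache):
    x, z, h_pre, h, s, w1, w2 = cache
    length = x.shape[1]
    dx = dy * s[:, None, :]
    ds = (dy * x).sum(axis=1)  # (N, C)
    dpre2 = ds * s * (1.0 - s)
    dw2 = h.T @ dpre2
    db2 = dpre2.sum(axis=0)
    dh = dpre2 @ w2.T
    dh *= h_pre > 0
    dw1 = z.T @ dh
    db1 = dh.sum(axis=0)
    dz = dh @ w1.T
    dx += dz[:, None, :] / length
    return dx, dw1, db1, dw2, db2


def gap_forward(x: np.ndarray):
    return x.mean(axis=1), x.shape


def gap_backward(dout: np.ndarray, x_shape):
    n, length, c = x_shape
    return np.repeat(dout[:, None, :], length, axis=1) / length


def dense_forward(x, w, b):
    return x @ w + b, x


def dense_backward(dout, x, w):
    return dout @ w.T, x.T @ dout, dout.sum(axis=0)


def softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean CE loss and gradient w.r.t. logits; y holds integer classes."""
    probs = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean()
    grad = probs.copy()
    grad[np.arange(n), y] -= 1.0
    return float(loss), (grad / n).astype(np.float32)


class Adam:
    """Adaptive-moment optimizer over a dict of parameter arrays."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        bias1 = 1.0 - self.beta1**self.t
        bias2 = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            update = (self.m[k] / bias1) / (np.sqrt(self.v[k] / bias2) + self.eps)
            params[k] -= (self.lr * update).astype(params[k].dtype)
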