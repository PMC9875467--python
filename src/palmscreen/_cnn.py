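"""A miniature convolutional network in pure numpy.

Architecture (fixed contract): two blocks of 3x3 convolution + ReLU +
2x2 max-pool, then one fully connected layer into a 2-way softmax.
Training is plain mini-batch SGD with an L2 penalty, deterministic given
the seed. Designed for 32x32x3 thumbnails and epoch counts in the single
digits — a stated-hyperparameter miniature, not a large-scale network.

Implementation notes: convolutions run via im2col so forward and backward
passes are single matrix multiplications; weights use He initialization;
inputs are scaled to [0, 1].
"""

from __future__ import annotations

import numpy as np


def _im2col(x: np.ndarray, k: int = 3) -> np.ndarray:
    """(N, H, W, C) -> (N, H-k+1, W-k+1, k*k*C) patch matrix (stride 1)."""
    n, h, w, c = x.shape
    out_h, out_w = h - k + 1, w - k + 1
    s = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x, shape=(n, out_h, out_w, k, k, c), strides=(s[0], s[1], s[2], s[1], s[2], s[3])
    )
    return cols.reshape(n, out_h, out_w, k * k * c)


def _pad1(x: np.ndarray) -> np.ndarray:
    return np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))


class _Conv:
    """3x3 same-padding convolution with bias."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = 9 * c_in
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out))
        self.b = np.zeros(c_out)

    def forward(self, x):
        self._cols = _im2col(_pad1(x))
        return self._cols @ self.w + self.b

    def backward(self, grad, lr, l2):
        n, h, w, _ = grad.shape
        g2 = grad.reshape(-1, grad.shape[-1])
        gw = self._cols.reshape(-1, self._cols.shape[-1]).T @ g2 / n
        gb = g2.sum(axis=0) / n
        # propagate to padded input, then strip the padding
        gcols = grad @ self.w.T  # (N, h, w, 9*C_in)
        c_in = self.w.shape[0] // 9
        gx = np.zeros((n, h + 2, w + 2, c_in))
        gcols = gcols.reshape(n, h, w, 3, 3, c_in)
        for i in range(3):
            for j in range(3):
                gx[:, i : i + h, j : j + w, :] += gcols[:, :, :, i, j, :]
        self.w -= lr * (gw + l2 * self.w)
        self.b -= lr * gb
        return gx[:, 1:-1, 1:-1, :]


class _Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.b = np.zeros(d_out)

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad, lr, l2):
        n = grad.shape[0]
        gw = self._x.T @ grad / n
        gx = grad @ self.w.T
        self.w -= lr * (gw + l2 * self.w)
        self.b -= lr * grad.sum(axis=0) / n
        return gx


def _maxpool(x):
    n, h, w, c = x.shape
    r = x.reshape(n, h // 2, 2, w // 2, 2, c)
    out = r.max(axis=(2, 4))
    mask = r == out[:, :, None, :, None, :]
    return out, mask


def _maxpool_back(grad, mask):
    # ties within a window (e.g. several zeros post-ReLU) share the gradient
    n, hh, _, ww, _, c = mask.shape
    count = mask.sum(axis=(2, 4), keepdims=True)
    g = grad[:, :, None, :, None, :] * mask / count
    return g.reshape(n, hh * 2, ww * 2, c)


class TinyConvNet:
    """Two conv/ReLU/pool blocks + dense softmax head, SGD-trained."""

    def __init__(
        self,
        input_hw: int = 32,
        channels: tuple[int, int] = (8, 16),
        n_classes: int = 2,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.input_hw = input_hw
        self.conv1 = _Conv(3, channels[0], rng)
        self.conv2 = _Conv(channels[0], channels[1], rng)
        flat = (input_hw // 4) ** 2 * channels[1]
        self.head = _Dense(flat, n_classes, rng)
        self._rng = rng

    def _forward(self, x):
        a1 = self.conv1.forward(x)
        r1 = np.maximum(a1, 0.0)
        p1, m1 = _maxpool(r1)
        a2 = self.conv2.forward(p1)
        r2 = np.maximum(a2, 0.0)
        p2, m2 = _maxpool(r2)
        flat = p2.reshape(x.shape[0], -1)
        logits = self.head.forward(flat)
        cache = (a1, m1, a2, m2, p2.shape)
        return logits, cache

    @staticmethod
    def _softmax(logits):
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict_proba(self, x: np.ndarray, batch: int = 256) -> np.ndarray:
        x = self._prep(x)
        out = [self._softmax(self._forward(x[i : i + batch])[0]) for i in range(0, len(x), batch)]
        return np.concatenate(out, axis=0)

    def _prep(self, x):
        x = np.asarray(x, dtype=np.float64)
        if x.max() > 1.5:  # uint8-range input
            x = x / 255.0
        if x.shape[1:3] != (self.input_hw, self.input_hw):
            raise ValueError(f"expected {self.input_hw}x{self.input_hw} thumbnails, got {x.shape}")
        return x

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        *,
        epochs: int = 10,
        batch_size: int = 32,
        lr: float = 0.01,
        l2: float = 1e-4,
    ) -> list[float]:
        """Train by mini-batch SGD; returns the per-epoch mean cross-entropy."""
        x = self._prep(x)
        y = np.asarray(y, dtype=np.int64)
        n = len(x)
        history = []
        for _ in range(epochs):
            order = self._rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                xb, yb = x[idx], y[idx]
                logits, (a1, m1, a2, m2, p2_shape) = self._forward(xb)
                probs = self._softmax(logits)
                losses.append(float(-np.log(probs[np.arange(len(yb)), yb] + 1e-12).mean()))
                grad = probs.copy()
                grad[np.arange(len(yb)), yb] -= 1.0
                g = self.head.backward(grad, lr, l2).reshape(p2_shape)
                g = _maxpool_back(g, m2) * (a2 > 0)
                g = self.conv2.backward(g, lr, l2)
                g = _maxpool_back(g, m1) * (a1 > 0)
                self.conv1.backward(g, lr, l2)
            history.append(float(np.mean(losses)))
        return history
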