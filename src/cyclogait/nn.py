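"""Minimal 1-D convolutional network primitives with manual backprop.

Pure-NumPy layers (conv, batch norm, ReLU, dropout, global average
pooling, dense) sized for short fixed-length sequences. Written so that
training is deterministic under a fixed seed and so that intermediate
feature maps and their gradients are directly accessible, which is what
gradient-based class activation mapping requires.

All tensors are float32 with layout (batch, time, channels).
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("v", "g")

    def __init__(self, value: np.ndarray):
        self.v = value.astype(np.float32)
        self.g = np.zeros_like(self.v)


class Conv1d:
    """Same-padded 1-D convolution; stride-2 halves the time axis."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        scale = np.sqrt(2.0 / (kernel * c_in))  # He init
        self.W = Param(rng.normal(0.0, scale, size=(kernel * c_in, c_out)))
        self.b = Param(np.zeros(c_out))
        self.k, self.s, self.c_in, self.c_out = kernel, stride, c_in, c_out
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, C = x.shape
        k, s = self.k, self.s
        t_out = (T + s - 1) // s
        pad = max(0, (t_out - 1) * s + k - T)
        left = pad // 2
        xp = np.pad(x, ((0, 0), (left, pad - left), (0, 0)))
        cols = np.empty((B, t_out, k, C), dtype=np.float32)
        for j in range(k):
            cols[:, :, j, :] = xp[:, j:j + s * t_out:s, :]
        flat = cols.reshape(B * t_out, k * C)
        out = flat @ self.W.v + self.b.v
        self._cache = (flat, x.shape, xp.shape, left, t_out)
        return out.reshape(B, t_out, self.c_out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        flat, x_shape, xp_shape, left, t_out = self._cache
        B, T, C = x_shape
        k, s = self.k, self.s
        dflat = dout.reshape(B * t_out, self.c_out)
        self.W.g += flat.T @ dflat
        self.b.g += dflat.sum(axis=0)
        dcols = (dflat @ self.W.v.T).reshape(B, t_out, k, C)
        dxp = np.zeros(xp_shape, dtype=np.float32)
        for j in range(k):
            dxp[:, j:j + s * t_out:s, :] += dcols[:, :, j, :]
        return dxp[:, left:left + T, :]


class BatchNorm:
    """Per-channel batch normalization over (batch, time)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mu = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv, training, x.shape[0] * x.shape[1])
        return (self.gamma.v * xhat + self.beta.v).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, training, n = self._cache
        self.gamma.g += (dout * xhat).sum(axis=(0, 1))
        self.beta.g += dout.sum(axis=(0, 1))
        if not training:
            return (dout * self.gamma.v * inv).astype(np.float32)
        dxhat = dout * self.gamma.v
        return (inv / n * (
            n * dxhat
            - dxhat.sum(axis=(0, 1))
            - xhat * (dxhat * xhat).sum(axis=(0, 1))
        )).astype(np.float32)


class Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / d_in)
        self.W = Param(rng.normal(0.0, scale, size=(d_in, d_out)))
        self.b = Param(np.zeros(d_out))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x
        return x @ self.W.v + self.b.v

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        self.W.g += x.T @ dout
        self.b.g += dout.sum(axis=0)
        return (dout @ self.W.v.T).astype(np.float32)


class ResidualBlock:
    """conv-BN-ReLU-dropout-conv-BN plus shortcut, ReLU after the add.

    The shortcut is the identity when shapes match, otherwise a strided
    1x1 projection convolution followed by batch norm.
    """

    def __init__(self, c_in: int, c_out: int, stride: int, kernel: int,
                 dropout: float, rng: np.random.Generator):
        self.conv1 = Conv1d(c_in, c_out, kernel, stride, rng)
        self.bn1 = BatchNorm(c_out)
        self.conv2 = Conv1d(c_out, c_out, kernel, 1, rng)
        self.bn2 = BatchNorm(c_out)
        self.dropout = dropout
        if stride != 1 or c_in != c_out:
            self.proj: Conv1d | None = Conv1d(c_in, c_out, 1, stride, rng)
            self.proj_bn: BatchNorm | None = BatchNorm(c_out)
        else:
            self.proj = None
            self.proj_bn = None
        self._cache = None

    def params(self):
        ps = self.conv1.params() + self.bn1.params() + self.conv2.params() + self.bn2.params()
        if self.proj is not None:
            ps += self.proj.params() + self.proj_bn.params()
        return ps

    def forward(self, x: np.ndarray, training: bool,
                rng: np.random.Generator) -> np.ndarray:
        h = self.bn1.forward(self.conv1.forward(x), training)
        mask1 = h > 0
        h = h * mask1
        if training and self.dropout > 0:
            keep = (rng.random(h.shape) >= self.dropout).astype(np.float32)
            h = h * keep / (1.0 - self.dropout)
        else:
            keep = None
        h = self.bn2.forward(self.conv2.forward(h), training)
        if self.proj is not None:
            sc = self.proj_bn.forward(self.proj.forward(x), training)
        else:
            sc = x
        out = h + sc
        mask2 = out > 0
        self._cache = (mask1, keep, mask2)
        return out * mask2

    def backward(self, dout: np.ndarray) -> np.ndarray:
        mask1, keep, mask2 = self._cache
        d = dout * mask2
        dh = self.conv2.backward(self.bn2.backward(d))
        if keep is not None:
            dh = dh * keep / (1.0 - self.dropout)
        dh = dh * mask1
        dx = self.conv1.backward(self.bn1.backward(dh))
        if self.proj is not None:
            dx = dx + self.proj.backward(self.proj_bn.backward(d))
        else:
            dx = dx + d
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient w.r.t. logits."""
    p = softmax(logits)
    n = len(y)
    loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, (dlogits / n).astype(np.float32)


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.v) for p in params]
        self.v = [np.zeros_like(p.v) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.g
            v *= self.beta2
            v += (1 - self.beta2) * p.g ** 2
            p.v -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.g[...] = 0.0
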