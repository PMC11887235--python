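"""Minimal CNN layer stack with manual backpropagation.

Implements exactly what the staging models need: 2D convolution (im2col),
ReLU, 2x2 max pooling, residual addition, flatten, fully connected layers,
softmax cross-entropy, and SGD with momentum.  All math is float64 numpy;
forward passes are deterministic, and initialization is a pure function of
the seed.

Shapes follow the (N, C, H, W) convention.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer", "Conv2d", "ReLU", "MaxPool2x2", "Flatten", "Linear",
    "ResidualBlock", "Sequential", "softmax", "cross_entropy_loss", "SGD",
]


class Layer:
    """Base layer: forward caches what backward needs."""

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv2d(Layer):
    """3x3/5x5 'same' convolution via im2col, stride 1, zero padding."""

    def __init__(self, c_in: int, c_out: int, ksize: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.k = c_in, c_out, ksize
        self.pad = ksize // 2
        fan_in = c_in * ksize * ksize
        # He initialization, appropriate for ReLU nets
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in))
        self.b = np.zeros(c_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # (N, C, H, W, k, k) -> (N, H, W, C*k*k)
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h, w, -1)
        self._cols = cols
        self._xshape = x.shape
        out = cols @ self.w.T + self.b  # (N, H, W, c_out)
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, _, h, w = grad.shape
        g = grad.transpose(0, 2, 3, 1).reshape(-1, self.c_out)  # (N*H*W, c_out)
        cols = self._cols.reshape(-1, self.c_in * self.k * self.k)
        self.dw = g.T @ cols / n
        self.db = g.sum(axis=0) / n
        dcols = (g @ self.w).reshape(n, h, w, self.c_in, self.k, self.k)
        # col2im: scatter-add each kernel tap back onto the padded grid
        p = self.pad
        dxp = np.zeros((n, self.c_in, h + 2 * p, w + 2 * p))
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + h, p : p + w] if p else dxp

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool2x2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/cols are dropped."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xt = x[:, :, : 2 * h2, : 2 * w2].reshape(n, c, h2, 2, w2, 2)
        xt = xt.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        self._argmax = xt.argmax(axis=-1)
        self._inshape = x.shape
        return xt.max(axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h2, w2 = grad.shape
        flat = np.zeros((n, c, h2, w2, 4))
        np.put_along_axis(flat, self._argmax[..., None], grad[..., None], axis=-1)
        flat = flat.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros(self._inshape)
        dx[:, :, : 2 * h2, : 2 * w2] = flat.reshape(n, c, 2 * h2, 2 * w2)
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_out, d_in))
        self.b = np.zeros(d_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n = grad.shape[0]
        self.dw = grad.T @ self._x / n
        self.db = grad.sum(axis=0) / n
        return grad @ self.w

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class ResidualBlock(Layer):
    """conv-relu-conv with identity skip, then ReLU (channel count fixed)."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.conv1 = Conv2d(channels, channels, 3, rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(channels, channels, 3, rng)
        self.relu_out = ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        return self.relu_out.forward(x + y)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.relu_out.backward(grad)
        g_branch = self.conv1.backward(self.relu1.backward(self.conv2.backward(g)))
        return g + g_branch

    def params(self):
        return self.conv1.params() + self.conv2.params()

    def grads(self):
        return self.conv1.grads() + self.conv2.grads()


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_loss(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean negative log-softmax loss and its gradient w.r.t. logits.

    The returned gradient is per-sample (not divided by N); layers divide by
    the batch size when accumulating parameter gradients.
    """
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -float(np.mean(np.log(p[np.arange(n), labels] + eps)))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad


class SGD:
    """Plain SGD with momentum over an explicit (params, grads) pairing."""

    def __init__(self, layers: list[Layer], lr: float = 0.01, momentum: float = 0.9):
        self.layers = layers
        self.lr = lr
        self.momentum = momentum
        self._vel = [np.zeros_like(p) for l in layers for p in l.params()]

    def step(self) -> None:
        i = 0
        for layer in self.layers:
            for p, g in zip(layer.params(), layer.grads()):
                self._vel[i] = self.momentum * self._vel[i] - self.lr * g
                p += self._vel[i]
                i += 1
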