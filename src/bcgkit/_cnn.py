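"""Minimal 1-D convolutional network with manual backprop, NumPy only.

Sized for minutes-scale CPU training on a few thousand short windows; no
autograd framework is available in the runtime environment, so each layer
implements its own forward/backward pass.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class Conv1d(Layer):
    """Valid-mode 1-D convolution, stride 1. Input (B, C, L) -> (B, O, L-k+1)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / (in_ch * kernel))
        self.w = rng.standard_normal((out_ch, in_ch, kernel)) * scale
        self.b = np.zeros(out_ch)
        self.kernel = kernel
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        win = sliding_window_view(x, self.kernel, axis=2)  # (B, C, L', k)
        self._win = win
        y = np.einsum("bclk,ock->bol", win, self.w, optimize=True)
        return y + self.b[None, :, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.grads[0][...] = np.einsum("bclk,bol->ock", self._win, g, optimize=True)
        self.grads[1][...] = g.sum(axis=(0, 2))
        k = self.kernel
        gp = np.pad(g, ((0, 0), (0, 0), (k - 1, k - 1)))
        gwin = sliding_window_view(gp, k, axis=2)  # (B, O, L, k)
        return np.einsum("bolk,ock->bcl", gwin, self.w[:, :, ::-1], optimize=True)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class MaxPool1d(Layer):
    """Non-overlapping max pooling; a trailing remainder shorter than the pool
    width is dropped."""

    def __init__(self, width: int):
        super().__init__()
        self.width = width

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, l = x.shape
        lp = l // self.width
        self._in_len = l
        xr = x[:, :, : lp * self.width].reshape(b, c, lp, self.width)
        self._arg = xr.argmax(axis=3)
        return xr.max(axis=3)

    def backward(self, g: np.ndarray) -> np.ndarray:
        b, c, lp = g.shape
        gx = np.zeros((b, c, self._in_len))
        ib, ic, il = np.ogrid[:b, :c, :lp]
        gxr = gx[:, :, : lp * self.width].reshape(b, c, lp, self.width)
        gxr[ib, ic, il, self._arg] = g
        return gx


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._l = x.shape[2]
        return x.mean(axis=2)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.repeat(g[:, :, None], self._l, axis=2) / self._l


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.w = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        self.b = np.zeros(n_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ g
        self.grads[1][...] = g.sum(axis=0)
        return g @ self.w.T


class ScaledTanh(Layer):
    """y = scale * tanh(x): bounds the regression output to +/- scale."""

    def __init__(self, scale: float):
        super().__init__()
        self.scale = scale

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._t = np.tanh(x)
        return self.scale * self._t

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self.scale * (1.0 - self._t**2)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g.reshape(self._shape)


class Net:
    """Plain sequential container trained with SGD on mean-squared error."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers
        self._velocity = [
            np.zeros_like(p) for layer in layers for p in layer.params
        ]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g: np.ndarray) -> None:
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def sgd_step(self, lr: float, momentum: float = 0.0, clip_norm: float = 0.0) -> None:
        scale = 1.0
        if clip_norm > 0:
            total = np.sqrt(
                sum(
                    float(np.sum(g**2))
                    for layer in self.layers
                    for g in layer.grads
                )
            )
            if total > clip_norm:
                scale = clip_norm / total
        i = 0
        for layer in self.layers:
            for p, g in zip(layer.params, layer.grads):
                v = self._velocity[i]
                v *= momentum
                v -= lr * scale * g
                p += v
                i += 1

    def get_weights(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        own = self.get_weights()
        if len(own) != len(weights):
            raise ValueError("weight count mismatch")
        for p, w in zip(own, weights):
            if p.shape != w.shape:
                raise ValueError(f"weight shape mismatch: {p.shape} vs {w.shape}")
            p[...] = w
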