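"""Minimal CNN building blocks with explicit analytic backpropagation.

Pure-numpy layers (im2col convolutions, ReLU, global max pooling, a
linear head) and an Adam optimizer — enough to train the compact
parameter-regression network on a CPU with full seed determinism.
Forward passes cache what the backward pass needs; ``backward`` returns
the gradient w.r.t. the layer input and stores parameter gradients on
the layer.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2d", "ReLU", "GlobalMaxPool", "Linear", "Adam", "Sequential"]


class Layer:
    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}


class Conv2d(Layer):
    """3x3-style convolution via im2col, stride >= 1, zero padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, stride: int = 1,
                 pad: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel * kernel
        self.W = (rng.standard_normal((c_out, fan_in)) * np.sqrt(2.0 / fan_in)
                  ).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.c_in, self.c_out = c_in, c_out
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        k, s, p = self.kernel, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        Ho, Wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * Ho * Wo, C * k * k)
        out = cols @ self.W.T + self.b
        self._cache = (cols, x.shape, Ho, Wo)
        return out.reshape(B, Ho, Wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xshape, Ho, Wo = self._cache
        B, C, H, W = xshape
        k, s, p = self.kernel, self.stride, self.pad
        d = dout.transpose(0, 2, 3, 1).reshape(-1, self.c_out)
        self.dW = (d.T @ cols).astype(np.float32)
        self.db = d.sum(axis=0).astype(np.float32)
        dcols = (d @ self.W).reshape(B, Ho, Wo, C, k, k)
        dxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + Ho * s:s, j:j + Wo * s:s] += \
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + H, p:p + W]

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class GlobalMaxPool(Layer):
    """(B, C, H, W) -> (B, C): max over space, routing gradient to the argmax."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        flat = x.reshape(B, C, H * W)
        self._arg = flat.argmax(axis=2)
        self._shape = x.shape
        return np.take_along_axis(flat, self._arg[..., None], axis=2)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, H, W = self._shape
        dx = np.zeros((B, C, H * W), dtype=np.float32)
        np.put_along_axis(dx, self._arg[..., None], dout[..., None], axis=2)
        return dx.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None,
                 bias_init: float = 0.0, w_scale: float = 1.0):
        rng = rng or np.random.default_rng(0)
        self.W = (rng.standard_normal((n_out, n_in)) * w_scale * np.sqrt(1.0 / n_in)
                  ).astype(np.float32)
        self.b = np.full(n_out, bias_init, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = (dout.T @ self._x).astype(np.float32)
        self.db = dout.sum(axis=0).astype(np.float32)
        return dout @ self.W

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def named_params(self) -> list[tuple[str, Layer, str]]:
        out = []
        for i, layer in enumerate(self.layers):
            for name in layer.params():
                out.append((f"{i}.{name}", layer, name))
        return out

    def get_state(self) -> dict[str, np.ndarray]:
        return {key: layer.params()[name].copy()
                for key, layer, name in self.named_params()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for key, layer, name in self.named_params():
            layer.params()[name][...] = state[key]


class Adam:
    """Adam with the standard bias correction; state keyed per parameter."""

    def __init__(self, model: Sequential, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {key: np.zeros_like(layer.params()[name])
                  for key, layer, name in model.named_params()}
        self.v = {key: np.zeros_like(layer.params()[name])
                  for key, layer, name in model.named_params()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, layer, name in self.model.named_params():
            g = layer.grads()[name]
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            mhat = self.m[key] / (1 - b1**self.t)
            vhat = self.v[key] / (1 - b2**self.t)
            layer.params()[name][...] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
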