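"""A compact NumPy neural-network engine for desk-scale CNN regression.

Implements exactly the pieces the trait regressors need — 2-D convolution
(valid padding, stride 1, via ``sliding_window_view``), average pooling,
global average pooling, dense layers, ReLU, a two-branch mixed
image+tabular network and an RMSprop optimizer with inverse-time learning
rate decay — with hand-written backward passes. Everything is float64 and
seeded, so runs are bit-reproducible on one thread.

This is a deliberately small engine for CPU-scale models; it is not a
general deep-learning framework.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Dense",
    "ReLU",
    "Conv2D",
    "AvgPool2D",
    "GlobalAvgPool",
    "Sequential",
    "MixedNetwork",
    "RMSprop",
    "mse_loss",
]


class Layer:
    """Base class; layers cache what backward needs during forward."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    """Affine layer ``y = x W + b`` with He/Glorot initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, relu_fan: bool = True):
        scale = np.sqrt((2.0 if relu_fan else 1.0) / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        # ReLU-bound layers start with a small positive bias so narrow
        # stacks do not die under the optimizer's large early steps
        self.b = np.full(n_out, 0.05) if relu_fan else np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.gW += self._x.T @ grad
        self.gb += grad.sum(axis=0)
        return grad @ self.W.T


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Conv2D(Layer):
    """3×3-style convolution, NHWC layout, valid padding, stride 1."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.kernel = kernel
        self.c_in = c_in
        fan_in = c_in * kernel * kernel
        # flat weight indexed by (channel, row-offset, col-offset) of the patch
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out))
        self.b = np.full(c_out, 0.05)  # see Dense: keeps ReLU maps alive early
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    def forward(self, x):
        k = self.kernel
        n, h, w, c = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        if h < k or w < k:
            raise ValueError(f"input {h}x{w} smaller than kernel {k}")
        # (N, oh, ow, C, k, k) -> flatten patch axes
        win = sliding_window_view(x, (k, k), axis=(1, 2))
        self._cols = win.reshape(n, h - k + 1, w - k + 1, c * k * k)
        self._xshape = x.shape
        return self._cols @ self.W + self.b

    def backward(self, grad):
        n, oh, ow, c_out = grad.shape
        k = self.kernel
        cols2 = self._cols.reshape(-1, self._cols.shape[-1])
        self.gW += cols2.T @ grad.reshape(-1, c_out)
        self.gb += grad.sum(axis=(0, 1, 2))
        gcols = (grad @ self.W.T).reshape(n, oh, ow, self.c_in, k, k)
        gx = np.zeros(self._xshape)
        for i in range(k):
            for j in range(k):
                gx[:, i : i + oh, j : j + ow, :] += gcols[:, :, :, :, i, j]
        return gx


class AvgPool2D(Layer):
    """Non-overlapping average pooling; trims edges not divisible by the size."""

    def __init__(self, size: int):
        self.size = size

    def forward(self, x):
        s = self.size
        n, h, w, c = x.shape
        h2, w2 = (h // s) * s, (w // s) * s
        self._xshape = x.shape
        self._trim = (h2, w2)
        xt = x[:, :h2, :w2, :]
        return xt.reshape(n, h2 // s, s, w2 // s, s, c).mean(axis=(2, 4))

    def backward(self, grad):
        s = self.size
        h2, w2 = self._trim
        gx = np.zeros(self._xshape)
        up = np.repeat(np.repeat(grad, s, axis=1), s, axis=2) / (s * s)
        gx[:, :h2, :w2, :] = up
        return gx


class GlobalAvgPool(Layer):
    """NHWC feature maps -> per-channel means, making the net size-agnostic."""

    def forward(self, x):
        self._xshape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad):
        n, h, w, c = self._xshape
        return np.broadcast_to(grad[:, None, None, :], self._xshape) / (h * w)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class MixedNetwork:
    """Two-branch network fusing image features with tabular climate features.

    ``forward(images, climate)`` concatenates the branch outputs and runs the
    fusion head. With ``clim_branch=None`` it degenerates to an image-only
    model whose head is the fusion stack.
    """

    def __init__(self, image_branch: Sequential, clim_branch: Sequential | None, fusion: Sequential):
        self.image_branch = image_branch
        self.clim_branch = clim_branch
        self.fusion = fusion
        self._split: int | None = None

    @property
    def mixed(self) -> bool:
        return self.clim_branch is not None

    def params(self):
        parts = [self.image_branch, self.fusion]
        if self.clim_branch is not None:
            parts.insert(1, self.clim_branch)
        return [p for part in parts for p in part.params()]

    def grads(self):
        parts = [self.image_branch, self.fusion]
        if self.clim_branch is not None:
            parts.insert(1, self.clim_branch)
        return [g for part in parts for g in part.grads()]

    def zero_grad(self) -> None:
        for g in self.grads():
            g[...] = 0.0

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params()))

    def forward(self, images: np.ndarray, climate: np.ndarray | None = None) -> np.ndarray:
        feats = self.image_branch.forward(images)
        if self.clim_branch is None:
            return self.fusion.forward(feats)
        if climate is None:
            raise ValueError("mixed model requires climate inputs")
        climate = np.asarray(climate, dtype=float)
        expected = self.clim_branch.layers[0].W.shape[0]
        if climate.ndim != 2 or climate.shape[1] != expected:
            raise ValueError(
                f"climate input must have shape (batch, {expected}), got {climate.shape}"
            )
        cfeats = self.clim_branch.forward(climate)
        self._split = feats.shape[1]
        return self.fusion.forward(np.concatenate([feats, cfeats], axis=1))

    def backward(self, grad: np.ndarray) -> None:
        g = self.fusion.backward(grad)
        if self.clim_branch is None:
            self.image_branch.backward(g)
        else:
            self.image_branch.backward(g[:, : self._split])
            self.clim_branch.backward(g[:, self._split :])

    def predict(self, images, climate=None, batch_size: int = 64) -> np.ndarray:
        out = []
        for i in range(0, len(images), batch_size):
            c = None if climate is None else climate[i : i + batch_size]
            out.append(self.forward(images[i : i + batch_size], c))
        return np.concatenate(out, axis=0)[:, 0]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights):
            p[...] = w


class RMSprop:
    """RMSprop with inverse-time learning-rate decay ``lr/(1 + decay·step)``."""

    def __init__(self, net: MixedNetwork, lr: float = 1e-3, rho: float = 0.9,
                 eps: float = 1e-7, decay: float = 1e-4):
        self.net = net
        self.lr, self.rho, self.eps, self.decay = lr, rho, eps, decay
        self.sq = [np.zeros_like(p) for p in net.params()]
        self.step = 0

    def update(self) -> None:
        self.step += 1
        lr_t = self.lr / (1.0 + self.decay * self.step)
        for p, g, s in zip(self.net.params(), self.net.grads(), self.sq):
            s *= self.rho
            s += (1.0 - self.rho) * g * g
            p -= lr_t * g / (np.sqrt(s) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient with respect to the predictions."""
    pred = pred.reshape(-1)
    diff = pred - np.asarray(target, dtype=float).reshape(-1)
    return float(np.mean(diff**2)), (2.0 * diff / diff.size).reshape(-1, 1)
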