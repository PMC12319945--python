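"""Minimal layer framework with explicit forward/backward passes.

All tensors are NCHW float32 numpy arrays (fully-connected layers use N x D).
Every layer caches what its backward pass needs on ``forward`` and releases it
on ``backward``; a layer therefore supports one pending backward at a time,
which is all the single-threaded trainer requires.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "Upsample2x",
    "GlobalAvgPool",
    "Linear",
    "Sequential",
]


class Parameter:
    """A learnable array with its accumulated gradient."""

    def __init__(self, value: np.ndarray) -> None:
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Layer):
    """k x k convolution, stride 1, 'same' zero padding (k odd).

    Implemented as a sum over kernel offsets of channel-mixing tensordots,
    which is both memory-light and fast at the model sizes used here.
    """

    def __init__(self, in_ch: int, out_ch: int, k: int = 3, *, rng: np.random.Generator) -> None:
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        self.weight = Parameter(_he_init(rng, (out_ch, in_ch, k, k), in_ch * k * k))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32))
        self._xpad: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {c}")
        p = self.k // 2
        xpad = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        y = np.empty((n, self.out_ch, h, w), dtype=np.float32)
        y[:] = self.bias.value[None, :, None, None]
        wv = self.weight.value
        for di in range(self.k):
            for dj in range(self.k):
                # (N,Cin,H,W) x (Cout,Cin) -> (N,Cout,H,W)
                y += np.einsum(
                    "nchw,oc->nohw",
                    xpad[:, :, di : di + h, dj : dj + w],
                    wv[:, :, di, dj],
                    optimize=True,
                )
        self._xpad = xpad if train else None
        self._shape = (n, c, h, w)
        return y

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        if self._xpad is None:
            raise RuntimeError("backward called without a training forward")
        n, c, h, w = self._shape
        p = self.k // 2
        xpad = self._xpad
        gpad = np.zeros_like(xpad)
        wv = self.weight.value
        for di in range(self.k):
            for dj in range(self.k):
                self.weight.grad[:, :, di, dj] += np.einsum(
                    "nohw,nchw->oc",
                    grad_out,
                    xpad[:, :, di : di + h, dj : dj + w],
                    optimize=True,
                )
                gpad[:, :, di : di + h, dj : dj + w] += np.einsum(
                    "nohw,oc->nchw", grad_out, wv[:, :, di, dj], optimize=True
                )
        self.bias.grad += grad_out.sum(axis=(0, 2, 3))
        self._xpad = None
        return gpad[:, :, p : p + h, p : p + w] if p else gpad


class BatchNorm2d(Layer):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        self.gamma = Parameter(np.ones(ch, dtype=np.float32))
        self.beta = Parameter(np.zeros(ch, dtype=np.float32))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        if train:
            self._cache = (xhat, inv_std)
        return (self.gamma.value[None, :, None, None] * xhat
                + self.beta.value[None, :, None, None]).astype(np.float32)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        self._cache = None
        m = grad_out.shape[0] * grad_out.shape[2] * grad_out.shape[3]
        dgamma = (grad_out * xhat).sum(axis=(0, 2, 3))
        dbeta = grad_out.sum(axis=(0, 2, 3))
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        g = self.gamma.value[None, :, None, None]
        dxhat = grad_out * g
        dx = (inv_std[None, :, None, None] / m) * (
            m * dxhat
            - dxhat.sum(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        )
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        g = grad_out * self._mask
        self._mask = None
        return g


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2; spatial dims must be even."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial size ({h},{w}) not divisible by 2")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(3, 5))
        if train:
            self._mask = xr == y[:, :, :, None, :, None]
            self._shape = x.shape
        return y

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        # split gradient equally among tied maxima (ties are measure-zero in practice)
        counts = self._mask.sum(axis=(3, 5))
        g = (self._mask * (grad_out / counts)[:, :, :, None, :, None]).reshape(n, c, h, w)
        self._mask = None
        return g.astype(np.float32)


class Upsample2x(Layer):
    """Nearest-neighbour x2 upsampling."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return grad_out.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)).astype(np.float32)


class GlobalAvgPool(Layer):
    """(N,C,H,W) -> (N,C)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return (np.broadcast_to(grad_out[:, :, None, None], self._shape) / (h * w)).astype(
            np.float32
        )


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int, *, rng: np.random.Generator) -> None:
        self.weight = Parameter(_he_init(rng, (in_dim, out_dim), in_dim))
        self.bias = Parameter(np.zeros(out_dim, dtype=np.float32))

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        self.weight.grad += self._x.T @ grad_out
        self.bias.grad += grad_out.sum(axis=0)
        g = grad_out @ self.weight.value.T
        self._x = None
        return g


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for lay in self.layers:
            out.extend(lay.parameters())
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for lay in self.layers:
            x = lay.forward(x, train=train)
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for lay in reversed(self.layers):
            grad_out = lay.backward(grad_out)
        return grad_out
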