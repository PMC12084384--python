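"""Minimal CNN building blocks in NumPy (float32, NCHW layout).

Convolutions use a gather/scatter im2col scheme: forward collects the nine
kernel-position slices into a patch tensor and reduces it with one GEMM;
backward scatters the column gradient back with nine strided slice-adds.
This keeps every hot loop inside BLAS while staying fully deterministic
for a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "GlobalAvgPool2d",
    "Dense",
    "Flatten",
]

DTYPE = np.float32


class Layer:
    """Base layer: forward/backward plus named parameter access."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> dict[str, np.ndarray]:
        return {}

    def gradients(self) -> dict[str, np.ndarray]:
        return {}

    def state(self) -> dict[str, np.ndarray]:
        """Non-trainable buffers (e.g. batch-norm running stats)."""
        return {}


class Conv2d(Layer):
    """2-D convolution, kernel 3, stride 2 by default, He-initialized."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        *,
        kernel: int = 3,
        stride: int = 2,
        padding: int = 0,
        rng: np.random.Generator,
    ):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel * kernel
        self.weight = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), (out_channels, in_channels, kernel, kernel)
        ).astype(DTYPE)
        self.bias = np.zeros(out_channels, dtype=DTYPE)
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias)

    def output_side(self, side: int) -> int:
        return (side + 2 * self.padding - self.kernel) // self.stride + 1

    def _gather(self, xp: np.ndarray, oh: int, ow: int) -> np.ndarray:
        b, c = xp.shape[:2]
        k, s = self.kernel, self.stride
        cols = np.empty((b, c, k, k, oh, ow), dtype=xp.dtype)
        for i in range(k):
            for j in range(k):
                cols[:, :, i, j] = xp[
                    :, :, i : i + s * (oh - 1) + 1 : s, j : j + s * (ow - 1) + 1 : s
                ]
        return cols

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, c, h, w = x.shape
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        oh, ow = self.output_side(h), self.output_side(w)
        cols = self._gather(xp, oh, ow)
        flat = cols.reshape(b, c * self.kernel * self.kernel, oh * ow)
        out = self.weight.reshape(self.out_channels, -1) @ flat
        out += self.bias[:, None]
        if train:
            self._cache = (flat, (b, c, h, w), (oh, ow))
        return out.reshape(b, self.out_channels, oh, ow)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        flat, (b, c, h, w), (oh, ow) = self._cache
        k, s, p = self.kernel, self.stride, self.padding
        g = grad.reshape(b, self.out_channels, oh * ow)
        self.dweight = np.tensordot(g, flat, axes=([0, 2], [0, 2])).reshape(
            self.weight.shape
        )
        self.dbias = g.sum(axis=(0, 2))
        dflat = self.weight.reshape(self.out_channels, -1).T @ g
        dcols = dflat.reshape(b, c, k, k, oh, ow)
        hp, wp = h + 2 * p, w + 2 * p
        dxp = np.zeros((b, c, hp, wp), dtype=grad.dtype)
        for i in range(k):
            for j in range(k):
                dxp[
                    :, :, i : i + s * (oh - 1) + 1 : s, j : j + s * (ow - 1) + 1 : s
                ] += dcols[:, :, i, j]
        self._cache = None
        return dxp[:, :, p : p + h, p : p + w] if p else dxp

    def parameters(self):
        return {"weight": self.weight, "bias": self.bias}

    def gradients(self):
        return {"weight": self.dweight, "bias": self.dbias}


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (batch, H, W).

    Training uses batch statistics and updates running estimates
    (momentum 0.9); evaluation uses the running estimates.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.9):
        self.eps = eps
        self.momentum = momentum
        self.gamma = np.ones(channels, dtype=DTYPE)
        self.beta = np.zeros(channels, dtype=DTYPE)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(DTYPE)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv_std[:, None, None]
        if train:
            self._cache = (xhat, inv_std)
        return (self.gamma[:, None, None] * xhat + self.beta[:, None, None]).astype(
            DTYPE, copy=False
        )

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        axes = (0, 2, 3)
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.dgamma = (grad * xhat).sum(axis=axes)
        self.dbeta = grad.sum(axis=axes)
        # standard batch-norm gradient, all reductions per channel
        dx = (
            self.gamma[:, None, None]
            * inv_std[:, None, None]
            * (
                grad
                - self.dbeta[:, None, None] / m
                - xhat * self.dgamma[:, None, None] / m
            )
        )
        self._cache = None
        return dx.astype(DTYPE, copy=False)

    def parameters(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def gradients(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = grad * self._mask
        self._mask = None
        return out


class GlobalAvgPool2d(Layer):
    """(B, C, H, W) -> (B, C) by spatial averaging."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        return np.broadcast_to(
            grad[:, :, None, None] / (h * w), (b, c, h, w)
        ).astype(DTYPE, copy=False)


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer, He-initialized."""

    def __init__(self, in_features: int, out_features: int, *, rng: np.random.Generator):
        self.weight = rng.normal(
            0.0, np.sqrt(2.0 / in_features), (in_features, out_features)
        ).astype(DTYPE)
        self.bias = np.zeros(out_features, dtype=DTYPE)
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.weight + self.bias

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dweight = self._x.T @ grad
        self.dbias = grad.sum(axis=0)
        dx = grad @ self.weight.T
        self._x = None
        return dx

    def parameters(self):
        return {"weight": self.weight, "bias": self.bias}

    def gradients(self):
        return {"weight": self.dweight, "bias": self.dbias}
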