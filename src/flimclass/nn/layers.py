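"""Layers with explicit forward/backward passes.

Tensor layout is (N, C, D, H, W) float32.  Convolutions are 'same'
(zero-padded) with optional per-axis stride, implemented as im2col +
matmul so the heavy lifting runs in BLAS; the input gradient is scattered
back with 27 strided slice-adds rather than a per-voxel loop.
"""

from __future__ import annotations

import itertools

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv3D",
    "MaxPool3D",
    "ReLU",
    "Flatten",
    "GlobalAvgPool",
    "Dense",
    "ResidualBlock",
]


class Layer:
    """Base layer; stateless layers only override forward/backward."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv3D(Layer):
    """3-D convolution, kernel 3x3x3, 'same' zero padding, optional stride."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        rng: np.random.Generator,
        kernel: int = 3,
        stride: tuple[int, int, int] = (1, 1, 1),
    ) -> None:
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for 'same' padding")
        self.k = kernel
        self.stride = stride
        fan_in = in_channels * kernel**3
        self.W = _he_init(rng, (out_channels, in_channels, kernel, kernel, kernel), fan_in)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache: tuple | None = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def out_shape(self, in_shape: tuple[int, int, int]) -> tuple[int, int, int]:
        sd, sh, sw = self.stride
        d, h, w = in_shape
        return (-(-d // sd), -(-h // sh), -(-w // sw))

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, D, H, W = x.shape
        k, (sd, sh, sw) = self.k, self.stride
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
        win = win[:, :, ::sd, ::sh, ::sw]  # (N, C, Do, Ho, Wo, k, k, k)
        Do, Ho, Wo = win.shape[2:5]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(
            N * Do * Ho * Wo, C * k**3
        )
        F = self.W.shape[0]
        out = cols @ self.W.reshape(F, -1).T + self.b
        self._cache = (cols, x.shape, (Do, Ho, Wo))
        return np.ascontiguousarray(
            out.reshape(N, Do, Ho, Wo, F).transpose(0, 4, 1, 2, 3)
        )

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape, (Do, Ho, Wo) = self._cache
        N, C, D, H, W = x_shape
        k, (sd, sh, sw) = self.k, self.stride
        p = k // 2
        F = self.W.shape[0]
        dmat = np.ascontiguousarray(dout.transpose(0, 2, 3, 4, 1)).reshape(-1, F)
        self.dW[...] = (dmat.T @ cols).reshape(self.W.shape)
        self.db[...] = dmat.sum(axis=0)
        dcols = (dmat @ self.W.reshape(F, -1)).reshape(
            N, Do, Ho, Wo, C, k, k, k
        ).transpose(0, 4, 1, 2, 3, 5, 6, 7)
        dxp = np.zeros((N, C, D + 2 * p, H + 2 * p, W + 2 * p), dtype=np.float32)
        for i, j, m in itertools.product(range(k), repeat=3):
            dxp[
                :,
                :,
                i : i + sd * Do : sd,
                j : j + sh * Ho : sh,
                m : m + sw * Wo : sw,
            ] += dcols[..., i, j, m]
        return dxp[:, :, p : p + D, p : p + H, p : p + W]


class MaxPool3D(Layer):
    """2x2x2 max pooling, stride 2; trailing odd rows/cols/frames dropped."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, D, H, W = x.shape
        d, h, w = D // 2, H // 2, W // 2
        if min(d, h, w) < 1:
            raise ValueError(f"input too small to pool: {x.shape}")
        xc = x[:, :, : 2 * d, : 2 * h, : 2 * w]
        xr = xc.reshape(N, C, d, 2, h, 2, w, 2)
        out = xr.max(axis=(3, 5, 7))
        mask = xr == out[:, :, :, None, :, None, :, None]
        # split gradient equally across ties
        self._cache = (x.shape, mask, mask.sum(axis=(3, 5, 7), keepdims=True))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x_shape, mask, ties = self._cache
        N, C, D, H, W = x_shape
        d, h, w = D // 2, H // 2, W // 2
        dexp = dout[:, :, :, None, :, None, :, None] * (mask / ties)
        dx = np.zeros(x_shape, dtype=np.float32)
        dx[:, :, : 2 * d, : 2 * h, : 2 * w] = dexp.reshape(
            N, C, 2 * d, 2 * h, 2 * w
        )
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class GlobalAvgPool(Layer):
    """Average over all spatial/temporal positions -> (N, C)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        N, C, D, H, W = self._shape
        scale = 1.0 / (D * H * W)
        return np.broadcast_to(
            dout[:, :, None, None, None] * scale, self._shape
        ).astype(np.float32)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        self.W = _he_init(rng, (n_in, n_out), n_in)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T


class ResidualBlock(Layer):
    """Two same-channel 3x3x3 convolutions with an identity skip:
    out = relu(x + conv2(relu(conv1(x))))."""

    def __init__(self, channels: int, rng: np.random.Generator) -> None:
        self.conv1 = Conv3D(channels, channels, rng)
        self.conv2 = Conv3D(channels, channels, rng)
        self.relu1 = ReLU()
        self.relu2 = ReLU()

    def params(self):
        return self.conv1.params() + self.conv2.params()

    def grads(self):
        return self.conv1.grads() + self.conv2.grads()

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        return self.relu2.forward(x + y)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.relu2.backward(dout)
        dy = self.conv1.backward(self.relu1.backward(self.conv2.backward(d)))
        return d + dy
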