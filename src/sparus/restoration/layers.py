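"""Minimal NumPy layer zoo with manual backpropagation.

Tensors are float32 ``(N, C, H, W)`` blocks.  Each layer caches what its
backward pass needs; ``backward`` must be called after ``forward`` with a
gradient of the same shape as the forward output.  Convolutions use a
9-slice scheme (one GEMM per kernel tap) to avoid materializing im2col
buffers.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2x2",
    "PixelShuffle",
    "pixel_shuffle",
    "pixel_unshuffle",
]


class Param:
    """A learnable tensor with its accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    # non-trainable state that must survive checkpointing (BN running stats)
    def state(self) -> dict[str, np.ndarray]:
        return {}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        pass


class Conv2d(Layer):
    """3x3 (or 1x1) same-padding convolution, stride 1, with bias."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel not in (1, 3):
            raise ValueError("only 1x1 and 3x3 kernels are supported")
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.pad = (kernel - 1) // 2
        fan_in = c_in * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_in, kernel, kernel, c_out))
        self.w = Param("w", w)
        self.b = Param("b", np.zeros(c_out))
        self._xpad: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {c}")
        p = self.pad
        xpad = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        self._xpad = xpad if train else None
        self._in_shape = x.shape
        out = np.zeros((n, h, w, self.c_out), dtype=np.float32)
        for ki in range(self.kernel):
            for kj in range(self.kernel):
                patch = xpad[:, :, ki : ki + h, kj : kj + w]  # (N,C,H,W)
                out += np.tensordot(patch, self.w.value[:, ki, kj, :], axes=([1], [0]))
        out += self.b.value
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._xpad is None:
            raise RuntimeError("backward called before training-mode forward")
        n, c, h, w = self._in_shape
        p = self.pad
        xpad = self._xpad
        dout_nhwf = np.ascontiguousarray(dout.transpose(0, 2, 3, 1))
        self.b.grad += dout_nhwf.sum(axis=(0, 1, 2))
        dxpad = np.zeros_like(xpad)
        for ki in range(self.kernel):
            for kj in range(self.kernel):
                patch = xpad[:, :, ki : ki + h, kj : kj + w]
                # dW: contract over batch and space
                self.w.grad[:, ki, kj, :] += np.tensordot(
                    patch, dout_nhwf, axes=([0, 2, 3], [0, 1, 2])
                )
                # dx: route dout back through this tap
                dpatch = np.tensordot(dout_nhwf, self.w.value[:, ki, kj, :], axes=([3], [1]))
                dxpad[:, :, ki : ki + h, kj : kj + w] += dpatch.transpose(0, 3, 1, 2)
        self._xpad = None
        if p:
            return dxpad[:, :, p:-p, p:-p]
        return dxpad

    def params(self) -> list[Param]:
        return [self.w, self.b]


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param("gamma", np.ones(channels))
        self.beta = Param("beta", np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        if train:
            self._cache = (xhat, inv_std)
        return (
            self.gamma.value[None, :, None, None] * xhat
            + self.beta.value[None, :, None, None]
        ).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward called before training-mode forward")
        xhat, inv_std = self._cache
        self._cache = None
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        dxhat = dout * g
        sum_dxhat = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (inv_std[None, :, None, None] / m) * (
            m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat
        )
        return dx.astype(np.float32)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def state(self) -> dict[str, np.ndarray]:
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        self.running_mean = np.asarray(state["running_mean"], dtype=np.float32)
        self.running_var = np.asarray(state["running_var"], dtype=np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        self._mask = x > 0 if train else None
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            raise RuntimeError("backward called before training-mode forward")
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2x2(Layer):
    """2x2 max pooling, stride 2; halves the spatial size."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("spatial size must be even for 2x2 pooling")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(n, c, h // 2, w // 2, 4)
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        if train:
            self._arg = arg
            self._in_shape = x.shape
        else:
            self._arg = None
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._arg is None:
            raise RuntimeError("backward called before training-mode forward")
        n, c, h, w = self._in_shape
        flat = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(flat, self._arg[..., None], dout[..., None], axis=-1)
        dx = (
            flat.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )
        self._arg = None
        return dx


def pixel_shuffle(x: np.ndarray, r: int) -> np.ndarray:
    """Rearrange (N, C*r^2, H, W) -> (N, C, H*r, W*r); a pure permutation."""
    n, c, h, w = x.shape
    if r < 1:
        raise ValueError("upscale factor must be >= 1")
    if c % (r * r) != 0:
        raise ValueError(f"channels ({c}) not divisible by r^2 ({r * r})")
    c_out = c // (r * r)
    return (
        x.reshape(n, c_out, r, r, h, w)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(n, c_out, h * r, w * r)
    )


def pixel_unshuffle(x: np.ndarray, r: int) -> np.ndarray:
    """Inverse of :func:`pixel_shuffle`."""
    n, c, hr, wr = x.shape
    if hr % r or wr % r:
        raise ValueError("spatial size not divisible by r")
    h, w = hr // r, wr // r
    return (
        x.reshape(n, c, h, r, w, r)
        .transpose(0, 1, 3, 5, 2, 4)
        .reshape(n, c * r * r, h, w)
    )


class PixelShuffle(Layer):
    def __init__(self, r: int):
        self.r = r

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return np.ascontiguousarray(pixel_shuffle(x, self.r))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.ascontiguousarray(pixel_unshuffle(dout, self.r))
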