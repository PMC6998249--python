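"""Layers with forward/backward passes.

Conventions: image tensors are channels-last ``(N, H, W, C)`` float arrays
(the GEMM-based convolution then produces contiguous outputs and the
normalization/pooling reductions run over leading axes); dense inputs are
``(N, features)``. Each layer stores its parameters in ``self.params`` and
accumulates gradients into ``self.grads`` during ``backward``. Layers with
``trainable = False`` still propagate gradients to their inputs but are
skipped by the optimizer; a frozen BatchNorm additionally runs in inference
mode (running statistics, no buffer updates) even during training.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    trainable = True

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, H, W, C) -> (N*H*W, k*k*C) patches under same-padding, stride 1."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (N, H, W, C, k, k)
    n, h, w, c = x.shape
    # patch layout (k, k, C): kernel rows, kernel cols, then channels
    return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
        n * h * w, k * k * c
    )


class Conv2D(Layer):
    """3x3 (configurable) convolution, stride 1, same padding.

    ``is_first`` marks the network input layer, whose input gradient is
    never needed and is skipped.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3,
                 rng: np.random.Generator | None = None, dtype=np.float32,
                 is_first: bool = False) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.is_first = is_first
        fan_in = in_channels * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_channels, fan_in))
        self.params = {"weight": w.astype(dtype), "bias": np.zeros(out_channels, dtype)}
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        col = _im2col(x, self.kernel)
        out = col @ self.params["weight"].T
        out += self.params["bias"]
        if train:
            self._cache = (col, x.shape)
        return out.reshape(n, h, w, self.out_channels)

    def backward(self, dout: np.ndarray) -> np.ndarray | None:
        col, x_shape = self._cache
        self._cache = None
        n, h, w, c = x_shape
        dflat = dout.reshape(n * h * w, self.out_channels)
        self.grads["weight"] = dflat.T @ col
        self.grads["bias"] = dflat.sum(axis=0)
        if self.is_first:
            return None
        # dx = convolution of dout with the spatially flipped, channel-swapped
        # kernel, expressed with the same patch layout (k, k, C_out)
        k = self.kernel
        wk = self.params["weight"].reshape(self.out_channels, k, k, c)
        wk_flip = np.ascontiguousarray(
            wk[:, ::-1, ::-1, :].transpose(3, 1, 2, 0)
        ).reshape(c, k * k * self.out_channels)
        dcol = _im2col(dout, k)
        dx = dcol @ wk_flip.T
        return dx.reshape(n, h, w, c)


class BatchNorm2D(Layer):
    """Per-channel batch normalization over (N, H, W) with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float32) -> None:
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.frozen = False  # frozen => inference statistics even in training
        self.params = {
            "gamma": np.ones(channels, dtype),
            "beta": np.zeros(channels, dtype),
        }
        self.buffers = {
            "running_mean": np.zeros(channels, dtype),
            "running_var": np.ones(channels, dtype),
        }
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train and not self.frozen:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            m = self.momentum
            self.buffers["running_mean"] = (
                m * self.buffers["running_mean"] + (1 - m) * mean
            ).astype(x.dtype)
            self.buffers["running_var"] = (
                m * self.buffers["running_var"] + (1 - m) * var
            ).astype(x.dtype)
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        ivstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * ivstd
        if train:
            self._cache = (xhat, ivstd)
        out = xhat * self.params["gamma"]
        out += self.params["beta"]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, ivstd = self._cache
        self._cache = None
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 1, 2))
        self.grads["beta"] = dout.sum(axis=(0, 1, 2))
        g = self.params["gamma"]
        if self.frozen:
            return dout * (g * ivstd)
        dxhat = dout * g
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 1, 2))
            - xhat * (dxhat * xhat).mean(axis=(0, 1, 2))
        ) * ivstd
        return dx


class ReLU(Layer):
    trainable = False

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2D(Layer):
    """Non-overlapping max pooling; trailing rows/cols beyond a multiple of
    the pool size are dropped (floor division)."""

    trainable = False

    def __init__(self, pool: int) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        p = self.pool
        n, h, w, c = x.shape
        ho, wo = h // p, w // p
        if ho < 1 or wo < 1:
            raise ValueError(f"input {h}x{w} too small for pool size {p}")
        xc = x[:, : ho * p, : wo * p, :]
        windows = xc.reshape(n, ho, p, wo, p, c).transpose(0, 1, 3, 5, 2, 4)
        windows = np.ascontiguousarray(windows).reshape(n, ho, wo, c, p * p)
        if train:
            self._argmax = windows.argmax(axis=-1)
            self._x_shape = x.shape
        return windows.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        p = self.pool
        n, h, w, c = self._x_shape
        ho, wo = h // p, w // p
        dwin = np.zeros((n, ho, wo, c, p * p), dtype=dout.dtype)
        np.put_along_axis(dwin, self._argmax[..., None], dout[..., None], axis=-1)
        dx = np.zeros((n, h, w, c), dtype=dout.dtype)
        dx[:, : ho * p, : wo * p, :] = (
            dwin.reshape(n, ho, wo, c, p, p)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, ho * p, wo * p, c)
        )
        return dx


class Dropout(Layer):
    """Inverted dropout: active only in training, identity at inference."""

    trainable = False

    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.rate == 0:
            return dout
        return dout * self._mask


class GlobalAvgPool(Layer):
    """(N, H, W, C) -> (N, C) spatial mean."""

    trainable = False

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._x_shape
        return np.broadcast_to(dout[:, None, None, :], (n, h, w, c)) / (h * w)


class Dense(Layer):
    """Affine layer. ``zero_init`` starts the weights at 0 — used for the
    final hazard head so the initial predictions are flat and any ranking the
    model produces comes from training signal, not from the random draw."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, dtype=np.float32,
                 zero_init: bool = False) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.in_features = in_features
        self.out_features = out_features
        if zero_init:
            w = np.zeros((out_features, in_features))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / in_features),
                           (out_features, in_features))
        self.params = {"weight": w.astype(dtype), "bias": np.zeros(out_features, dtype)}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if x.shape[1] != self.in_features:
            raise ValueError(
                f"expected {self.in_features} input features, got {x.shape[1]}"
            )
        if train:
            self._x = x
        return x @ self.params["weight"].T + self.params["bias"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["weight"] = dout.T @ self._x
        self.grads["bias"] = dout.sum(axis=0)
        return dout @ self.params["weight"]

    @property
    def n_parameters(self) -> int:
        return self.params["weight"].size + self.params["bias"].size
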