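"""Layer primitives with explicit backward passes.

Tensor convention: sequence data is ``(batch, length, channels)``; dense
data is ``(batch, features)``. Convolutions use the same-padding convention
(zero padding, output length equals input length); pooling uses floor
semantics, dropping a trailing window that does not fill.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv1d",
    "Dense",
    "BatchNorm1d",
    "MaxPool1d",
    "LeakyReLU",
    "ReLU",
    "Flatten",
    "Sequential",
    "conv1d_forward",
    "leaky_relu",
    "max_pool",
    "batch_norm_param_count",
]


class Param:
    """A trainable array and its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


class Layer:
    """Base layer: forward caches whatever backward needs."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[Param]:
        return []

    def output_shape(self, shape: tuple[int, ...]) -> tuple[int, ...]:
        """Shape bookkeeping on a per-sample shape (no batch axis)."""
        return shape


def _glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                    shape: tuple[int, ...], dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Conv1d(Layer):
    """Same-padded 1D convolution over (batch, length, channels).

    The kernel is stored as ``(kernel_size, in_channels, out_channels)``;
    forward is an im2col matrix product, so output length always equals input
    length and the map is linear in the input for fixed weights.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator | None = None, use_bias: bool = True,
                 dtype=np.float32, name: str = "conv") -> None:
        if out_channels < 1:
            raise ValueError("out_channels must be >= 1")
        if kernel_size < 1 or kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and >= 1")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.use_bias = use_bias
        rng = rng if rng is not None else np.random.default_rng(0)
        fan_in = kernel_size * in_channels
        fan_out = kernel_size * out_channels
        self.w = Param(
            _glorot_uniform(rng, fan_in, fan_out,
                            (kernel_size, in_channels, out_channels), dtype),
            name=f"{name}.w",
        )
        self.b = Param(np.zeros(out_channels, dtype=dtype), name=f"{name}.b")
        self._cols: np.ndarray | None = None
        self._in_len = 0

    def set_weights(self, weights: np.ndarray, bias: np.ndarray | None = None) -> None:
        """Load a kernel given as ``(out_channels, in_channels, kernel_size)``."""
        w = np.asarray(weights)
        if w.shape != (self.out_channels, self.in_channels, self.kernel_size):
            raise ValueError(f"bad kernel shape {w.shape}")
        self.w.value = np.ascontiguousarray(
            w.transpose(2, 1, 0).astype(self.w.value.dtype)
        )
        if bias is not None:
            self.b.value = np.asarray(bias, dtype=self.b.value.dtype).reshape(
                self.out_channels
            )

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        B, L, C = x.shape
        k = self.kernel_size
        p = k // 2
        xp = np.zeros((B, L + 2 * p, C), dtype=x.dtype)
        xp[:, p:L + p, :] = x
        # (B, L, C, k) view -> (B, L, k, C) -> (B, L, k*C)
        win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
        return np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B, L, k * C)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim != 3 or x.shape[2] != self.in_channels:
            raise ValueError(
                f"expected (batch, length, {self.in_channels}) input, got {x.shape}"
            )
        cols = self._im2col(x)
        self._cols = cols if training else None
        self._in_len = x.shape[1]
        wmat = self.w.value.reshape(self.kernel_size * self.in_channels,
                                    self.out_channels)
        y = cols @ wmat
        if self.use_bias:
            y += self.b.value
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols = self._cols
        if cols is None:
            raise RuntimeError("backward before forward(training=True)")
        B, L, _ = dout.shape
        k, Cin, Cout = self.kernel_size, self.in_channels, self.out_channels
        wmat = self.w.value.reshape(k * Cin, Cout)
        dflat = dout.reshape(B * L, Cout)
        self.w.grad += (cols.reshape(B * L, k * Cin).T @ dflat).reshape(k, Cin, Cout)
        if self.use_bias:
            self.b.grad += dflat.sum(axis=0)
        dcols = (dflat @ wmat.T).reshape(B, L, k, Cin)
        p = k // 2
        dxp = np.zeros((B, L + 2 * p, Cin), dtype=dout.dtype)
        for i in range(k):
            dxp[:, i:i + L, :] += dcols[:, :, i, :]
        return dxp[:, p:L + p, :]

    def parameters(self) -> list[Param]:
        return [self.w, self.b] if self.use_bias else [self.w]

    def output_shape(self, shape):
        return (shape[0], self.out_channels)


def conv1d_forward(x: np.ndarray, weights: np.ndarray,
                   bias: np.ndarray | float = 0.0) -> np.ndarray:
    """Functional same-padded convolution.

    ``x`` is ``(length, in_channels)`` or ``(batch, length, in_channels)``;
    ``weights`` is ``(out_channels, in_channels, kernel_size)``.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 3:
        raise ValueError("weights must be (out_channels, in_channels, kernel_size)")
    cout, cin, k = w.shape
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    if x.shape[2] != cin:
        raise ValueError(f"input has {x.shape[2]} channels, kernel expects {cin}")
    layer = Conv1d(cin, cout, k, dtype=float)
    layer.set_weights(w, np.broadcast_to(np.asarray(bias, dtype=float), (cout,)))
    y = layer.forward(x)
    return y[0] if squeeze else y


class Dense(Layer):
    """Fully connected layer over (batch, features)."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, dtype=np.float32,
                 name: str = "dense") -> None:
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_features = in_features
        self.out_features = out_features
        self.w = Param(
            _glorot_uniform(rng, in_features, out_features,
                            (in_features, out_features), dtype),
            name=f"{name}.w",
        )
        self.b = Param(np.zeros(out_features, dtype=dtype), name=f"{name}.b")
        self._x: np.ndarray | None = None

    def forward(self, x, training=False):
        if x.shape[1] != self.in_features:
            raise ValueError(f"expected {self.in_features} features, got {x.shape[1]}")
        self._x = x if training else None
        return x @ self.w.value + self.b.value

    def backward(self, dout):
        if self._x is None:
            raise RuntimeError("backward before forward(training=True)")
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value.T

    def parameters(self):
        return [self.w, self.b]

    def output_shape(self, shape):
        return (self.out_features,)


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length, channels).

    Learned scale gamma and offset beta plus tracked moving mean/variance,
    i.e. 4 parameters per channel in the bookkeeping sense (two trainable).
    Training mode standardizes with batch statistics and updates the moving
    ones; inference mode uses the moving statistics.
    """

    def __init__(self, channels: int, eps: float = 1e-3, momentum: float = 0.9,
                 dtype=np.float32, name: str = "bn") -> None:
        if channels < 1:
            raise ValueError("channels must be >= 1")
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(channels, dtype=dtype), name=f"{name}.gamma")
        self.beta = Param(np.zeros(channels, dtype=dtype), name=f"{name}.beta")
        self.moving_mean = np.zeros(channels, dtype=dtype)
        self.moving_var = np.ones(channels, dtype=dtype)
        self._cache = None

    @property
    def param_count(self) -> int:
        return batch_norm_param_count(self.channels)

    def forward(self, x, training=False):
        if x.shape[-1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[-1]}")
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.moving_mean = (m * self.moving_mean + (1 - m) * mean).astype(
                self.moving_mean.dtype
            )
            self.moving_var = (m * self.moving_var + (1 - m) * var).astype(
                self.moving_var.dtype
            )
        else:
            mean, var = self.moving_mean, self.moving_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if training:
            n = int(np.prod([x.shape[a] for a in axes]))
            self._cache = (xhat, inv_std, n)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dout):
        if self._cache is None:
            raise RuntimeError("backward before forward(training=True)")
        xhat, inv_std, n = self._cache
        axes = tuple(range(dout.ndim - 1))
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        g = dout * self.gamma.value
        return inv_std * (
            g - g.mean(axis=axes) - xhat * (g * xhat).mean(axis=axes)
        )

    def parameters(self):
        return [self.gamma, self.beta]


def batch_norm_param_count(channels: int) -> int:
    """Bookkeeping count: gamma, beta, moving mean, moving variance."""
    if channels < 1:
        raise ValueError("channels must be >= 1")
    return 4 * channels


class MaxPool1d(Layer):
    """Max pooling over the length axis with floor semantics.

    Output length is ``floor((L - size)/stride) + 1``; a trailing element
    that does not fill a window is dropped.
    """

    def __init__(self, size: int = 2, stride: int = 2) -> None:
        if size < 1 or stride < 1:
            raise ValueError("size and stride must be >= 1")
        self.size = size
        self.stride = stride
        self._cache = None

    def forward(self, x, training=False):
        B, L, C = x.shape
        if L < self.size:
            raise ValueError(f"sequence length {L} shorter than pool size {self.size}")
        # (B, L', C, size) strided windows
        win = np.lib.stride_tricks.sliding_window_view(x, self.size, axis=1)
        win = win[:, ::self.stride]
        out = win.max(axis=-1)
        if training:
            arg = win.argmax(axis=-1)
            self._cache = (arg, x.shape)
        return out

    def backward(self, dout):
        if self._cache is None:
            raise RuntimeError("backward before forward(training=True)")
        arg, shape = self._cache
        B, Lp, C = dout.shape
        dx = np.zeros(shape, dtype=dout.dtype)
        starts = np.arange(Lp) * self.stride
        pos = starts[None, :, None] + arg  # (B, L', C)
        bi = np.arange(B)[:, None, None]
        ci = np.arange(C)[None, None, :]
        np.add.at(dx, (bi, pos, ci), dout)
        return dx

    def output_shape(self, shape):
        L = (shape[0] - self.size) // self.stride + 1
        return (L, shape[1])


def max_pool(seq: np.ndarray, size: int = 2, stride: int = 2) -> np.ndarray:
    """Functional max pooling on a 1D sequence or (length, channels) array."""
    x = np.asarray(seq, dtype=float)
    squeeze1d = x.ndim == 1
    if squeeze1d:
        x = x[:, None]
    out = MaxPool1d(size, stride).forward(x[None])[0]
    return out[:, 0] if squeeze1d else out


class LeakyReLU(Layer):
    """max(x, alpha*x); continuous at zero, slope alpha on the negative side."""

    def __init__(self, alpha: float = 0.3) -> None:
        if not 0 <= alpha < 1:
            raise ValueError("alpha must lie in [0, 1)")
        self.alpha = alpha
        self._mask = None

    def forward(self, x, training=False):
        mask = x > 0
        if training:
            self._mask = mask
        return np.where(mask, x, self.alpha * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.alpha * dout)


class ReLU(LeakyReLU):
    def __init__(self) -> None:
        super().__init__(alpha=0.0)


def leaky_relu(v: np.ndarray | float, alpha: float = 0.3) -> np.ndarray | float:
    """Elementwise LeakyReLU: x for x > 0, alpha*x otherwise."""
    out = np.where(np.asarray(v) > 0, v, alpha * np.asarray(v))
    return float(out) if np.isscalar(v) else out


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)

    def output_shape(self, shape):
        return (int(np.prod(shape)),)


class Sequential(Layer):
    """A chain of layers applied in order."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = list(layers)

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def output_shape(self, shape):
        for layer in self.layers:
            shape = layer.output_shape(shape)
        return shape
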