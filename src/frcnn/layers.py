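"""Minimal NHWC tensor layers with exact forward and backward passes.

Implements the building blocks of the attention / mixed-pooling CNN:
valid stride-1 2-D convolution (cross-correlation convention), a 1x1
sigmoid spatial attention gate, channel-concatenating mixed (average +
max) pooling, ReLU, flatten, dense, and softmax cross-entropy.  The
convolution and pooling inner loops run as compiled kernels
(:mod:`frcnn._kernels`); every backward pass is the exact gradient of
its forward contract and is checked against central finite differences
in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as _k

__all__ = [
    "TensorBatch",
    "Layer",
    "Conv2D",
    "SpatialAttention",
    "MixedPool",
    "ReLU",
    "Flatten",
    "Dense",
    "conv2d_forward",
    "attention_forward",
    "mixed_pool_forward",
    "dense_forward",
    "relu",
    "softmax_xent",
    "softmax_probs",
]


@dataclass
class TensorBatch:
    """A batch of images, indexed (sample, row, column, channel).

    ``labels`` is an optional integer class vector aligned with axis 0.
    """

    values: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 4:
            raise ValueError(f"values must be 4-D (N,H,W,C), got {self.values.ndim}-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (self.values.shape[0],):
                raise ValueError("labels must be a vector of length N")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def image_shape(self) -> tuple[int, int, int]:
        return self.values.shape[1:]

    def subset(self, idx) -> "TensorBatch":
        lab = None if self.labels is None else self.labels[idx]
        return TensorBatch(self.values[idx], lab)


def _as_values(x) -> np.ndarray:
    return x.values if isinstance(x, TensorBatch) else np.asarray(x)


def _conv2d_raw(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Valid cross-correlation of (N,H,W,Ci) with (kh,kw,Ci,Co), no bias."""
    kh, kw, ci, co = weights.shape
    n, h, w, c = x.shape
    if c != ci:
        raise ValueError(f"channel mismatch: input has {c}, kernel expects {ci}")
    if h < kh or w < kw:
        raise ValueError("spatial dims smaller than kernel")
    out, _ = _k.conv2d_fwd(np.ascontiguousarray(x), np.ascontiguousarray(weights))
    return out


class Layer:
    """Base layer: shape inference, parameter storage, forward/backward."""

    kind: str = "base"

    def __init__(self) -> None:
        self.weights: np.ndarray | None = None
        self.bias: np.ndarray | None = None
        self.grads: dict[str, np.ndarray] = {}
        self._cache = None
        # set by the network on its first layer: nothing below consumes dx
        self.skip_input_grad = False

    # --- parameter plumbing -------------------------------------------------
    @property
    def params(self) -> list[np.ndarray]:
        return [p for p in (self.weights, self.bias) if p is not None]

    @params.setter
    def params(self, new: list[np.ndarray]) -> None:
        it = iter(new)
        if self.weights is not None:
            self.weights = next(it)
        if self.bias is not None:
            self.bias = next(it)

    def param_grads(self) -> list[np.ndarray]:
        out = []
        if self.weights is not None:
            out.append(self.grads["weights"])
        if self.bias is not None:
            out.append(self.grads["bias"])
        return out

    def n_params(self, in_shape: tuple) -> int:
        return 0

    # --- contracts ----------------------------------------------------------
    def out_shape(self, in_shape: tuple) -> tuple:
        raise NotImplementedError

    def init_params(self, in_shape: tuple, rng: np.random.Generator, dtype) -> None:
        pass

    def forward(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Conv2D(Layer):
    """Valid, stride-1 2-D convolution (cross-correlation) with bias."""

    kind = "conv2d"

    def __init__(self, filters: int, kernel: tuple[int, int] = (3, 3)) -> None:
        super().__init__()
        self.filters = int(filters)
        self.kernel = tuple(kernel)

    def out_shape(self, in_shape):
        h, w, c = in_shape
        kh, kw = self.kernel
        if h < kh or w < kw:
            raise ValueError(f"input {in_shape} smaller than kernel {self.kernel}")
        return (h - kh + 1, w - kw + 1, self.filters)

    def n_params(self, in_shape):
        kh, kw = self.kernel
        return (kh * kw * in_shape[2] + 1) * self.filters

    def init_params(self, in_shape, rng, dtype):
        kh, kw = self.kernel
        ci = in_shape[2]
        fan_in = kh * kw * ci
        fan_out = kh * kw * self.filters
        self.weights = _glorot(rng, (kh, kw, ci, self.filters), fan_in, fan_out, dtype)
        self.bias = np.zeros(self.filters, dtype=dtype)

    def forward(self, x):
        out, cols = _k.conv2d_fwd(np.ascontiguousarray(x),
                                  np.ascontiguousarray(self.weights))
        self._cache = (x.shape, cols)
        return out + self.bias

    def backward(self, dout):
        x_shape, cols = self._cache
        dx, dw, db = _k.conv2d_bwd(
            cols, x_shape, self.weights, np.ascontiguousarray(dout),
            not self.skip_input_grad,
        )
        self.grads = {"weights": dw, "bias": db}
        return dx


class SpatialAttention(Layer):
    """Sigmoid spatial gate: A = sigmoid(1x1 conv(x) + b); output x * A.

    The 1x1 kernel has shape (1, 1, C, 1) plus a scalar bias, so the gate
    adds C + 1 trainable parameters and preserves the input shape.  Every
    gate value lies strictly in (0, 1).
    """

    kind = "attention"

    def out_shape(self, in_shape):
        return tuple(in_shape)

    def n_params(self, in_shape):
        return in_shape[2] + 1

    def init_params(self, in_shape, rng, dtype):
        c = in_shape[2]
        self.weights = _glorot(rng, (1, 1, c, 1), c, 1, dtype)
        self.bias = np.zeros(1, dtype=dtype)

    def forward(self, x):
        c = x.shape[3]
        if self.weights.shape != (1, 1, c, 1):
            raise ValueError(
                f"attention kernel must be (1,1,{c},1), got {self.weights.shape}"
            )
        wvec = self.weights.reshape(c)
        s = x @ wvec + self.bias[0]          # (N,H,W)
        gate = 1.0 / (1.0 + np.exp(-s))[..., None]  # (N,H,W,1)
        self._cache = (x, gate)
        return x * gate

    def backward(self, dout):
        x, gate = self._cache
        c = x.shape[3]
        wvec = self.weights.reshape(c)
        dgate = np.sum(dout * x, axis=3, keepdims=True)
        ds = dgate * gate * (1.0 - gate)     # (N,H,W,1)
        dx = dout * gate + ds * wvec         # gate term + feature term
        dw = np.einsum("nhwc,nhwk->c", x, ds).reshape(1, 1, c, 1)
        db = np.array([ds.sum()], dtype=x.dtype)
        self.grads = {"weights": dw, "bias": db}
        return dx


class MixedPool(Layer):
    """Channel-concatenated average + max pooling.

    Non-overlapping windows, stride equal to pool size; trailing rows or
    columns that do not fill a window are dropped (floor semantics, e.g.
    61 -> 30 with a 2x2 pool).  Output channels = [average, max] halves,
    doubling the channel count; no trainable parameters.
    """

    kind = "mixed_pool"

    def __init__(self, pool: tuple[int, int] = (2, 2)) -> None:
        super().__init__()
        self.pool = tuple(pool)

    def out_shape(self, in_shape):
        h, w, c = in_shape
        ph, pw = self.pool
        if h < ph or w < pw:
            raise ValueError(f"spatial dims {in_shape[:2]} smaller than pool {self.pool}")
        return (h // ph, w // pw, 2 * c)

    def forward(self, x):
        n, h, w, c = x.shape
        ph, pw = self.pool
        if h < ph or w < pw:
            raise ValueError(f"spatial dims ({h},{w}) smaller than pool {self.pool}")
        out, idx = _k.mixed_pool_fwd(np.ascontiguousarray(x), ph, pw)
        self._cache = (x.shape, idx)
        return out

    def backward(self, dout):
        in_shape, idx = self._cache
        ph, pw = self.pool
        return _k.mixed_pool_bwd(np.ascontiguousarray(dout), idx,
                                 in_shape[1], in_shape[2], ph, pw)


class ReLU(Layer):
    kind = "relu"

    def out_shape(self, in_shape):
        return tuple(in_shape)

    def forward(self, x):
        self._cache = x > 0
        return np.maximum(x, 0, out=x)  # x is always a fresh upstream array

    def backward(self, dout):
        dout = dout * self._cache
        return dout


class Flatten(Layer):
    kind = "flatten"

    def out_shape(self, in_shape):
        return (int(np.prod(in_shape)),)

    def forward(self, x):
        self._cache = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._cache)


class Dense(Layer):
    """Affine map x @ W + b on flat feature batches."""

    kind = "dense"

    def __init__(self, units: int) -> None:
        super().__init__()
        self.units = int(units)

    def out_shape(self, in_shape):
        return (self.units,)

    def n_params(self, in_shape):
        return (in_shape[0] + 1) * self.units

    def init_params(self, in_shape, rng, dtype):
        ni = in_shape[0]
        self.weights = _glorot(rng, (ni, self.units), ni, self.units, dtype)
        self.bias = np.zeros(self.units, dtype=dtype)

    def forward(self, x):
        if x.shape[1] != self.weights.shape[0]:
            raise ValueError(
                f"feature mismatch: input has {x.shape[1]}, weights expect "
                f"{self.weights.shape[0]}"
            )
        self._cache = x
        return x @ self.weights + self.bias

    def backward(self, dout):
        x = self._cache
        self.grads = {"weights": x.T @ dout, "bias": dout.sum(axis=0)}
        return dout @ self.weights.T


# --- losses and functional wrappers ----------------------------------------

def softmax_probs(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_xent(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy under a softmax head.

    Returns ``(loss, probabilities)``; probability rows sum to 1.  The
    gradient w.r.t. logits is ``(probs - onehot) / N``.
    """
    labels = np.asarray(labels)
    k = logits.shape[1]
    if labels.min() < 0 or labels.max() >= k:
        raise IndexError(f"labels must lie in [0, {k}), got range "
                         f"[{labels.min()}, {labels.max()}]")
    probs = softmax_probs(logits)
    n = logits.shape[0]
    p_true = probs[np.arange(n), labels].astype(np.float64)
    loss = float(-np.mean(np.log(p_true + 1e-300)))
    return loss, probs


def softmax_xent_backward(probs: np.ndarray, labels: np.ndarray) -> np.ndarray:
    n, k = probs.shape
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return grad / n


def conv2d_forward(x, weights: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Functional valid conv: (N,H,W,Ci) x (kh,kw,Ci,Co) + (Co,)."""
    return _conv2d_raw(_as_values(x), weights) + bias


def attention_forward(x, weights: np.ndarray, bias: np.ndarray) -> np.ndarray:
    layer = SpatialAttention()
    layer.weights, layer.bias = weights, np.atleast_1d(bias)
    return layer.forward(_as_values(x))


def mixed_pool_forward(x, pool: tuple[int, int] = (2, 2)) -> np.ndarray:
    return MixedPool(pool).forward(_as_values(x))


def dense_forward(x, weights: np.ndarray, bias: np.ndarray) -> np.ndarray:
    layer = Dense(weights.shape[1])
    layer.weights, layer.bias = weights, bias
    return layer.forward(np.asarray(x))


def relu(x):
    x = np.asarray(x)
    return np.where(x > 0, x, 0.0).astype(x.dtype, copy=False)
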