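"""A compact, self-contained convolutional network in NumPy.

Implements exactly what the image models need and nothing more: 3x3
same-padding convolutions, ReLU, 2x2 max pooling, global average pooling,
dense layers, Adam, and binary-cross-entropy / mean-squared-error losses.
Layout is NHWC, float32. Global average pooling makes the network
size-agnostic, so the same topology trains on any input resolution.

Everything is deterministic given the seed (pure NumPy; no threading
nondeterminism beyond BLAS reduction order, which is stable in-process).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ValidationError


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3x3(Layer):
    """3x3 convolution, stride 1, same padding, NHWC."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        fan_in = 9 * c_in
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out))
        self.W = w.astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, H, W, C = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        win = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (B,H,W,C,3,3)
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
            B * H * W, 9 * C
        )
        out = cols @ self.W + self.b
        if train:
            self._cols, self._shape = cols, (B, H, W, C)
        return out.reshape(B, H, W, self.c_out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, H, W, C = self._shape
        dflat = dout.reshape(B * H * W, self.c_out)
        self.grads[0][...] = self._cols.T @ dflat
        self.grads[1][...] = dflat.sum(axis=0)
        dcols = (dflat @ self.W.T).reshape(B, H, W, 3, 3, C)
        dxp = np.zeros((B, H + 2, W + 2, C), dtype=np.float32)
        for ki in range(3):
            for kj in range(3):
                dxp[:, ki : ki + H, kj : kj + W, :] += dcols[:, :, :, ki, kj, :]
        del self._cols
        return dxp[:, 1 : H + 1, 1 : W + 1, :]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling; input H and W must be even."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, H, W, C = x.shape
        if H % 2 or W % 2:
            raise ValidationError("MaxPool2 requires even spatial dimensions")
        xr = x.reshape(B, H // 2, 2, W // 2, 2, C)
        out = xr.max(axis=(2, 4))
        if train:
            self._xr, self._out = xr, out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        mask = self._xr == self._out[:, :, None, :, None, :]
        counts = mask.sum(axis=(2, 4), keepdims=True)
        dxr = mask * (dout[:, :, None, :, None, :] / counts)
        B, Hh, _, Wh, _, C = dxr.shape
        return dxr.reshape(B, Hh * 2, Wh * 2, C).astype(np.float32)


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, H, W, C = self._shape
        return np.broadcast_to(
            dout[:, None, None, :] / (H * W), (B, H, W, C)
        ).astype(np.float32)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)).astype(
            np.float32
        )
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.W.T


@dataclass
class Adam:
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    _m: list = field(default_factory=list)
    _v: list = field(default_factory=list)
    _t: int = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if not self._m:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        self._t += 1
        b1t = 1 - self.beta1**self._t
        b2t = 1 - self.beta2**self._t
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class SmallCNN:
    """Conv(8)-Conv(16)-Conv(32)-Conv(32) blocks + GAP + Dense(16) + Dense(1).

    Each block is 3x3 conv -> ReLU -> 2x2 max pool. The single output is a
    logit for the detector (sigmoid applied at prediction time) or an
    unconstrained real for the size regressor. Well under 100k parameters.
    """

    def __init__(
        self,
        channels: tuple[int, ...] = (8, 16, 32, 32),
        dense_units: int = 16,
        in_channels: int = 3,
        seed: int = 0,
    ) -> None:
        rng = np.random.default_rng(seed)
        self.layers: list[Layer] = []
        c = in_channels
        for ch in channels:
            self.layers += [Conv3x3(c, ch, rng), ReLU(), MaxPool2()]
            c = ch
        self.layers += [GlobalAvgPool(), Dense(c, dense_units, rng), ReLU(),
                        Dense(dense_units, 1, rng)]
        self.channels = channels
        self.dense_units = dense_units
        self.in_channels = in_channels

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.asarray(x, dtype=np.float32)
        for layer in self.layers:
            out = layer.forward(out, train)
        return out[:, 0]

    def backward(self, dout: np.ndarray) -> None:
        grad = dout[:, None].astype(np.float32)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            if p.shape != w.shape:
                raise ValidationError("weight shape mismatch")
            p[...] = w


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dlogits)."""
    y = y.astype(np.float64)
    z = logits.astype(np.float64)
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    p = 1.0 / (1.0 + np.exp(-z))
    return float(loss), ((p - y) / len(y)).astype(np.float32)


def mse_loss(pred: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error; returns (loss, dloss/dpred)."""
    diff = pred.astype(np.float64) - y.astype(np.float64)
    return float(np.mean(diff**2)), (2 * diff / len(y)).astype(np.float32)


def fit(
    model: SmallCNN,
    X: np.ndarray,
    y: np.ndarray,
    epochs: int,
    batch_size: int = 16,
    lr: float = 1e-3,
    loss: str = "mse",
    seed: int = 0,
    optimizer: Adam | None = None,
) -> list[float]:
    """Train in-place with Adam; returns the per-epoch mean training loss."""
    if len(X) == 0:
        raise ValidationError("empty training set")
    loss_fn = {"mse": mse_loss, "bce": bce_with_logits}[loss]
    opt = optimizer or Adam(lr=lr)
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=np.float32)
    history = []
    for _ in range(epochs):
        order = rng.permutation(len(X))
        total, seen = 0.0, 0
        for s in range(0, len(X), batch_size):
            idx = order[s : s + batch_size]
            out = model.forward(X[idx], train=True)
            lval, dout = loss_fn(out, y[idx])
            model.backward(dout)
            opt.step(model.params, model.grads)
            total += lval * len(idx)
            seen += len(idx)
        history.append(total / seen)
    return history


def predict(model: SmallCNN, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Raw model outputs (logits for a detector, mm for a size model)."""
    outs = [
        model.forward(np.asarray(X[s : s + batch_size], dtype=np.float32))
        for s in range(0, len(X), batch_size)
    ]
    return np.concatenate(outs) if outs else np.empty(0)
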