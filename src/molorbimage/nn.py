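"""Minimal CNN building blocks with explicit backpropagation.

Everything the VGG-style regressor needs — 3×3 convolutions, 2×2 max
pooling, ReLU, fully connected layers, batch normalization, the AdamW
optimizer and a reduce-on-plateau learning-rate schedule — implemented on
NumPy arrays. Desk-scale images (tens of pixels per side) keep this fast
enough for CPU training; determinism follows from seeding the single
NumPy generator used for initialization and shuffling.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "ReLU", "MaxPool2x2", "Flatten", "Linear", "BatchNorm1D",
           "NeuralNet", "AdamW", "PlateauScheduler"]


class Layer:
    """Base layer: parameter/gradient dicts plus forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = state[k].copy()


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W), zero-padded by k//2 → (N, C*k*k, H*W) patch matrix."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    cols = np.empty((n, c, k * k, h * w), dtype=x.dtype)
    for di in range(k):
        for dj in range(k):
            patch = xp[:, :, di:di + h, dj:dj + w]
            cols[:, :, di * k + dj] = patch.reshape(n, c, h * w)
    return cols.reshape(n, c * k * k, h * w)


def _col2im(cols: np.ndarray, shape: tuple, k: int) -> np.ndarray:
    n, c, h, w = shape
    p = k // 2
    xp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=cols.dtype)
    cols = cols.reshape(n, c, k * k, h * w)
    for di in range(k):
        for dj in range(k):
            xp[:, :, di:di + h, dj:dj + w] += \
                cols[:, :, di * k + dj].reshape(n, c, h, w)
    return xp[:, :, p:p + h, p:p + w]


class Conv2D(Layer):
    """3×3 same-padding convolution, He-initialized."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator, kernel: int = 3):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        fan_in = in_channels * kernel * kernel
        self.params["w"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in),
            size=(out_channels, in_channels, kernel, kernel))
        self.params["b"] = np.zeros(out_channels)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        n, c, h, w = x.shape
        self._cols = _im2col(x, self.kernel)
        wmat = self.params["w"].reshape(self.out_channels, -1)
        y = np.einsum("oc,ncp->nop", wmat, self._cols, optimize=True)
        y += self.params["b"][None, :, None]
        return y.reshape(n, self.out_channels, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, _, h, w = self._shape
        dyf = dy.reshape(n, self.out_channels, h * w)
        self.grads["b"] = dyf.sum(axis=(0, 2))
        dw = np.einsum("nop,ncp->oc", dyf, self._cols, optimize=True)
        self.grads["w"] = dw.reshape(self.params["w"].shape)
        wmat = self.params["w"].reshape(self.out_channels, -1)
        dcols = np.einsum("oc,nop->ncp", wmat, dyf, optimize=True)
        return _col2im(dcols, self._shape, self.kernel)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2x2(Layer):
    """2×2 max pooling, stride 2, ceil mode (odd edges padded with −inf)."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, h, w = x.shape
        self._in_shape = x.shape
        ph, pw = (-h) % 2, (-w) % 2
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)),
                       constant_values=-np.inf)
        n, c, h2, w2 = x.shape
        xr = x.reshape(n, c, h2 // 2, 2, w2 // 2, 2)
        y = xr.max(axis=(3, 5))
        mask = xr == y[:, :, :, None, :, None]
        # break ties deterministically: keep only the first max per window
        flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h2 // 2, w2 // 2, 4)
        first = np.cumsum(flat, axis=-1) == 1
        self._mask = (flat & first).reshape(
            n, c, h2 // 2, w2 // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._padded_shape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h2, w2 = self._padded_shape
        dx = (self._mask * dy[:, :, :, None, :, None]).reshape(n, c, h2, w2)
        nh, nw = self._in_shape[2], self._in_shape[3]
        return dx[:, :, :nh, :nw]


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator):
        super().__init__()
        self.params["w"] = rng.normal(
            0.0, np.sqrt(2.0 / in_features), size=(out_features, in_features))
        self.params["b"] = np.zeros(out_features)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["w"].T + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["w"] = dy.T @ self._x
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["w"]


class BatchNorm1D(Layer):
    """Batch normalization over feature vectors (training batch statistics,
    running-average statistics in eval mode)."""

    def __init__(self, n_features: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(n_features)
        self.params["beta"] = np.zeros(n_features)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n = dy.shape[0]
        xhat = self._xhat
        self.grads["gamma"] = np.sum(dy * xhat, axis=0)
        self.grads["beta"] = dy.sum(axis=0)
        dxhat = dy * self.params["gamma"]
        return (dxhat - dxhat.mean(axis=0)
                - xhat * np.mean(dxhat * xhat, axis=0)) / self._std

    def state(self) -> dict[str, np.ndarray]:
        s = super().state()
        s["running_mean"] = self.running_mean.copy()
        s["running_var"] = self.running_var.copy()
        return s

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        super().load_state(state)
        self.running_mean = state["running_mean"].copy()
        self.running_var = state["running_var"].copy()


class NeuralNet:
    """A feed-forward stack of layers with shared forward/backward plumbing."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def n_parameters(self) -> int:
        return sum(int(p.size) for layer in self.layers
                   for p in layer.params.values())

    def state(self) -> list[dict[str, np.ndarray]]:
        return [layer.state() for layer in self.layers]

    def load_state(self, state: list[dict[str, np.ndarray]]) -> None:
        if len(state) != len(self.layers):
            raise ValueError("checkpoint/architecture mismatch: "
                             f"{len(state)} layer states for {len(self.layers)} layers")
        for layer, s in zip(self.layers, state):
            for k, v in layer.params.items():
                if s[k].shape != v.shape:
                    raise ValueError(
                        f"checkpoint/architecture mismatch in layer "
                        f"{type(layer).__name__}: {s[k].shape} vs {v.shape}")
            layer.load_state(s)


class AdamW:
    """AdamW: Adam moments with decoupled weight decay."""

    def __init__(self, net: NeuralNet, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-2):
        self.net = net
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in layer.params.items()}
                  for layer in net.layers]
        self.v = [{k: np.zeros_like(v) for k, v in layer.params.items()}
                  for layer in net.layers]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for li, layer in enumerate(self.net.layers):
            for k, p in layer.params.items():
                g = layer.grads.get(k)
                if g is None:
                    continue
                m = self.m[li][k]
                v = self.v[li][k]
                m *= self.beta1
                m += (1 - self.beta1) * g
                v *= self.beta2
                v += (1 - self.beta2) * g * g
                p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
                p -= self.lr * self.weight_decay * p


class PlateauScheduler:
    """Reduce-on-plateau: multiply LR by ``factor`` when the best validation
    loss has not improved by more than ``threshold`` for ``patience``
    consecutive epochs; never below ``lr_min``. The counter resets on
    improvement and after each reduction."""

    def __init__(self, lr_init: float, factor: float = 0.8,
                 patience: int = 10, lr_min: float = 1e-6,
                 threshold: float = 1e-6):
        self.lr = lr_init
        self.factor = factor
        self.patience = patience
        self.lr_min = lr_min
        self.threshold = threshold
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, val_loss: float) -> float:
        """Record one epoch's validation loss; return the LR for the next epoch."""
        if val_loss < self.best - self.threshold:
            self.best = val_loss
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs >= self.patience:
                self.lr = max(self.lr * self.factor, self.lr_min)
                self.bad_epochs = 0
        return self.lr
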