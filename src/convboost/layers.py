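"""Minimal 1-D neural-network layers with exact analytic gradients.

Everything operates on ``float64`` NumPy arrays.  Sequence-shaped activations
are ``(batch, length, channels)``; dense activations are ``(batch, units)``.
Each layer caches what its backward pass needs during ``forward`` and exposes
``params``/``grads`` dictionaries for the optimizer.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer: parameter-free identity."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def output_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        return in_shape


class Conv1D(Layer):
    """1-D convolution (cross-correlation) with 'valid' or 'same' padding, stride 1."""

    def __init__(self, in_channels: int, filters: int, kernel_size: int,
                 padding: str, rng: np.random.Generator) -> None:
        super().__init__()
        if padding not in ("valid", "same"):
            raise ValueError(f"padding must be 'valid' or 'same', got {padding!r}")
        self.kernel_size = kernel_size
        self.padding = padding
        fan_in = kernel_size * in_channels
        fan_out = kernel_size * filters
        self.params = {
            "W": glorot_uniform(rng, (kernel_size, in_channels, filters), fan_in, fan_out),
            "b": np.zeros(filters),
        }

    def _pads(self) -> tuple[int, int]:
        if self.padding == "valid":
            return 0, 0
        total = self.kernel_size - 1
        return total // 2, total - total // 2

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        K = self.kernel_size
        left, right = self._pads()
        xp = np.pad(x, ((0, 0), (left, right), (0, 0))) if left or right else x
        if xp.shape[1] < K:
            raise ValueError(
                f"spatial length {x.shape[1]} smaller than kernel {K}; use fewer blocks"
            )
        # patches: (n, L_out, C, K) -> (n, L_out, K*C) matching W reshape order (K, C)
        patches = sliding_window_view(xp, K, axis=1)          # (n, L_out, C, K)
        patches = np.ascontiguousarray(patches.transpose(0, 1, 3, 2))  # (n, L_out, K, C)
        n, L_out = patches.shape[:2]
        self._patches = patches.reshape(n * L_out, -1)
        self._x_shape = x.shape
        self._xp_len = xp.shape[1]
        W = self.params["W"]
        out = self._patches @ W.reshape(-1, W.shape[2]) + self.params["b"]
        return out.reshape(n, L_out, -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, L_out, F = dout.shape
        K = self.kernel_size
        W = self.params["W"]
        dflat = dout.reshape(n * L_out, F)
        self.grads["W"] = (self._patches.T @ dflat).reshape(W.shape)
        self.grads["b"] = dflat.sum(axis=0)
        dpatches = (dflat @ W.reshape(-1, F).T).reshape(n, L_out, K, -1)
        dxp = np.zeros((n, self._xp_len, W.shape[1]))
        for k in range(K):
            dxp[:, k : k + L_out, :] += dpatches[:, :, k, :]
        left, right = self._pads()
        return dxp[:, left : self._xp_len - right, :] if (left or right) else dxp

    def output_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        L, _ = in_shape
        F = self.params["W"].shape[2]
        if self.padding == "same":
            return (L, F)
        if L < self.kernel_size:
            raise ValueError(
                f"spatial length {L} smaller than kernel {self.kernel_size}; use fewer blocks"
            )
        return (L - self.kernel_size + 1, F)


class BatchNorm(Layer):
    """Batch normalization over batch (and spatial, if present) axes per channel.

    Running statistics use momentum 0.9: desk-scale runs see only a handful
    of batches per epoch, and slower-adapting statistics leave inference-mode
    evaluation (and hence early stopping) badly out of sync with the weights.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-3) -> None:
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels)}
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mu) / std
        if training:
            self._cache = (xhat, std, axes, x.shape)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, std, axes, shape = self._cache
        m = np.prod([shape[a] for a in axes])
        self.grads["gamma"] = (dout * xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        g = self.params["gamma"]
        dxhat = dout * g
        return (dxhat - dxhat.mean(axis=axes) - xhat * (dxhat * xhat).mean(axis=axes)) / std


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling; trailing remainder timesteps are dropped (floor)."""

    def __init__(self, pool_size: int) -> None:
        super().__init__()
        self.pool_size = pool_size

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        p = self.pool_size
        n, L, C = x.shape
        q = L // p
        if q == 0:
            raise ValueError(f"spatial length {L} smaller than pool size {p}")
        xr = x[:, : q * p, :].reshape(n, q, p, C)
        self._arg = xr.argmax(axis=2)
        self._in_shape = x.shape
        return xr.max(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, q, C = dout.shape
        p = self.pool_size
        dxr = np.zeros((n, q, p, C))
        ni, qi, ci = np.ogrid[:n, :q, :C]
        dxr[ni, qi, self._arg, ci] = dout
        dx = np.zeros(self._in_shape)
        dx[:, : q * p, :] = dxr.reshape(n, q * p, C)
        return dx

    def output_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        L, C = in_shape
        if L // self.pool_size == 0:
            raise ValueError(f"spatial length {L} smaller than pool size {self.pool_size}")
        return (L // self.pool_size, C)


class Dropout(Layer):
    """Inverted dropout: active only during training, identity at inference."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    """Row-major (position, channel) flattening to ``(n, L*C)``."""

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._in_shape)

    def output_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        return (int(np.prod(in_shape)),)


class Dense(Layer):
    def __init__(self, in_features: int, units: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params = {
            "W": glorot_uniform(rng, (in_features, units), in_features, units),
            "b": np.zeros(units),
        }

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T

    def output_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        return (self.params["W"].shape[1],)


class Embedding(Layer):
    """Token-index lookup table mapping ``(n, T)`` ints to ``(n, T, dim)``."""

    def __init__(self, vocab_size: int, dim: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.vocab_size = vocab_size
        self.params = {"E": rng.uniform(-0.05, 0.05, size=(vocab_size, dim))}

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        idx = np.asarray(x, dtype=np.int64)
        if idx.min() < 0 or idx.max() >= self.vocab_size:
            raise ValueError("token index outside [0, vocab_size)")
        self._idx = idx
        return self.params["E"][idx]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dE = np.zeros_like(self.params["E"])
        np.add.at(dE, self._idx, dout)
        self.grads["E"] = dE
        return np.zeros(self._idx.shape)  # input layer: gradient stops here

    def output_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        (T,) = in_shape
        return (T, self.params["E"].shape[1])


class Optimizer:
    def __init__(self, lr: float) -> None:
        self.lr = lr
        self._state: dict[int, dict[str, dict[str, np.ndarray]]] = {}

    def step(self, layers: list[Layer]) -> None:
        raise NotImplementedError


class Adam(Optimizer):
    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7) -> None:
        super().__init__(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, layers: list[Layer]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for lid, layer in enumerate(layers):
            if not layer.params:
                continue
            state = self._state.setdefault(lid, {
                k: {"m": np.zeros_like(v), "v": np.zeros_like(v)} for k, v in layer.params.items()
            })
            for k, g in layer.grads.items():
                s = state[k]
                s["m"] = self.beta1 * s["m"] + (1 - self.beta1) * g
                s["v"] = self.beta2 * s["v"] + (1 - self.beta2) * g * g
                layer.params[k] -= self.lr * (s["m"] / b1t) / (np.sqrt(s["v"] / b2t) + self.eps)


class RMSprop(Optimizer):
    def __init__(self, lr: float = 1e-3, rho: float = 0.9, eps: float = 1e-7) -> None:
        super().__init__(lr)
        self.rho, self.eps = rho, eps

    def step(self, layers: list[Layer]) -> None:
        for lid, layer in enumerate(layers):
            if not layer.params:
                continue
            state = self._state.setdefault(lid, {
                k: {"v": np.zeros_like(v)} for k, v in layer.params.items()
            })
            for k, g in layer.grads.items():
                s = state[k]
                s["v"] = self.rho * s["v"] + (1 - self.rho) * g * g
                layer.params[k] -= self.lr * g / (np.sqrt(s["v"]) + self.eps)
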