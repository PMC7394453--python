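"""Minimal 3D convolutional neural-network layers in NumPy.

Implements exactly the pieces the b0 synthesizer needs — 3x3x3 and 1x1x1
convolutions (im2col + GEMM), per-instance feature normalization, leaky
rectification, 2x average pooling, 2x nearest-neighbour upsampling — each
with a hand-written backward pass, plus an Adam optimizer with L2 weight
decay. Tensors are single-sample ``(channels, x, y, z)`` float32 arrays
(the training batch size is 1, which is also why instance norm rather than
batch norm is the right normalization here).

Everything is deterministic given the seed used at initialization.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv3d",
    "InstanceNorm3d",
    "LeakyReLU",
    "AvgPool3d",
    "Upsample3d",
    "Sequential",
    "Adam",
]


class Layer:
    """Base layer: ``params`` / ``grads`` dicts plus forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k, g in self.grads.items():
            g.fill(0.0)


class Conv3d(Layer):
    """3D convolution, kernel 3 (pad 1) or 1, stride 1, He-initialized."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        rng: np.random.Generator,
        leaky_slope: float = 0.01,
    ) -> None:
        super().__init__()
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        self.cin, self.cout, self.k = in_channels, out_channels, kernel
        fan_in = in_channels * kernel**3
        std = np.sqrt(2.0 / ((1.0 + leaky_slope**2) * fan_in))
        self.params["W"] = rng.normal(
            0.0, std, size=(out_channels, in_channels * kernel**3)
        ).astype(np.float32)
        self.params["b"] = np.zeros(out_channels, dtype=np.float32)
        self.grads["W"] = np.zeros_like(self.params["W"])
        self.grads["b"] = np.zeros_like(self.params["b"])
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, X, Y, Z = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        self._shape = x.shape
        if self.k == 1:
            cols = x.reshape(c, -1)
        else:
            xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
            cols = np.empty((c * 27, X * Y * Z), dtype=np.float32)
            o = 0
            for dx in range(3):
                for dy in range(3):
                    for dz in range(3):
                        cols[o::27, :] = xp[
                            :, dx : dx + X, dy : dy + Y, dz : dz + Z
                        ].reshape(c, -1)
                        o += 1
        # cols row order is (channel, offset) flattened, matching W's
        # (cin, k^3) layout
        self._cols = cols
        y = self.params["W"] @ cols + self.params["b"][:, None]
        return y.reshape(self.cout, X, Y, Z)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, X, Y, Z = self._shape
        dy2 = dy.reshape(self.cout, -1)
        self.grads["W"] += dy2 @ self._cols.T
        self.grads["b"] += dy2.sum(axis=1)
        dcols = self.params["W"].T @ dy2
        if self.k == 1:
            return dcols.reshape(self._shape)
        dxp = np.zeros((c, X + 2, Y + 2, Z + 2), dtype=np.float32)
        o = 0
        for dx in range(3):
            for dy_ in range(3):
                for dz in range(3):
                    dxp[:, dx : dx + X, dy_ : dy_ + Y, dz : dz + Z] += dcols[
                        o::27, :
                    ].reshape(c, X, Y, Z)
                    o += 1
        return dxp[:, 1:-1, 1:-1, 1:-1]

    def n_params(self) -> int:
        return self.params["W"].size + self.params["b"].size


class InstanceNorm3d(Layer):
    """Per-sample, per-channel normalization over the spatial dims."""

    def __init__(self, channels: int, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps = eps
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        self.grads["gamma"] = np.zeros(channels, dtype=np.float32)
        self.grads["beta"] = np.zeros(channels, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        c = x.shape[0]
        flat = x.reshape(c, -1)
        mu = flat.mean(axis=1, keepdims=True)
        var = flat.var(axis=1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (flat - mu) * self._inv
        y = self.params["gamma"][:, None] * self._xhat + self.params["beta"][:, None]
        return y.reshape(x.shape).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c = dy.shape[0]
        dyf = dy.reshape(c, -1)
        self.grads["gamma"] += (dyf * self._xhat).sum(axis=1)
        self.grads["beta"] += dyf.sum(axis=1)
        dxhat = dyf * self.params["gamma"][:, None]
        m1 = dxhat.mean(axis=1, keepdims=True)
        m2 = (dxhat * self._xhat).mean(axis=1, keepdims=True)
        dx = self._inv * (dxhat - m1 - self._xhat * m2)
        return dx.reshape(dy.shape).astype(np.float32)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01) -> None:
        super().__init__()
        self.slope = slope

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._pos = x > 0
        return np.where(self._pos, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._pos, dy, self.slope * dy)


class AvgPool3d(Layer):
    """2x2x2 average pooling; requires even spatial dims."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, X, Y, Z = x.shape
        if X % 2 or Y % 2 or Z % 2:
            raise ValueError(f"spatial dims must be even to pool, got {x.shape[1:]}")
        self._shape = x.shape
        return (
            x.reshape(c, X // 2, 2, Y // 2, 2, Z // 2, 2)
            .mean(axis=(2, 4, 6))
            .astype(np.float32)
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, X, Y, Z = self._shape
        up = np.repeat(np.repeat(np.repeat(dy, 2, 1), 2, 2), 2, 3)
        return (up / 8.0).astype(np.float32)


class Upsample3d(Layer):
    """2x nearest-neighbour upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(np.repeat(x, 2, 1), 2, 2), 2, 3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, X, Y, Z = dy.shape
        return (
            dy.reshape(c, X // 2, 2, Y // 2, 2, Z // 2, 2)
            .sum(axis=(2, 4, 6))
            .astype(np.float32)
        )


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for lyr in self.layers:
            x = lyr.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for lyr in reversed(self.layers):
            dy = lyr.backward(dy)
        return dy

    def zero_grad(self) -> None:
        for lyr in self.layers:
            lyr.zero_grad()


class Adam:
    """Adam with L2 weight decay (decay added to the gradient).

    ``param_refs`` is a list of ``(params_dict, grads_dict, key)`` triples
    so the optimizer updates layer arrays in place.
    """

    def __init__(
        self,
        param_refs: list[tuple[dict, dict, str]],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-5,
    ) -> None:
        self.refs = param_refs
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(p[k]) for p, _g, k in param_refs]
        self.v = [np.zeros_like(p[k]) for p, _g, k in param_refs]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for i, (p, g, k) in enumerate(self.refs):
            grad = g[k] + self.wd * p[k]
            self.m[i] = b1 * self.m[i] + (1 - b1) * grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * grad * grad
            p[k] -= self.lr * (self.m[i] / c1) / (np.sqrt(self.v[i] / c2) + self.eps)
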