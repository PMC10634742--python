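"""Minimal 3D CNN building blocks with explicit forward/backward passes.

Tensors are ``float64`` arrays in (N, C, D, H, W) layout. Each layer
caches what its backward pass needs during ``forward`` and releases it
after ``backward``. Convolutions are evaluated as a sum of shifted
tensor contractions (one ``tensordot`` per kernel offset), which keeps
memory flat and vectorises well for the small kernels used here.

Gradient correctness is enforced by finite-difference checks in the
test-suite rather than by an autograd engine.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float64


class Parameter:
    """A trainable array with an accumulated gradient and a freeze flag."""

    __slots__ = ("data", "grad", "trainable", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)
        self.trainable = True
        self.name = name

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3d(Layer):
    """3D convolution ('same' zero padding), weight shape (Cin, Cout, k, k, k)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        rng: np.random.Generator | None = None,
        name: str = "",
    ) -> None:
        rng = rng or np.random.default_rng()
        k = kernel_size
        fan_in = in_channels * k**3
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.weight = Parameter(
            rng.normal(scale=scale, size=(in_channels, out_channels, k, k, k)),
            name=f"{name}.weight",
        )
        self.bias = Parameter(np.zeros(out_channels), name=f"{name}.bias")
        self.kernel_size = k
        self.pad = (k - 1) // 2
        self.name = name
        self._xp: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        k, p = self.kernel_size, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x
        if training:
            self._xp = xp
        n, _, dd, hh, ww = x.shape
        w = self.weight.data
        acc = np.zeros((n, dd, hh, ww, w.shape[1]), dtype=DTYPE)
        for a in range(k):
            for b in range(k):
                for c in range(k):
                    acc += np.tensordot(
                        xp[:, :, a : a + dd, b : b + hh, c : c + ww],
                        w[:, :, a, b, c],
                        axes=([1], [0]),
                    )
        out = np.moveaxis(acc, -1, 1)
        out += self.bias.data[None, :, None, None, None]
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        assert self._xp is not None, "backward before forward(training=True)"
        k, p = self.kernel_size, self.pad
        xp = self._xp
        n, cout, dd, hh, ww = grad_out.shape
        g = np.moveaxis(grad_out, 1, -1)  # (N, D, H, W, Cout)
        self.bias.grad += g.sum(axis=(0, 1, 2, 3))
        w = self.weight.data
        grad_xp = np.zeros_like(xp)
        for a in range(k):
            for b in range(k):
                for c in range(k):
                    x_sub = xp[:, :, a : a + dd, b : b + hh, c : c + ww]
                    self.weight.grad[:, :, a, b, c] += np.tensordot(
                        x_sub, g, axes=([0, 2, 3, 4], [0, 1, 2, 3])
                    )
                    gx = np.tensordot(g, w[:, :, a, b, c], axes=([4], [1]))
                    grad_xp[:, :, a : a + dd, b : b + hh, c : c + ww] += np.moveaxis(
                        gx, -1, 1
                    )
        self._xp = None
        if p:
            return grad_xp[:, :, p:-p, p:-p, p:-p]
        return grad_xp


class BatchNorm3d(Layer):
    """Per-channel batch normalisation over (N, D, H, W).

    Batch statistics are used in training mode; exponential running
    estimates in eval mode. ``update_running_stats`` can be cleared to
    freeze the running estimates during fine-tuning.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "") -> None:
        self.gamma = Parameter(np.ones(channels), name=f"{name}.gamma")
        self.beta = Parameter(np.zeros(channels), name=f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self.update_running_stats = True
        self.name = name
        self._cache: tuple | None = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            if self.update_running_stats:
                m = self.momentum
                self.running_mean = (1 - m) * self.running_mean + m * mean
                self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) * inv_std[None, :, None, None, None]
        if training:
            self._cache = (xhat, inv_std)
        return self.gamma.data[None, :, None, None, None] * xhat + self.beta.data[
            None, :, None, None, None
        ]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        xhat, inv_std = self._cache
        self._cache = None
        axes = (0, 2, 3, 4)
        m = float(np.prod([grad_out.shape[i] for i in axes]))
        self.gamma.grad += (grad_out * xhat).sum(axis=axes)
        self.beta.grad += grad_out.sum(axis=axes)
        g = grad_out * self.gamma.data[None, :, None, None, None]
        gsum = g.sum(axis=axes)[None, :, None, None, None]
        gxsum = (g * xhat).sum(axis=axes)[None, :, None, None, None]
        return inv_std[None, :, None, None, None] * (g - gsum / m - xhat * gxsum / m)


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        g = grad_out * self._mask
        self._mask = None
        return g


class AvgPool3d(Layer):
    """2x2x2 average pooling; spatial dims must be even."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"pooling needs even spatial dims, got {(d, h, w)}")
        return x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2).mean(axis=(3, 5, 7))

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        g = grad_out / 8.0
        for axis in (2, 3, 4):
            g = np.repeat(g, 2, axis=axis)
        return g


class Upsample3d(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for axis in (2, 3, 4):
            x = np.repeat(x, 2, axis=axis)
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, c, d, h, w = grad_out.shape
        return grad_out.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2).sum(
            axis=(3, 5, 7)
        )


class Sigmoid(Layer):
    def __init__(self) -> None:
        self._out: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = 1.0 / (1.0 + np.exp(-x))
        if training:
            self._out = out
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        assert self._out is not None
        g = grad_out * self._out * (1.0 - self._out)
        self._out = None
        return g
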