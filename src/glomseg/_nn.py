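"""Compact numpy engine for small convolutional encoder–decoder networks.

Implements exactly the layer vocabulary the segmentation network needs —
3x3 same-padded convolution (linear / ReLU / sigmoid activation), batch
normalization, 2x2 max pooling, 2x nearest-neighbor upsampling, channel
concatenation — with hand-derived backward passes, plus the four first-order
optimizers used in the hyperparameter sweeps (SGD, Adam, RMSprop, Adadelta).

Tensors are NHWC float32. Convolution is evaluated as an im2col matrix
product so the heavy lifting stays in BLAS; its input gradient reuses the
same kernel applied to the 180°-rotated, transposed filter bank, which for
stride-1 same padding is an exact adjoint and avoids any scatter-add.

This engine favors clarity and testability over generality: stride is fixed
at 1 for convolutions and 2 for pooling/upsampling, which is all an
hourglass segmentation network requires.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Parameter:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray) -> None:
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    """Base class: forward caches whatever backward needs."""

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int = 3) -> np.ndarray:
    """(N,H,W,C) -> (N*H*W, k*k*C) patch matrix for stride-1 same padding."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))  # N,H,W,C,k,k
    n, h, w = x.shape[:3]
    return win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, -1)


class Conv2D(Layer):
    """3x3 convolution, stride 1, same padding, fused pointwise activation.

    ``activation`` is one of ``"linear"``, ``"relu"``, ``"sigmoid"``. Weights
    are He-initialized for ReLU and Glorot-initialized otherwise.
    """

    kind = "convolutional"

    def __init__(self, in_channels: int, out_channels: int,
                 activation: str = "linear", *,
                 rng: np.random.Generator, kernel: int = 3) -> None:
        if activation not in ("linear", "relu", "sigmoid"):
            raise ValueError(f"unknown activation {activation!r}")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.activation = activation
        self.kernel = kernel
        fan_in = kernel * kernel * in_channels
        fan_out = kernel * kernel * out_channels
        if activation == "relu":
            std = np.sqrt(2.0 / fan_in)
        else:
            std = np.sqrt(2.0 / (fan_in + fan_out))
        self.weight = Parameter(
            rng.normal(0.0, std, (kernel, kernel, in_channels, out_channels))
        )
        self.bias = Parameter(np.zeros(out_channels))
        self._cache: tuple | None = None

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, h, w, _ = x.shape
        cols = _im2col(x, self.kernel)
        z = cols @ self.weight.value.reshape(-1, self.out_channels)
        z += self.bias.value
        z = z.reshape(n, h, w, self.out_channels)
        if self.activation == "relu":
            y = np.maximum(z, 0.0)
        elif self.activation == "sigmoid":
            y = 1.0 / (1.0 + np.exp(-z))
        else:
            y = z
        if training:
            self._cache = (x.shape, cols, y)
        return y

    def _grad_to_preact(self, grad: np.ndarray, y: np.ndarray) -> np.ndarray:
        if self.activation == "relu":
            return grad * (y > 0)
        if self.activation == "sigmoid":
            return grad * y * (1.0 - y)
        return grad

    def backward(self, grad: np.ndarray, *, preact: bool = False) -> np.ndarray:
        """Backprop through the layer.

        With ``preact=True`` the incoming ``grad`` is already with respect to
        the pre-activation output (used to fuse sigmoid with cross-entropy);
        otherwise it is with respect to the activated output.
        """
        shape, cols, y = self._cache
        n, h, w, _ = shape
        dz = grad if preact else self._grad_to_preact(grad, y)
        dz2 = dz.reshape(n * h * w, self.out_channels)
        self.weight.grad += (cols.T @ dz2).reshape(self.weight.value.shape)
        self.bias.grad += dz2.sum(axis=0)
        # input gradient: correlate dz with the rotated, io-transposed kernel
        w_rot = self.weight.value[::-1, ::-1].transpose(0, 1, 3, 2)
        cols_dz = _im2col(dz, self.kernel)
        dx = cols_dz @ w_rot.reshape(-1, self.in_channels)
        return dx.reshape(shape)


class BatchNorm2D(Layer):
    """Per-channel batch normalization over the (N, H, W) axes.

    Training uses batch statistics and updates exponential running averages
    (keep fraction ``momentum``); inference uses the running averages.
    """

    kind = "normalization"

    def __init__(self, channels: int, momentum: float = 0.9,
                 eps: float = 1e-5) -> None:
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache: tuple | None = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(np.float32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if training:
            self._cache = (xhat, inv_std)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        m = float(np.prod(grad.shape[:3]))
        self.gamma.grad += (grad * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += grad.sum(axis=(0, 1, 2))
        dxhat = grad * self.gamma.value
        # standard batch-norm input gradient with batch statistics
        return (inv_std / m) * (
            m * dxhat
            - dxhat.sum(axis=(0, 1, 2))
            - xhat * (dxhat * xhat).sum(axis=(0, 1, 2))
        )


class MaxPool2D(Layer):
    """2x2 max pooling, stride 2. Requires even spatial dimensions."""

    kind = "max_pooling"

    def __init__(self) -> None:
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"max pooling needs even spatial dims, got {h}x{w}")
        xr = (x.reshape(n, h // 2, 2, w // 2, 2, c)
               .transpose(0, 1, 3, 5, 2, 4)
               .reshape(n, h // 2, w // 2, c, 4))
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if training:
            self._cache = (x.shape, idx)
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        shape, idx = self._cache
        n, h, w, c = shape
        dxr = np.zeros((n, h // 2, w // 2, c, 4), dtype=grad.dtype)
        np.put_along_axis(dxr, idx[..., None], grad[..., None], axis=-1)
        return (dxr.reshape(n, h // 2, w // 2, c, 2, 2)
                   .transpose(0, 1, 4, 2, 5, 3)
                   .reshape(shape))


class Upsample2D(Layer):
    """2x nearest-neighbor upsampling."""

    kind = "upsampling"

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c = grad.shape
        return grad.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class Concatenate(Layer):
    """Channel-axis concatenation of two same-resolution feature maps."""

    kind = "concatenate"

    def __init__(self) -> None:
        self._split: int | None = None

    def forward(self, a: np.ndarray, b: np.ndarray, training: bool) -> np.ndarray:  # type: ignore[override]
        if a.shape[:3] != b.shape[:3]:
            raise ValueError(
                f"concatenate inputs disagree spatially: {a.shape} vs {b.shape}"
            )
        self._split = a.shape[3]
        return np.concatenate([a, b], axis=3)

    def backward(self, grad: np.ndarray) -> tuple[np.ndarray, np.ndarray]:  # type: ignore[override]
        return grad[..., : self._split], grad[..., self._split :]


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def binary_cross_entropy(p: np.ndarray, y: np.ndarray,
                         eps: float = 1e-7) -> tuple[float, np.ndarray]:
    """Mean pixel BCE of probabilities ``p`` against {0,1} targets ``y``.

    Returns ``(loss, grad_preact)`` where ``grad_preact`` is the gradient
    with respect to the *pre-sigmoid* output, ``(p - y) / n`` — the fused
    sigmoid + cross-entropy form, which is numerically exact even at
    saturated probabilities.
    """
    pc = np.clip(p, eps, 1.0 - eps)
    loss = float(-(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc)).mean())
    grad_preact = ((p - y) / p.size).astype(np.float32)
    return loss, grad_preact


# ---------------------------------------------------------------------------
# Optimizers
# ---------------------------------------------------------------------------

class Optimizer:
    """Base optimizer over a fixed parameter list."""

    def __init__(self, params: Sequence[Parameter], lr: float) -> None:
        self.params = list(params)
        self.lr = lr

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:  # pragma: no cover
        raise NotImplementedError


class SGD(Optimizer):
    DEFAULT_LR = 0.01

    def __init__(self, params: Sequence[Parameter], lr: float = DEFAULT_LR,
                 momentum: float = 0.0) -> None:
        super().__init__(params, lr)
        self.momentum = momentum
        self._v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._v):
            if self.momentum:
                v *= self.momentum
                v += p.grad
                p.value -= self.lr * v
            else:
                p.value -= self.lr * p.grad


class Adam(Optimizer):
    DEFAULT_LR = 1e-3

    def __init__(self, params: Sequence[Parameter], lr: float = DEFAULT_LR,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7) -> None:
        super().__init__(params, lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        bc1 = 1.0 - self.beta1 ** self._t
        bc2 = 1.0 - self.beta2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class RMSprop(Optimizer):
    DEFAULT_LR = 1e-3

    def __init__(self, params: Sequence[Parameter], lr: float = DEFAULT_LR,
                 rho: float = 0.9, eps: float = 1e-7) -> None:
        super().__init__(params, lr)
        self.rho, self.eps = rho, eps
        self._v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._v):
            v *= self.rho
            v += (1 - self.rho) * p.grad**2
            p.value -= self.lr * p.grad / (np.sqrt(v) + self.eps)


class Adadelta(Optimizer):
    # classic formulation: the accumulated-update ratio sets the step size,
    # so the nominal learning rate stays at 1
    DEFAULT_LR = 1.0

    def __init__(self, params: Sequence[Parameter], lr: float = DEFAULT_LR,
                 rho: float = 0.95, eps: float = 1e-6) -> None:
        super().__init__(params, lr)
        self.rho, self.eps = rho, eps
        self._v = [np.zeros_like(p.value) for p in self.params]
        self._u = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        for p, v, u in zip(self.params, self._v, self._u):
            v *= self.rho
            v += (1 - self.rho) * p.grad**2
            delta = np.sqrt(u + self.eps) / np.sqrt(v + self.eps) * p.grad
            u *= self.rho
            u += (1 - self.rho) * delta**2
            p.value -= self.lr * delta


OPTIMIZERS: dict[str, type[Optimizer]] = {
    "sgd": SGD,
    "adam": Adam,
    "rmsprop": RMSprop,
    "adadelta": Adadelta,
}


def make_optimizer(name: str, params: Sequence[Parameter],
                   lr: float | None = None) -> Optimizer:
    """Instantiate an optimizer by name with its standard default rate."""
    try:
        cls = OPTIMIZERS[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown optimizer {name!r}; expected one of {sorted(OPTIMIZERS)}"
        ) from None
    return cls(params, lr) if lr is not None else cls(params)
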