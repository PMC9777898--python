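"""Minimal seeded neural-network core on numpy.

Provides exactly the pieces the two-phase model needs: dense and strided
convolutional layers with hand-written backprop, leaky-ReLU / ReLU / sigmoid
activations, inverted dropout, nearest-neighbour upsampling, a ``Sequential``
container that can expose intermediate activations (required for Grad-CAM),
and an Adam optimiser.  All randomness flows through explicit
``numpy.random.Generator`` objects so that training is bit-reproducible on a
single device.

Conventions: image batches are ``(N, C, H, W)`` float64 arrays, feature
batches are ``(N, D)``.  ``forward(x, train=)`` caches what ``backward``
needs; ``backward(grad)`` returns the gradient w.r.t. the layer input and
accumulates parameter gradients in ``layer.grads``.
"""

from __future__ import annotations

import numpy as np

#: computation dtype of all layer parameters and activations
DTYPE = np.float32

__all__ = [
    "Dense",
    "Conv2d",
    "Upsample2x",
    "Flatten",
    "Reshape",
    "ReLU",
    "LeakyReLU",
    "Sigmoid",
    "Dropout",
    "Sequential",
    "Adam",
    "sigmoid",
    "mse_loss_grad",
    "bce_loss_grad",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    x = np.asarray(x)
    out = np.empty_like(x, dtype=np.result_type(x.dtype, np.float32))
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base class: parameter-free, identity backward bookkeeping."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    """Affine layer ``y = x @ W + b`` with He-style seeded init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.params = {
            "W": rng.normal(0.0, scale, size=(n_in, n_out)).astype(DTYPE),
            "b": np.zeros(n_out, dtype=DTYPE),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad):
        self.grads["W"] += self._x.T @ grad
        self.grads["b"] += grad.sum(axis=0)
        return grad @ self.params["W"].T


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """Return ``(N, ho*wo, C*k*k)`` patch matrix plus output spatial dims."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, h, w = x.shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x, (n, c, k, k, ho, wo), (s0, s1, s2, s3, s2 * stride, s3 * stride)
    )
    cols = np.ascontiguousarray(cols.transpose(0, 4, 5, 1, 2, 3))
    return cols.reshape(n, ho * wo, c * k * k), ho, wo


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int, pad: int):
    """Scatter-add patch gradients back to the input layout."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    dx = np.zeros((n, c, hp, wp), dtype=dcols.dtype)
    dcols = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 4, 5, 1, 2)
    for i in range(k):
        for j in range(k):
            dx[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += dcols[
                :, :, i, j
            ]
    if pad:
        dx = dx[:, :, pad : pad + h, pad : pad + w]
    return dx


class Conv2d(Layer):
    """2-D convolution (square kernel, 'same'-style padding) via im2col."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        rng: np.random.Generator,
        kernel: int = 3,
        stride: int = 1,
        pad: int = 1,
    ) -> None:
        super().__init__()
        self.kernel, self.stride, self.pad = kernel, stride, pad
        fan_in = c_in * kernel * kernel
        self.params = {
            "W": rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in)).astype(DTYPE),
            "b": np.zeros(c_out, dtype=DTYPE),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train=False):
        self._x_shape = x.shape
        cols, ho, wo = _im2col(x, self.kernel, self.stride, self.pad)
        self._cols = cols
        n = x.shape[0]
        out = cols.reshape(n * ho * wo, -1) @ self.params["W"].T + self.params["b"]
        return out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)

    def backward(self, grad):
        n, c_out, ho, wo = grad.shape
        g = grad.transpose(0, 2, 3, 1).reshape(n, ho * wo, c_out)
        g2 = g.reshape(-1, c_out)
        self.grads["W"] += g2.T @ self._cols.reshape(g2.shape[0], -1)
        self.grads["b"] += g2.sum(axis=0)
        dcols = (g2 @ self.params["W"]).reshape(n, ho * wo, -1)
        return _col2im(dcols, self._x_shape, self.kernel, self.stride, self.pad)


class Upsample2x(Layer):
    """Nearest-neighbour 2x spatial upsampling."""

    def forward(self, x, train=False):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad):
        n, c, h, w = grad.shape
        return grad.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape) -> None:
        super().__init__()
        self.shape = tuple(shape)

    def forward(self, x, train=False):
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x >= 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01) -> None:
        super().__init__()
        self.slope = slope

    def forward(self, x, train=False):
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.slope * grad)


class Sigmoid(Layer):
    def forward(self, x, train=False):
        self._y = sigmoid(x)
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout; identity when ``train=False`` or rate 0."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        self._mask = mask.astype(x.dtype, copy=False)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Sequential:
    """Ordered layer stack with optional intermediate-activation capture."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = list(layers)

    def forward(self, x, train=False, collect=False):
        acts = []
        for layer in self.layers:
            x = layer.forward(x, train=train)
            if collect:
                acts.append(x)
        return (x, acts) if collect else x

    def backward(self, grad, stop_at: int | None = None):
        """Backprop through layers; if ``stop_at`` is given, stop after
        propagating down to (and excluding) layer index ``stop_at`` and
        return the gradient w.r.t. that layer's output."""
        lo = 0 if stop_at is None else stop_at + 1
        for layer in reversed(self.layers[lo:]):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        out = []
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params.items():
                out.append((f"{i}.{name}", arr, layer.grads[name]))
        return out

    def zero_grad(self):
        for layer in self.layers:
            for g in layer.grads.values():
                g[...] = 0.0

    def state_dict(self):
        return {
            f"{i}.{name}": arr.copy()
            for i, layer in enumerate(self.layers)
            for name, arr in layer.params.items()
        }

    def load_state_dict(self, state):
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name][...] = state[f"{i}.{name}"]


class Adam:
    """Adam over one or more Sequential modules."""

    def __init__(self, modules, lr: float, beta1=0.9, beta2=0.999, eps=1e-8) -> None:
        self.modules = list(modules)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {}
        self.v = {}
        for mi, mod in enumerate(self.modules):
            for name, arr, _ in mod.parameters():
                key = (mi, name)
                self.m[key] = np.zeros_like(arr)
                self.v[key] = np.zeros_like(arr)

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for mi, mod in enumerate(self.modules):
            for name, arr, grad in mod.parameters():
                key = (mi, name)
                m = self.m[key]
                v = self.v[key]
                m *= self.beta1
                m += (1.0 - self.beta1) * grad
                v *= self.beta2
                v += (1.0 - self.beta2) * grad * grad
                arr -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for mod in self.modules:
            mod.zero_grad()


def mse_loss_grad(x: np.ndarray, recon: np.ndarray):
    """Mean-over-samples of mean squared pixel error, plus d/d(recon)."""
    if x.shape != recon.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {recon.shape}")
    diff = recon - x
    n = x.shape[0]
    per_pixel = diff.size // n
    loss = float(np.mean(diff**2))
    grad = 2.0 * diff / (n * per_pixel)
    return loss, grad


def bce_loss_grad(y: np.ndarray, logits: np.ndarray):
    """Binary cross-entropy on logits; returns (loss, d/d(logits))."""
    y = np.asarray(y, dtype=float).reshape(-1)
    logits = logits.reshape(-1)
    # log(1+e^z) computed stably
    loss = float(np.mean(np.maximum(logits, 0) - logits * y + np.log1p(np.exp(-np.abs(logits)))))
    p = sigmoid(logits)
    grad = ((p - y) / y.size).astype(logits.dtype, copy=False)
    return loss, grad.reshape(-1, 1)
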