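"""Minimal 1-D neural-network building blocks with manual backprop.

Everything operates on float64 arrays shaped ``(N, C, L)`` (batch, channels,
temporal samples) for convolutional layers and ``(N, F)`` for dense layers.
Layers cache what their backward pass needs; ``backward`` accumulates parameter
gradients and returns the gradient with respect to the layer input. Gradients
are verified against central finite differences in the test suite.

Pooling follows floor semantics (an odd trailing sample is dropped, a
length-1 input passes through unchanged) while strided convolutions use
"same" padding with ceil(L / stride) output length, so temporal lengths are
governed only by strides and pools.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Layer",
    "Sequential",
    "Conv1d",
    "BatchNorm1d",
    "ReLU",
    "MaxPool1d",
    "AvgPool1d",
    "GlobalAvgPool1d",
    "Flatten",
    "Dense",
    "ResidualBlock",
    "Adam",
    "softmax",
    "sigmoid",
    "softmax_cross_entropy",
    "sigmoid_cross_entropy",
]


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base layer: forward/backward plus parameter and mode plumbing."""

    training: bool = True

    def parameters(self) -> list[Parameter]:
        return []

    def children(self) -> list["Layer"]:
        return []

    def all_parameters(self) -> list[Parameter]:
        out = list(self.parameters())
        for child in self.children():
            out.extend(child.all_parameters())
        return out

    def set_training(self, mode: bool) -> None:
        self.training = mode
        for child in self.children():
            child.set_training(mode)

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def children(self) -> list[Layer]:
        return self.layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def _same_pad(length: int, kernel: int, stride: int) -> tuple[int, int, int]:
    out = -(-length // stride)
    pad = max(0, (out - 1) * stride + kernel - length)
    return out, pad // 2, pad - pad // 2


class Conv1d(Layer):
    """1-D convolution with "same" padding, He-initialised."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.c_in, self.c_out, self.kernel, self.stride = c_in, c_out, kernel, stride
        self.w = Parameter(rng.normal(0.0, scale, size=(c_out, c_in * kernel)))
        self.b = Parameter(np.zeros(c_out))
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, length = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        out_len, pl, pr = _same_pad(length, self.kernel, self.stride)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        idx = np.arange(out_len)[:, None] * self.stride + np.arange(self.kernel)
        cols = xp[:, :, idx]                      # (n, c, out_len, k)
        cols = cols.transpose(0, 2, 1, 3).reshape(n, out_len, c * self.kernel)
        y = cols @ self.w.value.T + self.b.value  # (n, out_len, c_out)
        self._cache = (cols, length, pl, xp.shape)
        return np.ascontiguousarray(y.transpose(0, 2, 1))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, length, pl, xp_shape = self._cache
        n, _, out_len = grad.shape
        gy = grad.transpose(0, 2, 1)              # (n, out_len, c_out)
        flat_g = gy.reshape(-1, self.c_out)
        flat_c = cols.reshape(-1, self.c_in * self.kernel)
        self.w.grad += flat_g.T @ flat_c
        self.b.grad += flat_g.sum(axis=0)
        dcols = gy @ self.w.value                 # (n, out_len, c_in*k)
        dcols = dcols.reshape(n, out_len, self.c_in, self.kernel).transpose(0, 2, 1, 3)
        dxp = np.zeros(xp_shape)
        starts = np.arange(out_len) * self.stride
        for j in range(self.kernel):
            dxp[:, :, starts + j] += dcols[:, :, :, j]
        return dxp[:, :, pl:pl + length]


class BatchNorm1d(Layer):
    """Per-channel batch normalisation over the batch and temporal axes."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) / std[None, :, None]
        self._cache = (xhat, std)
        return self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, std = self._cache
        m = grad.shape[0] * grad.shape[2]
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2))
        self.beta.grad += grad.sum(axis=(0, 2))
        dxhat = grad * self.gamma.value[None, :, None]
        if not self.training:
            return dxhat / std[None, :, None]
        sum_d = dxhat.sum(axis=(0, 2))[None, :, None]
        sum_dx = (dxhat * xhat).sum(axis=(0, 2))[None, :, None]
        return (dxhat - sum_d / m - xhat * sum_dx / m) / std[None, :, None]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool1d(Layer):
    """Kernel-2 stride-2 max pool; identity on length-1 inputs."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, length = x.shape
        if length < 2:
            self._cache = None
            return x
        out_len = length // 2
        trimmed = x[:, :, :2 * out_len].reshape(n, c, out_len, 2)
        arg = trimmed.argmax(axis=3)
        self._cache = (arg, length, out_len)
        return trimmed.max(axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._cache is None:
            return grad
        arg, length, out_len = self._cache
        n, c, _ = grad.shape
        dx = np.zeros((n, c, out_len, 2))
        np.put_along_axis(dx, arg[..., None], grad[..., None], axis=3)
        dx = dx.reshape(n, c, 2 * out_len)
        if 2 * out_len < length:
            dx = np.pad(dx, ((0, 0), (0, 0), (0, length - 2 * out_len)))
        return dx


class AvgPool1d(Layer):
    """Kernel-2 stride-2 average pool; identity on length-1 inputs."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, length = x.shape
        if length < 2:
            self._length = None
            return x
        out_len = length // 2
        self._length = (length, out_len)
        return x[:, :, :2 * out_len].reshape(n, c, out_len, 2).mean(axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._length is None:
            return grad
        length, out_len = self._length
        dx = np.repeat(grad, 2, axis=2) / 2.0
        if 2 * out_len < length:
            dx = np.pad(dx, ((0, 0), (0, 0), (0, length - 2 * out_len)))
        return dx


class GlobalAvgPool1d(Layer):
    """Collapse the temporal axis to its mean: (N, C, L) -> (N, C)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._length = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.repeat(grad[:, :, None], self._length, axis=2) / self._length


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / n_in)
        self.w = Parameter(rng.normal(0.0, scale, size=(n_out, n_in)))
        self.b = Parameter(np.zeros(n_out))

    def parameters(self) -> list[Parameter]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.w.grad += grad.T @ self._x
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value


class ResidualBlock(Layer):
    """Two-convolution residual stage with a strided projection shortcut.

    Main path: conv(k, s=1) + BN + ReLU + conv(k, s=2) + BN.  Shortcut:
    kernel-1 stride-2 projection conv + BN.  Output: ReLU(main + shortcut).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int = 3,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.conv1 = Conv1d(c_in, c_out, kernel, stride=1, rng=rng)
        self.bn1 = BatchNorm1d(c_out)
        self.relu1 = ReLU()
        self.conv2 = Conv1d(c_out, c_out, kernel, stride=2, rng=rng)
        self.bn2 = BatchNorm1d(c_out)
        self.proj = Conv1d(c_in, c_out, 1, stride=2, rng=rng)
        self.proj_bn = BatchNorm1d(c_out)
        self.relu_out = ReLU()

    def children(self) -> list[Layer]:
        return [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2,
                self.proj, self.proj_bn, self.relu_out]

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.bn2.forward(self.conv2.forward(
            self.relu1.forward(self.bn1.forward(self.conv1.forward(x)))))
        s = self.proj_bn.forward(self.proj.forward(x))
        return self.relu_out.forward(h + s)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.relu_out.backward(grad)
        g_main = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(g)))))
        g_short = self.proj.backward(self.proj_bn.backward(g))
        return g_main + g_short


class Adam:
    """Adam optimiser over a flat parameter list."""

    def __init__(self, params: list[Parameter], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.beta1 * m + (1 - self.beta1) * p.grad
            v[...] = self.beta2 * v + (1 - self.beta2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray,
                          class_weights: np.ndarray | None = None
                          ) -> tuple[float, np.ndarray]:
    """Weighted categorical cross-entropy over integer labels.

    Per-sample losses are weighted by the weight of the sample's true class
    and normalised by the summed weights, so unit weights reduce exactly to
    the plain mean cross-entropy. Returns ``(loss, dloss/dlogits)``.
    """
    n, k = logits.shape
    p = softmax(logits)
    if class_weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(class_weights, dtype=np.float64)[y]
    total_w = w.sum()
    nll = -np.log(np.clip(p[np.arange(n), y], 1e-12, None))
    loss = float((w * nll).sum() / total_w)
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits *= (w / total_w)[:, None]
    return loss, dlogits


def sigmoid_cross_entropy(logits: np.ndarray, y: np.ndarray,
                          class_weights: np.ndarray | None = None
                          ) -> tuple[float, np.ndarray]:
    """Per-unit binary cross-entropy against one-hot targets.

    Used for the two-unit sigmoid head; the class decision is the argmax of
    the unit activations. Sample weights come from the true class, as in the
    softmax variant.
    """
    n, k = logits.shape
    t = np.zeros((n, k))
    t[np.arange(n), y] = 1.0
    p = sigmoid(logits)
    if class_weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(class_weights, dtype=np.float64)[y]
    total = w.sum() * k
    bce = -(t * np.log(np.clip(p, 1e-12, None))
            + (1 - t) * np.log(np.clip(1 - p, 1e-12, None)))
    loss = float((w[:, None] * bce).sum() / total)
    dlogits = (p - t) * (w[:, None] / total)
    return loss, dlogits
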