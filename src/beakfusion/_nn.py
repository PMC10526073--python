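"""Minimal NumPy neural-network core for the residual backbones.

Layers implement ``forward`` and ``backward`` explicitly (im2col
convolutions, batch normalization with running statistics, ReLU, max/global
average pooling, linear) together with a momentum-SGD optimizer and softmax
cross-entropy.  Tensors are NCHW ``float64`` unless noted.  The scope is
deliberately small: exactly what the residual classification backbones in
:mod:`beakfusion.deep_backbone` need, on CPU, deterministically.
"""

from __future__ import annotations

import numpy as np


class Parameter:
    __slots__ = ("value", "grad", "momentum")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)
        self.momentum = np.zeros_like(value)


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, int, int]:
    """(N, C, H, W) -> (N*Ho*Wo, C*k*k) patch matrix."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, k, k)
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(
    cols: np.ndarray, x_shape: tuple, k: int, stride: int, pad: int, ho: int, wo: int
) -> np.ndarray:
    """Scatter-add the inverse of :func:`_im2col`."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    out = np.zeros((n, c, hp, wp))
    cols = cols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            out[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += cols[
                :, :, :, :, i, j
            ]
    return out[:, :, pad : hp - pad if pad else hp, pad : wp - pad if pad else wp]


class Conv2d(Layer):
    """k x k convolution, He-initialized, no bias (batch norm follows)."""

    def __init__(self, cin: int, cout: int, k: int, stride: int, pad: int, rng: np.random.Generator):
        fan_in = cin * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, fan_in))
        self.weight = Parameter(w)
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        self._cache = None

    def parameters(self):
        return [self.weight]

    def forward(self, x, train):
        cols, ho, wo = _im2col(x, self.k, self.stride, self.pad)
        out = cols @ self.weight.value.T
        n = x.shape[0]
        if train:
            self._cache = (cols, x.shape, ho, wo)
        return out.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2)

    def backward(self, grad):
        cols, x_shape, ho, wo = self._cache
        n = x_shape[0]
        g = grad.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.cout)
        self.weight.grad += g.T @ cols
        dcols = g @ self.weight.value
        return _col2im(dcols, x_shape, self.k, self.stride, self.pad, ho, wo)


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, grad):
        xhat, inv = self._cache
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.value[None, :, None, None]
        gsum = g.sum(axis=(0, 2, 3), keepdims=True)
        gxsum = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return inv[None, :, None, None] * (g - gsum / m - xhat * gxsum / m)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, train):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad):
        return grad * self._mask


class MaxPool2d(Layer):
    def __init__(self, k: int, stride: int, pad: int = 0):
        self.k, self.stride, self.pad = k, stride, pad
        self._cache = None

    def forward(self, x, train):
        n, c, h, w = x.shape
        # zero padding is safe here: pooling always follows a ReLU
        x4 = x.reshape(n * c, 1, h, w)
        cols, ho, wo = _im2col(x4, self.k, self.stride, self.pad)
        arg = cols.argmax(axis=1)
        out = cols[np.arange(cols.shape[0]), arg].reshape(n, c, ho, wo)
        if train:
            self._cache = (arg, (n * c, 1, h, w), ho, wo, cols.shape)
        return out

    def backward(self, grad):
        arg, x_shape, ho, wo, cols_shape = self._cache
        n_c = x_shape[0]
        dcols = np.zeros(cols_shape)
        flat = grad.reshape(-1)
        dcols[np.arange(cols_shape[0]), arg] = flat
        dx = _col2im(dcols, x_shape, self.k, self.stride, self.pad, ho, wo)
        return dx.reshape(grad.shape[0], -1, x_shape[2], x_shape[3])


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C)."""

    def __init__(self):
        self._hw = None

    def forward(self, x, train):
        self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        h, w = self._hw
        return np.broadcast_to(grad[:, :, None, None], grad.shape + (h, w)).copy() / (h * w)


class Linear(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        self.weight = Parameter(rng.normal(0.0, np.sqrt(2.0 / nin), size=(nout, nin)))
        self.bias = Parameter(np.zeros(nout))
        self._x = None

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, grad):
        self.weight.grad += grad.T @ self._x
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def parameters(self):
        return [p for l in self.layers for p in l.parameters()]

    def forward(self, x, train):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


class ResidualBlock(Layer):
    """Pre-built residual unit: main branch + (optional projection) shortcut,
    summed, then ReLU."""

    def __init__(self, main: Sequential, shortcut: Sequential | None):
        self.main = main
        self.shortcut = shortcut
        self.relu = ReLU()

    def parameters(self):
        params = self.main.parameters()
        if self.shortcut is not None:
            params += self.shortcut.parameters()
        return params

    def forward(self, x, train):
        out = self.main.forward(x, train)
        sc = x if self.shortcut is None else self.shortcut.forward(x, train)
        return self.relu.forward(out + sc, train)

    def backward(self, grad):
        grad = self.relu.backward(grad)
        dx_main = self.main.backward(grad)
        dx_sc = grad if self.shortcut is None else self.shortcut.backward(grad)
        return dx_main + dx_sc


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.log(np.clip(probs[np.arange(n), y], 1e-300, None)).mean()
    grad = probs.copy()
    grad[np.arange(n), y] -= 1.0
    return float(loss), grad / n


class SGD:
    """Stochastic gradient descent with momentum (default 0.9)."""

    def __init__(self, params: list[Parameter], lr: float, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        for p in self.params:
            p.momentum[...] = self.momentum * p.momentum - self.lr * p.grad
            p.value += p.momentum


def get_state(layer: Layer) -> list[np.ndarray]:
    """Snapshot of all trainable parameters and batch-norm statistics."""
    state = [p.value.copy() for p in layer.parameters()]
    state += [s.copy() for s in _bn_stats(layer)]
    return state


def set_state(layer: Layer, state: list[np.ndarray]) -> None:
    params = layer.parameters()
    for p, v in zip(params, state[: len(params)]):
        p.value[...] = v
    for s, v in zip(_bn_stats(layer), state[len(params) :]):
        s[...] = v


def _bn_stats(layer: Layer) -> list[np.ndarray]:
    stats: list[np.ndarray] = []
    if isinstance(layer, BatchNorm2d):
        stats += [layer.running_mean, layer.running_var]
    for child in ("layers",):
        for sub in getattr(layer, child, []):
            stats += _bn_stats(sub)
    if isinstance(layer, ResidualBlock):
        stats += _bn_stats(layer.main)
        if layer.shortcut is not None:
            stats += _bn_stats(layer.shortcut)
    return stats
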