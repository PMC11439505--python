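"""A small, deterministic NumPy neural-network engine.

Implements exactly the pieces the adherence classifiers need -- 1-D
convolution, max pooling, dense layers, ReLU, softmax cross-entropy and
Adam -- with explicit manual backpropagation.  Networks here are tiny
(hundreds of parameters, tens of training samples per participant), so a
dependency-free engine keeps training bit-reproducible under a fixed seed
and single-threaded execution.

Array convention: batches are ``(B, L, C)`` for sequence layers (length L,
channels C) and ``(B, D)`` after flattening.
"""

from __future__ import annotations

import numpy as np

from .errors import ShapeError

__all__ = [
    "Param", "Layer", "Conv1D", "ReLU", "MaxPool1D", "Flatten", "Dense",
    "Sequential", "Adam", "softmax", "softmax_cross_entropy", "convolve1d",
]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


class Layer:
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    def out_shape(self, shape: tuple) -> tuple:
        """Static shape propagation, used to validate an architecture."""
        return shape


class Conv1D(Layer):
    """Valid-mode 1-D convolution over the time axis, stride 1.

    Weights have shape (kernel, in_channels, out_channels).  As is standard
    for learned kernels, the layer computes the sliding dot product without
    flipping the kernel -- equivalent in expressive power to the flipped
    form, since the flip can be absorbed into the learned weights.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, name: str = "conv"):
        self.k = kernel_size
        self.name = name
        scale = np.sqrt(2.0 / (kernel_size * in_channels))
        self.W = Param(scale * rng.standard_normal((kernel_size, in_channels, out_channels)))
        self.b = Param(np.zeros(out_channels))
        self._x: np.ndarray | None = None

    def out_shape(self, shape):
        B, L, C = shape
        if self.k > L:
            raise ShapeError(
                f"layer {self.name}: kernel {self.k} longer than input length {L}")
        return (B, L - self.k + 1, self.W.value.shape[2])

    def forward(self, x):
        B, L, C = x.shape
        if self.k > L:
            raise ShapeError(
                f"layer {self.name}: kernel {self.k} longer than input length {L}")
        Lo = L - self.k + 1
        out = np.broadcast_to(self.b.value, (B, Lo, self.W.value.shape[2])).copy()
        for j in range(self.k):
            out += x[:, j:j + Lo, :] @ self.W.value[j]
        self._x = x
        return out

    def backward(self, grad):
        x = self._x
        B, L, C = x.shape
        Lo = L - self.k + 1
        dx = np.zeros_like(x)
        for j in range(self.k):
            self.W.grad[j] += np.einsum("blc,blf->cf", x[:, j:j + Lo, :], grad)
            dx[:, j:j + Lo, :] += grad @ self.W.value[j].T
        self.b.grad += grad.sum(axis=(0, 1))
        return dx

    def params(self):
        return [self.W, self.b]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling along the time axis (floor division)."""

    def __init__(self, pool_size: int, name: str = "pool"):
        self.p = pool_size
        self.name = name

    def out_shape(self, shape):
        B, L, C = shape
        if L // self.p < 1:
            raise ShapeError(
                f"layer {self.name}: input length {L} shorter than pool {self.p}")
        return (B, L // self.p, C)

    def forward(self, x):
        B, L, C = x.shape
        Lo = L // self.p
        if Lo < 1:
            raise ShapeError(
                f"layer {self.name}: input length {L} shorter than pool {self.p}")
        blocks = x[:, :Lo * self.p, :].reshape(B, Lo, self.p, C)
        self._argmax = blocks.argmax(axis=2)
        self._in_shape = x.shape
        return blocks.max(axis=2)

    def backward(self, grad):
        B, L, C = self._in_shape
        Lo = L // self.p
        dblocks = np.zeros((B, Lo, self.p, C))
        b, l, c = np.ogrid[:B, :Lo, :C]
        dblocks[b, l, self._argmax, c] = grad
        dx = np.zeros((B, L, C))
        dx[:, :Lo * self.p, :] = dblocks.reshape(B, Lo * self.p, C)
        return dx


class Flatten(Layer):
    def out_shape(self, shape):
        B = shape[0]
        return (B, int(np.prod(shape[1:])))

    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 name: str = "dense"):
        self.name = name
        scale = np.sqrt(2.0 / in_dim)
        self.W = Param(scale * rng.standard_normal((in_dim, out_dim)))
        self.b = Param(np.zeros(out_dim))

    def out_shape(self, shape):
        B, D = shape
        if D != self.W.value.shape[0]:
            raise ShapeError(
                f"layer {self.name}: expects input dim {self.W.value.shape[0]}, got {D}")
        return (B, self.W.value.shape[1])

    def forward(self, x):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T

    def params(self):
        return [self.W, self.b]


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def out_shape(self, shape):
        for layer in self.layers:
            shape = layer.out_shape(shape)
        return shape

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


class Adam:
    """Adam with bias correction; state is per-parameter and deterministic."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray,
                          sample_weight: np.ndarray | None = None
                          ) -> tuple[float, np.ndarray]:
    """Weighted-mean cross-entropy and its gradient w.r.t. the logits."""
    B = len(y)
    p = softmax(logits)
    if sample_weight is None:
        sample_weight = np.ones(B)
    wsum = sample_weight.sum()
    loss = float(-(sample_weight * np.log(p[np.arange(B), y] + 1e-12)).sum() / wsum)
    grad = p.copy()
    grad[np.arange(B), y] -= 1.0
    grad *= (sample_weight / wsum)[:, None]
    return loss, grad


def convolve1d(f: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Valid-mode 1-D convolution of a series ``f`` with a kernel ``g``.

    The kernel slides from the start of the series to its end; output
    element ``i`` is the sum over ``j`` of ``g(j) * f(i - j + m//2)`` in
    1-based centered indexing (the kernel-flipped sliding dot product),
    giving ``n - m + 1`` outputs.
    """
    f = np.asarray(f, dtype=float)
    g = np.asarray(g, dtype=float)
    if f.ndim != 1 or g.ndim != 1:
        raise ValueError("convolve1d operates on 1-D arrays")
    if len(g) > len(f):
        raise ValueError(f"kernel of length {len(g)} longer than input {len(f)}")
    windows = np.lib.stride_tricks.sliding_window_view(f, len(g))
    return windows @ g[::-1]
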