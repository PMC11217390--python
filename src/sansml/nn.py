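"""Minimal CNN stack on numpy.

Just enough machinery to train the compact reference classifier on a CPU:
3x3 same-padding convolutions, batch normalisation, ReLU, 2x2 max pooling,
pooled/flattened heads, numerically stable softmax cross-entropy and Adam.
Everything is float32 and deterministic given the seed passed to the
initialiser.

Tensors are channels-last, (N, H, W, C). Convolutions run as one im2col GEMM
on BLAS; the memory-bound pieces around the GEMMs (column packing, pooling,
normalisation statistics) are compiled numba loops (see ``_fast``), and the
large per-layer temporaries are cached between batches, which together make
single-core training of the compact net practical.
"""

from __future__ import annotations

import numpy as np

from . import _fast
from .exceptions import ValidationError

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2",
    "Flatten",
    "GlobalAvgPool",
    "Dense",
    "Sequential",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
    "build_compact_cnn",
]


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Batch-mean cross-entropy -log softmax(logits)[label] and its gradient."""
    n = logits.shape[0]
    z = logits - logits.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1))
    loss = float(np.mean(lse - z[np.arange(n), labels]))
    grad = softmax(logits)
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(logits.dtype)


class Layer:
    params: list = []
    grads: list = []
    stats: list = []        # persistent non-trainable state (e.g. BN running stats)
    training: bool = True

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError

    def _buf(self, name: str, shape, zero: bool = False) -> np.ndarray:
        """Named scratch buffer, reused across batches of equal size.

        Re-touching freshly mmapped pages every batch costs more than the
        arithmetic at these sizes, so each layer keeps its large temporaries
        alive between calls. A buffer is evicted (not kept alongside) when the
        requested shape changes, so alternating batch sizes cannot pile up
        multi-GB duplicate sets.
        """
        cache = getattr(self, "_buffers", None)
        if cache is None:
            cache = self._buffers = {}
        arr = cache.get(name)
        if arr is None or arr.shape != tuple(shape):
            cache[name] = None      # drop before allocating the replacement
            arr = cache[name] = np.zeros(shape, dtype=np.float32)
        elif zero:
            arr.fill(0.0)
        return arr

    def release(self) -> None:
        """Free cached buffers and saved activations (parameters are kept)."""
        self._buffers = {}
        for attr in ("_cols", "_mask", "_idx", "_x"):
            if hasattr(self, attr):
                setattr(self, attr, None)


class Conv2d(Layer):
    """3x3 convolution, stride 1, same (zero) padding, He initialisation.

    im2col layout (N, H, W, 9, C): each of the nine kernel offsets is filled
    from a contiguous shifted slice of the padded input, and the whole layer
    is then a single (N*H*W, 9C) @ (9C, C_out) GEMM. The column tensor is
    kept for the backward pass, which is two GEMMs plus the transposed
    scatter of the same nine slices.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, bias: bool = True):
        std = np.sqrt(2.0 / (c_in * 9))
        self.W = rng.normal(0.0, std, size=(9 * c_in, c_out)).astype(np.float32)
        # a conv feeding a batch norm gets no bias: the normalisation would
        # subtract it exactly and its gradient would be identically zero
        self.b = np.zeros(c_out, dtype=np.float32) if bias else None
        self.params = [self.W] + ([self.b] if bias else [])
        self.grads = [np.zeros_like(p) for p in self.params]
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x):
        n, H, W, c = x.shape
        xpad = self._buf("xpad", (n, H + 2, W + 2, c))  # border stays zero
        xpad[:, 1:-1, 1:-1, :] = x
        cols = self._buf("cols", (n, H, W, 9, c))
        _fast.im2col(xpad, cols)
        self._cols, self._shape = cols, (n, H, W, c)
        y = self._buf("y", (n * H * W, self.c_out))
        np.matmul(cols.reshape(-1, 9 * c), self.W, out=y)
        if self.b is not None:
            y += self.b
        return y.reshape(n, H, W, self.c_out)

    def backward(self, dy):
        n, H, W, c = self._shape
        dyf = dy.reshape(-1, self.c_out)
        cols2d = self._cols.reshape(-1, 9 * c)
        self.grads[0][...] = cols2d.T @ dyf
        if self.b is not None:
            self.grads[1][...] = dyf.sum(axis=0)
        # dW is done with the columns, so reuse their storage for dcols
        np.matmul(dyf, self.W.T, out=cols2d)
        dcols = cols2d.reshape(n, H, W, 9, c)
        dxpad = self._buf("dxpad", (n, H + 2, W + 2, c), zero=True)
        _fast.col2im_add(dcols, dxpad)
        self._cols = None
        return dxpad[:, 1:-1, 1:-1, :]


class BatchNorm2d(Layer):
    """Per-channel batch normalisation over (N, H, W).

    Standard affine form with running statistics for inference; momentum 0.1.
    This is what lets the compact net train from scratch at a useful learning
    rate instead of crawling for tens of epochs.
    """

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.stats = [self.running_mean, self.running_var]
        self.eps, self.momentum = eps, momentum

    def forward(self, x):
        n = x.shape[0] * x.shape[1] * x.shape[2]
        c = x.shape[3]
        x2 = x.reshape(n, c)
        xhat = self._buf("xhat", x.shape)
        if self.training:
            mu = np.empty(c, dtype=np.float32)
            var = np.empty(c, dtype=np.float32)
            _fast.bn_stats(x2, mu, var)   # single compiled pass, f64 accumulators
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu = self.running_mean.astype(np.float32)
            var = self.running_var.astype(np.float32)
        inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        self._inv = inv
        y = self._buf("y", x.shape)
        _fast.bn_fwd_apply(x2, mu, inv, self.gamma, self.beta,
                           xhat.reshape(n, c), y.reshape(n, c))
        return y

    def backward(self, dy):
        xhat = self._buffers["xhat"]
        n = dy.shape[0] * dy.shape[1] * dy.shape[2]
        c = dy.shape[3]
        dy2 = dy.reshape(n, c)
        _fast.bn_grads(dy2, xhat.reshape(n, c), self.grads[0], self.grads[1])
        coef = (self.gamma * self._inv).astype(np.float32)
        dx = self._buf("dx", dy.shape)
        _fast.bn_bwd_apply(dy2, xhat.reshape(n, c), coef,
                           (self.grads[0] / n).astype(np.float32),
                           (self.grads[1] / n).astype(np.float32),
                           dx.reshape(n, c))
        return dx


class ReLU(Layer):
    """In-place rectifier: the surrounding layers hand over scratch tensors,
    never caller-owned data, so mutating them is safe and saves two large
    temporaries per block."""

    def forward(self, x):
        self._mask = x > 0
        np.multiply(x, self._mask, out=x)
        return x

    def backward(self, dy):
        np.multiply(dy, self._mask, out=dy)
        return dy


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/columns are cropped."""

    def forward(self, x):
        self._in_shape = x.shape
        out, self._idx = _fast.maxpool2_fwd(x)
        return out

    def backward(self, dy):
        dx = self._buf("dx", self._in_shape)
        return _fast.maxpool2_bwd(np.ascontiguousarray(dy), self._idx, dx)


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(len(x), -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class GlobalAvgPool(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy):
        n, H, W, c = self._shape
        return np.broadcast_to(dy[:, None, None, :], self._shape) / np.float32(H * W)


class Dense(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / c_in)
        self.W = rng.normal(0.0, std, size=(c_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.W.T


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy

    def release(self):
        for l in self.layers:
            l.release()

    def train(self, mode: bool = True):
        for l in self.layers:
            l.training = mode
        return self

    @property
    def _arrays(self):
        return [a for l in self.layers for a in (*l.params, *l.stats)]

    def state_dict(self):
        return {f"p{i}": p for i, p in enumerate(self._arrays)}

    def load_state_dict(self, state):
        for i, p in enumerate(self._arrays):
            p[...] = state[f"p{i}"]


class Adam:
    """Adaptive moment estimation with the usual bias correction."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        if lr <= 0:
            raise ValidationError("learning rate must be positive")
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.betas
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


def build_compact_cnn(
    n_classes: int, seed: int = 0, input_hw: tuple[int, int] = (180, 180)
) -> Sequential:
    """The compact reference classifier: 4 conv blocks (16/32/64/128 channels,
    3x3 kernels, batch norm, ReLU, stride-2 max pooling) and a linear C-way
    head on the flattened 11x11x128 feature map.

    The head is deliberately position-aware rather than globally pooled: the
    radius at which a ring or a form-factor minimum sits on the detector is
    the discriminating feature of a scattering pattern, and global average
    pooling erases exactly that information at this network scale (it cost
    ~0.12 held-out accuracy on the 6-model benchmark).
    """
    rng = np.random.default_rng(seed)
    chans = [1, 16, 32, 64, 128]
    layers: list[Layer] = []
    h, w = input_hw
    for c_in, c_out in zip(chans[:-1], chans[1:]):
        layers += [Conv2d(c_in, c_out, rng, bias=False), BatchNorm2d(c_out), ReLU(), MaxPool2()]
        h, w = h // 2, w // 2
    layers += [Flatten(), Dense(h * w * chans[-1], n_classes, rng)]
    return Sequential(layers)
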