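"""Minimal numpy engine for small convolutional encoder-decoder networks.

Implements exactly the pieces the three-channel U-Net needs — padded 2D
convolutions, stride-1/2 transposed convolutions (as the adjoint of a strided
convolution, matching the framework-standard definition), 2x2 max pooling,
leaky ReLU, inverted dropout and the Adam optimizer — with hand-written
backward passes. Everything is single-precision numpy (a small network does
not need float64 and float32 roughly halves CPU time), fully deterministic
given a seed, and sized for CPU training on small images.

Array convention: (N, C, H, W).
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32

# ---------------------------------------------------------------------------
# convolution primitives (shift-and-multiply; kernels are small)
# ---------------------------------------------------------------------------

def conv_fwd(x: np.ndarray, W: np.ndarray, stride: int, pad: int) -> np.ndarray:
    """Correlate x (N,Cin,H,W) with W (Cout,Cin,k,k)."""
    n, c, h, w = x.shape
    co, ci, k, _ = W.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    y = np.zeros((n, co, oh, ow), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            xs = xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
            y += np.einsum("nchw,oc->nohw", xs, W[:, :, i, j], optimize=True)
    return y


def conv_dw(x: np.ndarray, dy: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """Weight gradient of conv_fwd. x is the layer input, dy the output grad."""
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh, ow = dy.shape[2], dy.shape[3]
    co, ci = dy.shape[1], x.shape[1]
    dW = np.zeros((co, ci, k, k), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            xs = xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
            dW[:, :, i, j] = np.einsum("nchw,nohw->oc", xs, dy, optimize=True)
    return dW


def conv_dx(
    dy: np.ndarray, W: np.ndarray, x_spatial: tuple[int, int], stride: int, pad: int
) -> np.ndarray:
    """Input gradient of conv_fwd (also the forward map of a transposed conv)."""
    n, co, oh, ow = dy.shape
    _, ci, k, _ = W.shape
    h, w = x_spatial
    dxp = np.zeros((n, ci, h + 2 * pad, w + 2 * pad), dtype=dy.dtype)
    for i in range(k):
        for j in range(k):
            contrib = np.einsum("nohw,oc->nchw", dy, W[:, :, i, j], optimize=True)
            dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += contrib
    return dxp[:, :, pad : pad + h, pad : pad + w]


def glorot_uniform(rng: np.random.Generator, shape: tuple, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, shape).astype(DTYPE)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv2d(Layer):
    """Padded ("same") 2D convolution, stride 1."""

    def __init__(self, cin: int, cout: int, k: int = 3, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.k, self.pad = k, (k - 1) // 2
        self.W = glorot_uniform(rng, (cout, cin, k, k), cin * k * k, cout * k * k)
        self.b = np.zeros(cout, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=DTYPE)
        self._x = x
        return conv_fwd(x, self.W, 1, self.pad) + self.b[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW += conv_dw(self._x, dy, self.k, 1, self.pad)
        self.db += dy.sum(axis=(0, 2, 3))
        return conv_dx(dy, self.W, self._x.shape[2:], 1, self.pad)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size


class ConvTranspose2d(Layer):
    """Transposed convolution: the adjoint of a stride-s padded convolution.

    With kernel 3, padding 1 and output_padding s-1 the spatial size is
    multiplied exactly by the stride, so stride 2 doubles H and W and stride 1
    preserves them.
    """

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride, self.pad = k, stride, (k - 1) // 2
        # weight of the underlying conv mapping cout-channel images to cin
        self.W = glorot_uniform(rng, (cin, cout, k, k), cin * k * k, cout * k * k)
        self.b = np.zeros(cout, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=DTYPE)
        self._x = x
        h, w = x.shape[2] * self.stride, x.shape[3] * self.stride
        y = conv_dx(x, self.W, (h, w), self.stride, self.pad)
        return y + self.b[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.db += dy.sum(axis=(0, 2, 3))
        self.dW += conv_dw(dy, self._x, self.k, self.stride, self.pad)
        return conv_fwd(dy, self.W, self.stride, self.pad)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.1):
        if not 0 < slope < 1:
            raise ValueError("leaky slope must be in (0, 1)")
        self.slope = slope

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.slope * dy)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (spatial sizes must be even)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(3, 5))
        # break ties toward the first max so the gradient is not double-counted
        windows = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        first = np.argmax(windows, axis=-1)
        m = np.zeros(windows.shape, dtype=bool)
        np.put_along_axis(m, first[..., None], True, axis=-1)
        self._mask = m.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._shape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        out = self._mask * dy[:, :, :, None, :, None]
        return out.reshape(n, c, h, w)


class Dropout(Layer):
    """Inverted dropout; active only in training mode."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = ((self.rng.random(x.shape) < keep) / keep).astype(x.dtype)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 4e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
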