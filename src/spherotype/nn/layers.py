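"""Minimal 3D CNN building blocks on numpy (CPU, single precision).

Convolutions are evaluated in the frequency domain (scipy.fft): with a 5^3
kernel on 20x50x50 volumes the FFT route is severalfold faster on one CPU
core than im2col + GEMM, and both forward and backward passes reduce to
pointwise products of cached spectra.  All layers implement ``forward`` and
``backward`` and expose ``params()`` as (name, value, gradient) triples for
the optimizer.  Everything is deterministic given the initializing rng.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as sfft


class Layer:
    train_mode: bool = True

    def params(self):
        return []

    def forward(self, x, train: bool = True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv3D(Layer):
    """Same-padding 3D convolution (cross-correlation), stride 1.

    Weights: (c_out, c_in, k, k, k), He-initialized.  The forward pass
    computes y = x * w + b with zero padding k//2; gradients are exact.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 first_layer: bool = False):
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        self.first_layer = first_layer  # data layer: input gradient not needed
        scale = np.sqrt(2.0 / (c_in * kernel**3))
        self.w = (rng.standard_normal((c_out, c_in, kernel, kernel, kernel)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._fft_shape: tuple[int, ...] | None = None
        self._spatial: tuple[int, ...] | None = None
        self._xf = None

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]

    def _shapes(self, spatial):
        if self._spatial != spatial:
            self._spatial = tuple(spatial)
            self._fft_shape = tuple(
                sfft.next_fast_len(d + self.k - 1, real=True) for d in spatial
            )
        return self._fft_shape

    # spectral batches above this many complex elements are processed
    # sample-by-sample: the pointwise product + inverse FFT then stay
    # cache-resident instead of streaming a >100 MB array three times
    _CHUNK_LIMIT = 4_000_000

    def _chunk(self, n_spec: int, n: int) -> int:
        return 1 if n_spec * n > self._CHUNK_LIMIT else n

    def forward(self, x, train: bool = True):
        x = np.ascontiguousarray(x, dtype=np.float32)
        n = x.shape[0]
        spatial = x.shape[2:]
        S = self._shapes(spatial)
        p = self.k // 2
        off = self.k - 1 - p
        sl = (slice(None), slice(None),
              slice(off, off + spatial[0]),
              slice(off, off + spatial[1]),
              slice(off, off + spatial[2]))
        xf = sfft.rfftn(x, s=S, axes=(2, 3, 4))
        wf = sfft.rfftn(self.w[:, :, ::-1, ::-1, ::-1], s=S, axes=(2, 3, 4))
        n_spec = self.c_out * int(np.prod(xf.shape[2:]))
        step = self._chunk(n_spec, n)
        y = np.empty((n, self.c_out) + tuple(spatial), dtype=np.float32)
        for i in range(0, n, step):
            yf = np.einsum("ncdhw,fcdhw->nfdhw", xf[i:i + step], wf, optimize=True)
            y[i:i + step] = sfft.irfftn(yf, s=S, axes=(2, 3, 4))[sl]
        y += self.b[None, :, None, None, None]
        if train:
            self._xf = xf
        return y

    def backward(self, dy):
        dy = np.ascontiguousarray(dy, dtype=np.float32)
        n = dy.shape[0]
        spatial = self._spatial
        S = self._fft_shape
        p = self.k // 2
        n_spec = max(self.c_out, self.c_in) * (S[0] * S[1] * (S[2] // 2 + 1))
        step = self._chunk(n_spec, n)

        # weight gradient: circular correlation of input with dy, gathered at
        # lags tau - p (negative lags wrap to the end of the FFT frame)
        dwf = None
        dyf_parts = []
        for i in range(0, n, step):
            dyf = sfft.rfftn(dy[i:i + step], s=S, axes=(2, 3, 4))
            dyf_parts.append(dyf)
            part = np.einsum(
                "ncdhw,nfdhw->fcdhw", np.conj(self._xf[i:i + step]), dyf, optimize=True
            )
            dwf = part if dwf is None else dwf + part
        corr = sfft.irfftn(dwf, s=S, axes=(2, 3, 4))
        idx = [np.array([(p - t) % S[ax] for t in range(self.k)]) for ax in range(3)]
        self.dw = np.ascontiguousarray(
            corr[:, :, idx[0]][:, :, :, idx[1]][:, :, :, :, idx[2]], dtype=np.float32
        )
        self.db = dy.sum(axis=(0, 2, 3, 4), dtype=np.float64).astype(np.float32)
        self._xf = None
        if self.first_layer:
            return None

        # input gradient: full convolution of dy with the (unflipped) kernel
        wf = sfft.rfftn(self.w, s=S, axes=(2, 3, 4))
        sl = (slice(None), slice(None),
              slice(p, p + spatial[0]),
              slice(p, p + spatial[1]),
              slice(p, p + spatial[2]))
        dx = np.empty((n, self.c_in) + tuple(spatial), dtype=np.float32)
        for j, i in enumerate(range(0, n, step)):
            dxf = np.einsum("nfdhw,fcdhw->ncdhw", dyf_parts[j], wf, optimize=True)
            dx[i:i + step] = sfft.irfftn(dxf, s=S, axes=(2, 3, 4))[sl]
        return dx


class BatchNorm3D(Layer):
    """Per-feature-channel batch normalization over (N, D, H, W)."""

    def __init__(self, n_channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n_channels, dtype=np.float32)
        self.beta = np.zeros(n_channels, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n_channels, dtype=np.float32)
        self.running_var = np.ones(n_channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [("gamma", self.gamma, self.dgamma), ("beta", self.beta, self.dbeta)]

    def forward(self, x, train: bool = True):
        axes = (0, 2, 3, 4)
        if train:
            # single-pass moments; float64 accumulation only in the reduction
            mean = x.mean(axis=axes, dtype=np.float64)
            sq = np.einsum("ncdhw,ncdhw->c", x, x, optimize=True)
            m = x.shape[0] * x.shape[2] * x.shape[3] * x.shape[4]
            var = sq / m - mean**2
            var = np.clip(var, 0, None)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(np.float32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        ivar = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = x - mean.astype(np.float32)[None, :, None, None, None]
        xhat *= ivar[None, :, None, None, None]
        if train:
            self._cache = (xhat, ivar)
        y = xhat * self.gamma[None, :, None, None, None]
        y += self.beta[None, :, None, None, None]
        return y

    def backward(self, dy):
        xhat, ivar = self._cache
        self._cache = None
        axes = (0, 2, 3, 4)
        m = dy.shape[0] * dy.shape[2] * dy.shape[3] * dy.shape[4]
        self.dbeta = dy.sum(axis=axes, dtype=np.float64).astype(np.float32)
        self.dgamma = np.einsum("ncdhw,ncdhw->c", dy, xhat, optimize=True).astype(np.float32)
        g = (self.gamma * ivar / m)[None, :, None, None, None]
        dy *= m  # dy is always an upstream temporary
        dy -= self.dbeta[None, :, None, None, None]
        dy -= xhat * self.dgamma[None, :, None, None, None]
        dy *= g
        return dy


class ReLU(Layer):
    """Rectifier; clips in place (the upstream activation is not reused)."""

    def __init__(self):
        self._mask = None

    def forward(self, x, train: bool = True):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0, out=x)

    def backward(self, dy):
        dy *= self._mask  # dy is always an upstream temporary
        self._mask = None
        return dy


class MaxPool3D(Layer):
    """Non-overlapping (2,2,2) max pooling; odd trailing planes are dropped.

    Backward distributes the gradient to every voxel attaining the block
    maximum (ties share), which keeps the pass deterministic.
    """

    def __init__(self, pool: tuple[int, int, int] = (2, 2, 2)):
        self.pool = pool
        self._cache = None

    def forward(self, x, train: bool = True):
        pz, py, px = self.pool
        n, c, d, h, w = x.shape
        dd, hh, ww = d // pz, h // py, w // px
        crop = x[:, :, : dd * pz, : hh * py, : ww * px]
        # strided pairwise maxima (last axis first) beat a blockwise
        # reduction over tiny axes on large activations
        y = crop
        for ax, p in ((4, px), (3, py), (2, pz)):
            if p > 1:
                sl = [slice(None)] * 5
                parts = []
                for off in range(p):
                    sl[ax] = slice(off, None, p)
                    parts.append(y[tuple(sl)])
                y = np.maximum.reduce(parts)
        if train:
            self._cache = (x.shape, crop, y)
        return y

    def backward(self, dy):
        pz, py, px = self.pool
        in_shape, crop, y = self._cache
        self._cache = None
        n, c, d, h, w = in_shape
        dd, hh, ww = d // pz, h // py, w // px
        blocks = crop.reshape(n, c, dd, pz, hh, py, ww, px)
        y_b = y[:, :, :, None, :, None, :, None]
        mask = blocks == y_b
        dgrid = mask * dy[:, :, :, None, :, None, :, None]
        dx = np.zeros(in_shape, dtype=np.float32)
        dx[:, :, : dd * pz, : hh * py, : ww * px] = dgrid.reshape(
            n, c, dd * pz, hh * py, ww * px
        )
        return dx


class Flatten(Layer):
    def __init__(self):
        self._shape = None

    def forward(self, x, train: bool = True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]

    def forward(self, x, train: bool = True):
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.dw = (self._x.T @ dy).astype(np.float32)
        self.db = dy.sum(axis=0, dtype=np.float64).astype(np.float32)
        dx = dy @ self.w.T
        self._x = None
        return dx


class ReLUDense(ReLU):
    """ReLU for 2D (dense) activations; identical math, separate name only
    for readable layer listings."""


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, y_idx: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean cross-entropy loss, gradient wrt logits, and probabilities."""
    probs = softmax(logits.astype(np.float64))
    n = len(y_idx)
    p_true = np.clip(probs[np.arange(n), y_idx], 1e-12, None)
    loss = float(-np.log(p_true).mean())
    grad = probs.copy()
    grad[np.arange(n), y_idx] -= 1.0
    grad /= n
    return loss, grad.astype(np.float32), probs


class Adam:
    """Adam optimizer over all layer parameters (in-place updates)."""

    def __init__(self, layers, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = layers
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {}
        self.v = {}
        for li, layer in enumerate(layers):
            for name, value, _ in layer.params():
                self.m[(li, name)] = np.zeros_like(value)
                self.v[(li, name)] = np.zeros_like(value)

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for li, layer in enumerate(self.layers):
            for name, value, grad in layer.params():
                m = self.m[(li, name)]
                v = self.v[(li, name)]
                m *= b1
                m += (1 - b1) * grad
                v *= b2
                v += (1 - b2) * grad**2
                value -= lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
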