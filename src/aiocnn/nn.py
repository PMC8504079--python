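"""Minimal NumPy neural-network engine used by the AIO classifiers.

Implements exactly the pieces the two-branch architecture needs: 2D/1D
convolutions with 'same' padding (computed as a sum of shifted-slice
matrix products, so all heavy lifting is BLAS), max pooling, dense layers,
ReLU, an intensity-embedding branch, L2 weight decay and the Adam
optimizer.  Everything runs in float32; all randomness flows through an
explicit ``numpy.random.Generator`` so a (spec, seed) pair fixes the
initial parameters bit-for-bit.

The embedding branch maps each discrete pixel intensity (vocabulary
0-255) to a learned dense vector and average-pools over pixel positions.
Average pooling makes the branch output a linear function of the image's
normalized intensity histogram, so it is computed directly as
``histogram @ embedding_matrix``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv2D", "Conv1D", "MaxPool2D", "MaxPool1D",
    "ReLU", "Flatten", "Dense", "HistogramEmbedding",
    "Adam", "intensity_histogram",
    "sigmoid", "softmax", "binary_loss_and_grad", "categorical_loss_and_grad",
]


def _he_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Layer:
    """Base layer: parameter dict ``p``, gradient dict ``g``."""

    def __init__(self) -> None:
        self.p: dict[str, np.ndarray] = {}
        self.g: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def reg_loss(self) -> float:
        return 0.0


class Conv2D(Layer):
    """k x k convolution, stride 1, 'same' zero padding, NHWC layout."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 l2: float, rng: np.random.Generator) -> None:
        super().__init__()
        self.k = kernel
        self.l2 = l2
        fan_in = kernel * kernel * c_in
        self.p["W"] = _he_uniform(rng, (kernel, kernel, c_in, c_out), fan_in)
        self.p["b"] = np.zeros(c_out, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        N, H, W, C = x.shape
        k, pad = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        c_out = self.p["W"].shape[-1]
        # im2col: one large matmul beats k*k small ones for small C
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(N * H * W, k * k * C)
        y = cols @ self.p["W"].reshape(k * k * C, c_out)
        self._cols = cols if train else None
        self._shape = (N, H, W, C)
        return y.reshape(N, H, W, c_out) + self.p["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, H, W, C = self._shape
        k, pad = self.k, self.k // 2
        c_out = dy.shape[-1]
        dyf = dy.reshape(-1, c_out)
        self.g["W"] = (self._cols.T @ dyf).reshape(self.p["W"].shape) \
            + 2.0 * self.l2 * self.p["W"]
        self.g["b"] = dyf.sum(axis=0)
        dcols = (dyf @ self.p["W"].reshape(-1, c_out).T) \
            .reshape(N, H, W, k, k, C)
        dxp = np.zeros((N, H + 2 * pad, W + 2 * pad, C), dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                dxp[:, di:di + H, dj:dj + W, :] += dcols[:, :, :, di, dj, :]
        self._cols = None
        return dxp[:, pad:pad + H, pad:pad + W, :]

    def reg_loss(self) -> float:
        return float(self.l2 * np.sum(self.p["W"].astype(np.float64) ** 2))


class Conv1D(Layer):
    """Length-k convolution, stride 1, 'same' zero padding, NLC layout."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 l2: float, rng: np.random.Generator) -> None:
        super().__init__()
        self.k = kernel
        self.l2 = l2
        self.p["W"] = _he_uniform(rng, (kernel, c_in, c_out), kernel * c_in)
        self.p["b"] = np.zeros(c_out, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        N, L, C = x.shape
        k, pad = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        c_out = self.p["W"].shape[-1]
        win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
        cols = win.transpose(0, 1, 3, 2).reshape(N * L, k * C)
        y = cols @ self.p["W"].reshape(k * C, c_out)
        self._cols = cols if train else None
        self._shape = (N, L, C)
        return y.reshape(N, L, c_out) + self.p["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, L, C = self._shape
        k, pad = self.k, self.k // 2
        c_out = dy.shape[-1]
        dyf = dy.reshape(-1, c_out)
        self.g["W"] = (self._cols.T @ dyf).reshape(self.p["W"].shape) \
            + 2.0 * self.l2 * self.p["W"]
        self.g["b"] = dyf.sum(axis=0)
        dcols = (dyf @ self.p["W"].reshape(-1, c_out).T).reshape(N, L, k, C)
        dxp = np.zeros((N, L + 2 * pad, C), dtype=np.float32)
        for d in range(k):
            dxp[:, d:d + L, :] += dcols[:, :, d, :]
        self._cols = None
        return dxp[:, pad:pad + L, :]

    def reg_loss(self) -> float:
        return float(self.l2 * np.sum(self.p["W"].astype(np.float64) ** 2))


class MaxPool2D(Layer):
    def __init__(self, pool: int = 2) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        N, H, W, C = x.shape
        p = self.pool
        xr = x.reshape(N, H // p, p, W // p, p, C)
        xr = xr.transpose(0, 1, 3, 5, 2, 4).reshape(N, H // p, W // p, C, p * p)
        self._arg = np.argmax(xr, axis=-1) if train else None
        self._shape = (N, H, W, C)
        return xr.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, H, W, C = self._shape
        p = self.pool
        out = np.zeros((N, H // p, W // p, C, p * p), dtype=dy.dtype)
        np.put_along_axis(out, self._arg[..., None], dy[..., None], axis=-1)
        out = out.reshape(N, H // p, W // p, C, p, p)
        # invert the forward transpose: back to (N, H//p, p, W//p, p, C)
        return out.transpose(0, 1, 4, 2, 5, 3).reshape(N, H, W, C)


class MaxPool1D(Layer):
    def __init__(self, pool: int = 2) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        N, L, C = x.shape
        p = self.pool
        xr = x.reshape(N, L // p, p, C).transpose(0, 1, 3, 2)
        self._arg = np.argmax(xr, axis=-1) if train else None
        self._shape = (N, L, C)
        return xr.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, L, C = self._shape
        p = self.pool
        out = np.zeros((N, L // p, C, p), dtype=dy.dtype)
        np.put_along_axis(out, self._arg[..., None], dy[..., None], axis=-1)
        return out.transpose(0, 1, 3, 2).reshape(N, L, C)


class AvgPool2D(Layer):
    """Non-overlapping mean pooling, (N, H, W, C) -> (N, H/p, W/p, C)."""

    def __init__(self, pool: int = 2) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        N, H, W, C = x.shape
        p = self.pool
        self._shape = x.shape
        return x.reshape(N, H // p, p, W // p, p, C).mean(axis=(2, 4))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, H, W, C = self._shape
        p = self.pool
        dy = dy[:, :, None, :, None, :] / (p * p)
        return np.broadcast_to(
            dy, (N, H // p, p, W // p, p, C)
        ).reshape(N, H, W, C).astype(np.float32)


class AvgPool1D(Layer):
    """Non-overlapping mean pooling, (N, L, C) -> (N, L/p, C)."""

    def __init__(self, pool: int = 2) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        N, L, C = x.shape
        p = self.pool
        self._shape = x.shape
        return x.reshape(N, L // p, p, C).mean(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, L, C = self._shape
        p = self.pool
        dy = dy[:, :, None, :] / p
        return np.broadcast_to(dy, (N, L // p, p, C)).reshape(N, L, C).astype(
            np.float32)


class GlobalAvgPool2D(Layer):
    """Mean over the spatial axes: (N, H, W, C) -> (N, C)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        return np.broadcast_to(dy[:, None, None, :] / (h * w),
                               self._shape).astype(dy.dtype)


class GlobalAvgPool1D(Layer):
    """Mean over the length axis: (N, L, C) -> (N, C)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, length, c = self._shape
        return np.broadcast_to(dy[:, None, :] / length,
                               self._shape).astype(dy.dtype)


class BatchNorm(Layer):
    """Per-channel batch normalization over all leading axes.

    Works for (N, H, W, C), (N, L, C) and (N, C) inputs; uses batch
    statistics at train time and exponential running averages at
    inference.
    """

    def __init__(self, channels: int, momentum: float = 0.9,
                 eps: float = 1e-5) -> None:
        super().__init__()
        self.p["gamma"] = np.ones(channels, dtype=np.float32)
        self.p["beta"] = np.zeros(channels, dtype=np.float32)
        self.run_mean = np.zeros(channels, dtype=np.float32)
        self.run_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = (self.momentum * self.run_mean
                             + (1 - self.momentum) * mean).astype(np.float32)
            self.run_var = (self.momentum * self.run_var
                            + (1 - self.momentum) * var).astype(np.float32)
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * inv
            self._cache = (xhat, inv.astype(np.float32), axes,
                           int(np.prod([x.shape[a] for a in axes])))
            return (self.p["gamma"] * xhat + self.p["beta"]).astype(np.float32)
        inv = 1.0 / np.sqrt(self.run_var + self.eps)
        return (self.p["gamma"] * (x - self.run_mean) * inv
                + self.p["beta"]).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, axes, m = self._cache
        self.g["gamma"] = (dy * xhat).sum(axis=axes)
        self.g["beta"] = dy.sum(axis=axes)
        dxhat = dy * self.p["gamma"]
        dx = (inv / m) * (m * dxhat
                          - dxhat.sum(axis=axes)
                          - xhat * (dxhat * xhat).sum(axis=axes))
        self._cache = None
        return dx.astype(np.float32)


class Dropout(Layer):
    """Inverted dropout with a layer-owned deterministic generator."""

    def __init__(self, rate: float, seed: int) -> None:
        super().__init__()
        self.rate = rate
        self.rng = np.random.default_rng(seed)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate <= 0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return (x * self._mask).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return (dy * self._mask).astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, l2: float,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.l2 = l2
        self.p["W"] = _he_uniform(rng, (n_in, n_out), n_in)
        self.p["b"] = np.zeros(n_out, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x if train else None
        return x @ self.p["W"] + self.p["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.g["W"] = self._x.T @ dy + 2.0 * self.l2 * self.p["W"]
        self.g["b"] = dy.sum(axis=0)
        self._x = None
        return dy @ self.p["W"].T

    def reg_loss(self) -> float:
        return float(self.l2 * np.sum(self.p["W"].astype(np.float64) ** 2))


class HistogramEmbedding(Layer):
    """Intensity-embedding branch: mean-pooled embedding of pixel values.

    Input is the per-sample normalized intensity histogram (N, vocab);
    output is (N, dim) — exactly the average of the embedded intensities.
    """

    def __init__(self, dim: int, rng: np.random.Generator,
                 vocab: int = 256) -> None:
        super().__init__()
        self.vocab = vocab
        self.p["E"] = (rng.standard_normal((vocab, dim)) * 0.05).astype(np.float32)

    def forward(self, hist: np.ndarray, train: bool = False) -> np.ndarray:
        self._h = hist if train else None
        return hist @ self.p["E"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.g["E"] = self._h.T @ dy
        self._h = None
        return dy @ self.p["E"].T


def intensity_histogram(intensities: np.ndarray, vocab: int = 256) -> np.ndarray:
    """Per-sample normalized counts of integer intensities, (N, vocab)."""
    ints = np.asarray(intensities)
    flat = ints.reshape(ints.shape[0], -1)
    n_pix = flat.shape[1]
    out = np.empty((flat.shape[0], vocab), dtype=np.float32)
    for i in range(flat.shape[0]):
        out[i] = np.bincount(flat[i].astype(np.int64), minlength=vocab)[:vocab]
    return out / np.float32(n_pix)


class Adam:
    """Adam optimizer over the parameter dicts of a list of layers."""

    def __init__(self, layers, learning_rate: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 epsilon: float = 1e-7) -> None:
        self.layers = [ly for ly in layers if ly.p]
        self.lr = learning_rate
        self.b1, self.b2, self.eps = beta1, beta2, epsilon
        self.t = 0
        self.m = {(i, k): np.zeros_like(v)
                  for i, ly in enumerate(self.layers) for k, v in ly.p.items()}
        self.v = {(i, k): np.zeros_like(v)
                  for i, ly in enumerate(self.layers) for k, v in ly.p.items()}

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, ly in enumerate(self.layers):
            for k, w in ly.p.items():
                g = ly.g[k]
                m = self.m[(i, k)]
                v = self.v[(i, k)]
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                w -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# output heads / losses
# ---------------------------------------------------------------------------

def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    z = z.astype(np.float64)
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def binary_loss_and_grad(logits: np.ndarray, y: np.ndarray):
    """Mean binary cross-entropy from logits; returns (loss, dlogits, p)."""
    z = logits.reshape(-1)
    p = sigmoid(z)
    # log(1+e^-|z|) formulation is stable for both signs
    loss = float(np.mean(np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0) - z * y))
    dz = ((p - y) / z.size).astype(np.float32).reshape(-1, 1)
    return loss, dz, p


def categorical_loss_and_grad(logits: np.ndarray, y: np.ndarray):
    """Mean softmax cross-entropy from logits; returns (loss, dlogits, p)."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.mean(np.log(np.clip(p[np.arange(n), y], 1e-12, None))))
    dz = p.copy()
    dz[np.arange(n), y] -= 1.0
    return loss, (dz / n).astype(np.float32), p
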