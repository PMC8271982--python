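"""Minimal CNN building blocks in numpy (float32, channels-last).

Tensors are (batch, height, width, channels).  Convolutions are fixed at
3×3 kernel, stride 1, padding 1 — the only geometry the architecture
uses — and are evaluated as nine per-offset GEMMs on contiguous slices
of the padded input, which keeps both passes on BLAS without expensive
strided gathers.  The backward data pass is the transposed convolution
accumulated into the padded gradient buffer.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv3x3",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2x2",
    "GlobalAvgPool",
    "Dense",
    "softmax",
    "softmax_cross_entropy",
]

_OFFSETS = [(di, dj) for di in range(3) for dj in range(3)]


class Conv3x3:
    """3×3 convolution, stride 1, pad 1; He-uniform init, no bias (BN follows)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in * 9
        limit = np.sqrt(6.0 / fan_in)
        # weight[t] is the (C_in, C_out) matrix of kernel tap t (row-major 3×3)
        self.weight = rng.uniform(-limit, limit, size=(9, c_in, c_out)).astype(
            np.float32
        )
        self.grad_weight = np.zeros_like(self.weight)
        self._cols: list[np.ndarray] | None = None
        self._in_shape: tuple[int, ...] | None = None

    @property
    def params(self):
        return [(self.weight, self.grad_weight, True)]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        """(B, H, W, C) → contiguous (B·H·W, 9·C) patch matrix."""
        b, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        cols = np.empty((b, h, w, 9, c), dtype=np.float32)
        for t, (di, dj) in enumerate(_OFFSETS):
            cols[:, :, :, t, :] = xp[:, di : di + h, dj : dj + w, :]
        return cols.reshape(b * h * w, 9 * c)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, h, w, c = x.shape
        cols = self._im2col(x)
        out = cols @ self.weight.reshape(9 * c, self.c_out)
        if train:
            self._cols, self._in_shape = cols, x.shape
        return out.reshape(b, h, w, self.c_out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, h, w, k = dout.shape
        c = self.c_in
        dflat = np.ascontiguousarray(dout).reshape(-1, k)
        self.grad_weight = (self._cols.T @ dflat).reshape(9, c, k)
        self._cols = None
        # transposed convolution: scatter per-tap gradients back onto the
        # padded input grid
        dcols = (dflat @ self.weight.reshape(9 * c, k).T).reshape(b, h, w, 9, c)
        dxp = np.zeros((b, h + 2, w + 2, c), dtype=np.float32)
        for t, (di, dj) in enumerate(_OFFSETS):
            dxp[:, di : di + h, dj : dj + w, :] += dcols[:, :, :, t, :]
        return dxp[:, 1 : h + 1, 1 : w + 1, :]


class BatchNorm2d:
    """Per-channel batch normalization with running inference statistics."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.grad_gamma = np.zeros_like(self.gamma)
        self.grad_beta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache: tuple | None = None

    @property
    def params(self):
        return [
            (self.gamma, self.grad_gamma, False),
            (self.beta, self.grad_beta, False),
        ]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
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
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x - mean) * inv_std
        if train:
            self._cache = (xhat, inv_std)
        return self.gamma * xhat + self.beta

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        self._cache = None
        self.grad_gamma = (dout * xhat).sum(axis=(0, 1, 2))
        self.grad_beta = dout.sum(axis=(0, 1, 2))
        dxhat = dout * self.gamma
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 1, 2))
            - xhat * (dxhat * xhat).mean(axis=(0, 1, 2))
        ) * inv_std
        return dx.astype(np.float32)


class ReLU:
    params: list = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2x2:
    """2×2 max pooling, stride 2, floor semantics on odd extents."""

    params: list = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, h, w, c = x.shape
        ho, wo = h // 2, w // 2
        patches = (
            x[:, : 2 * ho, : 2 * wo, :]
            .reshape(b, ho, 2, wo, 2, c)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(b, ho, wo, c, 4)
        )
        idx = patches.argmax(axis=-1)
        out = np.take_along_axis(patches, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._in_shape = idx, x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, h, w, c = self._in_shape
        ho, wo = h // 2, w // 2
        dpatches = np.zeros((b, ho, wo, c, 4), dtype=dout.dtype)
        np.put_along_axis(dpatches, self._idx[..., None], dout[..., None], axis=-1)
        dx = np.zeros((b, h, w, c), dtype=dout.dtype)
        dx[:, : 2 * ho, : 2 * wo, :] = (
            dpatches.reshape(b, ho, wo, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(b, 2 * ho, 2 * wo, c)
        )
        self._idx = None
        return dx


class GlobalAvgPool:
    """Reduce each feature map to its spatial mean: (B, H, W, C) → (B, C)."""

    params: list = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, h, w, c = self._shape
        return np.broadcast_to(
            dout[:, None, None, :] / (h * w), (b, h, w, c)
        ).astype(dout.dtype)


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / n_in)
        self.weight = rng.uniform(-limit, limit, size=(n_out, n_in)).astype(
            np.float32
        )
        self.bias = np.zeros(n_out, dtype=np.float32)
        self.grad_weight = np.zeros_like(self.weight)
        self.grad_bias = np.zeros_like(self.bias)

    @property
    def params(self):
        return [
            (self.weight, self.grad_weight, True),
            (self.bias, self.grad_bias, False),
        ]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.weight.T + self.bias

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grad_weight = dout.T @ self._x
        self.grad_bias = dout.sum(axis=0)
        dx = dout @ self.weight
        self._x = None
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -float(np.log(p[np.arange(n), labels] + 1e-12).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, (dlogits / n).astype(np.float32)
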