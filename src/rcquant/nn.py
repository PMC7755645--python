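"""A small self-contained CNN engine (numpy, CPU).

Implements exactly the layers the premorbid segmentation network needs —
3×3/1×1 convolution (im2col), batch normalization, ReLU, 2×2 max pooling,
×2 bilinear upsampling — with hand-derived backward passes, an Adam
optimizer and a soft-Dice loss.  Tensors are NCHW float32.  Everything is
deterministic given the RNG passed to the initializers; there is no
threading or device state.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


class Layer:
    """Base class: forward/backward plus (param, grad) pair discovery."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def param_pairs(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return []


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N,C,Hp,Wp) already padded → (N*H*W, C*k*k) patch matrix."""
    win = sliding_window_view(x, (k, k), axis=(2, 3))  # (N,C,H,W,k,k)
    win = win.transpose(0, 2, 3, 1, 4, 5)
    n, h, w = win.shape[:3]
    return np.ascontiguousarray(win).reshape(n * h * w, -1)


class Conv2d(Layer):
    """Same-padded 2D correlation, kernel size 1 or 3, stride 1."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        if k not in (1, 3):
            raise ValueError("kernel size must be 1 or 3")
        self.cin, self.cout, self.k = cin, cout, k
        fan_in = cin * k * k
        # He-normal init, suited to the ReLU nonlinearity that follows
        self.w = (rng.standard_normal((cout, cin, k, k)) * np.sqrt(2.0 / fan_in)).astype(F32)
        self.b = np.zeros(cout, dtype=F32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        self._shape = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = _im2col(xp, self.k)
        if train:
            self._cols = cols
        y = cols @ self.w.reshape(self.cout, -1).T
        y += self.b
        return y.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, _, h, w = dy.shape
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, self.cout)
        self.dw[...] = (dyf.T @ self._cols).reshape(self.w.shape)
        self.db[...] = dyf.sum(axis=0)
        # dX = same-padded correlation of dY with the spatially flipped,
        # channel-transposed kernel
        p = self.k // 2
        wr = self.w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(self.cin, -1)
        dyp = np.pad(dy, ((0, 0), (0, 0), (p, p), (p, p))) if p else dy
        dx = _im2col(dyp, self.k) @ wr.T
        self._cols = None
        return dx.reshape(n, h, w, self.cin).transpose(0, 3, 1, 2)

    def param_pairs(self):
        return [(self.w, self.dw), (self.b, self.db)]

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=F32)
        self.beta = np.zeros(c, dtype=F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.run_mean = np.zeros(c, dtype=F32)
        self.run_var = np.ones(c, dtype=F32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean = (self.momentum * self.run_mean + (1 - self.momentum) * mu).astype(F32)
            self.run_var = (self.momentum * self.run_var + (1 - self.momentum) * var).astype(F32)
        else:
            mu, var = self.run_mean, self.run_var
        ivstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[:, None, None]) * ivstd[:, None, None]
        if train:
            self._cache = (xhat, ivstd)
        return (self.gamma[:, None, None] * xhat + self.beta[:, None, None]).astype(F32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, ivstd = self._cache
        self._cache = None
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.dgamma[...] = (dy * xhat).sum(axis=(0, 2, 3))
        self.dbeta[...] = dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma[:, None, None]
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) * ivstd[:, None, None]
        return dx.astype(F32)

    def param_pairs(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    @property
    def n_params(self) -> int:
        return self.gamma.size + self.beta.size


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2(Layer):
    """2×2 max pooling, stride 2 (spatial size must be even)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = np.ascontiguousarray(xr).reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._inshape = idx, x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._inshape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(dx).reshape(n, c, h, w)


def _upsample_matrix(n: int) -> np.ndarray:
    """Row-interpolation matrix for ×2 bilinear upsampling (n → 2n)."""
    src = (np.arange(2 * n) + 0.5) / 2.0 - 0.5
    i0 = np.floor(src).astype(int)
    frac = src - i0
    lo = np.clip(i0, 0, n - 1)
    hi = np.clip(i0 + 1, 0, n - 1)
    m = np.zeros((2 * n, n), dtype=F32)
    np.add.at(m, (np.arange(2 * n), lo), (1 - frac).astype(F32))
    np.add.at(m, (np.arange(2 * n), hi), frac.astype(F32))
    return m


class BilinearUp2(Layer):
    """×2 bilinear upsampling; backward is the exact transpose."""

    _cache: dict[int, np.ndarray] = {}

    @classmethod
    def _matrix(cls, n: int) -> np.ndarray:
        if n not in cls._cache:
            cls._cache[n] = _upsample_matrix(n)
        return cls._cache[n]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        mh = self._matrix(x.shape[2])
        mw = self._matrix(x.shape[3])
        return (mh @ x @ mw.T).astype(F32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        mh = self._matrix(dy.shape[2] // 2)
        mw = self._matrix(dy.shape[3] // 2)
        return (mh.T @ dy @ mw).astype(F32)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def soft_dice_loss(p: np.ndarray, t: np.ndarray, eps: float = 1.0):
    """Per-sample soft Dice loss, averaged over the batch.

    Returns ``(loss, dL/dp)`` for probabilities ``p`` and binary targets
    ``t``, both (N, 1, H, W).  The smoothing term ``eps`` keeps empty
    targets well-defined.
    """
    axes = (1, 2, 3)
    inter = (p * t).sum(axis=axes)
    denom = p.sum(axis=axes) + t.sum(axis=axes)
    dice = (2 * inter + eps) / (denom + eps)
    loss = float(np.mean(1.0 - dice))
    n = p.shape[0]
    grad = (-2 * t / (denom + eps)[:, None, None, None]
            + ((2 * inter + eps) / (denom + eps) ** 2)[:, None, None, None]) / n
    return loss, grad.astype(F32)


class Adam:
    """Adam optimizer over the (param, grad) pairs of a list of layers."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.pairs = [pg for layer in layers for pg in layer.param_pairs()]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for (p, g), m, v in zip(self.pairs, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def get_state(layers: list[Layer]) -> list[np.ndarray]:
    """Snapshot all learnable parameters and BN running stats."""
    state = []
    for layer in layers:
        for p, _ in layer.param_pairs():
            state.append(p.copy())
        if isinstance(layer, BatchNorm2d):
            state.append(layer.run_mean.copy())
            state.append(layer.run_var.copy())
    return state


def set_state(layers: list[Layer], state: list[np.ndarray]) -> None:
    it = iter(state)
    for layer in layers:
        for p, _ in layer.param_pairs():
            p[...] = next(it)
        if isinstance(layer, BatchNorm2d):
            layer.run_mean[...] = next(it)
            layer.run_var[...] = next(it)
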