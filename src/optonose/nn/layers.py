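"""CPU neural-network primitives with explicit forward/backward passes.

Convolutions are lowered to im2col + BLAS matrix products, which keeps a
small dense-block network trainable on a single CPU core at the image sizes
this package uses.  Every layer caches what its backward pass needs; all
tensors are float32 in (N, C, H, W) layout.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


class Conv2d(Layer):
    """Same-padded stride-1 convolution (k x k or 1 x 1)."""

    def __init__(self, cin: int, cout: int, ksize: int, rng: np.random.Generator,
                 name: str = "conv"):
        self.cin, self.cout, self.k = cin, cout, ksize
        self.pad = ksize // 2
        std = np.sqrt(2.0 / (ksize * ksize * cin))
        self.W = Param(f"{name}.W", rng.normal(0.0, std, size=(cout, cin * ksize * ksize)))
        self.b = Param(f"{name}.b", np.zeros(cout))
        self._cache = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if self.k == 1:
            return np.ascontiguousarray(x.transpose(0, 2, 3, 1).reshape(-1, c))
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        # (N, C, H, W, k, k) -> (N*H*W, C*k*k)
        return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, c * self.k * self.k
        )

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        cols = self._im2col(x)
        y = cols @ self.W.value.T + self.b.value
        self._cache = (cols, (n, c, h, w)) if train else None
        return np.ascontiguousarray(y.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2))

    def backward(self, dy):
        cols, (n, c, h, w) = self._cache
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, self.cout)
        self.W.grad += dyf.T @ cols
        self.b.grad += dyf.sum(axis=0)
        dcols = dyf @ self.W.value
        if self.k == 1:
            return np.ascontiguousarray(dcols.reshape(n, h, w, c).transpose(0, 3, 1, 2))
        dcols = dcols.reshape(n, h, w, c, self.k, self.k)
        dxp = np.zeros((n, c, h + 2 * self.pad, w + 2 * self.pad), dtype=np.float32)
        for ki in range(self.k):
            for kj in range(self.k):
                dxp[:, :, ki:ki + h, kj:kj + w] += dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        return dxp[:, :, self.pad:self.pad + h, self.pad:self.pad + w]

    def params(self):
        return [self.W, self.b]


class BatchNorm2d(Layer):
    def __init__(self, c: int, name: str = "bn", momentum: float = 0.1, eps: float = 1e-5):
        self.c, self.momentum, self.eps = c, momentum, eps
        self.gamma = Param(f"{name}.gamma", np.ones(c))
        self.beta = Param(f"{name}.beta", np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self._cache = None
        # freeze_stats: normalize with running statistics while still caching
        # for backward — used for single-image gradient passes (Grad-CAM),
        # where batch statistics over one image would act as instance norm
        self.freeze_stats = False

    def forward(self, x, train=True):
        if train and not self.freeze_stats:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        if train:
            self._cache = (xhat, inv_std, self.freeze_stats)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dy):
        xhat, inv_std, frozen = self._cache
        dgamma = (dy * xhat).sum(axis=(0, 2, 3))
        dbeta = dy.sum(axis=(0, 2, 3))
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        if frozen:  # mean/var are constants, so the chain rule is diagonal
            return dy * (self.gamma.value * inv_std)[None, :, None, None]
        n_eff = dy.shape[0] * dy.shape[2] * dy.shape[3]
        coeff = (self.gamma.value * inv_std / n_eff)[None, :, None, None]
        return coeff * (n_eff * dy - dbeta[None, :, None, None] - xhat * dgamma[None, :, None, None])

    def params(self):
        return [self.gamma, self.beta]


class ReLU(Layer):
    def forward(self, x, train=True):
        mask = x > 0
        if train:
            self._mask = mask
        return x * mask

    def backward(self, dy):
        return dy * self._mask


class AvgPool2(Layer):
    """2 x 2 average pooling (odd trailing rows/columns are dropped)."""

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        h2, w2 = h // 2 * 2, w // 2 * 2
        self._shape = (n, c, h, w)
        xc = x[:, :, :h2, :w2]
        return xc.reshape(n, c, h2 // 2, 2, w2 // 2, 2).mean(axis=(3, 5))

    def backward(self, dy):
        n, c, h, w = self._shape
        dx = np.zeros((n, c, h, w), dtype=np.float32)
        up = np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3) * 0.25
        dx[:, :, :up.shape[2], :up.shape[3]] = up
        return dx


def _adaptive_bins(size: int, g: int) -> list[tuple[int, int]]:
    return [(int(np.floor(i * size / g)), int(np.ceil((i + 1) * size / g))) for i in range(g)]


class SPP(Layer):
    """Spatial pyramid pooling: adaptive average pooling at several grid
    levels, flattened and concatenated into one fixed-length vector."""

    def __init__(self, levels: tuple[int, ...]):
        if not levels:
            raise ValueError("spp_levels must not be empty")
        self.levels = tuple(int(g) for g in levels)

    def out_features(self, c: int) -> int:
        return c * sum(g * g for g in self.levels)

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        self._shape = x.shape
        self._bins = []
        chunks = []
        for g in self.levels:
            rb, cb = _adaptive_bins(h, g), _adaptive_bins(w, g)
            self._bins.append((rb, cb))
            pooled = np.empty((n, c, g, g), dtype=np.float32)
            for i, (r0, r1) in enumerate(rb):
                for j, (c0, c1) in enumerate(cb):
                    pooled[:, :, i, j] = x[:, :, r0:r1, c0:c1].mean(axis=(2, 3))
            chunks.append(pooled.reshape(n, -1))
        return np.concatenate(chunks, axis=1)

    def backward(self, dy):
        n, c, h, w = self._shape
        dx = np.zeros((n, c, h, w), dtype=np.float32)
        offset = 0
        for g, (rb, cb) in zip(self.levels, self._bins):
            seg = dy[:, offset:offset + c * g * g].reshape(n, c, g, g)
            offset += c * g * g
            for i, (r0, r1) in enumerate(rb):
                for j, (c0, c1) in enumerate(cb):
                    area = (r1 - r0) * (c1 - c0)
                    dx[:, :, r0:r1, c0:c1] += seg[:, :, i, j, None, None] / area
        return dx


class Linear(Layer):
    def __init__(self, fin: int, fout: int, rng: np.random.Generator,
                 init_std: float | None = None, name: str = "fc"):
        std = init_std if init_std is not None else np.sqrt(2.0 / fin)
        self.W = Param(f"{name}.W", rng.normal(0.0, std, size=(fout, fin)))
        self.b = Param(f"{name}.b", np.zeros(fout))

    def forward(self, x, train=True):
        if train:
            self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dy):
        self.W.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value

    def params(self):
        return [self.W, self.b]


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over the batch; returns (loss, dlogits, probs)."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = len(labels)
    loss = float(-np.log(probs[np.arange(n), labels] + 1e-12).mean())
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, (dlogits / n).astype(np.float32), probs


class SGD:
    """SGD with momentum and decoupled-from-nothing classic L2 weight decay
    (applied to every parameter, matching the training protocol)."""

    def __init__(self, params: list[Param], momentum: float = 0.9, weight_decay: float = 1e-4):
        self.params = params
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._buf = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self, lr: float) -> None:
        for p, buf in zip(self.params, self._buf):
            g = p.grad + self.weight_decay * p.value
            buf *= self.momentum
            buf += g
            p.value -= lr * buf
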