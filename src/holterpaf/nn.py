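"""Minimal NumPy neural-network layers for the segment encoder.

Implements exactly what the residual spectrogram encoder needs — 2-D
convolution (im2col-free slice gather/scatter), batch normalization, ReLU,
residual blocks with projection shortcuts, global average pooling, linear
layers, a binary-cross-entropy-with-logits loss and Adam — with explicit
forward/backward passes.  All computation is deterministic given the seed;
gradients are verified against central differences in the test suite.
"""

from __future__ import annotations

from itertools import product

import numpy as np

__all__ = [
    "Param", "Conv2d", "BatchNorm2d", "ReLU", "Linear",
    "ResidualBlock", "GlobalAvgPool", "SmallResNet",
    "Adam", "bce_with_logits", "sigmoid",
]


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(
    logits: np.ndarray, y: np.ndarray, sample_weight: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dlogits)."""
    z, t = logits.ravel(), y.ravel().astype(float)
    # log(1+exp(-|z|)) formulation for stability
    losses = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    p = sigmoid(z)
    if sample_weight is None:
        w = np.ones_like(z)
    else:
        w = sample_weight.ravel()
    wsum = w.sum()
    loss = float((losses * w).sum() / wsum)
    dz = ((p - t) * w / wsum).reshape(logits.shape)
    return loss, dz


class Conv2d:
    """2-D convolution, square kernel, symmetric zero padding."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int, stride: int,
                 padding: int, rng: np.random.Generator, dtype=np.float32):
        k = kernel_size
        fan_in = c_in * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k))
        self.W = Param(w.astype(dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))
        self.k, self.stride, self.pad = k, stride, padding
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        k, s, p = self.k, self.stride, self.pad
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        cols = np.empty((n, oh, ow, c, k * k), dtype=x.dtype)
        for idx, (i, j) in enumerate(product(range(k), range(k))):
            cols[..., idx] = xp[:, :, i:i + s * oh:s, j:j + s * ow:s]\
                .transpose(0, 2, 3, 1)
        colmat = cols.reshape(n * oh * ow, c * k * k)
        wmat = self.W.value.reshape(self.W.value.shape[0], -1)
        out = colmat @ wmat.T + self.b.value
        self._cache = (colmat, x.shape, xp.shape, (oh, ow))
        return out.reshape(n, oh, ow, -1).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        colmat, xshape, xpshape, (oh, ow) = self._cache
        k, s, p = self.k, self.stride, self.pad
        n, c, h, w = xshape
        c_out = dout.shape[1]
        dmat = dout.transpose(0, 2, 3, 1).reshape(-1, c_out)
        wmat = self.W.value.reshape(c_out, -1)
        self.W.grad += (dmat.T @ colmat).reshape(self.W.value.shape)
        self.b.grad += dmat.sum(axis=0)
        dcols = (dmat @ wmat).reshape(n, oh, ow, c, k * k)
        dxp = np.zeros(xpshape, dtype=dout.dtype)
        for idx, (i, j) in enumerate(product(range(k), range(k))):
            dxp[:, :, i:i + s * oh:s, j:j + s * ow:s] += \
                dcols[..., idx].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + h, p:p + w]

    def params(self) -> list[Param]:
        return [self.W, self.b]


class BatchNorm2d:
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = Param(np.ones(c, dtype=dtype))
        self.beta = Param(np.zeros(c, dtype=dtype))
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(x.dtype)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape, training)
        return self.gamma.value[None, :, None, None] * xhat \
            + self.beta.value[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, shape, training = self._cache
        n, c, h, w = shape
        m = n * h * w
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.value[None, :, None, None]
        if not training:
            return dxhat * inv[None, :, None, None]
        # full batch-norm backward (mean and variance depend on the batch)
        sum_dxhat = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (inv[None, :, None, None] / m) * (
            m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat
        )
        return dx

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


class ReLU:
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    def params(self) -> list[Param]:
        return []


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in))
        self.W = Param(w.astype(dtype))
        self.b = Param(np.zeros(n_out, dtype=dtype))

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.grad += dout.T @ self._x
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value

    def params(self) -> list[Param]:
        return [self.W, self.b]


class GlobalAvgPool:
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(
            dout[:, :, None, None] / (h * w), self._shape
        ).astype(dout.dtype).copy()

    def params(self) -> list[Param]:
        return []


class ResidualBlock:
    """[conv-bn-relu, conv-bn] + shortcut, then ReLU.

    The shortcut is the identity when shape is preserved, otherwise a 1x1
    strided projection convolution with its own batch norm.
    """

    def __init__(self, c_in: int, c_out: int, kernel_size: int, stride: int,
                 rng: np.random.Generator, dtype=np.float32):
        p = kernel_size // 2
        self.conv1 = Conv2d(c_in, c_out, kernel_size, stride, p, rng, dtype)
        self.bn1 = BatchNorm2d(c_out, dtype=dtype)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, kernel_size, 1, p, rng, dtype)
        self.bn2 = BatchNorm2d(c_out, dtype=dtype)
        self.relu_out = ReLU()
        if stride != 1 or c_in != c_out:
            self.proj: Conv2d | None = Conv2d(c_in, c_out, 1, stride, 0, rng, dtype)
            self.proj_bn: BatchNorm2d | None = BatchNorm2d(c_out, dtype=dtype)
        else:
            self.proj = None
            self.proj_bn = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        out = self.relu1.forward(
            self.bn1.forward(self.conv1.forward(x, training), training), training)
        out = self.bn2.forward(self.conv2.forward(out, training), training)
        if self.proj is not None:
            skip = self.proj_bn.forward(self.proj.forward(x, training), training)
        else:
            skip = x
        return self.relu_out.forward(out + skip, training)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.relu_out.backward(dout)
        dmain = self.conv1.backward(
            self.bn1.backward(self.relu1.backward(
                self.conv2.backward(self.bn2.backward(d)))))
        if self.proj is not None:
            dskip = self.proj.backward(self.proj_bn.backward(d))
        else:
            dskip = d
        return dmain + dskip

    def params(self) -> list[Param]:
        out = (self.conv1.params() + self.bn1.params()
               + self.conv2.params() + self.bn2.params())
        if self.proj is not None:
            out += self.proj.params() + self.proj_bn.params()
        return out


class SmallResNet:
    """Residual CNN over (3, F, T) spectrograms -> latent vector + one logit.

    Architecture: ``n_blocks`` residual blocks (stride 2 between blocks for
    downsampling, stride 1 into the first), global average pooling, a linear
    layer to ``latent_dim`` with ReLU (the exposed latent), and a final
    linear layer to a single logit.
    """

    def __init__(self, in_channels: int = 3, channels: tuple[int, ...] = (16, 32, 64),
                 kernel_size: int = 3, latent_dim: int = 32,
                 seed: int = 0, dtype=np.float32):
        if len(channels) < 1:
            raise ValueError("at least one residual block is required")
        if latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        rng = np.random.default_rng(seed)
        self.dtype = dtype
        self.blocks: list[ResidualBlock] = []
        c_prev = in_channels
        for b, c in enumerate(channels):
            stride = 1 if b == 0 else 2
            self.blocks.append(
                ResidualBlock(c_prev, c, kernel_size, stride, rng, dtype))
            c_prev = c
        self.pool = GlobalAvgPool()
        self.fc_latent = Linear(c_prev, latent_dim, rng, dtype)
        self.relu_latent = ReLU()
        self.fc_out = Linear(latent_dim, 1, rng, dtype)
        self.latent_dim = latent_dim

    def forward(self, x: np.ndarray, training: bool = False
                ) -> tuple[np.ndarray, np.ndarray]:
        """Returns (logits of shape (n,), latents of shape (n, latent_dim))."""
        h = np.ascontiguousarray(x, dtype=self.dtype)
        for blk in self.blocks:
            h = blk.forward(h, training)
        h = self.pool.forward(h, training)
        latent = self.relu_latent.forward(
            self.fc_latent.forward(h, training), training)
        logits = self.fc_out.forward(latent, training)
        return logits.ravel(), latent

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.fc_out.backward(dlogits.reshape(-1, 1).astype(self.dtype))
        d = self.fc_latent.backward(self.relu_latent.backward(d))
        d = self.pool.backward(d)
        for blk in reversed(self.blocks):
            d = blk.backward(d)

    def params(self) -> list[Param]:
        out: list[Param] = []
        for blk in self.blocks:
            out += blk.params()
        out += self.fc_latent.params() + self.fc_out.params()
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    # -- serialization -----------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {}
        for i, p in enumerate(self.params()):
            state[f"param_{i}"] = p.value
        bn_i = 0
        for blk in self.blocks:
            for bn in (blk.bn1, blk.bn2, blk.proj_bn):
                if bn is None:
                    continue
                state[f"bn_{bn_i}_mean"] = bn.running_mean
                state[f"bn_{bn_i}_var"] = bn.running_var
                bn_i += 1
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.value = state[f"param_{i}"].astype(self.dtype)
            p.grad = np.zeros_like(p.value)
        bn_i = 0
        for blk in self.blocks:
            for bn in (blk.bn1, blk.bn2, blk.proj_bn):
                if bn is None:
                    continue
                bn.running_mean = state[f"bn_{bn_i}_mean"].astype(self.dtype)
                bn.running_var = state[f"bn_{bn_i}_var"].astype(self.dtype)
                bn_i += 1


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - b1) * (p.grad - m)
            v += (1 - b2) * (p.grad * p.grad - v)
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
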