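"""Numpy layers with explicit forward/backward passes.

Conventions
-----------
* Sequence tensors are ``(batch, length, channels)``; vector tensors are
  ``(batch, channels)``.
* Each layer caches what its backward pass needs on ``self``; a layer
  instance is therefore used by one forward/backward pair at a time.
* ``Param.decay`` marks weights subject to L2 regularization (kernels yes,
  biases and normalization gains no, matching common deep-learning
  practice for sequence models).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv1D",
    "MaxPool1D",
    "LayerNorm",
    "BatchNorm",
    "ReLU",
    "Dropout",
    "Dense",
    "GRU",
    "Adam",
    "global_norm_clip",
]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("name", "value", "grad", "decay")

    def __init__(self, name: str, value: np.ndarray, decay: bool = False):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)
        self.decay = decay

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
            fan_out: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Conv1D(Layer):
    """Same-padded 1D convolution with stride 1 (odd kernel width)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, *, bias: bool = True,
                 name: str = "conv", rng=None, dtype=np.float32):
        if kernel % 2 != 1:
            raise ValueError("kernel width must be odd for same padding")
        rng = rng or np.random.default_rng(0)
        self.kernel = kernel
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.W = Param(
            f"{name}.W",
            _glorot(rng, (kernel * in_ch, out_ch), kernel * in_ch, out_ch, dtype),
            decay=True,
        )
        self.b = Param(f"{name}.b", np.zeros(out_ch, dtype=dtype)) if bias else None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    @staticmethod
    def _im2col(x: np.ndarray, kernel: int, pad_left: int, pad_right: int):
        B, L, C = x.shape
        xp = np.pad(x, ((0, 0), (pad_left, pad_right), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, kernel, axis=1)
        # win: (B, L_out, C, kernel) -> (B, L_out, kernel*C)
        return win.transpose(0, 1, 3, 2).reshape(B, win.shape[1], kernel * C)

    def forward(self, x, train=False, rng=None):
        p = self.kernel // 2
        cols = self._im2col(x, self.kernel, p, p)
        self._cols = cols
        self._in_shape = x.shape
        out = cols @ self.W.value
        if self.b is not None:
            out = out + self.b.value
        return out

    def backward(self, dout):
        B, L, C = self._in_shape
        k, p = self.kernel, self.kernel // 2
        cols = self._cols
        kc = cols.shape[-1]
        self.W.grad += cols.reshape(-1, kc).T @ dout.reshape(-1, self.out_ch)
        if self.b is not None:
            self.b.grad += dout.sum(axis=(0, 1))
        # dx = same-padded correlation of dout with the flipped kernel
        Wm = self.W.value.reshape(k, self.in_ch, self.out_ch)
        Wflip = Wm[::-1].transpose(0, 2, 1).reshape(k * self.out_ch, self.in_ch)
        dcols = self._im2col(dout, k, k - 1 - p, p)
        dx = dcols @ Wflip
        self._cols = None
        return dx


class MaxPool1D(Layer):
    """Non-overlapping max pooling along the length axis."""

    def __init__(self, width: int = 2):
        self.width = width

    def forward(self, x, train=False, rng=None):
        B, L, C = x.shape
        if L % self.width != 0:
            raise ValueError(f"length {L} not divisible by pool width {self.width}")
        xr = x.reshape(B, L // self.width, self.width, C)
        self._in_shape = x.shape
        if self.width == 2:
            a, b = xr[:, :, 0, :], xr[:, :, 1, :]
            self._take_b = b > a  # ties route the gradient to the first slot
            return np.where(self._take_b, b, a)
        self._arg = xr.argmax(axis=2)
        return np.take_along_axis(xr, self._arg[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dout):
        B, L, C = self._in_shape
        dxr = np.zeros((B, L // self.width, self.width, C), dtype=dout.dtype)
        if self.width == 2:
            np.copyto(dxr[:, :, 0, :], dout, where=~self._take_b)
            np.copyto(dxr[:, :, 1, :], dout, where=self._take_b)
        else:
            np.put_along_axis(
                dxr, self._arg[:, :, None, :], dout[:, :, None, :], axis=2
            )
        return dxr.reshape(B, L, C)


class LayerNorm(Layer):
    """Per-position normalization over channels with learnable gain/shift.

    Unlike batch normalization this is independent of the batch, so 3'
    zero padding cannot leak statistics across examples; a zero input
    vector stays (near) zero as long as the shift stays near zero.
    """

    def __init__(self, ch: int, *, eps: float = 1e-5, name: str = "ln",
                 dtype=np.float32):
        self.eps = eps
        self.gamma = Param(f"{name}.gamma", np.ones(ch, dtype=dtype))
        self.beta = Param(f"{name}.beta", np.zeros(ch, dtype=dtype))

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False, rng=None):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._xhat, self._inv = xhat, inv
        return xhat * self.gamma.value + self.beta.value

    def backward(self, dout):
        xhat, inv = self._xhat, self._inv
        n = xhat.shape[-1]
        axes = tuple(range(dout.ndim - 1))
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self.gamma.value
        dx = (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
        ) * inv
        self._xhat = self._inv = None
        return dx


class BatchNorm(Layer):
    """Batch normalization over the batch axis of ``(batch, channels)`` input."""

    def __init__(self, ch: int, *, eps: float = 1e-5, momentum: float = 0.9,
                 name: str = "bn", dtype=np.float32):
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(f"{name}.gamma", np.ones(ch, dtype=dtype))
        self.beta = Param(f"{name}.beta", np.zeros(ch, dtype=dtype))
        self.running_mean = np.zeros(ch, dtype=np.float64)
        self.running_var = np.ones(ch, dtype=np.float64)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False, rng=None):
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mu = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._xhat, self._inv, self._train = xhat, inv, train
        return xhat * self.gamma.value + self.beta.value

    def backward(self, dout):
        xhat, inv = self._xhat, self._inv
        self.gamma.grad += (dout * xhat).sum(axis=0)
        self.beta.grad += dout.sum(axis=0)
        dxhat = dout * self.gamma.value
        if not self._train:
            return dxhat * inv
        n = xhat.shape[0]
        dx = (
            dxhat
            - dxhat.mean(axis=0)
            - xhat * (dxhat * xhat).mean(axis=0)
        ) * inv
        self._xhat = self._inv = None
        return dx


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0,1)")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        keep = rng.random(x.shape, dtype=np.float32) >= self.rate
        self._mask = keep.astype(x.dtype) / np.asarray(1.0 - self.rate, dtype=x.dtype)
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Dense(Layer):
    def __init__(self, in_ch: int, out_ch: int, *, bias: bool = True,
                 name: str = "dense", rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.W = Param(f"{name}.W", _glorot(rng, (in_ch, out_ch), in_ch, out_ch,
                                            dtype), decay=True)
        self.b = Param(f"{name}.b", np.zeros(out_ch, dtype=dtype)) if bias else None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=False, rng=None):
        self._x = x
        out = x @ self.W.value
        if self.b is not None:
            out = out + self.b.value
        return out

    def backward(self, dout):
        self.W.grad += self._x.T @ dout
        if self.b is not None:
            self.b.grad += dout.sum(axis=0)
        dx = dout @ self.W.value.T
        self._x = None
        return dx


class GRU(Layer):
    """Gated recurrent unit returning the final hidden state.

    Uses the double-bias ("reset after") formulation: separate input and
    recurrent biases, with the reset gate applied after the recurrent
    matrix product:

        z = sigmoid(x Wz + bxz + h Uz + bhz)
        r = sigmoid(x Wr + bxr + h Ur + bhr)
        n = tanh(x Wn + bxn + r * (h Un + bhn))
        h' = z * h + (1 - z) * n

    With ``backwards=True`` the sequence is consumed from its last position
    to its first, so a 3'-padded mRNA is summarized at the information-dense
    5' end.
    """

    def __init__(self, in_ch: int, hidden: int, *, backwards: bool = True,
                 name: str = "gru", rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.hidden = hidden
        self.backwards = backwards
        self.Wx = Param(f"{name}.Wx", _glorot(rng, (in_ch, 3 * hidden), in_ch,
                                              hidden, dtype), decay=True)
        # orthogonal-ish recurrent init: QR of a normal draw
        q, _ = np.linalg.qr(rng.standard_normal((hidden, hidden)))
        Uh = np.concatenate([q] + [
            np.linalg.qr(rng.standard_normal((hidden, hidden)))[0]
            for _ in range(2)
        ], axis=1)
        self.Uh = Param(f"{name}.Uh", Uh.astype(dtype), decay=True)
        self.bx = Param(f"{name}.bx", np.zeros(3 * hidden, dtype=dtype))
        self.bh = Param(f"{name}.bh", np.zeros(3 * hidden, dtype=dtype))

    def params(self):
        return [self.Wx, self.Uh, self.bx, self.bh]

    def forward(self, x, train=False, rng=None):
        B, T, C = x.shape
        H = self.hidden
        order = range(T - 1, -1, -1) if self.backwards else range(T)
        h = np.zeros((B, H), dtype=x.dtype)
        # precompute all input projections at once
        xproj = x.reshape(B * T, C) @ self.Wx.value + self.bx.value
        xproj = xproj.reshape(B, T, 3 * H)
        cache = []
        for t in order:
            hproj = h @ self.Uh.value + self.bh.value
            xz, xr, xn = np.split(xproj[:, t], 3, axis=1)
            hz, hr, hn = np.split(hproj, 3, axis=1)
            z = _sigmoid(xz + hz)
            r = _sigmoid(xr + hr)
            n = np.tanh(xn + r * hn)
            h_new = z * h + (1.0 - z) * n
            cache.append((t, h, z, r, n, hn))
            h = h_new
        self._cache = cache
        self._x = x
        return h

    def backward(self, dh):
        x = self._x
        B, T, C = x.shape
        H = self.hidden
        dx = np.zeros_like(x)
        dxproj = np.zeros((B, T, 3 * H), dtype=x.dtype)
        dh = dh.copy()
        for t, h_prev, z, r, n, hn in reversed(self._cache):
            dz = dh * (h_prev - n)
            dn = dh * (1.0 - z)
            dh_prev = dh * z
            da_n = dn * (1.0 - n * n)          # pre-tanh
            da_z = dz * z * (1.0 - z)          # pre-sigmoid
            da_r = (da_n * hn) * r * (1.0 - r)
            dhn = da_n * r
            dxproj[:, t, :H] = da_z
            dxproj[:, t, H:2 * H] = da_r
            dxproj[:, t, 2 * H:] = da_n
            dhproj = np.concatenate([da_z, da_r, dhn], axis=1)
            self.Uh.grad += h_prev.T @ dhproj
            self.bh.grad += dhproj.sum(axis=0)
            dh = dh_prev + dhproj @ self.Uh.value.T
        flat = dxproj.reshape(B * T, 3 * H)
        self.Wx.grad += x.reshape(B * T, C).T @ flat
        self.bx.grad += flat.sum(axis=0)
        dx = (flat @ self.Wx.value.T).reshape(B, T, C)
        self._cache = None
        self._x = None
        return dx


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

def global_norm_clip(params: list[Param], max_norm: float) -> float:
    """Scale all gradients jointly so their global L2 norm is <= max_norm."""
    total = float(sum(np.sum(p.grad.astype(np.float64) ** 2) for p in params))
    norm = np.sqrt(total)
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for p in params:
            p.grad *= scale
    return norm


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.98, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0
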