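"""NumPy layers with hand-written reverse-mode gradients.

Sequences are (channels, time) float64 arrays processed one record at a
time.  Each layer caches what its backward pass needs during forward; a
forward call invalidates the previous cache.  Gradients accumulate into
``Param.grad`` (+=), so callers zero grads between optimizer steps.
"""

from __future__ import annotations

import numpy as np

from ..errors import ValidationError

_EPS = 1e-12


class Param:
    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class CausalConv1d(Layer):
    """Weight-normalized causal dilated 1-D convolution.

    Padding p = (k-1)*d then right-chomp is folded into index arithmetic:
    y[:, n] = b + sum_i W[:, :, i] @ x[:, n - d*i].  With weight
    normalization W = g * V / ||V|| (norm per output channel); at
    construction g = ||V|| so the initial weight equals the raw draw.
    """

    def __init__(self, c_in: int, c_out: int, k: int, dilation: int,
                 rng: np.random.Generator, name: str = "conv",
                 weight_norm: bool = True, init_sd: float | None = None):
        if k < 1 or dilation < 1:
            raise ValidationError("kernel size and dilation must be >= 1")
        self.c_in, self.c_out, self.k, self.d = c_in, c_out, k, dilation
        self.weight_norm = weight_norm
        if init_sd is None:  # He-scaled for the ReLU stack
            init_sd = np.sqrt(2.0 / (c_in * k))
        v = rng.normal(0.0, init_sd, (c_out, c_in, k))
        self.v = Param(f"{name}.v", v)
        self.b = Param(f"{name}.b", np.zeros(c_out))
        if weight_norm:
            norms = np.sqrt((v ** 2).sum(axis=(1, 2)))
            self.g = Param(f"{name}.g", norms)

    def params(self) -> list[Param]:
        ps = [self.v, self.b]
        if self.weight_norm:
            ps.append(self.g)
        return ps

    def _weight(self):
        if not self.weight_norm:
            return self.v.value, None
        norms = np.sqrt((self.v.value ** 2).sum(axis=(1, 2))) + _EPS
        w = self.g.value[:, None, None] * self.v.value / norms[:, None, None]
        return w, norms

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        w, self._norms = self._weight()
        self._w = w
        n = x.shape[1]
        y = np.repeat(self.b.value[:, None], n, axis=1)
        for i in range(self.k):
            s = i * self.d
            if s < n:
                y[:, s:] += w[:, :, i] @ x[:, : n - s]
        return y

    def backward(self, gout: np.ndarray) -> np.ndarray:
        x, w = self._x, self._w
        n = x.shape[1]
        self.b.grad += gout.sum(axis=1)
        dw = np.zeros_like(w)
        gin = np.zeros_like(x)
        for i in range(self.k):
            s = i * self.d
            if s < n:
                dw[:, :, i] = gout[:, s:] @ x[:, : n - s].T
                gin[:, : n - s] += w[:, :, i].T @ gout[:, s:]
        if self.weight_norm:
            norms = self._norms
            v = self.v.value
            dot = (dw * v).sum(axis=(1, 2))
            self.g.grad += dot / norms
            gv = (self.g.value / norms)[:, None, None] * dw \
                - (self.g.value * dot / norms ** 3)[:, None, None] * v
            self.v.grad += gv
        else:
            self.v.grad += dw
        return gin


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gout):
        return np.where(self._mask, gout, 0.0)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValidationError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, gout):
        if self._mask is None:
            return gout
        return gout * self._mask


class ChannelAttention(Layer):
    """Squeeze-and-excitation style per-channel gating with causal pooling.

    The squeeze is a *running* time average m(n) = mean(z[:, :n+1]), so the
    gate at time n — sigmoid(W2 relu(W1 m(n) + b1) + b2) — depends only on
    activations at times <= n and the layer preserves strict causality.
    Output is z scaled per channel by the gate; bottleneck width is
    max(1, C // reduction).
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator,
                 name: str = "attn", init_sd: float | None = None):
        if reduction < 1:
            raise ValidationError(f"attention_reduction must be >= 1, got {reduction}")
        cb = max(1, channels // reduction)
        sd1 = init_sd if init_sd is not None else np.sqrt(2.0 / channels)
        sd2 = init_sd if init_sd is not None else np.sqrt(2.0 / cb)
        self.w1 = Param(f"{name}.w1", rng.normal(0.0, sd1, (cb, channels)))
        self.b1 = Param(f"{name}.b1", np.zeros(cb))
        self.w2 = Param(f"{name}.w2", rng.normal(0.0, sd2, (channels, cb)))
        self.b2 = Param(f"{name}.b2", np.zeros(channels))

    def params(self):
        return [self.w1, self.b1, self.w2, self.b2]

    def forward(self, z, training=False):
        self._z = z
        n = z.shape[1]
        self._counts = np.arange(1, n + 1, dtype=np.float64)
        self._m = np.cumsum(z, axis=1) / self._counts          # running mean
        self._h_pre = self.w1.value @ self._m + self.b1.value[:, None]
        self._h = np.maximum(self._h_pre, 0.0)
        self._gate = _sigmoid(self.w2.value @ self._h + self.b2.value[:, None])
        return z * self._gate

    def backward(self, gout):
        z, gate = self._z, self._gate
        dgate = gout * z
        gz = gout * gate
        ds = dgate * gate * (1.0 - gate)
        self.w2.grad += ds @ self._h.T
        self.b2.grad += ds.sum(axis=1)
        dh = self.w2.value.T @ ds
        dh_pre = np.where(self._h_pre > 0, dh, 0.0)
        self.w1.grad += dh_pre @ self._m.T
        self.b1.grad += dh_pre.sum(axis=1)
        dm = self.w1.value.T @ dh_pre
        # m(n) = cumsum(z)/ (n+1): dz[t] = sum_{n >= t} dm[n] / (n+1)
        gz += np.cumsum((dm / self._counts)[:, ::-1], axis=1)[:, ::-1]
        return gz


class TemporalAttention(Layer):
    """Causally masked scaled dot-product self-attention over time.

    Q/K/V are 1x1 projections of z; position n attends only to j <= n, so
    the layer preserves the network's causality.  O(N^2) — intended for the
    temporal-variant experiments, not the default channel gating.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 name: str = "attn", init_sd: float | None = None):
        self.c = channels
        sd = init_sd if init_sd is not None else np.sqrt(1.0 / channels)
        self.wq = Param(f"{name}.wq", rng.normal(0.0, sd, (channels, channels)))
        self.wk = Param(f"{name}.wk", rng.normal(0.0, sd, (channels, channels)))
        self.wv = Param(f"{name}.wv", rng.normal(0.0, sd, (channels, channels)))

    def params(self):
        return [self.wq, self.wk, self.wv]

    def forward(self, z, training=False):
        self._z = z
        n = z.shape[1]
        q = self.wq.value @ z
        k = self.wk.value @ z
        v = self.wv.value @ z
        s = (q.T @ k) / np.sqrt(self.c)
        mask = np.triu(np.ones((n, n), dtype=bool), k=1)  # j > i forbidden
        s[mask] = -np.inf
        s -= s.max(axis=1, keepdims=True)
        a = np.exp(s)
        a /= a.sum(axis=1, keepdims=True)
        self._q, self._k, self._v, self._a = q, k, v, a
        return v @ a.T

    def backward(self, gout):
        z, q, k, v, a = self._z, self._q, self._k, self._v, self._a
        dv = gout @ a
        da = gout.T @ v          # (N, N)
        ds = a * (da - (da * a).sum(axis=1, keepdims=True))
        ds /= np.sqrt(self.c)
        dq = k @ ds.T
        dk = q @ ds
        self.wq.grad += dq @ z.T
        self.wk.grad += dk @ z.T
        self.wv.grad += dv @ z.T
        return self.wq.value.T @ dq + self.wk.value.T @ dk + self.wv.value.T @ dv


class ResidualBlock(Layer):
    """One residual level: two weight-normalized causal dilated convolutions
    (each followed by ReLU and Dropout), attention at the end of the first
    branch, a 1x1-convolution skip when channel counts differ, and a final
    ReLU on the sum."""

    def __init__(self, c_in: int, c_out: int, k: int, dilation: int,
                 dropout: float, attention: str, reduction: int,
                 rng: np.random.Generator, name: str = "block",
                 init_sd: float | None = None):
        self.conv1 = CausalConv1d(c_in, c_out, k, dilation, rng,
                                  name=f"{name}.conv1", init_sd=init_sd)
        self.relu1 = ReLU()
        self.drop1 = Dropout(dropout, rng)
        self.conv2 = CausalConv1d(c_out, c_out, k, dilation, rng,
                                  name=f"{name}.conv2", init_sd=init_sd)
        self.relu2 = ReLU()
        self.drop2 = Dropout(dropout, rng)
        if attention == "channel":
            self.attn: Layer | None = ChannelAttention(
                c_out, reduction, rng, name=f"{name}.attn", init_sd=init_sd)
        elif attention == "temporal":
            self.attn = TemporalAttention(c_out, rng, name=f"{name}.attn",
                                          init_sd=init_sd)
        elif attention == "none":
            self.attn = None
        else:
            raise ValidationError(f"unknown attention variant {attention!r}")
        self.down = None
        if c_in != c_out:
            self.down = CausalConv1d(c_in, c_out, 1, 1, rng,
                                     name=f"{name}.down", weight_norm=False,
                                     init_sd=init_sd)
        self.relu_out = ReLU()
        self._branch = [self.conv1, self.relu1, self.drop1,
                        self.conv2, self.relu2, self.drop2]
        if self.attn is not None:
            self._branch.append(self.attn)

    def params(self):
        ps = []
        for layer in self._branch:
            ps.extend(layer.params())
        if self.down is not None:
            ps.extend(self.down.params())
        return ps

    def forward(self, x, training=False):
        h = x
        for layer in self._branch:
            h = layer.forward(h, training=training)
        skip = x if self.down is None else self.down.forward(x, training=training)
        if h.shape != skip.shape:  # pragma: no cover - internal invariant
            raise ValidationError("shape mismatch between branch and skip path")
        return self.relu_out.forward(h + skip, training=training)

    def backward(self, gout):
        gsum = self.relu_out.backward(gout)
        g = gsum
        for layer in reversed(self._branch):
            g = layer.backward(g)
        gskip = gsum if self.down is None else self.down.backward(gsum)
        return g + gskip
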