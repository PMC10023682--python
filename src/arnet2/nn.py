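"""Minimal NumPy neural-network layer library with hand-derived backprop.

Implements exactly the pieces the two-stage tachogram classifier needs:
1-D convolution (im2col), batch normalization, ReLU, max-pooling with
ceil semantics, dropout, dense layers, a GRU cell unrolled over short
sequences, a weighted binary cross-entropy (with-logits) loss and the
Adam optimizer.  Everything is deterministic given the supplied
``numpy.random.Generator``; all gradients are exercised by finite-
difference checks in the test suite.

Array layout is channels-last: (batch, length, channels).
"""
from __future__ import annotations

import math
from typing import List, Optional, Sequence

import numpy as np


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> List[Param]:
        return []

    def children(self) -> List["Layer"]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _he_init(shape, fan_in: int, rng: np.random.Generator, dtype) -> np.ndarray:
    return (rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape)).astype(dtype)


class Conv1D(Layer):
    """Same-padded 1-D convolution, stride 1, via im2col."""

    def __init__(self, in_ch: int, out_ch: int, k: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.k = k
        self.in_ch, self.out_ch = in_ch, out_ch
        self.pad_left = (k - 1) // 2
        self.pad_right = k // 2
        self.W = Param(_he_init((k * in_ch, out_ch), k * in_ch, rng, dtype))
        self.b = Param(np.zeros(out_ch, dtype=dtype))
        self._cols = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training):
        B, L, C = x.shape
        xp = np.pad(x, ((0, 0), (self.pad_left, self.pad_right), (0, 0)))
        cols = np.empty((B, L, self.k, C), dtype=x.dtype)
        for j in range(self.k):
            cols[:, :, j, :] = xp[:, j:j + L, :]
        self._cols = cols
        self._in_shape = (B, L, C)
        out = cols.reshape(B, L, self.k * C) @ self.W.value + self.b.value
        return out

    def backward(self, dout):
        B, L, C = self._in_shape
        cols2 = self._cols.reshape(B * L, self.k * C)
        dout2 = dout.reshape(B * L, self.out_ch)
        self.W.grad += cols2.T @ dout2
        self.b.grad += dout2.sum(axis=0)
        dcols = (dout2 @ self.W.value.T).reshape(B, L, self.k, C)
        dxp = np.zeros((B, L + self.k - 1, C), dtype=dout.dtype)
        for j in range(self.k):
            dxp[:, j:j + L, :] += dcols[:, :, j, :]
        return dxp[:, self.pad_left:self.pad_left + L, :]


class BatchNorm(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = Param(np.ones(ch, dtype=dtype))
        self.beta = Param(np.zeros(ch, dtype=dtype))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(ch, dtype=dtype)
        self.running_var = np.ones(ch, dtype=dtype)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(x.dtype)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * ivar
        if training:
            self._xhat, self._ivar, self._n = xhat, ivar, x.shape[0] * x.shape[1]
        else:
            self._xhat, self._ivar, self._n = xhat, ivar, None
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dout):
        xhat, ivar = self._xhat, self._ivar
        self.gamma.grad += (dout * xhat).sum(axis=(0, 1))
        self.beta.grad += dout.sum(axis=(0, 1))
        dxhat = dout * self.gamma.value
        if self._n is None:  # inference-mode backward (fixed statistics)
            return dxhat * ivar
        n = self._n
        return (ivar / n) * (n * dxhat
                             - dxhat.sum(axis=(0, 1), keepdims=True)
                             - xhat * (dxhat * xhat).sum(axis=(0, 1), keepdims=True))


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool1D(Layer):
    """Pool of width/stride 2 with ceil semantics (59 -> 30 -> 15)."""

    def forward(self, x, training):
        B, L, C = x.shape
        self._L = L
        L2 = (L + 1) // 2
        if L % 2:
            pad = np.full((B, 1, C), -np.inf, dtype=x.dtype)
            x = np.concatenate([x, pad], axis=1)
        xr = x.reshape(B, L2, 2, C)
        self._idx = xr.argmax(axis=2)
        return np.take_along_axis(xr, self._idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dout):
        B, L2, C = dout.shape
        dxp = np.zeros((B, L2, 2, C), dtype=dout.dtype)
        np.put_along_axis(dxp, self._idx[:, :, None, :], dout[:, :, None, :], axis=2)
        return dxp.reshape(B, 2 * L2, C)[:, :self._L, :]

    @staticmethod
    def out_len(L: int) -> int:
        return (L + 1) // 2


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask.astype(x.dtype)

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask.astype(dout.dtype)


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.W = Param(_he_init((d_in, d_out), d_in, rng, dtype))
        self.b = Param(np.zeros(d_out, dtype=dtype))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout):
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def params(self):
        out: List[Param] = []
        for l in self.layers:
            out.extend(l.params())
        return out

    def children(self):
        return list(self.layers)

    def forward(self, x, training):
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


class ResBlock(Layer):
    """Pre-activation residual block: (BN-ReLU-Conv) x 2 + shortcut.

    The shortcut is the identity when channel counts match, otherwise a
    1x1 convolution projection.  When ``downsample`` is set, a width-2
    max-pool (ceil semantics) is applied to the merged output, halving
    the temporal length.
    """

    def __init__(self, in_ch: int, out_ch: int, k: int, downsample: bool,
                 rng: np.random.Generator, dtype=np.float32):
        self.main = Sequential([
            BatchNorm(in_ch, dtype=dtype), ReLU(),
            Conv1D(in_ch, out_ch, k, rng, dtype=dtype),
            BatchNorm(out_ch, dtype=dtype), ReLU(),
            Conv1D(out_ch, out_ch, k, rng, dtype=dtype),
        ])
        self.proj = Conv1D(in_ch, out_ch, 1, rng, dtype=dtype) if in_ch != out_ch else None
        self.pool = MaxPool1D() if downsample else None

    def params(self):
        out = self.main.params()
        if self.proj is not None:
            out.extend(self.proj.params())
        return out

    def children(self):
        out = [self.main]
        if self.proj is not None:
            out.append(self.proj)
        if self.pool is not None:
            out.append(self.pool)
        return out

    def forward(self, x, training):
        h = self.main.forward(x, training)
        s = self.proj.forward(x, training) if self.proj is not None else x
        out = h + s
        if self.pool is not None:
            out = self.pool.forward(out, training)
        return out

    def backward(self, dout):
        if self.pool is not None:
            dout = self.pool.backward(dout)
        dx = self.main.backward(dout)
        if self.proj is not None:
            dx = dx + self.proj.backward(dout)
        else:
            dx = dx + dout
        return dx


class GRU(Layer):
    """Single-layer GRU unrolled over short sequences; returns last state.

    Update equations (channels-last, zero initial state)::

        z_t = sigmoid(x_t Wz + h_{t-1} Uz + bz)
        r_t = sigmoid(x_t Wr + h_{t-1} Ur + br)
        c_t = tanh(x_t Wc + (r_t * h_{t-1}) Uc + bc)
        h_t = (1 - z_t) * c_t + z_t * h_{t-1}
    """

    def __init__(self, d_in: int, units: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.units = units

        def w(shape, fan):
            return Param((rng.normal(0, math.sqrt(1.0 / fan), size=shape)).astype(dtype))

        self.Wz, self.Uz, self.bz = w((d_in, units), d_in), w((units, units), units), Param(np.zeros(units, dtype=dtype))
        self.Wr, self.Ur, self.br = w((d_in, units), d_in), w((units, units), units), Param(np.zeros(units, dtype=dtype))
        self.Wc, self.Uc, self.bc = w((d_in, units), d_in), w((units, units), units), Param(np.zeros(units, dtype=dtype))

    def params(self):
        return [self.Wz, self.Uz, self.bz, self.Wr, self.Ur, self.br,
                self.Wc, self.Uc, self.bc]

    def forward(self, x, training):
        B, T, D = x.shape
        h = np.zeros((B, self.units), dtype=x.dtype)
        self._cache = []
        for t in range(T):
            xt = x[:, t, :]
            z = _sigmoid(xt @ self.Wz.value + h @ self.Uz.value + self.bz.value)
            r = _sigmoid(xt @ self.Wr.value + h @ self.Ur.value + self.br.value)
            c = np.tanh(xt @ self.Wc.value + (r * h) @ self.Uc.value + self.bc.value)
            h_new = (1 - z) * c + z * h
            self._cache.append((xt, h, z, r, c))
            h = h_new
        self._T, self._B, self._D = T, B, D
        return h

    def backward(self, dh):
        T, B, D = self._T, self._B, self._D
        dx = np.zeros((B, T, D), dtype=dh.dtype)
        for t in range(T - 1, -1, -1):
            xt, h_prev, z, r, c = self._cache[t]
            dc = dh * (1 - z)
            dz = dh * (h_prev - c)
            dh_prev = dh * z
            dc_pre = dc * (1 - c * c)
            self.Wc.grad += xt.T @ dc_pre
            self.Uc.grad += (r * h_prev).T @ dc_pre
            self.bc.grad += dc_pre.sum(axis=0)
            drh = dc_pre @ self.Uc.value.T
            dr = drh * h_prev
            dh_prev = dh_prev + drh * r
            dz_pre = dz * z * (1 - z)
            dr_pre = dr * r * (1 - r)
            self.Wz.grad += xt.T @ dz_pre
            self.Uz.grad += h_prev.T @ dz_pre
            self.bz.grad += dz_pre.sum(axis=0)
            self.Wr.grad += xt.T @ dr_pre
            self.Ur.grad += h_prev.T @ dr_pre
            self.br.grad += dr_pre.sum(axis=0)
            dh_prev = dh_prev + dz_pre @ self.Uz.value.T + dr_pre @ self.Ur.value.T
            dx[:, t, :] = dz_pre @ self.Wz.value.T + dr_pre @ self.Wr.value.T + dc_pre @ self.Wc.value.T
            dh = dh_prev
        return dx


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    return _sigmoid(np.asarray(x, dtype=float))


def weighted_bce_with_logits(logits: np.ndarray, y: np.ndarray,
                             pos_weight: float = 1.0) -> tuple:
    """Mean weighted binary cross-entropy on logits; returns (loss, dlogits).

    The positive class is up-weighted by ``pos_weight`` (prevalence
    correction N_neg / N_pos by default upstream).
    """
    z = logits.reshape(-1)
    y = y.reshape(-1).astype(z.dtype)
    softplus = np.logaddexp(0.0, z)      # log(1 + e^z)
    softplus_neg = np.logaddexp(0.0, -z)
    losses = pos_weight * y * softplus_neg + (1 - y) * softplus
    n = len(z)
    loss = float(losses.mean()) if n else 0.0
    s = _sigmoid(z)
    dz = ((1 - y) * s - pos_weight * y * (1 - s)) / max(n, 1)
    return loss, dz.reshape(logits.shape)


class Adam:
    """Adam with optional global-norm gradient clipping.

    Clipping keeps the aggressive default learning rate usable on small
    batches, where an occasional large batch gradient can otherwise throw
    the optimizer into a regime it does not recover from.
    """

    def __init__(self, params: Sequence[Param], lr: float = 1e-2,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 max_grad_norm: Optional[float] = None):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.max_grad_norm = max_grad_norm
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        if self.max_grad_norm is not None:
            norm = math.sqrt(sum(float(np.sum(p.grad.astype(np.float64) ** 2))
                                 for p in self.params))
            if norm > self.max_grad_norm:
                scale = self.max_grad_norm / norm
                for p in self.params:
                    p.grad *= scale
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad ** 2
            p.value -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.value.dtype)


def iter_modules(net: Layer):
    """Depth-first iteration over a layer tree (including ``net`` itself)."""
    yield net
    for c in net.children():
        yield from iter_modules(c)


def batchnorms(net: Layer) -> List["BatchNorm"]:
    return [m for m in iter_modules(net) if isinstance(m, BatchNorm)]


def get_state(net: Layer) -> dict:
    """Snapshot of parameters and batch-norm running statistics."""
    return {
        "params": [p.value.copy() for p in net.params()],
        "bn": [(bn.running_mean.copy(), bn.running_var.copy())
               for bn in batchnorms(net)],
    }


def set_state(net: Layer, state: dict) -> None:
    for p, v in zip(net.params(), state["params"]):
        p.value[...] = v
    for bn, (mean, var) in zip(batchnorms(net), state["bn"]):
        bn.running_mean = mean.copy()
        bn.running_var = var.copy()


def numerical_gradient(f, param: Param, eps: float = 1e-5) -> np.ndarray:
    """Central finite-difference gradient of scalar ``f()`` wrt ``param``."""
    g = np.zeros_like(param.value)
    it = np.nditer(param.value, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = param.value[idx]
        param.value[idx] = orig + eps
        fp = f()
        param.value[idx] = orig - eps
        fm = f()
        param.value[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
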