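"""Minimal numpy neural-network primitives with manual backpropagation.

Provides exactly the layers the pipeline's two small networks need — a
bidirectional LSTM tagger and a convolutional role classifier: embedding
tables, dense layers, an LSTM cell unrolled over a sentence, a width-w
1-D convolution with max-over-time pooling, log-softmax losses and an
Adam optimizer with global-norm gradient clipping.

All layers cache what their backward pass needs; ``zero_grad`` resets the
accumulated parameter gradients.  Everything is float64 and seeded, so a
fixed seed gives bit-identical training runs.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


def uniform_init(rng: np.random.Generator, shape: tuple[int, ...], scale: float) -> np.ndarray:
    return rng.uniform(-scale, scale, size=shape)


class Embedding(Layer):
    """Lookup table with a dedicated unknown row at index 0."""

    def __init__(self, n_rows: int, dim: int, rng: np.random.Generator,
                 scale: float = 0.5, trainable: bool = True):
        self.table = Param(uniform_init(rng, (n_rows, dim), scale))
        self.trainable = trainable
        self._ids: list[np.ndarray] = []

    def params(self) -> list[Param]:
        return [self.table] if self.trainable else []

    def forward(self, ids: Sequence[int]) -> np.ndarray:
        ids = np.asarray(ids, dtype=int)
        self._ids.append(ids)
        return self.table.value[ids]

    def backward(self, d_out: np.ndarray) -> None:
        ids = self._ids.pop()
        if self.trainable:
            np.add.at(self.table.grad, ids, d_out)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = math.sqrt(6.0 / (d_in + d_out))
        self.W = Param(uniform_init(rng, (d_in, d_out), scale))
        self.b = Param(np.zeros(d_out))
        self._x: list[np.ndarray] = []

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x.append(x)
        return x @ self.W.value + self.b.value

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        x = self._x.pop()
        self.W.grad += x.T @ d_out if d_out.ndim == 2 else np.outer(x, d_out)
        self.b.grad += d_out.sum(axis=0) if d_out.ndim == 2 else d_out
        return d_out @ self.W.value.T


class LSTM(Layer):
    """A single-direction LSTM unrolled over one sequence at a time."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.d_in, self.d_h = d_in, d_hidden
        scale = math.sqrt(6.0 / (d_in + d_hidden))
        self.Wx = Param(uniform_init(rng, (d_in, 4 * d_hidden), scale))
        self.Wh = Param(uniform_init(rng, (d_hidden, 4 * d_hidden), scale))
        b = np.zeros(4 * d_hidden)
        b[d_hidden : 2 * d_hidden] = 1.0  # forget-gate bias
        self.b = Param(b)
        self._cache: list[list[tuple]] = []

    def params(self) -> list[Param]:
        return [self.Wx, self.Wh, self.b]

    def forward(self, X: np.ndarray) -> np.ndarray:
        n = X.shape[0]
        H = self.d_h
        h = np.zeros(H)
        c = np.zeros(H)
        out = np.zeros((n, H))
        steps = []
        for t in range(n):
            z = X[t] @ self.Wx.value + h @ self.Wh.value + self.b.value
            i = _sigmoid(z[:H])
            f = _sigmoid(z[H : 2 * H])
            o = _sigmoid(z[2 * H : 3 * H])
            g = np.tanh(z[3 * H :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            steps.append((X[t], h, c, i, f, o, g, tc))
            h, c = h_new, c_new
            out[t] = h
        self._cache.append(steps)
        return out

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        steps = self._cache.pop()
        n = d_out.shape[0]
        H = self.d_h
        dX = np.zeros((n, self.d_in))
        dh_next = np.zeros(H)
        dc_next = np.zeros(H)
        for t in range(n - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, o, g, tc = steps[t]
            dh = d_out[t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate([
                di * i * (1 - i),
                df * f * (1 - f),
                do * o * (1 - o),
                dg * (1 - g * g),
            ])
            self.Wx.grad += np.outer(x_t, dz)
            self.Wh.grad += np.outer(h_prev, dz)
            self.b.grad += dz
            dX[t] = dz @ self.Wx.value.T
            dh_next = dz @ self.Wh.value.T
        return dX


class BiLSTM(Layer):
    """Forward and backward LSTMs; h_i concatenates both directions."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.fwd = LSTM(d_in, d_hidden, rng)
        self.bwd = LSTM(d_in, d_hidden, rng)

    def params(self) -> list[Param]:
        return self.fwd.params() + self.bwd.params()

    def forward(self, X: np.ndarray) -> np.ndarray:
        hf = self.fwd.forward(X)
        hb = self.bwd.forward(X[::-1])[::-1]
        return np.concatenate([hf, hb], axis=1)

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        H = self.fwd.d_h
        dxf = self.fwd.backward(d_out[:, :H])
        dxb = self.bwd.backward(d_out[::-1, H:])[::-1]
        return dxf + dxb


class ConvMaxPool(Layer):
    """Width-w 1-D convolution over a sequence with tanh nonlinearity and
    max-over-time pooling; sequences shorter than the width are zero-padded."""

    def __init__(self, d_in: int, width: int, n_filters: int, rng: np.random.Generator):
        self.width = width
        self.d_in = d_in
        scale = math.sqrt(6.0 / (width * d_in + n_filters))
        self.W = Param(uniform_init(rng, (width * d_in, n_filters), scale))
        self.b = Param(np.zeros(n_filters))
        self._cache: list[tuple] = []

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def _windows(self, X: np.ndarray) -> np.ndarray:
        n = X.shape[0]
        pad = self.width // 2
        Xp = np.zeros((n + 2 * pad, self.d_in))
        Xp[pad : pad + n] = X
        return np.stack(
            [Xp[t : t + self.width].ravel() for t in range(n)], axis=0
        )

    def forward(self, X: np.ndarray) -> np.ndarray:
        if X.shape[0] == 0:
            X = np.zeros((1, self.d_in))
        Wnd = self._windows(X)  # (n, width*d_in)
        pre = Wnd @ self.W.value + self.b.value  # (n, F)
        act = np.tanh(pre)
        amax = act.argmax(axis=0)  # (F,)
        pooled = act[amax, np.arange(act.shape[1])]
        self._cache.append((X.shape[0], Wnd, act, amax))
        return pooled

    def backward(self, d_pooled: np.ndarray) -> np.ndarray:
        n, Wnd, act, amax = self._cache.pop()
        F = d_pooled.shape[0]
        d_pre = np.zeros_like(act)
        vals = act[amax, np.arange(F)]
        d_pre[amax, np.arange(F)] = d_pooled * (1.0 - vals * vals)
        self.W.grad += Wnd.T @ d_pre
        self.b.grad += d_pre.sum(axis=0)
        d_wnd = d_pre @ self.W.value.T  # (n, width*d_in)
        pad = self.width // 2
        dXp = np.zeros((n + 2 * pad, self.d_in))
        for t in range(n):
            dXp[t : t + self.width] += d_wnd[t].reshape(self.width, self.d_in)
        return dXp[pad : pad + n]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def log_softmax(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=-1, keepdims=True)
    s = logits - m
    return s - np.log(np.exp(s).sum(axis=-1, keepdims=True))


def softmax(logits: np.ndarray) -> np.ndarray:
    return np.exp(log_softmax(logits))


def nll_loss_and_grad(log_probs: np.ndarray, targets: Sequence[int]) -> tuple[float, np.ndarray]:
    """Mean negative log-likelihood and its gradient wrt the logits."""
    targets = np.asarray(targets, dtype=int)
    n = log_probs.shape[0]
    loss = -log_probs[np.arange(n), targets].mean()
    d_logits = np.exp(log_probs)
    d_logits[np.arange(n), targets] -= 1.0
    return float(loss), d_logits / n


class Adam:
    """Adam with global-norm gradient clipping."""

    def __init__(self, params: Iterable[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 clip_norm: float = 5.0):
        self.params = list(params)
        self.lr, self.eps, self.clip_norm = lr, eps, clip_norm
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        total = math.sqrt(sum(float((p.grad ** 2).sum()) for p in self.params))
        scale = min(1.0, self.clip_norm / (total + 1e-12))
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad * scale
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
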