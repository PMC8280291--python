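"""Minimal NumPy neural-network core for sequence-to-vector regression.

Implements exactly what the inverse model needs: simple RNN, LSTM and GRU
layers (with full backpropagation through time), a bidirectional wrapper,
inverted dropout, a dense head, mean-squared-error loss and the Adam
optimizer.  Everything is float32 and vectorized over the batch; the only
Python-level loop is over the 251 time steps.

Conventions
-----------
* Sequence tensors are (batch, time, features).
* Input kernels use Glorot-uniform init, recurrent kernels orthogonal init
  (per-gate blocks), biases zero except the LSTM forget gate (init 1.0).
* The GRU is the classic formulation: the reset gate multiplies the hidden
  projection inside the candidate activation, with a single bias per gate.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    fan_in, fan_out = shape
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


def orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    a = rng.standard_normal((n, n))
    q, r = np.linalg.qr(a)
    return (q * np.sign(np.diag(r))).astype(F32)


def orthogonal_blocks(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """(n, k*n) recurrent kernel made of k independent orthogonal blocks."""
    return np.concatenate([orthogonal(rng, n) for _ in range(k)], axis=1)


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(F32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, input_dim: int, output_dim: int, rng: np.random.Generator):
        self.W = Param(glorot_uniform(rng, (input_dim, output_dim)))
        self.b = Param(np.zeros(output_dim, dtype=F32))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy):
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class Dropout(Layer):
    """Inverted dropout; identity when rate is 0 or in inference mode."""

    def __init__(self, rate: float):
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout in training mode needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate).astype(F32) / F32(1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class LSTM(Layer):
    """Single-direction LSTM; gate order i, f, g (candidate), o."""

    def __init__(self, input_dim: int, hidden: int, rng: np.random.Generator,
                 return_sequences: bool):
        self.H = hidden
        self.return_sequences = return_sequences
        self.Wx = Param(glorot_uniform(rng, (input_dim, 4 * hidden)))
        self.Wh = Param(orthogonal_blocks(rng, hidden, 4))
        b = np.zeros(4 * hidden, dtype=F32)
        b[hidden: 2 * hidden] = 1.0  # forget-gate bias
        self.b = Param(b)

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x, training=False, rng=None):
        B, T, D = x.shape
        H = self.H
        xp = (x.reshape(B * T, D) @ self.Wx.value + self.b.value).reshape(B, T, 4 * H)
        I = np.empty((B, T, H), dtype=F32)
        Fg = np.empty_like(I)
        G = np.empty_like(I)
        O = np.empty_like(I)
        C = np.empty_like(I)
        TC = np.empty_like(I)
        Hs = np.empty_like(I)
        h = np.zeros((B, H), dtype=F32)
        c = np.zeros((B, H), dtype=F32)
        Wh = self.Wh.value
        for t in range(T):
            z = xp[:, t] + h @ Wh
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            I[:, t], Fg[:, t], G[:, t], O[:, t] = i, f, g, o
            C[:, t], TC[:, t], Hs[:, t] = c, tc, h
        self._cache = (x, I, Fg, G, O, C, TC, Hs)
        return Hs if self.return_sequences else h

    def backward(self, dy):
        x, I, Fg, G, O, C, TC, Hs = self._cache
        B, T, D = x.shape
        H = self.H
        dZ = np.empty((B, T, 4 * H), dtype=F32)
        dh = np.zeros((B, H), dtype=F32)
        dc = np.zeros((B, H), dtype=F32)
        WhT = self.Wh.value.T
        for t in range(T - 1, -1, -1):
            if self.return_sequences:
                dh = dh + dy[:, t]
            elif t == T - 1:
                dh = dh + dy
            i, f, g, o, tc = I[:, t], Fg[:, t], G[:, t], O[:, t], TC[:, t]
            c_prev = C[:, t - 1] if t > 0 else np.zeros((B, H), dtype=F32)
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dz = dZ[:, t]
            dz[:, :H] = di * i * (1.0 - i)
            dz[:, H:2 * H] = df * f * (1.0 - f)
            dz[:, 2 * H:3 * H] = dg * (1.0 - g * g)
            dz[:, 3 * H:] = do * o * (1.0 - o)
            dh = dz @ WhT
            dc = dc * f
        dZf = dZ.reshape(B * T, 4 * H)
        self.Wx.grad += x.reshape(B * T, D).T @ dZf
        self.b.grad += dZf.sum(axis=0)
        Hprev = np.concatenate(
            [np.zeros((B, 1, H), dtype=F32), Hs[:, :-1]], axis=1
        ).reshape(B * T, H)
        self.Wh.grad += Hprev.T @ dZf
        return (dZf @ self.Wx.value.T).reshape(B, T, D)


class GRU(Layer):
    """Single-direction GRU, classic formulation:

    z = sigmoid(x Wxz + h Whz + bz), r = sigmoid(x Wxr + h Whr + br),
    n = tanh(x Wxn + r * (h Whn) + bn), h' = z * h + (1 - z) * n.
    """

    def __init__(self, input_dim: int, hidden: int, rng: np.random.Generator,
                 return_sequences: bool):
        self.H = hidden
        self.return_sequences = return_sequences
        self.Wx = Param(glorot_uniform(rng, (input_dim, 3 * hidden)))  # z, r, n
        self.Whzr = Param(orthogonal_blocks(rng, hidden, 2))
        self.Whn = Param(orthogonal(rng, hidden))
        self.b = Param(np.zeros(3 * hidden, dtype=F32))

    def params(self):
        return [self.Wx, self.Whzr, self.Whn, self.b]

    def forward(self, x, training=False, rng=None):
        B, T, D = x.shape
        H = self.H
        xp = (x.reshape(B * T, D) @ self.Wx.value + self.b.value).reshape(B, T, 3 * H)
        Z = np.empty((B, T, H), dtype=F32)
        R = np.empty_like(Z)
        N = np.empty_like(Z)
        HN = np.empty_like(Z)   # h_prev @ Whn
        Hs = np.empty_like(Z)
        h = np.zeros((B, H), dtype=F32)
        for t in range(T):
            zr = _sigmoid(xp[:, t, :2 * H] + h @ self.Whzr.value)
            z, r = zr[:, :H], zr[:, H:]
            hn = h @ self.Whn.value
            n = np.tanh(xp[:, t, 2 * H:] + r * hn)
            h = z * h + (1.0 - z) * n
            Z[:, t], R[:, t], N[:, t], HN[:, t], Hs[:, t] = z, r, n, hn, h
        self._cache = (x, Z, R, N, HN, Hs)
        return Hs if self.return_sequences else h

    def backward(self, dy):
        x, Z, R, N, HN, Hs = self._cache
        B, T, D = x.shape
        H = self.H
        dP = np.empty((B, T, 3 * H), dtype=F32)   # preactivation grads z, r, n
        A = np.empty((B, T, H), dtype=F32)        # dpre_n * r (for Whn grad)
        dh = np.zeros((B, H), dtype=F32)
        WhzrT = self.Whzr.value.T
        WhnT = self.Whn.value.T
        for t in range(T - 1, -1, -1):
            if self.return_sequences:
                dh = dh + dy[:, t]
            elif t == T - 1:
                dh = dh + dy
            z, r, n, hn = Z[:, t], R[:, t], N[:, t], HN[:, t]
            h_prev = Hs[:, t - 1] if t > 0 else np.zeros((B, H), dtype=F32)
            dz = dh * (h_prev - n) * z * (1.0 - z)
            dn_pre = dh * (1.0 - z) * (1.0 - n * n)
            dr = dn_pre * hn * r * (1.0 - r)
            a = dn_pre * r
            dP[:, t, :H] = dz
            dP[:, t, H:2 * H] = dr
            dP[:, t, 2 * H:] = dn_pre
            A[:, t] = a
            dh = dh * z + dP[:, t, :2 * H] @ WhzrT + a @ WhnT
        dPf = dP.reshape(B * T, 3 * H)
        self.Wx.grad += x.reshape(B * T, D).T @ dPf
        self.b.grad += dPf.sum(axis=0)
        Hprev = np.concatenate(
            [np.zeros((B, 1, H), dtype=F32), Hs[:, :-1]], axis=1
        ).reshape(B * T, H)
        self.Whzr.grad += Hprev.T @ dPf[:, :2 * H]
        self.Whn.grad += Hprev.T @ A.reshape(B * T, H)
        return (dPf @ self.Wx.value.T).reshape(B, T, D)


class SimpleRNN(Layer):
    """Vanilla tanh recurrent layer."""

    def __init__(self, input_dim: int, hidden: int, rng: np.random.Generator,
                 return_sequences: bool):
        self.H = hidden
        self.return_sequences = return_sequences
        self.Wx = Param(glorot_uniform(rng, (input_dim, hidden)))
        self.Wh = Param(orthogonal(rng, hidden))
        self.b = Param(np.zeros(hidden, dtype=F32))

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x, training=False, rng=None):
        B, T, D = x.shape
        H = self.H
        xp = (x.reshape(B * T, D) @ self.Wx.value + self.b.value).reshape(B, T, H)
        Hs = np.empty((B, T, H), dtype=F32)
        h = np.zeros((B, H), dtype=F32)
        for t in range(T):
            h = np.tanh(xp[:, t] + h @ self.Wh.value)
            Hs[:, t] = h
        self._cache = (x, Hs)
        return Hs if self.return_sequences else h

    def backward(self, dy):
        x, Hs = self._cache
        B, T, D = x.shape
        H = self.H
        dP = np.empty((B, T, H), dtype=F32)
        dh = np.zeros((B, H), dtype=F32)
        WhT = self.Wh.value.T
        for t in range(T - 1, -1, -1):
            if self.return_sequences:
                dh = dh + dy[:, t]
            elif t == T - 1:
                dh = dh + dy
            h = Hs[:, t]
            dpre = dh * (1.0 - h * h)
            dP[:, t] = dpre
            dh = dpre @ WhT
        dPf = dP.reshape(B * T, H)
        self.Wx.grad += x.reshape(B * T, D).T @ dPf
        self.b.grad += dPf.sum(axis=0)
        Hprev = np.concatenate(
            [np.zeros((B, 1, H), dtype=F32), Hs[:, :-1]], axis=1
        ).reshape(B * T, H)
        self.Wh.grad += Hprev.T @ dPf
        return (dPf @ self.Wx.value.T).reshape(B, T, D)


class Bidirectional(Layer):
    """Runs a forward and a time-reversed copy of a recurrent layer and
    concatenates their features (Keras-style 'concat' merge)."""

    def __init__(self, forward_layer: Layer, backward_layer: Layer):
        if forward_layer.return_sequences != backward_layer.return_sequences:
            raise ValueError("both directions must agree on return_sequences")
        self.fwd = forward_layer
        self.bwd = backward_layer
        self.return_sequences = forward_layer.return_sequences

    def params(self):
        return self.fwd.params() + self.bwd.params()

    def forward(self, x, training=False, rng=None):
        yf = self.fwd.forward(x, training, rng)
        yb = self.bwd.forward(x[:, ::-1], training, rng)
        if self.return_sequences:
            return np.concatenate([yf, yb[:, ::-1]], axis=2)
        return np.concatenate([yf, yb], axis=1)

    def backward(self, dy):
        H = self.fwd.H
        if self.return_sequences:
            dyf, dyb = dy[:, :, :H], dy[:, :, H:][:, ::-1]
        else:
            dyf, dyb = dy[:, :H], dy[:, H:]
        dxf = self.fwd.backward(np.ascontiguousarray(dyf))
        dxb = self.bwd.backward(np.ascontiguousarray(dyb))
        return dxf + dxb[:, ::-1]


class Sequential:
    """A plain stack of layers with shared forward/backward plumbing."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, training=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights) -> None:
        params = self.params()
        if len(weights) != len(params):
            raise ValueError("weight count mismatch")
        for p, w in zip(params, weights):
            if p.value.shape != w.shape:
                raise ValueError(f"weight shape mismatch: {p.value.shape} vs {w.shape}")
            p.value[...] = w

    @property
    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())


class Adam:
    """Adam with the usual defaults (lr 1e-3, beta1 0.9, beta2 0.999)."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1.0 - self.b2 ** self.t) / (1.0 - self.b1 ** self.t)
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.value -= (lr_t * m / (np.sqrt(v) + self.eps)).astype(F32)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over all elements, and its gradient w.r.t. pred."""
    diff = (pred - target).astype(F32)
    loss = float(np.mean(diff.astype(np.float64) ** 2))
    grad = (2.0 / diff.size) * diff
    return loss, grad
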