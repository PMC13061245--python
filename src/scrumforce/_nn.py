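"""Self-contained NumPy neural-network backend.

Implements the handful of layer types the scrummaging pipeline needs —
dense, 1-D convolution and transposed convolution, batch normalisation,
dropout, LSTM — together with Adam and the two losses (MSE, binary
cross-entropy). Everything is float32, batch-major, and driven by an
explicit ``numpy.random.Generator`` so that training runs are bitwise
reproducible for a given seed on a given platform.

Gradients are hand-derived and verified against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32

# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

_SELU_LAMBDA = 1.0507009873554805
_SELU_ALPHA = 1.6732632423543772


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Activation:
    """Element-wise activation layer ('relu'|'leaky_relu'|'selu'|'tanh'|'sigmoid')."""

    def __init__(self, kind: str, alpha: float = 0.2):
        self.kind = kind
        self.alpha = alpha
        self._cache = None

    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, x, training=False):
        k = self.kind
        if k == "relu":
            y = np.maximum(x, 0.0)
            self._cache = x
        elif k == "leaky_relu":
            y = np.where(x >= 0, x, self.alpha * x)
            self._cache = x
        elif k == "selu":
            y = _SELU_LAMBDA * np.where(x >= 0, x, _SELU_ALPHA * (np.exp(np.minimum(x, 0.0)) - 1.0))
            self._cache = x
        elif k == "tanh":
            y = np.tanh(x)
            self._cache = y
        elif k == "sigmoid":
            y = _sigmoid(x)
            self._cache = y
        else:  # pragma: no cover - guarded at construction sites
            raise ValueError(f"unknown activation {k!r}")
        return y.astype(DTYPE, copy=False)

    def backward(self, dy):
        k = self.kind
        c = self._cache
        if k == "relu":
            return dy * (c > 0)
        if k == "leaky_relu":
            return dy * np.where(c >= 0, 1.0, self.alpha).astype(DTYPE)
        if k == "selu":
            dpos = np.full_like(c, _SELU_LAMBDA)
            dneg = _SELU_LAMBDA * _SELU_ALPHA * np.exp(np.minimum(c, 0.0))
            return dy * np.where(c >= 0, dpos, dneg)
        if k == "tanh":
            return dy * (1.0 - c * c)
        if k == "sigmoid":
            return dy * c * (1.0 - c)
        raise AssertionError


# ---------------------------------------------------------------------------
# core layers
# ---------------------------------------------------------------------------


class Dense:
    """Affine map on the last axis; leading axes (batch, time, ...) pass through."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        x = self._x
        x2 = x.reshape(-1, x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.dW[...] = x2.T @ dy2
        self.db[...] = dy2.sum(axis=0)
        return (dy @ self.W.T).reshape(x.shape)


def _same_pad(n_in: int, k: int, stride: int) -> tuple[int, int]:
    n_out = -(-n_in // stride)  # ceil
    total = max((n_out - 1) * stride + k - n_in, 0)
    return total // 2, total - total // 2


class Conv1D:
    """1-D convolution, 'same' zero padding, (batch, length, channels) layout."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int, rng: np.random.Generator):
        self.k, self.stride = kernel, stride
        limit = np.sqrt(6.0 / (kernel * c_in + kernel * c_out))
        self.W = rng.uniform(-limit, limit, size=(kernel, c_in, c_out)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, training=False):
        B, L, C = x.shape
        pl, pr = _same_pad(L, self.k, self.stride)
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=1)[:, :: self.stride]
        # win: (B, L_out, C, k)
        y = np.tensordot(win, self.W, axes=([3, 2], [0, 1])) + self.b
        self._cache = (win, x.shape, pl)
        return y.astype(DTYPE, copy=False)

    def backward(self, dy):
        win, xshape, pl = self._cache
        B, L, C = xshape
        self.dW[...] = np.tensordot(dy, win, axes=([0, 1], [0, 1])).transpose(2, 1, 0)
        self.db[...] = dy.sum(axis=(0, 1))
        _, pr = _same_pad(L, self.k, self.stride)
        dxp = np.zeros((B, L + pl + pr, C), dtype=DTYPE)
        L_out = dy.shape[1]
        for kk in range(self.k):
            # dy (B, L_out, c_out) @ W[kk].T (c_out, c_in) -> scatter at kk + stride*t
            contrib = dy @ self.W[kk].T
            dxp[:, kk : kk + (L_out - 1) * self.stride + 1 : self.stride] += contrib
        return dxp[:, pl : pl + L]


class Conv1DTranspose:
    """Stride-upsampling transposed 1-D convolution; output length = stride * input length."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int, rng: np.random.Generator):
        if kernel < stride:
            raise ValueError("kernel must be >= stride")
        self.k, self.stride = kernel, stride
        limit = np.sqrt(6.0 / (kernel * c_in + kernel * c_out))
        self.W = rng.uniform(-limit, limit, size=(kernel, c_in, c_out)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def _geometry(self, L):
        full = (L - 1) * self.stride + self.k
        crop = (self.k - self.stride) // 2
        return full, crop

    def forward(self, x, training=False):
        B, L, C = x.shape
        full, crop = self._geometry(L)
        out = np.zeros((B, full, self.W.shape[2]), dtype=DTYPE)
        for kk in range(self.k):
            out[:, kk : kk + (L - 1) * self.stride + 1 : self.stride] += x @ self.W[kk]
        self._x = x
        return out[:, crop : crop + L * self.stride] + self.b

    def backward(self, dy):
        x = self._x
        B, L, C = x.shape
        full, crop = self._geometry(L)
        dfull = np.zeros((B, full, self.W.shape[2]), dtype=DTYPE)
        dfull[:, crop : crop + L * self.stride] = dy
        dx = np.zeros_like(x)
        for kk in range(self.k):
            sl = dfull[:, kk : kk + (L - 1) * self.stride + 1 : self.stride]
            dx += sl @ self.W[kk].T
            self.dW[kk] = np.tensordot(x, sl, axes=([0, 1], [0, 1]))
        self.db[...] = dy.sum(axis=(0, 1))
        return dx


class BatchNorm:
    """Batch normalisation over batch (and time, for 3-D inputs) per feature/channel."""

    def __init__(self, n_feat: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n_feat, dtype=DTYPE)
        self.beta = np.zeros(n_feat, dtype=DTYPE)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n_feat, dtype=DTYPE)
        self.running_var = np.ones(n_feat, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean[...] = m * self.running_mean + (1 - m) * mean
            self.running_var[...] = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv.astype(DTYPE), axes, x.shape)
        return (self.gamma * xhat + self.beta).astype(DTYPE, copy=False)

    def backward(self, dy):
        xhat, inv, axes, shape = self._cache
        n = np.prod([shape[a] for a in axes])
        self.dgamma[...] = (dy * xhat).sum(axis=axes)
        self.dbeta[...] = dy.sum(axis=axes)
        dxhat = dy * self.gamma
        dx = (inv / n) * (n * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes))
        return dx.astype(DTYPE, copy=False)


class Dropout:
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng
        self._mask = None

    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class Reshape:
    def __init__(self, shape: tuple):
        self.shape = shape
        self._in = None

    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, x, training=False):
        self._in = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, dy):
        return dy.reshape(self._in)


class Flatten(Reshape):
    def __init__(self):
        super().__init__((-1,))


class LSTM:
    """Single LSTM layer returning the full hidden-state sequence (B, T, H).

    Gate order i, f, g, o; forget-gate bias initialised to 1.
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        H = n_hidden
        lim_x = np.sqrt(6.0 / (n_in + 4 * H))
        lim_h = np.sqrt(6.0 / (H + 4 * H))
        self.Wx = rng.uniform(-lim_x, lim_x, size=(n_in, 4 * H)).astype(DTYPE)
        self.Wh = rng.uniform(-lim_h, lim_h, size=(H, 4 * H)).astype(DTYPE)
        self.b = np.zeros(4 * H, dtype=DTYPE)
        self.b[H : 2 * H] = 1.0
        self.H = H
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def grads(self):
        return [self.dWx, self.dWh, self.db]

    def forward(self, x, training=False):
        B, T, F = x.shape
        H = self.H
        h = np.zeros((B, H), dtype=DTYPE)
        c = np.zeros((B, H), dtype=DTYPE)
        hs = np.zeros((B, T, H), dtype=DTYPE)
        cache = []
        for t in range(T):
            a = x[:, t] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H : 2 * H])
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = _sigmoid(a[:, 3 * H :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            hs[:, t] = h
            cache.append((i, f, g, o, c_prev, tc, h_prev))
        self._cache = (x, cache)
        return hs

    def backward(self, dhs):
        x, cache = self._cache
        B, T, F = x.shape
        H = self.H
        self.dWx[...] = 0
        self.dWh[...] = 0
        self.db[...] = 0
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, H), dtype=DTYPE)
        dc_next = np.zeros((B, H), dtype=DTYPE)
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, tc, h_prev = cache[t]
            dh = dhs[:, t] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc_next = dc * f
            da = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=1,
            ).astype(DTYPE, copy=False)
            self.dWx += x[:, t].T @ da
            self.dWh += h_prev.T @ da
            self.db += da.sum(axis=0)
            dx[:, t] = da @ self.Wx.T
            dh_next = da @ self.Wh.T
        return dx


# ---------------------------------------------------------------------------
# model container + optimizer + losses
# ---------------------------------------------------------------------------


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]

    def forward(self, x, training=False):
        for l in self.layers:
            x = l.forward(x, training=training)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy

    def get_weights(self):
        return [p.copy() for p in self.params()]

    def set_weights(self, weights):
        for p, w in zip(self.params(), weights, strict=True):
            p[...] = w


class Adam:
    def __init__(self, params, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def mse_loss(pred, target):
    """Mean squared error and its gradient w.r.t. pred."""
    diff = pred - target
    loss = float(np.mean(diff * diff))
    return loss, (2.0 / diff.size) * diff.astype(DTYPE, copy=False)


def bce_loss(prob, target, eps: float = 1e-7):
    """Binary cross-entropy on probabilities and its gradient w.r.t. prob."""
    p = np.clip(prob, eps, 1.0 - eps)
    loss = float(-np.mean(target * np.log(p) + (1.0 - target) * np.log(1.0 - p)))
    grad = ((p - target) / (p * (1.0 - p))) / p.size
    return loss, grad.astype(DTYPE, copy=False)
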