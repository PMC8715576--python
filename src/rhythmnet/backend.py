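"""A compact numpy neural-network engine for 1-D sequence classification.

Implements exactly the layer set the rhythm classifier needs — 1-D
convolution (same padding), batch normalization, ReLU, dropout, max pooling,
bidirectional LSTM, dense and softmax — with hand-written backward passes
and an Adam optimizer.  Array layout is ``(batch, channels, length)``
through the convolutional stack and ``(batch, time, features)`` through the
recurrent stack.

The engine is deliberately small: fixed layer order, no graph tracing, no
broadcasting generality.  It exists so the full training/evaluation
pipeline runs anywhere numpy does.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1D",
    "BatchNorm1D",
    "ReLU",
    "Dropout",
    "MaxPool1D",
    "BiLSTM",
    "ToSequence",
    "Dense",
    "Softmax",
    "Sequential",
    "Adam",
]


class Layer:
    """Base layer: parameters in ``params``, gradients in ``grads``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv1D(Layer):
    """Same-padded 1-D convolution, stride 1: (B, C, L) -> (B, F, L)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        self.in_channels, self.out_channels, self.kernel = in_channels, out_channels, kernel
        self.params["W"] = _he_init(rng, (out_channels, in_channels, kernel),
                                    in_channels * kernel, dtype)
        self.params["b"] = np.zeros(out_channels, dtype=dtype)
        self._xp: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, C, L = x.shape
        K = self.kernel
        pad_l = (K - 1) // 2
        pad_r = K - 1 - pad_l
        xp = np.pad(x, ((0, 0), (0, 0), (pad_l, pad_r)))
        if training:
            self._xp = xp
        W = self.params["W"]
        y = np.empty((B, self.out_channels, L), dtype=x.dtype)
        y[:] = self.params["b"][:, None]
        for k in range(K):
            # (F, C) @ (B, C, L) -> (B, F, L)
            y += np.matmul(W[:, :, k], xp[:, :, k : k + L])
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._xp
        B, F, L = dy.shape
        K = self.kernel
        W = self.params["W"]
        dW = np.empty_like(W)
        dy_flat = dy.transpose(1, 0, 2).reshape(F, -1)  # (F, B*L)
        for k in range(K):
            seg = xp[:, :, k : k + L].transpose(1, 0, 2).reshape(self.in_channels, -1)
            dW[:, :, k] = dy_flat @ seg.T
        self.grads["W"] = dW
        self.grads["b"] = dy.sum(axis=(0, 2))
        dxp = np.zeros_like(xp)
        WT = W.transpose(1, 0, 2)  # (C, F, K)
        for k in range(K):
            dxp[:, :, k : k + L] += np.matmul(WT[:, :, k], dy)
        pad_l = (K - 1) // 2
        self._xp = None
        return dxp[:, :, pad_l : pad_l + L]


class BatchNorm1D(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float32) -> None:
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(channels, dtype=dtype)
        self.params["beta"] = np.zeros(channels, dtype=dtype)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None]) * inv_std[:, None]
        if training:
            self._cache = (xhat, inv_std)
        return self.params["gamma"][:, None] * xhat + self.params["beta"][:, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        self._cache = None
        B, C, L = dy.shape
        n = B * L
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 2))
        self.grads["beta"] = dy.sum(axis=(0, 2))
        g = self.params["gamma"][:, None]
        dxhat = dy * g
        return (inv_std[:, None] / n) * (
            n * dxhat
            - dxhat.sum(axis=(0, 2), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        )


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._mask = x > 0
            return x * self._mask
        return np.maximum(x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        out = dy * self._mask
        self._mask = None
        return out


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        out = dy * self._mask
        self._mask = None
        return out


class MaxPool1D(Layer):
    """Non-overlapping max pooling along length; trailing remainder dropped."""

    def __init__(self, size: int = 2) -> None:
        super().__init__()
        if size < 1:
            raise ValueError("pool size must be >= 1")
        self.size = size
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, C, L = x.shape
        s = self.size
        Lo = L // s
        if Lo < 1:
            raise ValueError(f"input length {L} too short for pool size {s}")
        xr = x[:, :, : Lo * s].reshape(B, C, Lo, s)
        idx = xr.argmax(axis=3)
        if training:
            self._cache = (idx, x.shape)
        return np.take_along_axis(xr, idx[..., None], axis=3)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, in_shape = self._cache
        self._cache = None
        B, C, L = in_shape
        s = self.size
        Lo = dy.shape[2]
        dxr = np.zeros((B, C, Lo, s), dtype=dy.dtype)
        np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=3)
        dx = np.zeros(in_shape, dtype=dy.dtype)
        dx[:, :, : Lo * s] = dxr.reshape(B, C, Lo * s)
        return dx


class ToSequence(Layer):
    """(batch, channels, length) -> (batch, time, features) transpose."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return np.ascontiguousarray(x.transpose(0, 2, 1))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.ascontiguousarray(dy.transpose(0, 2, 1))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


class _LSTMDirection:
    """One direction of an LSTM over (B, T, I); gate order i, f, g, o."""

    def __init__(self, input_size: int, hidden: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        self.hidden = hidden
        s = 1.0 / np.sqrt(hidden)
        self.Wx = (rng.uniform(-s, s, (input_size, 4 * hidden))).astype(dtype)
        self.Wh = (rng.uniform(-s, s, (hidden, 4 * hidden))).astype(dtype)
        self.b = np.zeros(4 * hidden, dtype=dtype)
        # forget-gate bias 1: standard trick for stable early training
        self.b[hidden : 2 * hidden] = 1.0
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, T, _ = x.shape
        H = self.hidden
        h = np.zeros((B, H), dtype=x.dtype)
        c = np.zeros((B, H), dtype=x.dtype)
        hs = np.empty((T, B, H), dtype=x.dtype)
        if training:
            gates = np.empty((T, B, 4 * H), dtype=x.dtype)
            cs = np.empty((T, B, H), dtype=x.dtype)
            cprevs = np.empty((T, B, H), dtype=x.dtype)
            hprevs = np.empty((T, B, H), dtype=x.dtype)
        xW = x @ self.Wx + self.b  # (B, T, 4H)
        for t in range(T):
            z = xW[:, t, :] + h @ self.Wh
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            if training:
                hprevs[t], cprevs[t] = h, c
            c = f * c + i * g
            h = o * np.tanh(c)
            hs[t] = h
            if training:
                gates[t] = np.concatenate([i, f, g, o], axis=1)
                cs[t] = c
        if training:
            self._cache = (x, gates, cs, cprevs, hprevs)
        return hs.transpose(1, 0, 2)  # (B, T, H)

    def backward(self, dh_seq: np.ndarray) -> np.ndarray:
        """dh_seq: (B, T, H) gradient on every hidden output; returns dx."""
        x, gates, cs, cprevs, hprevs = self._cache
        self._cache = None
        B, T, _ = x.shape
        H = self.hidden
        dz_all = np.empty((B, T, 4 * H), dtype=x.dtype)
        dh_next = np.zeros((B, H), dtype=x.dtype)
        dc_next = np.zeros((B, H), dtype=x.dtype)
        for t in range(T - 1, -1, -1):
            i = gates[t][:, :H]
            f = gates[t][:, H : 2 * H]
            g = gates[t][:, 2 * H : 3 * H]
            o = gates[t][:, 3 * H :]
            tanh_c = np.tanh(cs[t])
            dh = dh_seq[:, t, :] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1 - tanh_c**2) + dc_next
            di = dc * g
            df = dc * cprevs[t]
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            dz_all[:, t, :] = dz
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
        self.dWx += x.reshape(B * T, -1).T @ dz_all.reshape(B * T, -1)
        self.db += dz_all.sum(axis=(0, 1))
        # recurrent weight gradient: sum_t h_{t-1}^T dz_t
        hp = hprevs.transpose(1, 0, 2).reshape(B * T, H)
        self.dWh += hp.T @ dz_all.reshape(B * T, -1)
        return dz_all @ self.Wx.T


class BiLSTM(Layer):
    """Bidirectional LSTM; forward and backward hidden states concatenated.

    With ``return_sequences`` the output is (B, T, 2H); otherwise the final
    state of each direction — forward at t = T-1, backward at t = 0 — is
    concatenated into (B, 2H).
    """

    def __init__(self, input_size: int, hidden: int, rng: np.random.Generator,
                 return_sequences: bool = True, dtype=np.float32) -> None:
        super().__init__()
        self.hidden = hidden
        self.return_sequences = return_sequences
        self.fwd = _LSTMDirection(input_size, hidden, rng, dtype)
        self.bwd = _LSTMDirection(input_size, hidden, rng, dtype)
        self.params = {
            "fwd_Wx": self.fwd.Wx, "fwd_Wh": self.fwd.Wh, "fwd_b": self.fwd.b,
            "bwd_Wx": self.bwd.Wx, "bwd_Wh": self.bwd.Wh, "bwd_b": self.bwd.b,
        }
        self._T = 0

    def _sync_grads(self) -> None:
        self.grads = {
            "fwd_Wx": self.fwd.dWx, "fwd_Wh": self.fwd.dWh, "fwd_b": self.fwd.db,
            "bwd_Wx": self.bwd.dWx, "bwd_Wh": self.bwd.dWh, "bwd_b": self.bwd.db,
        }

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._T = x.shape[1]
        hf = self.fwd.forward(x, training)
        hb = self.bwd.forward(x[:, ::-1, :], training)[:, ::-1, :]
        if self.return_sequences:
            return np.concatenate([hf, hb], axis=2)
        return np.concatenate([hf[:, -1, :], hb[:, 0, :]], axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        H, T = self.hidden, self._T
        for d in (self.fwd, self.bwd):
            d.dWx[:] = 0; d.dWh[:] = 0; d.db[:] = 0
        if self.return_sequences:
            dhf = dy[:, :, :H]
            dhb = dy[:, :, H:]
        else:
            B = dy.shape[0]
            dhf = np.zeros((B, T, H), dtype=dy.dtype)
            dhb = np.zeros((B, T, H), dtype=dy.dtype)
            dhf[:, -1, :] = dy[:, :H]
            dhb[:, 0, :] = dy[:, H:]
        dx = self.fwd.backward(np.ascontiguousarray(dhf))
        dx_b = self.bwd.backward(np.ascontiguousarray(dhb[:, ::-1, :]))
        dx += dx_b[:, ::-1, :]
        self._sync_grads()
        return dx


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        self.params["W"] = _he_init(rng, (in_features, out_features), in_features, dtype)
        self.params["b"] = np.zeros(out_features, dtype=dtype)
        self._x = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        self._x = None
        return dy @ self.params["W"].T


class Softmax(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._p = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=1, keepdims=True)
        if training:
            self._p = p
        return p

    def backward(self, dp: np.ndarray) -> np.ndarray:
        p = self._p
        self._p = None
        return p * (dp - (dp * p).sum(axis=1, keepdims=True))


class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[int, dict[str, np.ndarray]] = {}
        self._v: dict[int, dict[str, np.ndarray]] = {}

    def step(self, layers: list[Layer]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1 - b1**self.t
        corr2 = 1 - b2**self.t
        for li, layer in enumerate(layers):
            if not layer.params:
                continue
            m = self._m.setdefault(li, {k: np.zeros_like(v) for k, v in layer.params.items()})
            v = self._v.setdefault(li, {k: np.zeros_like(p) for k, p in layer.params.items()})
            for k, p in layer.params.items():
                g = layer.grads.get(k)
                if g is None:
                    continue
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                p -= self.lr * (m[k] / corr1) / (np.sqrt(v[k] / corr2) + self.eps)


class Sequential:
    """Ordered layer stack with loss-aware train steps.

    ``loss_grad`` receives (y_true, probabilities) and returns dL/dp; the
    softmax Jacobian is applied inside the softmax layer's backward pass.
    """

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        outs = [self.forward(x[i : i + batch_size]) for i in range(0, x.shape[0], batch_size)]
        return np.concatenate(outs, axis=0)

    def backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def train_step(self, x: np.ndarray, y: np.ndarray, loss_fn, loss_grad,
                   optimizer: Adam) -> float:
        p = self.forward(x, training=True)
        loss = loss_fn(y, p)
        self.backward(loss_grad(y, p).astype(p.dtype))
        optimizer.step(self.layers)
        return float(loss)

    @property
    def num_params(self) -> int:
        return sum(int(p.size) for layer in self.layers for p in layer.params.values())
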