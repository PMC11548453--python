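"""Compact NumPy implementation of a stacked many-to-one LSTM classifier.

Architecture: one or more LSTM layers (intermediate layers emit full
sequences, the last emits its final hidden state), dropout on that final
state, an optional intermediate dense layer, and a single sigmoid output
unit producing P(foot flat).  Trained with Adam on binary cross-entropy
via backpropagation through time.

Conventions follow the common recurrent-layer parameterization: gate
pre-activations z = x·Wx + h·Wh + b split into input/forget/candidate/
output gates; the configurable activation applies to the candidate and
to the cell output (gates stay sigmoid); the forget-gate bias starts at 1.
Parameter count per layer is 4·(u·(c+u)+u) for u units and c inputs.
Recurrent matmuls run through BLAS; the elementwise cell updates are
fused numba kernels (see ``_lstm_kernels``).
"""

from __future__ import annotations

import numpy as np

from ._lstm_kernels import lstm_step_backward, lstm_step_forward

_F = np.float32

_ACT_CODES = {"tanh": 0, "sigmoid": 1, "relu": 2}


def _sigmoid(x):
    out = np.empty_like(x)
    np.negative(x, out=out)
    np.exp(out, out=out)
    out += 1.0
    np.reciprocal(out, out=out)
    return out


class LSTMNet:
    """Weights + forward/backward passes; training loops live in the estimator."""

    def __init__(self, n_channels: int, n_units: int, n_layers: int,
                 dense_active: bool, n_dense_units: int, activation: str,
                 dropout: float, seed: int = 0):
        if activation not in _ACT_CODES:
            raise ValueError(
                f"unknown activation {activation!r}; choose from {sorted(_ACT_CODES)}")
        self.n_channels = n_channels
        self.n_units = n_units
        self.n_layers = n_layers
        self.dense_active = dense_active
        self.n_dense_units = n_dense_units
        self.activation = activation
        self.dropout = dropout
        self._code = _ACT_CODES[activation]

        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        c = n_channels
        for layer in range(n_layers):
            u = n_units
            self.params[f"Wx{layer}"] = self._glorot(rng, c, 4 * u)
            self.params[f"Wh{layer}"] = self._glorot(rng, u, 4 * u)
            b = np.zeros(4 * u, dtype=_F)
            b[u:2 * u] = 1.0  # forget-gate bias
            self.params[f"b{layer}"] = b
            c = u
        if dense_active:
            self.params["Wd"] = self._glorot(rng, c, n_dense_units)
            self.params["bd"] = np.zeros(n_dense_units, dtype=_F)
            c = n_dense_units
        self.params["Wo"] = self._glorot(rng, c, 1)
        self.params["bo"] = np.zeros(1, dtype=_F)

    @staticmethod
    def _glorot(rng, fan_in: int, fan_out: int) -> np.ndarray:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, (fan_in, fan_out)).astype(_F)

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # ------------------------------------------------------------------ forward
    def forward(self, X: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None):
        """X: (B, T, C) float32 → probabilities (B,), plus caches for BPTT."""
        X = np.ascontiguousarray(X, dtype=_F)
        B, T, _ = X.shape
        H = self.n_units
        caches = []
        layer_in = X
        for layer in range(self.n_layers):
            Wx, Wh, b = (self.params[f"Wx{layer}"], self.params[f"Wh{layer}"],
                         self.params[f"b{layer}"])
            # input contribution for all timesteps in one gemm
            zx = (layer_in.reshape(B * T, -1) @ Wx).reshape(B, T, 4 * H)
            buf = {name: np.empty((T, B, H), dtype=_F)
                   for name in ("i", "f", "o", "g", "dg", "ac", "dac",
                                "h_prev", "c_prev", "hs")}
            h = np.zeros((B, H), dtype=_F)
            c = np.zeros((B, H), dtype=_F)
            c_next = np.empty((B, H), dtype=_F)
            for t in range(T):
                buf["h_prev"][t] = h
                buf["c_prev"][t] = c
                z = zx[:, t, :] + h @ Wh
                z += b
                h = buf["hs"][t]
                lstm_step_forward(z, c, self._code, buf["i"][t], buf["f"][t],
                                  buf["o"][t], buf["g"][t], buf["dg"][t],
                                  c_next, buf["ac"][t], buf["dac"][t], h)
                c, c_next = c_next, c
            buf["layer_in"] = layer_in
            caches.append(buf)
            layer_in = np.ascontiguousarray(np.moveaxis(buf["hs"], 0, 1))  # (B, T, H)

        h_final = layer_in[:, -1, :]
        head: dict = {"h_final": h_final}
        x = h_final
        if training and self.dropout > 0.0:
            if rng is None:
                rng = np.random.default_rng()
            mask = (rng.random(x.shape) >= self.dropout).astype(_F) / _F(1.0 - self.dropout)
            x = x * mask
            head["drop_mask"] = mask
        if self.dense_active:
            pre_d = x @ self.params["Wd"] + self.params["bd"]
            xd = np.maximum(pre_d, 0.0)
            head.update(dense_in=x, pre_d=pre_d, xd=xd)
            x = xd
        head["out_in"] = x
        logits = (x @ self.params["Wo"] + self.params["bo"])[:, 0]
        p = _sigmoid(logits)
        return p, (caches, head)

    # ----------------------------------------------------------------- backward
    def backward(self, X: np.ndarray, p: np.ndarray, y: np.ndarray, cache):
        """Mean binary cross-entropy gradients for all parameters."""
        caches, head = cache
        B = p.shape[0]
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        dlogits = ((p - y) / B).astype(_F)  # sigmoid + BCE

        x = head["out_in"]
        grads["Wo"] += x.T @ dlogits[:, None]
        grads["bo"] += dlogits.sum(keepdims=True)
        dx = dlogits[:, None] @ self.params["Wo"].T
        if self.dense_active:
            dpre = dx * (head["pre_d"] > 0)
            grads["Wd"] += head["dense_in"].T @ dpre
            grads["bd"] += dpre.sum(axis=0)
            dx = dpre @ self.params["Wd"].T
        if "drop_mask" in head:
            dx = dx * head["drop_mask"]

        H = self.n_units
        T = caches[0]["i"].shape[0]
        # gradient w.r.t. the top layer's output sequence: only final step used
        dH_seq = np.zeros((T, B, H), dtype=_F)
        dH_seq[-1] = dx

        for layer in range(self.n_layers - 1, -1, -1):
            cc = caches[layer]
            Wx, Wh = self.params[f"Wx{layer}"], self.params[f"Wh{layer}"]
            WhT = np.ascontiguousarray(Wh.T)
            dZ = np.empty((T, B, 4 * H), dtype=_F)
            dh_carry = np.zeros((B, H), dtype=_F)
            dc_carry = np.zeros((B, H), dtype=_F)
            for t in range(T - 1, -1, -1):
                dh = dH_seq[t] + dh_carry
                lstm_step_backward(dh, dc_carry, cc["i"][t], cc["f"][t],
                                   cc["o"][t], cc["g"][t], cc["dg"][t],
                                   cc["ac"][t], cc["dac"][t], cc["c_prev"][t],
                                   dZ[t])
                dh_carry = dZ[t] @ WhT
            TB = T * B
            layer_in = cc["layer_in"]  # (B, T, C)
            Xin = np.ascontiguousarray(np.moveaxis(layer_in, 0, 1)).reshape(TB, -1)
            dZ2 = dZ.reshape(TB, 4 * H)
            grads[f"Wx{layer}"] += Xin.T @ dZ2
            grads[f"Wh{layer}"] += cc["h_prev"].reshape(TB, H).T @ dZ2
            grads[f"b{layer}"] += dZ2.sum(axis=0)
            if layer > 0:
                dH_seq = (dZ2 @ Wx.T).reshape(T, B, H)
        return grads


class Adam:
    """Adam optimizer over a parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, p in params.items():
            g = grads[k]
            m = self.m[k]
            v = self.v[k]
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * np.square(g)
            p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)


def bce_loss(p: np.ndarray, y: np.ndarray, eps: float = 1e-7) -> float:
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
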