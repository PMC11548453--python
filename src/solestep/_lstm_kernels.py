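"""Fused elementwise LSTM cell kernels (numba-jitted).

The recurrent matmuls go through BLAS; everything elementwise in a cell
update — gate squashing, cell/candidate activations and their local
derivatives — is fused into single passes here so a training step is not
dominated by intermediate array traffic.

Activation codes: 0 = tanh, 1 = sigmoid, 2 = relu (candidate and cell
output; gates are always sigmoid).  Cell states are clipped to ±50.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_CLIP = 50.0


@njit(fastmath=True, cache=False)
def _act(x, code):
    if code == 0:
        return np.tanh(x)
    if code == 1:
        return 1.0 / (1.0 + np.exp(-x))
    return x if x > 0.0 else 0.0


@njit(fastmath=True, cache=False)
def _dact(a, pre, code):
    if code == 0:
        return 1.0 - a * a
    if code == 1:
        return a * (1.0 - a)
    return 1.0 if pre > 0.0 else 0.0


@njit(fastmath=True, cache=False)
def lstm_step_forward(z, c_prev, code, i, f, o, g, dg, c, ac, dac, h):
    """One cell update for a batch; all outputs written in place."""
    B, H4 = z.shape
    H = H4 // 4
    for b in range(B):
        for j in range(H):
            zi = z[b, j]
            zf = z[b, H + j]
            zg = z[b, 2 * H + j]
            zo = z[b, 3 * H + j]
            iv = 1.0 / (1.0 + np.exp(-zi))
            fv = 1.0 / (1.0 + np.exp(-zf))
            ov = 1.0 / (1.0 + np.exp(-zo))
            gv = _act(zg, code)
            cv = fv * c_prev[b, j] + iv * gv
            if cv > _CLIP:
                cv = _CLIP
            elif cv < -_CLIP:
                cv = -_CLIP
            av = _act(cv, code)
            i[b, j] = iv
            f[b, j] = fv
            o[b, j] = ov
            g[b, j] = gv
            dg[b, j] = _dact(gv, zg, code)
            c[b, j] = cv
            ac[b, j] = av
            dac[b, j] = _dact(av, cv, code)
            h[b, j] = ov * av


@njit(fastmath=True, cache=False)
def lstm_step_backward(dh, dc_carry, i, f, o, g, dg, ac, dac, c_prev, dz):
    """Backward cell update: writes gate pre-activation grads into dz and
    updates dc_carry in place for the next (earlier) timestep."""
    B, H = dh.shape
    for b in range(B):
        for j in range(H):
            iv = i[b, j]
            fv = f[b, j]
            ov = o[b, j]
            dhv = dh[b, j]
            do = dhv * ac[b, j]
            dc = dhv * ov * dac[b, j] + dc_carry[b, j]
            dz[b, j] = dc * g[b, j] * iv * (1.0 - iv)
            dz[b, H + j] = dc * c_prev[b, j] * fv * (1.0 - fv)
            dz[b, 2 * H + j] = dc * iv * dg[b, j]
            dz[b, 3 * H + j] = do * ov * (1.0 - ov)
            dc_carry[b, j] = dc * fv
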