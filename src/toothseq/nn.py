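"""Minimal numpy neural-network engine for the sequence classifiers.

Implements exactly what the classification architectures need — GRU, LSTM and
vanilla-RNN layers with full backpropagation through time, a small 2D
convolutional stack, dense layers, softmax cross-entropy on integer labels,
and the Adam optimizer. Everything is float64 and deterministic given the
seed; analytic gradients are validated against finite differences in the
test suite.

Conventions
-----------
Sequences are (batch, timesteps, features). Recurrent weights are stored as
``Wx`` (input→gates), ``Wh`` (hidden→gates) and a single bias ``b``; gate
blocks are concatenated along the last axis (GRU: [z, r, n]; LSTM:
[i, f, g, o]). The GRU uses the convention

    z = sigmoid(x·Wxz + h·Uhz + bz)          (update gate; keeps old state)
    r = sigmoid(x·Wxr + h·Uhr + br)          (reset gate)
    n = tanh(x·Wxn + bn + r ⊙ (h·Uhn))       (candidate state)
    h' = z ⊙ h + (1 − z) ⊙ n
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np

__all__ = [
    "init_recurrent",
    "init_dense",
    "recurrent_forward",
    "recurrent_backward",
    "dense_forward",
    "dense_backward",
    "relu",
    "softmax",
    "softmax_xent",
    "conv_forward",
    "conv_backward",
    "maxpool_forward",
    "maxpool_backward",
    "Adam",
    "GATE_MULT",
]

GATE_MULT = {"GRU": 3, "LSTM": 4, "RNN": 1}


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _orthogonal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    a = rng.standard_normal((max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))  # fix sign convention for determinism
    return q[:rows, :cols] if q.shape != (rows, cols) else q


def init_dense(rng: np.random.Generator, d_in: int, d_out: int) -> Dict[str, np.ndarray]:
    limit = np.sqrt(6.0 / (d_in + d_out))
    return {
        "W": rng.uniform(-limit, limit, (d_in, d_out)),
        "b": np.zeros(d_out),
    }


def init_recurrent(
    rng: np.random.Generator, kind: str, d_in: int, units: int
) -> Dict[str, np.ndarray]:
    """Glorot input weights, orthogonal recurrent weights, zero bias.

    LSTM forget-gate bias starts at 1 (standard trick for gradient flow).
    """
    g = GATE_MULT[kind]
    limit = np.sqrt(6.0 / (d_in + units))
    Wx = rng.uniform(-limit, limit, (d_in, g * units))
    Wh = np.hstack([_orthogonal(rng, units, units) for _ in range(g)])
    b = np.zeros(g * units)
    if kind == "LSTM":
        b[units : 2 * units] = 1.0
    return {"Wx": Wx, "Wh": Wh, "b": b}


# ---------------------------------------------------------------------------
# recurrent layers
# ---------------------------------------------------------------------------


def recurrent_forward(kind: str, params: Dict, X: np.ndarray):
    """Run a recurrent layer over a (B, T, D) batch.

    Returns (H, cache) where H is the full hidden sequence (B, T, U).
    """
    Wx, Wh, b = params["Wx"], params["Wh"], params["b"]
    B, T, D = X.shape
    U = Wh.shape[0]
    H = np.zeros((B, T, U))
    h = np.zeros((B, U))
    Gx = X.reshape(B * T, D) @ Wx  # all input projections at once
    Gx = Gx.reshape(B, T, -1) + b
    if kind == "GRU":
        Z = np.zeros((B, T, U))
        R = np.zeros((B, T, U))
        N = np.zeros((B, T, U))
        M = np.zeros((B, T, U))
        Hprev = np.zeros((B, T, U))
        for t in range(T):
            gh = h @ Wh
            z = _sigmoid(Gx[:, t, :U] + gh[:, :U])
            r = _sigmoid(Gx[:, t, U : 2 * U] + gh[:, U : 2 * U])
            m = gh[:, 2 * U :]
            n = np.tanh(Gx[:, t, 2 * U :] + r * m)
            Hprev[:, t] = h
            h = z * h + (1.0 - z) * n
            Z[:, t], R[:, t], N[:, t], M[:, t] = z, r, n, m
            H[:, t] = h
        cache = (X, Z, R, N, M, Hprev)
    elif kind == "LSTM":
        I = np.zeros((B, T, U))
        Fg = np.zeros((B, T, U))
        G = np.zeros((B, T, U))
        O = np.zeros((B, T, U))
        C = np.zeros((B, T, U))
        Cprev = np.zeros((B, T, U))
        Hprev = np.zeros((B, T, U))
        c = np.zeros((B, U))
        for t in range(T):
            g = Gx[:, t] + h @ Wh
            i = _sigmoid(g[:, :U])
            f = _sigmoid(g[:, U : 2 * U])
            gg = np.tanh(g[:, 2 * U : 3 * U])
            o = _sigmoid(g[:, 3 * U :])
            Cprev[:, t] = c
            Hprev[:, t] = h
            c = f * c + i * gg
            h = o * np.tanh(c)
            I[:, t], Fg[:, t], G[:, t], O[:, t], C[:, t] = i, f, gg, o, c
            H[:, t] = h
        cache = (X, I, Fg, G, O, C, Cprev, Hprev)
    elif kind == "RNN":
        Hprev = np.zeros((B, T, U))
        for t in range(T):
            Hprev[:, t] = h
            h = np.tanh(Gx[:, t] + h @ Wh)
            H[:, t] = h
        cache = (X, H, Hprev)
    else:
        raise ValueError(f"unknown recurrent kind {kind!r}")
    return H, cache


def recurrent_backward(kind: str, params: Dict, dH: np.ndarray, cache):
    """BPTT. ``dH`` holds the loss gradient w.r.t. every hidden state
    (zero rows where only the final state feeds the loss).

    Returns (dX, grads).
    """
    Wx, Wh = params["Wx"], params["Wh"]
    U = Wh.shape[0]
    X = cache[0]
    B, T, D = X.shape
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros_like(params["b"])
    dX = np.zeros_like(X)
    carry = np.zeros((B, U))
    if kind == "GRU":
        _, Z, R, N, M, Hprev = cache
        for t in range(T - 1, -1, -1):
            dh = dH[:, t] + carry
            z, r, n, m, hp = Z[:, t], R[:, t], N[:, t], M[:, t], Hprev[:, t]
            dz = dh * (hp - n) * z * (1.0 - z)
            dan = dh * (1.0 - z) * (1.0 - n * n)
            dm = dan * r
            dr = dan * m
            dar = dr * r * (1.0 - r)
            da = np.hstack([dz, dar, dan])
            x = X[:, t]
            dWx += x.T @ da
            dWh += hp.T @ np.hstack([dz, dar, dm])
            db += da.sum(axis=0)
            dX[:, t] = da @ Wx.T
            carry = (
                dh * z
                + dm @ Wh[:, 2 * U :].T
                + dar @ Wh[:, U : 2 * U].T
                + dz @ Wh[:, :U].T
            )
    elif kind == "LSTM":
        _, I, Fg, G, O, C, Cprev, Hprev = cache
        dc_carry = np.zeros((B, U))
        for t in range(T - 1, -1, -1):
            dh = dH[:, t] + carry
            i, f, g, o, c, cp, hp = (
                I[:, t],
                Fg[:, t],
                G[:, t],
                O[:, t],
                C[:, t],
                Cprev[:, t],
                Hprev[:, t],
            )
            tc = np.tanh(c)
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_carry
            di = dc * g
            df = dc * cp
            dg = dc * i
            dc_carry = dc * f
            da = np.hstack(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ]
            )
            x = X[:, t]
            dWx += x.T @ da
            dWh += hp.T @ da
            db += da.sum(axis=0)
            dX[:, t] = da @ Wx.T
            carry = da @ Wh.T
    elif kind == "RNN":
        _, H, Hprev = cache
        for t in range(T - 1, -1, -1):
            dh = dH[:, t] + carry
            h, hp = H[:, t], Hprev[:, t]
            da = dh * (1.0 - h * h)
            x = X[:, t]
            dWx += x.T @ da
            dWh += hp.T @ da
            db += da.sum(axis=0)
            dX[:, t] = da @ Wx.T
            carry = da @ Wh.T
    else:
        raise ValueError(f"unknown recurrent kind {kind!r}")
    return dX, {"Wx": dWx, "Wh": dWh, "b": db}


# ---------------------------------------------------------------------------
# dense / activations / loss
# ---------------------------------------------------------------------------


def dense_forward(params: Dict, x: np.ndarray):
    return x @ params["W"] + params["b"], x


def dense_backward(params: Dict, dout: np.ndarray, x: np.ndarray):
    return dout @ params["W"].T, {"W": x.T @ dout, "b": dout.sum(axis=0)}


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_xent(logits: np.ndarray, y: np.ndarray):
    """Mean sparse categorical cross-entropy and its gradient w.r.t. logits."""
    p = softmax(logits)
    n = len(y)
    idx = np.arange(n)
    loss = float(-np.log(np.maximum(p[idx, y], 1e-300)).mean())
    dlogits = p.copy()
    dlogits[idx, y] -= 1.0
    return loss, dlogits / n, p


# ---------------------------------------------------------------------------
# convolution (3x3, stride 1, same padding) and 2x2 max pooling
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray) -> np.ndarray:
    """(B, C, H, W) → (B, H*W, C*9) for a 3x3 same-padded window."""
    B, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = np.empty((B, C, 9, H, W))
    k = 0
    for dy in range(3):
        for dx in range(3):
            cols[:, :, k] = xp[:, :, dy : dy + H, dx : dx + W]
            k += 1
    return cols.transpose(0, 3, 4, 1, 2).reshape(B, H * W, C * 9)


def _col2im(dcols: np.ndarray, shape) -> np.ndarray:
    B, C, H, W = shape
    d = dcols.reshape(B, H, W, C, 9).transpose(0, 3, 4, 1, 2)
    dxp = np.zeros((B, C, H + 2, W + 2))
    k = 0
    for dy in range(3):
        for dx in range(3):
            dxp[:, :, dy : dy + H, dx : dx + W] += d[:, :, k]
            k += 1
    return dxp[:, :, 1:-1, 1:-1]


def conv_forward(params: Dict, x: np.ndarray):
    """3x3 convolution, stride 1, same padding. W: (F, C, 3, 3)."""
    W, b = params["W"], params["b"]
    Fn, C = W.shape[:2]
    B, _, H, Wd = x.shape
    cols = _im2col(x)
    out = cols @ W.reshape(Fn, -1).T + b
    return out.reshape(B, H, Wd, Fn).transpose(0, 3, 1, 2), (cols, x.shape)


def conv_backward(params: Dict, dout: np.ndarray, cache):
    cols, xshape = cache
    W = params["W"]
    Fn = W.shape[0]
    B, _, H, Wd = dout.shape
    d = dout.transpose(0, 2, 3, 1).reshape(B, H * Wd, Fn)
    dW = np.einsum("bnf,bnc->fc", d, cols).reshape(W.shape)
    db = d.sum(axis=(0, 1))
    dcols = d @ W.reshape(Fn, -1)
    return _col2im(dcols, xshape), {"W": dW, "b": db}


def maxpool_forward(x: np.ndarray, ph: int = 2, pw: int = 2):
    """(ph, pw) max pool with matching stride; odd trailing rows/cols are
    cropped. A window of 1 along an axis leaves that axis untouched."""
    B, C, H, W = x.shape
    Ho, Wo = H // ph, W // pw
    xc = x[:, :, : Ho * ph, : Wo * pw]
    win = xc.reshape(B, C, Ho, ph, Wo, pw).transpose(0, 1, 2, 4, 3, 5).reshape(
        B, C, Ho, Wo, ph * pw
    )
    arg = win.argmax(axis=-1)
    out = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]
    return out, (arg, x.shape, ph, pw)


def maxpool_backward(dout: np.ndarray, cache):
    arg, xshape, ph, pw = cache
    B, C, H, W = xshape
    Ho, Wo = H // ph, W // pw
    dwin = np.zeros((B, C, Ho, Wo, ph * pw))
    np.put_along_axis(dwin, arg[..., None], dout[..., None], axis=-1)
    dx = np.zeros(xshape)
    dx[:, :, : Ho * ph, : Wo * pw] = (
        dwin.reshape(B, C, Ho, Wo, ph, pw).transpose(0, 1, 2, 4, 3, 5).reshape(
            B, C, Ho * ph, Wo * pw
        )
    )
    return dx


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, lr: float = 5e-4, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m: Dict[str, np.ndarray] = {}
        self.v: Dict[str, np.ndarray] = {}

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, g in grads.items():
            if name not in self.m:
                self.m[name] = np.zeros_like(g)
                self.v[name] = np.zeros_like(g)
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            mhat = self.m[name] / (1 - b1**self.t)
            vhat = self.v[name] / (1 - b2**self.t)
            params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
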