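"""NumPy neural-network primitives: LSTM, additive attention, Adam.

All layers implement explicit forward/backward passes over float64 arrays.
Batched sequences are (B, T, ...) with a {0,1} validity mask; padded steps
carry the previous hidden state through unchanged, which makes a trailing-pad
forward LSTM and a leading-pad (reversed) backward LSTM behave identically
to running on the unpadded sequence.  Gradients for every layer are checked
against central finite differences in the test-suite.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable piecewise form
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax_rows(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def uniform_init(rng: np.random.Generator, shape: tuple[int, ...],
                 scale: float = 0.05) -> np.ndarray:
    return rng.uniform(-scale, scale, size=shape)


# --------------------------------------------------------------------------
# LSTM (fused-gate batched layer)
#
# parameters: Wx (d_in, 4u), Wh (u, 4u), b (4u,); gate order [i, f, g, o]
# with i, f, o sigmoid gates and g = tanh candidate:
#   f_t = sigma(Wf . [h_{t-1}; x_t] + b_f)        (forget gate)
#   i_t = sigma(Wi . [h_{t-1}; x_t] + b_i)        (input gate)
#   g_t = tanh (Wc . [h_{t-1}; x_t] + b_c)        (candidate cell)
#   c_t = f_t * c_{t-1} + i_t * g_t
#   o_t = sigma(Wo . [h_{t-1}; x_t] + b_o)        (output gate)
#   h_t = o_t * tanh(c_t)


def lstm_param_shapes(d_in: int, units: int) -> dict[str, tuple[int, ...]]:
    return {"Wx": (d_in, 4 * units), "Wh": (units, 4 * units), "b": (4 * units,)}


def lstm_forward(
    X: np.ndarray,          # (B, T, d_in)
    mask: np.ndarray,       # (B, T) in {0,1}
    params: Mapping[str, np.ndarray],
) -> tuple[np.ndarray, dict]:
    """Run a batched unidirectional LSTM; returns (H, cache).

    Masked steps carry (h, c) through unchanged, so the initial zero state
    survives any leading padding and trailing padding freezes the state.
    """
    Wx, Wh, b = params["Wx"], params["Wh"], params["b"]
    B, T, _ = X.shape
    u = Wh.shape[0]
    h = np.zeros((B, u))
    c = np.zeros((B, u))
    H = np.zeros((B, T, u))
    steps = []
    # precompute input projections for all steps at once
    XW = X.reshape(B * T, -1) @ Wx
    XW = XW.reshape(B, T, 4 * u)
    for t in range(T):
        a = XW[:, t] + h @ Wh + b
        i = sigmoid(a[:, :u])
        f = sigmoid(a[:, u:2 * u])
        g = np.tanh(a[:, 2 * u:3 * u])
        o = sigmoid(a[:, 3 * u:])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        m = mask[:, t][:, None]
        steps.append({"h_prev": h, "c_prev": c, "i": i, "f": f, "g": g,
                      "o": o, "tc": tc, "m": m})
        h = m * h_new + (1.0 - m) * h
        c = m * c_new + (1.0 - m) * c
        H[:, t] = h
    cache = {"X": X, "steps": steps, "params": params, "u": u}
    return H, cache


def lstm_backward(dH: np.ndarray, cache: dict) -> tuple[np.ndarray, dict]:
    """Backpropagate through time; returns (dX, grads)."""
    X, steps, params, u = cache["X"], cache["steps"], cache["params"], cache["u"]
    Wx, Wh = params["Wx"], params["Wh"]
    B, T, d_in = X.shape
    dX = np.zeros_like(X)
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros_like(params["b"])
    dh_next = np.zeros((B, u))
    dc_next = np.zeros((B, u))
    dA = np.zeros((B, T, 4 * u))
    for t in range(T - 1, -1, -1):
        s = steps[t]
        m = s["m"]
        dh = dH[:, t] + dh_next
        dc = dc_next
        # masked positions pass gradient straight to the previous state
        dh_gate = m * dh
        dc_gate = m * dc
        do = dh_gate * s["tc"]
        dtc = dh_gate * s["o"]
        dc_new = dc_gate + dtc * (1.0 - s["tc"] ** 2)
        di = dc_new * s["g"]
        df = dc_new * s["c_prev"]
        dg = dc_new * s["i"]
        da = np.concatenate([
            di * s["i"] * (1.0 - s["i"]),
            df * s["f"] * (1.0 - s["f"]),
            dg * (1.0 - s["g"] ** 2),
            do * s["o"] * (1.0 - s["o"]),
        ], axis=1)
        dA[:, t] = da
        dWh += s["h_prev"].T @ da
        db += da.sum(axis=0)
        dh_next = da @ Wh.T + (1.0 - m) * dh
        dc_next = dc_new * s["f"] + (1.0 - m) * dc
    dX = (dA.reshape(B * T, 4 * u) @ Wx.T).reshape(B, T, d_in)
    dWx = X.reshape(B * T, d_in).T @ dA.reshape(B * T, 4 * u)
    return dX, {"Wx": dWx, "Wh": dWh, "b": db}


def bilstm_forward(
    X: np.ndarray, mask: np.ndarray,
    fwd: Mapping[str, np.ndarray], bwd: Mapping[str, np.ndarray],
) -> tuple[np.ndarray, dict]:
    """Bidirectional LSTM: per-position concat [h_fwd_t ; h_bwd_t], size 2u."""
    Hf, cf = lstm_forward(X, mask, fwd)
    Hb_rev, cb = lstm_forward(X[:, ::-1], mask[:, ::-1], bwd)
    Hb = Hb_rev[:, ::-1]
    H = np.concatenate([Hf, Hb], axis=2)
    return H, {"cf": cf, "cb": cb, "u": Hf.shape[2]}


def bilstm_backward(dH: np.ndarray, cache: dict) -> tuple[np.ndarray, dict, dict]:
    u = cache["u"]
    dXf, gf = lstm_backward(np.ascontiguousarray(dH[:, :, :u]), cache["cf"])
    dXb_rev, gb = lstm_backward(np.ascontiguousarray(dH[:, ::-1, u:]), cache["cb"])
    dX = dXf + dXb_rev[:, ::-1]
    return dX, gf, gb


# --------------------------------------------------------------------------
# additive attention pooling
#
#   u_i   = tanh(Wa . H_i + ba)
#   e_i   = q . u_i
#   alpha = softmax(e) over unmasked positions
#   ctx   = sum_i alpha_i H_i
# rows with no valid position (empty emotional side) get alpha = 0, ctx = 0.


def attention_param_shapes(d_in: int, d_att: int) -> dict[str, tuple[int, ...]]:
    return {"Wa": (d_in, d_att), "ba": (d_att,), "q": (d_att,)}


def attention_forward(
    H: np.ndarray, mask: np.ndarray, params: Mapping[str, np.ndarray],
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Masked additive attention; returns (context, alpha, cache)."""
    Wa, ba, q = params["Wa"], params["ba"], params["q"]
    U = np.tanh(H @ Wa + ba)          # (B, T, d_att)
    scores = U @ q                    # (B, T)
    neg = np.finfo(float).min / 4
    scores_masked = np.where(mask > 0, scores, neg)
    alpha = softmax_rows(scores_masked)
    alpha = alpha * (mask > 0)        # exact zeros on padding
    valid = mask.sum(axis=1) > 0
    alpha = np.where(valid[:, None], alpha, 0.0)
    # renormalise guard (softmax already sums to 1 on valid rows)
    ctx = np.einsum("bt,btd->bd", alpha, H)
    cache = {"H": H, "U": U, "alpha": alpha, "params": params, "valid": valid}
    return ctx, alpha, cache


def attention_backward(dctx: np.ndarray, cache: dict) -> tuple[np.ndarray, dict]:
    H, U, alpha, valid = cache["H"], cache["U"], cache["alpha"], cache["valid"]
    Wa, q = cache["params"]["Wa"], cache["params"]["q"]
    dH = alpha[:, :, None] * dctx[:, None, :]
    dalpha = np.einsum("bd,btd->bt", dctx, H)
    # softmax jacobian (alpha is zero on masked/invalid entries already)
    inner = (alpha * dalpha).sum(axis=1, keepdims=True)
    dscores = alpha * (dalpha - inner)
    dscores = np.where(valid[:, None], dscores, 0.0)
    dq = np.einsum("bt,btd->d", dscores, U)
    dU = dscores[:, :, None] * q
    dpre = dU * (1.0 - U ** 2)
    dWa = np.einsum("btd,bta->da", H, dpre)
    dba = dpre.sum(axis=(0, 1))
    dH += dpre @ Wa.T
    return dH, {"Wa": dWa, "ba": dba, "q": dq}


# --------------------------------------------------------------------------
# Adam


class Adam:
    """Adam optimizer over a dict of named parameter arrays."""

    def __init__(self, param_names, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: None for k in param_names}
        self.v = {k: None for k in param_names}

    def step(self, params: dict[str, np.ndarray], grads: Mapping[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            if self.m.get(k) is None:
                self.m[k] = np.zeros_like(params[k])
                self.v[k] = np.zeros_like(params[k])
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
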