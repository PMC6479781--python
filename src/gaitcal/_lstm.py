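"""Minimal batched LSTM with hand-rolled backpropagation through time.

numpy-only on purpose: tensors here are desk-scale (tens of sequences of
101 steps) and the training recipe is fixed (full-batch gradient descent),
so a deep-learning framework would be dead weight.  Gate order is
input, forget, cell, output; the forget-gate bias starts at 1.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np


def init_params(rng: np.random.Generator, in_dim: int, hidden: int,
                out_dim: int, n_layers: int = 2) -> Dict[str, np.ndarray]:
    params: Dict[str, np.ndarray] = {}
    d = in_dim
    for l in range(n_layers):
        fan = d + hidden
        scale = 1.0 / np.sqrt(fan)
        params[f"W{l}"] = rng.uniform(-scale, scale, (fan, 4 * hidden))
        b = np.zeros(4 * hidden)
        b[hidden:2 * hidden] = 1.0          # forget-gate bias
        params[f"b{l}"] = b
        d = hidden
    scale = 1.0 / np.sqrt(hidden)
    params["Wy"] = rng.uniform(-scale, scale, (hidden, out_dim))
    params["by"] = np.zeros(out_dim)
    return params


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _layer_forward(X: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Run one LSTM layer over (n, T, d) input; returns (n, T, H) + cache."""
    n, T, d = X.shape
    H = W.shape[1] // 4
    h = np.zeros((n, H), dtype=X.dtype)
    c = np.zeros((n, H), dtype=X.dtype)
    Hs = np.empty((T, n, H), dtype=X.dtype)
    cache = []
    for t in range(T):
        zin = np.concatenate([X[:, t, :], h], axis=1)
        z = zin @ W + b
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H])
        o = _sigmoid(z[:, 3 * H:])
        c_prev = c
        c = f * c_prev + i * g
        tc = np.tanh(c)
        h = o * tc
        Hs[t] = h
        cache.append((zin, i, f, g, o, c_prev, tc))
    return Hs.transpose(1, 0, 2), cache


def _layer_backward(dH: np.ndarray, W: np.ndarray, cache: list):
    """BPTT for one layer.  ``dH`` is (n, T, H) gradient w.r.t. outputs.

    Returns (dX, dW, db)."""
    n, T, H = dH.shape
    d_in = W.shape[0] - H
    dW = np.zeros_like(W)
    db = np.zeros(4 * H, dtype=W.dtype)
    dX = np.empty((n, T, d_in), dtype=W.dtype)
    dh_next = np.zeros((n, H), dtype=W.dtype)
    dc = np.zeros((n, H), dtype=W.dtype)
    for t in range(T - 1, -1, -1):
        zin, i, f, g, o, c_prev, tc = cache[t]
        dh = dH[:, t, :] + dh_next
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc * tc)
        di = dc * g
        dg = dc * i
        df = dc * c_prev
        dz = np.concatenate([
            di * i * (1.0 - i),
            df * f * (1.0 - f),
            dg * (1.0 - g * g),
            do * o * (1.0 - o),
        ], axis=1)
        dW += zin.T @ dz
        db += dz.sum(axis=0)
        dzin = dz @ W.T
        dX[:, t, :] = dzin[:, :d_in]
        dh_next = dzin[:, d_in:]
        dc = dc * f
    return dX, dW, db


def forward(params: Dict[str, np.ndarray], X: np.ndarray, n_layers: int = 2):
    """Full forward pass: stacked LSTM layers + linear read-out."""
    caches = []
    inp = X
    for l in range(n_layers):
        inp, cache = _layer_forward(inp, params[f"W{l}"], params[f"b{l}"])
        caches.append(cache)
    Y = inp @ params["Wy"] + params["by"]
    return Y, (caches, inp)


def backward(params: Dict[str, np.ndarray], X: np.ndarray, dY: np.ndarray,
             state, n_layers: int = 2) -> Dict[str, np.ndarray]:
    caches, h_top = state
    grads = {"Wy": np.einsum("nth,nto->ho", h_top, dY),
             "by": dY.sum(axis=(0, 1))}
    dH = dY @ params["Wy"].T
    for l in range(n_layers - 1, -1, -1):
        dH, dW, db = _layer_backward(dH, params[f"W{l}"], caches[l])
        grads[f"W{l}"] = dW
        grads[f"b{l}"] = db
    return grads


def clip_global_norm(grads: Dict[str, np.ndarray], max_norm: float) -> float:
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / total
        for k in grads:
            grads[k] = grads[k] * scale
    return total
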