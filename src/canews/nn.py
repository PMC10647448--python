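"""Minimal NumPy implementation of a stacked GRU sequence classifier.

This module provides exactly the network the early-warning score needs —
stacked gated recurrent unit (GRU) layers read an hourly vital-sign window,
the final hidden state feeds a 2-unit softmax head, and training minimises
binary cross-entropy with Adam.  Forward, backward (backprop through time)
and the optimiser are written against plain ndarrays, so training is fully
deterministic for a given seed and thread configuration.

GRU cell (classic formulation), for input x_t and previous hidden h_{t-1}:

    z_t = sigmoid(x_t Wz + h_{t-1} Uz + bz)          update gate
    r_t = sigmoid(x_t Wr + h_{t-1} Ur + br)          reset gate
    n_t = tanh(x_t Wn + (r_t * h_{t-1}) Un + bn)     candidate state
    h_t = (1 - z_t) * h_{t-1} + z_t * n_t

For speed the three input projections are stored as one (F, 3H) matrix
``Wx`` (gate order z, r, n) applied to the whole sequence in a single
matmul before the time loop, and the z/r recurrent projections share one
(H, 2H) matrix ``Uzr``; only the candidate projection ``Un`` needs the
reset gate inside the loop.  Inverted dropout is applied to each layer's
output sequence during training only.  All parameter gradients are exact
(checked against finite differences in the test suite).
"""

from __future__ import annotations

import numpy as np
from scipy.special import softmax

__all__ = ["GRUClassifier", "Adam", "cross_entropy"]

_LAYER_KEYS = ("Wx", "bx", "Uzr", "Un")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # tanh-based logistic: numerically equivalent and markedly faster than
    # exp-based formulations on this workload
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    return q * np.sign(np.diag(r))


def _gru_layer_forward(X: np.ndarray, p: dict) -> tuple[np.ndarray, dict]:
    """Run one GRU layer over X (N, T, F) → hidden sequence (N, T, H)."""
    N, T, F = X.shape
    H = p["Un"].shape[0]
    # input-side projections for all timesteps and gates at once
    proj = X.reshape(N * T, F) @ p["Wx"] + p["bx"]
    proj = proj.reshape(N, T, 3 * H)
    dt = p["Wx"].dtype
    h = np.zeros((N, H), dtype=dt)
    hidden = np.empty((N, T, H), dtype=dt)
    Z = np.empty((N, T, H), dtype=dt)
    R = np.empty((N, T, H), dtype=dt)
    Cand = np.empty((N, T, H), dtype=dt)
    Hprev = np.empty((N, T, H), dtype=dt)
    for t in range(T):
        zr = _sigmoid(proj[:, t, : 2 * H] + h @ p["Uzr"])
        z, r = zr[:, :H], zr[:, H:]
        n = np.tanh(proj[:, t, 2 * H :] + (r * h) @ p["Un"])
        Hprev[:, t, :] = h
        h = (1.0 - z) * h + z * n
        hidden[:, t, :] = h
        Z[:, t, :], R[:, t, :], Cand[:, t, :] = z, r, n
    cache = {"X": X, "Z": Z, "R": R, "N": Cand, "Hprev": Hprev}
    return hidden, cache


def _gru_layer_backward(
    dhidden: np.ndarray, cache: dict, p: dict
) -> tuple[dict, np.ndarray]:
    """Backprop through time for one layer.

    ``dhidden`` is the loss gradient w.r.t. the layer's output sequence.
    Returns parameter gradients and the gradient w.r.t. the layer input.
    """
    X, Z, R, Cand, Hprev = cache["X"], cache["Z"], cache["R"], cache["N"], cache["Hprev"]
    N, T, F = X.shape
    H = p["Un"].shape[0]
    dt = p["Wx"].dtype
    da = np.empty((N, T, 3 * H), dtype=dt)  # pre-activation grads, order z, r, n
    dUzr = np.zeros_like(p["Uzr"])
    dUn = np.zeros_like(p["Un"])
    Uzr_T = p["Uzr"].T
    Un_T = p["Un"].T
    dh_carry = np.zeros((N, H), dtype=dt)
    for t in range(T - 1, -1, -1):
        z, r, n, h_prev = Z[:, t, :], R[:, t, :], Cand[:, t, :], Hprev[:, t, :]
        dh = dhidden[:, t, :] + dh_carry
        da_n = (dh * z) * (1.0 - n * n)
        d_rh = da_n @ Un_T
        da_r = (d_rh * h_prev) * r * (1.0 - r)
        da_z = (dh * (n - h_prev)) * z * (1.0 - z)
        da_zr = np.concatenate([da_z, da_r], axis=1)
        dh_carry = dh * (1.0 - z) + d_rh * r + da_zr @ Uzr_T
        dUzr += h_prev.T @ da_zr
        dUn += (r * h_prev).T @ da_n
        da[:, t, :H] = da_z
        da[:, t, H : 2 * H] = da_r
        da[:, t, 2 * H :] = da_n
    da_flat = da.reshape(N * T, 3 * H)
    grads = {
        "Wx": X.reshape(N * T, F).T @ da_flat,
        "bx": da_flat.sum(axis=0),
        "Uzr": dUzr,
        "Un": dUn,
    }
    dX = (da_flat @ p["Wx"].T).reshape(N, T, F)
    return grads, dX


def cross_entropy(probs: np.ndarray, y: np.ndarray, sample_weight=None) -> float:
    """Mean binary cross-entropy of the event-class softmax probability."""
    eps = 1e-12
    ll = -np.log(np.clip(probs[np.arange(len(y)), y], eps, None))
    if sample_weight is not None:
        return float(np.average(ll, weights=sample_weight))
    return float(ll.mean())


class GRUClassifier:
    """Stacked GRU layers + 2-unit softmax head over fixed-length windows."""

    def __init__(
        self,
        input_dim: int,
        hidden: int = 24,
        n_layers: int = 3,
        dropout: float = 0.3,
        seed: int = 0,
        dtype=np.float32,
    ):
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        self.input_dim = input_dim
        self.hidden = hidden
        self.n_layers = n_layers
        self.dropout = dropout
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        for layer in range(n_layers):
            fan_in = input_dim if layer == 0 else hidden
            self.params[f"{layer}.Wx"] = np.concatenate(
                [_glorot(rng, fan_in, hidden) for _ in range(3)], axis=1
            )
            self.params[f"{layer}.bx"] = np.zeros(3 * hidden)
            self.params[f"{layer}.Uzr"] = np.concatenate(
                [_orthogonal(rng, hidden) for _ in range(2)], axis=1
            )
            self.params[f"{layer}.Un"] = _orthogonal(rng, hidden)
        self.params["out.W"] = _glorot(rng, hidden, 2)
        self.params["out.b"] = np.zeros(2)
        self.params = {k: v.astype(self.dtype) for k, v in self.params.items()}

    def _layer_params(self, layer: int) -> dict:
        return {k: self.params[f"{layer}.{k}"] for k in _LAYER_KEYS}

    def forward(
        self, X: np.ndarray, training: bool = False,
        rng: np.random.Generator | None = None,
    ):
        """Return softmax probabilities (N, 2) and a cache for backward."""
        seq = np.ascontiguousarray(X, dtype=self.dtype)
        layer_caches = []
        for layer in range(self.n_layers):
            hidden, cache = _gru_layer_forward(seq, self._layer_params(layer))
            mask = None
            if training and self.dropout > 0.0:
                keep = 1.0 - self.dropout
                u = rng.random(hidden.shape, dtype=np.float32)
                mask = (u < keep).astype(self.dtype) / keep
                hidden = hidden * mask
            layer_caches.append((cache, mask))
            seq = hidden
        last = seq[:, -1, :]
        logits = last @ self.params["out.W"] + self.params["out.b"]
        probs = softmax(logits, axis=1)
        fwd_cache = (X, layer_caches, last, probs)
        return probs, fwd_cache

    def backward(self, fwd_cache, y: np.ndarray, sample_weight=None) -> dict:
        """Gradients of mean cross-entropy w.r.t. every parameter."""
        X, layer_caches, last, probs = fwd_cache
        N = len(y)
        dlogits = probs.astype(self.dtype)
        dlogits[np.arange(N), y] -= 1.0
        if sample_weight is not None:
            w = np.asarray(sample_weight, dtype=self.dtype)
            dlogits *= (w / w.sum())[:, None]
        else:
            dlogits /= N
        grads = {
            "out.W": last.T @ dlogits,
            "out.b": dlogits.sum(axis=0),
        }
        dlast = dlogits @ self.params["out.W"].T
        T = X.shape[1]
        dseq = np.zeros((N, T, self.hidden), dtype=self.dtype)
        dseq[:, -1, :] = dlast
        for layer in range(self.n_layers - 1, -1, -1):
            cache, mask = layer_caches[layer]
            if mask is not None:
                dseq = dseq * mask
            layer_grads, dseq = _gru_layer_backward(
                dseq, cache, self._layer_params(layer)
            )
            for k, g in layer_grads.items():
                grads[f"{layer}.{k}"] = g
        return grads

    def predict_proba(self, X: np.ndarray, batch_size: int = 4096) -> np.ndarray:
        """Event-class probability per window, inference mode (no dropout)."""
        out = np.empty(len(X))
        for start in range(0, len(X), batch_size):
            probs, _ = self.forward(X[start : start + batch_size], training=False)
            out[start : start + batch_size] = probs[:, 1]
        return out

    def copy(self) -> "GRUClassifier":
        clone = GRUClassifier.__new__(GRUClassifier)
        clone.__dict__.update(
            {k: v for k, v in self.__dict__.items() if k != "params"}
        )
        clone.params = {k: v.copy() for k, v in self.params.items()}
        return clone


class Adam:
    """Adam optimiser with the conventional default parameters."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1 ** self.t)
            v_hat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
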