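"""Temporal-relation branch: sliding-window covariance sequences and the LSTM.

A 9 s, 30-channel trial is divided into seven 3 s segments with a 1 s step.
Each segment's regularized covariance matrix is half-vectorized (diagonal plus
lower triangle, row-major) into a 465-element vector ``m_t``; the ordered
sequence ``[m_1, ..., m_7]`` describes how the inter-channel relations evolve
across the trial.  A 2-layer LSTM, unrolled over the seven steps, maps the
sequence to the final hidden state of the second layer, the temporal feature
vector fed to the fusion classifier.

The LSTM is implemented directly in NumPy (batched forward and
backpropagation-through-time) with the conventional gate layout
``z = x W_x + h W_h + b`` split into input/forget/cell/output gates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spd import covariance

__all__ = [
    "segment_trial",
    "vech_lower",
    "unvech",
    "vech_length",
    "trial_to_sequence",
    "LSTMLayerParams",
    "LSTMParams",
    "init_lstm",
    "lstm_forward",
    "lstm_backward",
    "lstm_apply_grads",
]

N_SEGMENTS = 7  # 9 s trial, 3 s window, 1 s step


def segment_trial(
    X: np.ndarray,
    win: float = 3.0,
    step: float = 1.0,
    fs: float = 250.0,
) -> np.ndarray:
    """Slice a ``(channels, samples)`` signal into overlapping windows.

    Returns an array of shape ``(n_segments, channels, win*fs)`` where
    ``n_segments = floor((T - win)/step) + 1`` and segment ``t`` covers the
    half-open sample interval ``[t*step*fs, t*step*fs + win*fs)``.
    """
    X = np.asarray(X)
    if X.ndim != 2:
        raise ValueError(f"expected (channels, samples), got shape {X.shape}")
    n_samp = X.shape[1]
    w = int(round(win * fs))
    s = int(round(step * fs))
    if w > n_samp:
        raise ValueError(f"window of {w} samples exceeds signal length {n_samp}")
    n_seg = (n_samp - w) // s + 1
    return np.stack([X[:, t * s : t * s + w] for t in range(n_seg)])


def vech_length(n: int) -> int:
    return n * (n + 1) // 2


def vech_lower(C: np.ndarray) -> np.ndarray:
    """Half-vectorize a symmetric matrix: rows ``i``, columns ``j <= i``.

    The 2x2 matrix ``[[a, b], [b, c]]`` maps to ``(a, b, c)``; a 30x30
    matrix maps to a 465-vector.
    """
    C = np.asarray(C)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {C.shape}")
    i, j = np.tril_indices(C.shape[0])
    return C[i, j]


def unvech(v: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vech_lower`; reconstructs the symmetric matrix."""
    v = np.asarray(v)
    m = v.shape[-1]
    n = int((np.sqrt(8 * m + 1) - 1) / 2)
    if vech_length(n) != m:
        raise ValueError(f"length {m} is not a triangular number")
    C = np.zeros(v.shape[:-1] + (n, n), dtype=v.dtype)
    i, j = np.tril_indices(n)
    C[..., i, j] = v
    C[..., j, i] = v
    return C


def trial_to_sequence(
    trial: np.ndarray,
    win: float = 3.0,
    step: float = 1.0,
    fs: float = 250.0,
    eps: float = 1e-8,
) -> np.ndarray:
    """Covariance sequence of a trial: shape ``(7, 465)`` for a 9 s, 30-channel trial.

    Each segment is mean-centered per channel, its covariance estimated and
    eigenvalue-floored, then half-vectorized.
    """
    segs = segment_trial(trial, win=win, step=step, fs=fs)
    return np.stack([vech_lower(covariance(seg, eps=eps)) for seg in segs])


# ---------------------------------------------------------------------------
# LSTM
# ---------------------------------------------------------------------------


@dataclass
class LSTMLayerParams:
    wx: np.ndarray  # (input_size, 4*hidden)
    wh: np.ndarray  # (hidden, 4*hidden)
    b: np.ndarray  # (4*hidden,)

    @property
    def hidden_size(self) -> int:
        return self.wh.shape[0]

    def copy(self) -> "LSTMLayerParams":
        return LSTMLayerParams(self.wx.copy(), self.wh.copy(), self.b.copy())


@dataclass
class LSTMParams:
    """Weights of the stacked (two-layer by default) LSTM."""

    layers: list

    @property
    def hidden_size(self) -> int:
        return self.layers[-1].hidden_size

    def copy(self) -> "LSTMParams":
        return LSTMParams([l.copy() for l in self.layers])


def init_lstm(
    input_size: int,
    hidden_size: int = 64,
    n_layers: int = 2,
    forget_bias: float = 1.0,
    rng: np.random.Generator | None = None,
) -> LSTMParams:
    """Small-uniform initialization with a positive forget-gate bias."""
    rng = np.random.default_rng(rng)
    layers = []
    in_size = input_size
    k = 1.0 / np.sqrt(hidden_size)
    for _ in range(n_layers):
        wx = rng.uniform(-k, k, size=(in_size, 4 * hidden_size))
        wh = rng.uniform(-k, k, size=(hidden_size, 4 * hidden_size))
        b = np.zeros(4 * hidden_size)
        b[hidden_size : 2 * hidden_size] = forget_bias
        layers.append(LSTMLayerParams(wx, wh, b))
        in_size = hidden_size
    return LSTMParams(layers)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (np.tanh(0.5 * x) + 1.0)


def lstm_forward(
    x: np.ndarray,
    params: LSTMParams,
    strict: bool = True,
    return_cache: bool = False,
):
    """Run the stacked LSTM over a batch of sequences.

    Parameters
    ----------
    x : (batch, steps, features) array; ``strict=True`` requires exactly
        seven steps, the trial segmentation contract.

    Returns the final hidden state of the top layer, shape
    ``(batch, hidden_size)``, plus the BPTT cache when requested.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 2:
        x = x[None]
    if x.ndim != 3:
        raise ValueError(f"expected (batch, steps, features), got shape {x.shape}")
    if strict and x.shape[1] != N_SEGMENTS:
        raise ValueError(
            f"expected {N_SEGMENTS}-step sequences (strict mode), got {x.shape[1]}"
        )
    B, T, _ = x.shape
    cache = []
    inp = x
    for layer in params.layers:
        H = layer.hidden_size
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        steps = []
        hs = np.empty((B, T, H))
        for t in range(T):
            xt = inp[:, t]
            z = xt @ layer.wx + h @ layer.wh + layer.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            steps.append((xt, h, c, i, f, g, o, c_new, tc))
            h, c = h_new, c_new
            hs[:, t] = h
        cache.append((layer, steps, hs))
        inp = hs
    out = inp[:, -1]
    if return_cache:
        return out, cache
    return out


def lstm_backward(cache, grad_out: np.ndarray):
    """Backpropagation through time from a gradient on the final hidden state.

    Returns a list of per-layer dicts with keys ``wx``, ``wh``, ``b``.
    """
    grads = []
    upper_dh = None  # (B, T, H) gradient flowing into each layer's hidden sequence
    for li in range(len(cache) - 1, -1, -1):
        layer, steps, hs = cache[li]
        H = layer.hidden_size
        T = len(steps)
        B = hs.shape[0]
        dwx = np.zeros_like(layer.wx)
        dwh = np.zeros_like(layer.wh)
        db = np.zeros_like(layer.b)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        dinp = np.zeros((B, T, layer.wx.shape[0]))
        for t in range(T - 1, -1, -1):
            xt, h_prev, c_prev, i, f, g, o, c_new, tc = steps[t]
            dh = dh_next.copy()
            if li == len(cache) - 1:
                if t == T - 1:
                    dh += grad_out
            else:
                dh += upper_dh[:, t]
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dwx += xt.T @ dz
            dwh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dh_next = dz @ layer.wh.T
            dinp[:, t] = dz @ layer.wx.T
        grads.insert(0, {"wx": dwx, "wh": dwh, "b": db})
        upper_dh = dinp
    return grads


def lstm_apply_grads(params: LSTMParams, grads, lr: float) -> None:
    """In-place plain gradient step on every layer."""
    for layer, g in zip(params.layers, grads):
        if any(not np.all(np.isfinite(v)) for v in g.values()):
            raise FloatingPointError("non-finite LSTM gradient")
        layer.wx -= lr * g["wx"]
        layer.wh -= lr * g["wh"]
        layer.b -= lr * g["b"]
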