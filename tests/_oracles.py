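"""Independent reference implementations used to validate the package.

Everything here is deliberately written in the most naive way possible
(explicit loops, textbook formulas, bisection) and shares no code with the
implementation it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def two_pass_covariance(X: np.ndarray) -> np.ndarray:
    """Textbook two-pass sample covariance of a (channels, samples) block."""
    X = np.asarray(X, dtype=float)
    n, q = X.shape
    mean = np.array([sum(X[i]) / q for i in range(n)])
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            C[i, j] = sum((X[i, t] - mean[i]) * (X[j, t] - mean[j]) for t in range(q))
    return C / (q - 1)


def stein_scalar(a: float, b: float) -> float:
    """Symmetric Stein divergence for 1x1 matrices."""
    return np.log((a + b) / 2.0) - 0.5 * np.log(a * b)


def center_1x1_bisection(values, lo=1e-8, hi=1e8, tol=1e-14) -> float:
    """Scalar Stein barycenter: root of the stationarity condition by bisection."""

    def grad(c):
        return sum(2.0 / (v + c) for v in values) - len(values) / c

    flo, fhi = grad(lo), grad(hi)
    assert flo * fhi < 0, "bracket does not straddle the root"
    while hi - lo > tol * max(1.0, hi):
        mid = 0.5 * (lo + hi)
        if grad(lo) * grad(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def pearson_naive(u, v) -> float:
    """Pearson correlation straight from the defining sums."""
    u = list(map(float, u))
    v = list(map(float, v))
    n = len(u)
    mu = sum(u) / n
    mv = sum(v) / n
    num = sum((a - mu) * (b - mv) for a, b in zip(u, v))
    du = sum((a - mu) ** 2 for a in u) ** 0.5
    dv = sum((b - mv) ** 2 for b in v) ** 0.5
    return num / (du * dv)


def zeta_brute_force(M_V, M_D, combo, omega=0.9, intra_pairs="unordered",
                     cross_matched=True):
    """Explicit pair-enumeration of the four zeta component sums."""
    M_V = np.asarray(M_V, dtype=float)
    M_D = np.asarray(M_D, dtype=float)
    combo = list(combo)

    def phi_vv(i, j):
        return pearson_naive(M_V[:, i], M_V[:, j])

    def phi_dd(i, j):
        return pearson_naive(M_D[:, i], M_D[:, j])

    def phi_vd(i, j):
        return pearson_naive(M_V[:, i], M_D[:, j])

    if intra_pairs == "unordered":
        pairs = list(combinations(combo, 2))
    else:
        pairs = [(i, j) for i in combo for j in combo if i != j]
    gamma = sum(np.exp(phi_vv(i, j) - omega) for i, j in pairs)
    theta = sum(np.exp(phi_dd(i, j) - omega) for i, j in pairs)
    upsilon = sum((phi_vv(i, j) - phi_dd(i, j)) ** 2 for i, j in pairs)
    phi = 0.0
    for i in combo:
        for j in combo:
            if i == j and not cross_matched:
                continue
            phi += np.exp(phi_vd(i, j))
    zeta = (gamma + theta) / (phi + upsilon)
    return gamma, theta, phi, upsilon, zeta


def lstm_reference(x, params):
    """Gate-by-gate, sample-by-sample LSTM recurrence (no batching, no tricks)."""

    def sig(v):
        return 1.0 / (1.0 + np.exp(-v))

    x = np.asarray(x, dtype=float)
    outputs = []
    for sample in x:
        inp = [row for row in sample]
        for layer in params.layers:
            H = layer.wh.shape[0]
            h = np.zeros(H)
            c = np.zeros(H)
            seq = []
            for xt in inp:
                z = xt @ layer.wx + h @ layer.wh + layer.b
                i = sig(z[0:H])
                f = sig(z[H : 2 * H])
                g = np.tanh(z[2 * H : 3 * H])
                o = sig(z[3 * H : 4 * H])
                c = f * c + i * g
                h = o * np.tanh(c)
                seq.append(h)
            inp = seq
        outputs.append(inp[-1])
    return np.stack(outputs)


def random_spd(rng, n, cond=5.0):
    """Random SPD matrix with controlled conditioning."""
    Q, _ = np.linalg.qr(rng.standard_normal((n, n)))
    lam = np.exp(rng.uniform(-np.log(cond) / 2, np.log(cond) / 2, size=n))
    return (Q * lam) @ Q.T


def confusion_metrics_naive(tp, fn, tn, fp):
    """Percent metrics straight from the defining ratios (drowsy positive)."""
    acc = 100.0 * (tp + tn) / (tp + fn + tn + fp)
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp)
    prec = 100.0 * tp / (tp + fp)
    f1 = 2 * prec * sens / (prec + sens)
    return acc, sens, spec, f1
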