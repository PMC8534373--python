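"""Brain-state analysis through the forward problem of source conduction.

Given an inverse-solution transform ``W`` (channels x sources) mapping scalp
signals to source activity ``s = W^T x``, and the diagonal source covariance
``Sigma_s`` (sources assumed mutually independent), the forward weight matrix
relating sources back to channels satisfies ``Sigma_x W = A Sigma_s`` and is
recovered in closed form as

    A = Sigma_x W Sigma_s^{-1}.

Averaging per-trial ``A`` within each driving state gives class weight
matrices; each column is the weight assignment of one source onto all
channels.  A location-scale Student-t distribution is fitted to each column,
and the discrete Kullback-Leibler divergence between the two fitted densities
(on a shared grid) quantifies how much that source's weight assignment
differs between the fatigue and vigilant states; per-source divergences are
min-max normalized to [0, 1] for comparison.

The transform ``W`` is an input: supply one from an external inverse solution
or generate a synthetic semi-orthogonal stand-in via
:func:`synthetic_transform`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SourceModel",
    "synthetic_transform",
    "estimate_source_variances",
    "forward_weights",
    "class_weight_matrices",
    "fit_t",
    "t_density_grid",
    "kl_divergence",
    "normalize_kl",
    "source_kl_report",
]

DEFAULT_K = 364  # source count of the default head model geometry


@dataclass(frozen=True)
class SourceModel:
    """Transform and source-variance bundle of the forward problem."""

    W: np.ndarray  # (channels, sources)
    sigma_s: np.ndarray  # (sources,) positive variances (diagonal Sigma_s)

    def __post_init__(self):
        if self.W.shape[1] != self.sigma_s.shape[0]:
            raise ValueError("W columns and sigma_s length must match")
        if np.any(self.sigma_s <= 0):
            raise ValueError("source variances must be positive (Sigma_s invertible)")


def synthetic_transform(
    n_channels: int = 30, n_sources: int = DEFAULT_K, seed: int = 0
) -> np.ndarray:
    """Synthetic stand-in for an inverse-solution transform.

    A random matrix with orthonormal *rows* (semi-orthogonal), so no channel
    direction is degenerate; it is a fixture for pipelines lacking a real
    head-model solution, not a physical model.
    """
    rng = np.random.default_rng(seed)
    G = rng.standard_normal((n_channels, n_sources))
    if n_sources >= n_channels:  # usual case: many sources, orthonormal rows
        Q, R = np.linalg.qr(G.T)
        return (Q * np.sign(np.diag(R))).T
    Q, R = np.linalg.qr(G)  # fewer sources than channels: orthonormal columns
    return Q * np.sign(np.diag(R))


def estimate_source_variances(sigma_x: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Diagonal of the source covariance ``W^T Sigma_x W``.

    Off-diagonal entries are discarded under the independent-sources
    assumption; the diagonal is what ``Sigma_s`` needs.
    """
    v = np.einsum("ik,ij,jk->k", W, sigma_x, W, optimize=True)
    return np.asarray(v, dtype=float)


def forward_weights(sigma_x: np.ndarray, W: np.ndarray, sigma_s: np.ndarray) -> np.ndarray:
    """Closed-form forward weights ``A = Sigma_x W Sigma_s^{-1}``.

    ``sigma_s`` is the vector of source variances (the diagonal).  The result
    satisfies ``Sigma_x W = A Sigma_s`` exactly.
    """
    sigma_s = np.asarray(sigma_s, dtype=float)
    if sigma_s.ndim == 2:
        sigma_s = np.diag(sigma_s)
    if np.any(sigma_s == 0):
        raise ValueError("Sigma_s is singular: zero source variance")
    return (np.asarray(sigma_x, dtype=float) @ W) / sigma_s


def class_weight_matrices(covs, labels, W: np.ndarray, sigma_s: np.ndarray):
    """Per-class averages of the per-trial forward weight matrices.

    Returns ``(A_fatigue, A_vigilant)`` with labels 1 = fatigue/drowsy,
    0 = vigilant.
    """
    labels = np.asarray(labels)
    covs = list(covs)
    groups = {}
    for cls in (1, 0):
        sel = [C for C, y in zip(covs, labels) if y == cls]
        if not sel:
            raise ValueError(f"class {cls} is empty")
        groups[cls] = np.mean([forward_weights(C, W, sigma_s) for C in sel], axis=0)
    return groups[1], groups[0]


def fit_t(weights) -> tuple:
    """Maximum-likelihood location-scale Student-t fit of one weight column.

    Returns ``(df, loc, scale)``; raises on degenerate (constant or too short)
    input.
    """
    w = np.asarray(weights, dtype=float)
    if w.size < 10:
        raise ValueError("need at least 10 values for a stable t fit")
    if np.ptp(w) == 0:
        raise ValueError("constant weight column; add jitter before fitting")
    df, loc, scale = stats.t.fit(w)
    return float(df), float(loc), float(scale)


def t_density_grid(params_p: tuple, params_q: tuple, n_grid: int = 512,
                   span: float = 6.0):
    """Shared evaluation grid and normalized discrete densities of two t fits.

    The grid spans both fits' ``loc +- span * scale``; the densities are
    normalized to sum to one over the grid cells.
    """
    lo = min(params_p[1] - span * params_p[2], params_q[1] - span * params_q[2])
    hi = max(params_p[1] + span * params_p[2], params_q[1] + span * params_q[2])
    grid = np.linspace(lo, hi, n_grid)
    p = stats.t.pdf(grid, *params_p)
    q = stats.t.pdf(grid, *params_q)
    return grid, p / p.sum(), q / q.sum()


def kl_divergence(P, Q) -> float:
    """Discrete Kullback-Leibler divergence ``sum_i P_i log(P_i / Q_i)`` (natural log).

    ``P`` and ``Q`` must be normalized over the same grid, and ``Q`` must be
    positive wherever ``P`` is.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError("P and Q must share a grid")
    if not (np.isclose(P.sum(), 1.0, atol=1e-6) and np.isclose(Q.sum(), 1.0, atol=1e-6)):
        raise ValueError("P and Q must each sum to 1")
    support = P > 0
    if np.any(Q[support] <= 0):
        raise ValueError("Q vanishes on the support of P")
    return float(np.sum(P[support] * np.log(P[support] / Q[support])))


def normalize_kl(values) -> np.ndarray:
    """Min-max scale per-source divergences to [0, 1]."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        warnings.warn("all divergences equal; normalized values set to 0", stacklevel=2)
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def source_kl_report(covs, labels, W: np.ndarray, sigma_s=None,
                     n_grid: int = 512) -> "pd.DataFrame":
    """Per-source t fits of both class weight columns and their KL divergence.

    ``sigma_s`` defaults to the source variances estimated from the pooled
    mean covariance.  Returns a DataFrame with one row per source.
    """
    import pandas as pd

    covs = list(covs)
    if sigma_s is None:
        sigma_s = estimate_source_variances(np.mean(covs, axis=0), W)
    a_fat, a_vig = class_weight_matrices(covs, labels, W, sigma_s)
    rows = []
    for k in range(W.shape[1]):
        pf = fit_t(a_fat[:, k])
        pv = fit_t(a_vig[:, k])
        _, P, Q = t_density_grid(pf, pv, n_grid=n_grid)
        rows.append(
            {
                "source": k,
                "df_fatigue": pf[0], "loc_fatigue": pf[1], "scale_fatigue": pf[2],
                "df_vigilant": pv[0], "loc_vigilant": pv[1], "scale_vigilant": pv[2],
                "kl": kl_divergence(P, Q),
            }
        )
    df = pd.DataFrame(rows)
    df["kl_normalized"] = normalize_kl(df["kl"].to_numpy())
    return df
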