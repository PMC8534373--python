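"""Symmetric positive-definite (SPD) covariance primitives.

This module provides the building blocks shared by every stage of the
pipeline: channel-covariance estimation, eigenvalue-floor regularization,
the symmetric Stein divergence between SPD matrices, and the fixed-point
iteration that computes the Stein barycenter ("center") of a set of
covariance matrices.  The Stein divergence between two SPD matrices
``A`` and ``B`` is

    S(A, B) = log det((A + B) / 2) - (1/2) log det(A B)

which is symmetric, nonnegative, vanishes iff ``A == B`` and is invariant
under congruence ``A -> G A G^T`` for invertible ``G``.  The center of a
set ``{C_i}`` minimizes the summed squared divergence and is found by
iterating

    C_new = ( (1/M) sum_i ((C_i + C)/2)^{-1} )^{-1}

from the arithmetic mean.  Distances from a trial covariance to the
vigilant/drowsy class centers form the two-dimensional distance feature
used by the fusion classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "covariance",
    "regularize_spd",
    "stein_divergence",
    "stein_center",
    "center_gradient_residual",
    "class_centers",
    "distance_features",
    "CenterResult",
    "CenterPair",
    "is_spd",
    "logdet_spd",
    "SYMMETRY_RTOL",
]

#: relative symmetry tolerance: max|A - A^T| <= SYMMETRY_RTOL * scale
SYMMETRY_RTOL = 1e-10

#: default eigenvalue floor applied to estimated covariances
DEFAULT_EPS = 1e-8


def _check_symmetric(C: np.ndarray, name: str = "matrix") -> None:
    C = np.asarray(C)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError(f"{name} must be square, got shape {C.shape}")
    scale = max(float(np.max(np.abs(C))), 1.0)
    asym = float(np.max(np.abs(C - C.T)))
    if asym > SYMMETRY_RTOL * scale:
        raise ValueError(
            f"{name} is not symmetric: max|A - A^T| = {asym:.3e} "
            f"exceeds {SYMMETRY_RTOL:.1e} * scale"
        )


def is_spd(C: np.ndarray) -> bool:
    """True if ``C`` is symmetric and admits a Cholesky factorization."""
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        return False
    scale = max(float(np.max(np.abs(C))), 1.0)
    if float(np.max(np.abs(C - C.T))) > SYMMETRY_RTOL * scale:
        return False
    try:
        np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        return False
    return True


def logdet_spd(C: np.ndarray) -> float:
    """log determinant of an SPD matrix via its Cholesky factor.

    Numerically stable for near-singular matrices; raises
    ``numpy.linalg.LinAlgError`` if ``C`` is not positive definite.
    """
    L = np.linalg.cholesky(np.asarray(C, dtype=float))
    return 2.0 * float(np.sum(np.log(np.diag(L))))


def covariance(
    X: np.ndarray,
    eps: float = DEFAULT_EPS,
    center: bool = True,
    regularize: bool = True,
) -> np.ndarray:
    """Channel covariance ``C = X X^T / (Q - 1)`` of a ``(channels, samples)`` block.

    The model assumes zero-mean signals; ``center=True`` enforces the
    assumption by removing the empirical per-channel mean before the outer
    product.  The result is eigenvalue-floored at ``eps`` unless
    ``regularize=False``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"expected 2-D (channels, samples) array, got shape {X.shape}")
    q = X.shape[1]
    if q < 2:
        raise ValueError(f"need at least 2 samples to estimate a covariance, got {q}")
    if center:
        X = X - X.mean(axis=1, keepdims=True)
    C = (X @ X.T) / (q - 1)
    C = 0.5 * (C + C.T)
    if regularize:
        C = regularize_spd(C, eps)
    return C


def regularize_spd(C: np.ndarray, eps: float = DEFAULT_EPS) -> np.ndarray:
    """Floor the eigenvalues of a symmetric matrix at ``eps``.

    Eigenvectors are preserved: ``C = U max(L, eps I) U^T``.  Raises if the
    input is not symmetric or ``eps`` is not positive.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    C = np.asarray(C, dtype=float)
    _check_symmetric(C, "regularize_spd input")
    lam, U = np.linalg.eigh(C)
    if lam[0] > eps:
        return 0.5 * (C + C.T)
    lam = np.where(lam > eps, lam, eps)
    out = (U * lam) @ U.T
    return 0.5 * (out + out.T)


def stein_divergence(A: np.ndarray, B: np.ndarray, form: str = "symmetric") -> float:
    """Stein divergence between two SPD matrices of equal size.

    ``form="symmetric"`` (default) is the symmetric Stein / S-divergence
    ``log det((A+B)/2) - (1/2) log det(AB)``; ``form="literal"`` drops the
    one-half exponent on the product term (``log det((A+B)/2) - log det(AB)``),
    a variant kept for comparison although it is neither nonnegative nor
    scale-consistent.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"size mismatch: {A.shape} vs {B.shape}")
    mid = logdet_spd(0.5 * (A + B))
    ld = logdet_spd(A) + logdet_spd(B)
    if form == "symmetric":
        val = mid - 0.5 * ld
        # clip the tiny negative values produced by rounding when A ~= B
        return max(val, 0.0) if val > -1e-12 * max(abs(mid), 1.0) else val
    if form == "literal":
        return mid - ld
    raise ValueError(f"unknown form {form!r}; expected 'symmetric' or 'literal'")


@dataclass(frozen=True)
class CenterResult:
    """Stein barycenter of a set of SPD matrices with convergence diagnostics."""

    matrix: np.ndarray
    iterations: int
    residual: float  #: Frobenius norm of the last fixed-point step
    converged: bool
    residuals: tuple = ()  #: per-iteration step norms


@dataclass(frozen=True)
class CenterPair:
    """Class centers of the two driving states, computed on training trials only."""

    vigilant: CenterResult
    drowsy: CenterResult

    @property
    def matrices(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vigilant.matrix, self.drowsy.matrix


def stein_center(
    matrices,
    thre: float = 1e-9,
    max_iter: int = 50,
) -> CenterResult:
    """Fixed-point Stein barycenter of ``matrices``.

    Starts from the arithmetic mean and iterates
    ``C_new = ((1/M) sum_i ((C_i + C)/2)^{-1})^{-1}`` until the Frobenius
    change drops below ``thre`` or ``max_iter`` iterations are reached.
    Every input must be SPD (checked before iterating).
    """
    mats = [np.asarray(C, dtype=float) for C in matrices]
    if len(mats) == 0:
        raise ValueError("need at least one matrix")
    for k, C in enumerate(mats):
        if not is_spd(C):
            raise ValueError(f"input matrix {k} is not SPD")
    stack = np.stack(mats)
    center = stack.mean(axis=0)
    residual = np.inf
    history = []
    it = 0
    while it < max_iter:
        inv_mid = np.linalg.inv(0.5 * (stack + center))
        new = np.linalg.inv(inv_mid.mean(axis=0))
        new = 0.5 * (new + new.T)
        residual = float(np.linalg.norm(new - center))
        history.append(residual)
        center = new
        it += 1
        if residual < thre:
            break
    return CenterResult(matrix=center, iterations=it, residual=residual,
                        converged=residual < thre, residuals=tuple(history))


def center_gradient_residual(center: np.ndarray, matrices) -> float:
    """Frobenius norm of the barycenter stationarity condition.

    At the optimum, ``sum_i ((C + C_i)/2)^{-1} - M C^{-1} = 0``; the norm of
    the left-hand side measures how close a candidate center is.
    """
    mats = np.stack([np.asarray(C, dtype=float) for C in matrices])
    g = np.linalg.inv(0.5 * (mats + center)).sum(axis=0)
    g -= len(mats) * np.linalg.inv(center)
    return float(np.linalg.norm(g))


def class_centers(
    covs,
    labels,
    thre: float = 1e-9,
    max_iter: int = 50,
) -> CenterPair:
    """Stein centers of the vigilant (label 0) and drowsy (label 1) covariances."""
    labels = np.asarray(labels)
    covs = list(covs)
    vig = [C for C, y in zip(covs, labels) if y == 0]
    dro = [C for C, y in zip(covs, labels) if y == 1]
    if not vig or not dro:
        raise ValueError("both classes must be present to compute class centers")
    return CenterPair(
        vigilant=stein_center(vig, thre=thre, max_iter=max_iter),
        drowsy=stein_center(dro, thre=thre, max_iter=max_iter),
    )


def distance_features(C_trial: np.ndarray, centers: CenterPair) -> np.ndarray:
    """Two-vector of Stein distances to the class centers, vigilant first."""
    cv, cd = centers.matrices
    return np.array(
        [stein_divergence(C_trial, cv), stein_divergence(C_trial, cd)], dtype=float
    )
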