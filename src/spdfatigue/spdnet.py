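"""SPD network: bilinear maps, eigenvalue rectification and log-eigenvalue flattening.

The spatial branch projects each whole-trial covariance matrix through the
stack BiMap -> ReEig -> BiMap -> LogEig:

* BiMap: ``X -> W^T X W`` with a full-column-rank (by default semi-orthogonal)
  map ``W``, reducing dimension while staying on the SPD cone;
* ReEig: eigenvalues below a rectification threshold are replaced by the
  threshold, the nonlinearity of the network;
* LogEig: ``X -> U log(L) U^T`` maps the SPD manifold to its tangent space so
  ordinary Euclidean operations (flattening, inner products) apply.

The final symmetric matrix is half-vectorized into the spatial feature vector.
Gradients are derived by hand: the backward pass through both eigenvalue
layers uses the Daleckii-Krein formula for derivatives of matrix functions,
with a pairwise eigenvalue-difference floor for near-degenerate spectra, and
the maps ``W`` are retracted back to the Stiefel manifold by QR after each
Euclidean step (retraction can be disabled to train unconstrained full-rank
maps instead).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .temporal import vech_length, vech_lower

__all__ = [
    "SPDNetParams",
    "init_spdnet",
    "bimap",
    "reeig",
    "logeig",
    "spdnet_forward",
    "spdnet_backward",
    "spdnet_apply_grads",
]

#: floor on pairwise eigenvalue differences in the Daleckii-Krein backward
EIG_DIFF_FLOOR = 1e-12


@dataclass
class SPDNetParams:
    """Weights of the two bilinear maps plus the rectification threshold."""

    w1: np.ndarray  # (d0, d1)
    w2: np.ndarray  # (d1, d2)
    eps_rect: float = 1e-4
    stiefel: bool = True  # retract maps to semi-orthogonal columns after updates

    @property
    def out_dim(self) -> int:
        return vech_length(self.w2.shape[1])

    def copy(self) -> "SPDNetParams":
        return SPDNetParams(self.w1.copy(), self.w2.copy(), self.eps_rect, self.stiefel)


def init_spdnet(
    d0: int = 30,
    d1: int = 24,
    d2: int = 16,
    eps_rect: float = 1e-4,
    stiefel: bool = True,
    rng: np.random.Generator | None = None,
) -> SPDNetParams:
    """Semi-orthogonal random initialization of both maps."""
    rng = np.random.default_rng(rng)
    if not (d0 >= d1 >= d2 >= 1):
        raise ValueError(f"layer sizes must satisfy d0 >= d1 >= d2 >= 1, got {(d0, d1, d2)}")
    w1 = _orthonormal_columns(rng.standard_normal((d0, d1)))
    w2 = _orthonormal_columns(rng.standard_normal((d1, d2)))
    return SPDNetParams(w1, w2, eps_rect=eps_rect, stiefel=stiefel)


def _orthonormal_columns(W: np.ndarray) -> np.ndarray:
    Q, R = np.linalg.qr(W)
    # fix signs so the retraction is a deterministic, continuous map
    return Q * np.sign(np.diag(R))


def _validate_map(W: np.ndarray) -> None:
    W = np.asarray(W)
    if W.ndim != 2 or W.shape[0] < W.shape[1]:
        raise ValueError(f"map must be a tall (n, m) matrix with n >= m, got {W.shape}")
    if np.linalg.matrix_rank(W) < W.shape[1]:
        raise ValueError("bilinear map is rank deficient")


def bimap(X: np.ndarray, W: np.ndarray, validate: bool = True) -> np.ndarray:
    """Bilinear map ``W^T X W`` (batched over a leading axis if present)."""
    if validate:
        _validate_map(W)
    X = np.asarray(X, dtype=float)
    Y = np.einsum("ik,...ij,jl->...kl", W, X, W, optimize=True)
    return 0.5 * (Y + np.swapaxes(Y, -1, -2))


def _sym(G: np.ndarray) -> np.ndarray:
    return 0.5 * (G + np.swapaxes(G, -1, -2))


def _eig_fn(X: np.ndarray, h, hprime):
    """Apply the scalar function ``h`` to the eigenvalues of symmetric ``X``.

    Returns the transformed matrices plus the cache needed by
    :func:`_eig_fn_backward`.
    """
    X = _sym(np.asarray(X, dtype=float))
    lam, U = np.linalg.eigh(X)
    hl = h(lam)
    Y = np.einsum("...ik,...k,...jk->...ij", U, hl, U, optimize=True)
    return _sym(Y), (U, lam, hl, hprime(lam))


def _eig_fn_backward(G: np.ndarray, cache) -> np.ndarray:
    """Daleckii-Krein backward through an eigenvalue function.

    ``grad_X = U (P o (U^T G U)) U^T`` with the first-divided-difference
    matrix ``P_ij = (h(l_i) - h(l_j)) / (l_i - l_j)``, replaced by ``h'`` on
    (near-)coincident eigenvalue pairs.
    """
    U, lam, hl, hpl = cache
    G = _sym(np.asarray(G, dtype=float))
    M = np.einsum("...ki,...kl,...lj->...ij", U, G, U, optimize=True)
    dl = lam[..., :, None] - lam[..., None, :]
    num = hl[..., :, None] - hl[..., None, :]
    hp_mid = 0.5 * (hpl[..., :, None] + hpl[..., None, :])
    P = np.where(np.abs(dl) > EIG_DIFF_FLOOR, num / np.where(dl == 0, 1.0, dl), hp_mid)
    out = np.einsum("...ik,...kl,...jl->...ij", U, P * M, U, optimize=True)
    return _sym(out)


def reeig(X: np.ndarray, eps_rect: float = 1e-4, return_cache: bool = False):
    """Eigenvalue rectification: eigenvalues below ``eps_rect`` are raised to it."""
    if eps_rect <= 0:
        raise ValueError("eps_rect must be positive")
    Y, cache = _eig_fn(
        X,
        lambda l: np.maximum(l, eps_rect),
        lambda l: (l > eps_rect).astype(float),
    )
    return (Y, cache) if return_cache else Y


def logeig(X: np.ndarray, return_cache: bool = False):
    """Matrix logarithm of an SPD matrix, ``U log(L) U^T``."""
    X = np.asarray(X, dtype=float)
    lam = np.linalg.eigvalsh(_sym(X))
    if np.any(lam <= 0):
        raise ValueError("logeig requires a positive-definite input")
    Y, cache = _eig_fn(X, np.log, lambda l: 1.0 / l)
    return (Y, cache) if return_cache else Y


def spdnet_forward(
    C: np.ndarray,
    params: SPDNetParams,
    return_cache: bool = False,
):
    """Map trial covariances to spatial feature vectors.

    ``C`` is a single ``(n, n)`` SPD matrix or a batch ``(B, n, n)``; the
    output is the half-vectorized LogEig matrix, length ``d2*(d2+1)/2`` per
    trial.
    """
    C = np.asarray(C, dtype=float)
    single = C.ndim == 2
    X0 = C[None] if single else C
    if X0.shape[-1] != params.w1.shape[0]:
        raise ValueError(
            f"input dimension {X0.shape[-1]} does not match W1 rows {params.w1.shape[0]}"
        )
    X1 = bimap(X0, params.w1, validate=False)
    X2, cache_re = reeig(X1, params.eps_rect, return_cache=True)
    X3 = bimap(X2, params.w2, validate=False)
    X4, cache_log = logeig(X3, return_cache=True)
    i, j = np.tril_indices(X4.shape[-1])
    feats = X4[..., i, j]
    if single:
        feats = feats[0]
    if return_cache:
        return feats, (X0, X1, X2, X3, cache_re, cache_log, params)
    return feats


def _vech_grad_to_sym(g: np.ndarray, n: int) -> np.ndarray:
    """Lift a gradient on vech entries to the symmetrized matrix gradient."""
    G = np.zeros(g.shape[:-1] + (n, n), dtype=float)
    i, j = np.tril_indices(n)
    G[..., i, j] = g
    return _sym(G)


def spdnet_backward(cache, grad_feats: np.ndarray):
    """Gradients of the loss w.r.t. both bilinear maps.

    ``grad_feats`` has shape ``(B, d2*(d2+1)/2)``; the per-trial gradients are
    summed over the batch.  Returns ``{"w1": ..., "w2": ...}``.
    """
    X0, X1, X2, X3, cache_re, cache_log, params = cache
    d2 = params.w2.shape[1]
    G4 = _vech_grad_to_sym(np.atleast_2d(grad_feats), d2)
    G3 = _eig_fn_backward(G4, cache_log)
    # BiMap2: X3 = W2^T X2 W2
    G2 = np.einsum("ik,...kl,jl->...ij", params.w2, G3, params.w2, optimize=True)
    dw2 = 2.0 * np.einsum("...ij,...jk,...kl->il", X2, params.w2[None], G3, optimize=True)
    G1 = _eig_fn_backward(G2, cache_re)
    dw1 = 2.0 * np.einsum("...ij,...jk,...kl->il", X0, params.w1[None], G1, optimize=True)
    return {"w1": dw1, "w2": dw2}


def spdnet_apply_grads(params: SPDNetParams, grads, lr: float) -> None:
    """Euclidean gradient step on the maps, then QR retraction if on Stiefel."""
    for key in ("w1", "w2"):
        if not np.all(np.isfinite(grads[key])):
            raise FloatingPointError(f"non-finite SPDNet gradient for {key}")
    params.w1 = params.w1 - lr * grads["w1"]
    params.w2 = params.w2 - lr * grads["w2"]
    if params.stiefel:
        params.w1 = _orthonormal_columns(params.w1)
        params.w2 = _orthonormal_columns(params.w2)
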