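"""Temporal-relation validity analysis: trajectory matrices and the zeta statistic.

Averaging the 7x465 covariance sequences of all trials of one class yields the
class trajectory matrices ``M_V`` and ``M_D``; each column traces how one
channel pair's covariance evolves across the seven segments.  For a chosen set
of columns the ratio statistic

    zeta = (Gamma + Theta) / (Phi + Upsilon)

contrasts intra-class against inter-class Pearson correlations (phi) of those
trajectories: ``Gamma``/``Theta`` sum ``exp(phi - omega)`` over intra-class
column pairs of ``M_V``/``M_D``, ``Phi`` sums ``exp(phi)`` over cross-class
pairs, and ``Upsilon`` sums squared differences between the matched intra-class
correlations of the two classes.  High zeta marks column combinations whose
temporal dynamics are consistent within a class but differ between classes.

Pair-counting conventions (the defining sums do not pin them down) are
explicit arguments: intra-class pairs are counted once (unordered) by default,
and the cross-class sum runs over all ordered pairs including matched columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

__all__ = [
    "class_trajectories",
    "pcc",
    "zeta",
    "ZetaReport",
    "sample_combinations",
    "rank_combinations",
]

DEFAULT_OMEGA = 0.9


def class_trajectories(sequences, labels):
    """Class-mean trajectory matrices ``(M_V, M_D)``.

    ``sequences`` is ``(n_trials, 7, 465)`` (or any consistent shape);
    ``labels`` uses 0 = vigilant, 1 = drowsy.
    """
    seqs = np.asarray(sequences, dtype=float)
    labels = np.asarray(labels)
    mv = seqs[labels == 0]
    md = seqs[labels == 1]
    if len(mv) == 0 or len(md) == 0:
        raise ValueError("both classes must be present")
    return mv.mean(axis=0), md.mean(axis=0)


def pcc(u, v) -> float:
    """Pearson correlation of two trajectories; 0 (with a warning) if one is flat."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    du = u - u.mean()
    dv = v - v.mean()
    su = np.sqrt(np.sum(du * du))
    sv = np.sqrt(np.sum(dv * dv))
    if su == 0.0 or sv == 0.0:
        warnings.warn("zero-variance trajectory; correlation set to 0", stacklevel=2)
        return 0.0
    return float(np.clip(np.sum(du * dv) / (su * sv), -1.0, 1.0))


@dataclass(frozen=True)
class ZetaReport:
    """The four component sums and their ratio for one column combination."""

    combination: tuple
    gamma: float
    theta: float
    phi: float
    upsilon: float
    omega: float

    @property
    def zeta(self) -> float:
        return (self.gamma + self.theta) / (self.phi + self.upsilon)


def zeta(
    M_V: np.ndarray,
    M_D: np.ndarray,
    combo,
    omega: float = DEFAULT_OMEGA,
    intra_pairs: str = "unordered",
    cross_matched: bool = True,
) -> ZetaReport:
    """Compute the zeta statistic for one column combination.

    ``intra_pairs`` chooses whether intra-class (and matched-difference) pairs
    are counted once ("unordered") or twice ("ordered"); ``cross_matched``
    controls whether the cross-class sum includes the matched pairs ``i == j``.
    """
    M_V = np.asarray(M_V, dtype=float)
    M_D = np.asarray(M_D, dtype=float)
    if M_V.shape != M_D.shape:
        raise ValueError("trajectory matrices must have equal shapes")
    combo = tuple(int(c) for c in combo)
    if len(combo) < 2 or len(set(combo)) != len(combo):
        raise ValueError("combo must hold at least 2 distinct column indices")
    ncol = M_V.shape[1]
    if any(c < 0 or c >= ncol for c in combo):
        raise ValueError(f"column index out of range [0, {ncol})")
    if intra_pairs not in ("unordered", "ordered"):
        raise ValueError("intra_pairs must be 'unordered' or 'ordered'")
    mult = 1.0 if intra_pairs == "unordered" else 2.0

    gamma = theta = upsilon = 0.0
    for i, j in combinations(combo, 2):
        cv = pcc(M_V[:, i], M_V[:, j])
        cd = pcc(M_D[:, i], M_D[:, j])
        gamma += mult * np.exp(cv - omega)
        theta += mult * np.exp(cd - omega)
        upsilon += mult * (cv - cd) ** 2
    phi = 0.0
    for i in combo:
        for j in combo:
            if i == j and not cross_matched:
                continue
            phi += np.exp(pcc(M_V[:, i], M_D[:, j]))
    return ZetaReport(combination=combo, gamma=float(gamma), theta=float(theta),
                      phi=float(phi), upsilon=float(upsilon), omega=omega)


def sample_combinations(
    k: int,
    pool: int = 465,
    n_samples: int = 1000,
    seed: int = 0,
    exhaustive_limit: int = 10_000,
):
    """Distinct column index sets of size ``k``.

    Enumerates all ``C(pool, k)`` sets when that count is within
    ``exhaustive_limit``; otherwise samples distinct sets without replacement
    under the given seed.  ``n_samples`` above the number of available sets is
    capped with a warning.
    """
    if k < 1 or k > pool:
        raise ValueError(f"k must be in [1, {pool}]")
    total = comb(pool, k)
    if total <= exhaustive_limit:
        sets = [tuple(c) for c in combinations(range(pool), k)]
        if n_samples >= total:
            if n_samples > total:
                warnings.warn(
                    f"n_samples={n_samples} exceeds C({pool},{k})={total}; capped",
                    stacklevel=2,
                )
            return sets
        rng = np.random.default_rng(seed)
        idx = rng.choice(total, size=n_samples, replace=False)
        return [sets[i] for i in sorted(idx)]
    rng = np.random.default_rng(seed)
    seen: set = set()
    out = []
    while len(out) < n_samples:
        c = tuple(sorted(rng.choice(pool, size=k, replace=False).tolist()))
        if c not in seen:
            seen.add(c)
            out.append(c)
    return out


def rank_combinations(
    M_V: np.ndarray,
    M_D: np.ndarray,
    k: int,
    n_samples: int = 1000,
    omega: float = DEFAULT_OMEGA,
    seed: int = 0,
    top: int | None = None,
    **zeta_kwargs,
) -> pd.DataFrame:
    """Score column combinations by zeta and return them in descending order.

    The result table carries one row per combination with columns
    ``combination, Gamma, Theta, Phi, Upsilon, zeta``.
    """
    pool = np.asarray(M_V).shape[1]
    combos = sample_combinations(k, pool=pool, n_samples=n_samples, seed=seed)
    rows = []
    for c in combos:
        r = zeta(M_V, M_D, c, omega=omega, **zeta_kwargs)
        rows.append(
            {
                "combination": r.combination,
                "Gamma": r.gamma,
                "Theta": r.theta,
                "Phi": r.phi,
                "Upsilon": r.upsilon,
                "zeta": r.zeta,
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["zeta", "combination"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return df.head(top) if top is not None else df
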