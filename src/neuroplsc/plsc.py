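"""Core PLSC: cross-block correlation, SVD, saliences, latent scores.

Given z-scored blocks Yz (n x q behavior) and Xz (n x p brain), the
behavior-by-brain Pearson correlation matrix

    R = Yz' Xz / (n - 1)

is decomposed as R = U diag(s) V'. Columns of U (behavioral saliences)
and V (brain saliences) are paired latent directions; the squared
singular values, as percentages of their total, give each component's
explained cross-block covariance. Latent scores are the projections
Lx = Xz V and Ly = Yz U, and each component's effect size is the Pearson
correlation r between its paired latent score columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PLSResult:
    """Fitted PLSC decomposition.

    Attributes
    ----------
    U, V
        q x K behavioral and p x K brain saliences (unit-norm columns,
        sign fixed so each component's largest-|u| entry is positive).
    s
        K singular values, non-increasing.
    explained
        Percentage of total squared singular value mass per component;
        the denominator includes ALL min(p, q) singular values, so the
        retained components' percentages do not depend on K.
    Lx, Ly
        n x K latent score matrices (brain, behavior).
    r
        Per-component Pearson correlation between Lx[:, k] and Ly[:, k];
        NaN where a latent column is constant.
    """

    U: pd.DataFrame
    V: pd.DataFrame
    s: np.ndarray
    explained: np.ndarray
    Lx: pd.DataFrame
    Ly: pd.DataFrame
    r: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.s)


def cross_correlation(Yz: pd.DataFrame, Xz: pd.DataFrame) -> pd.DataFrame:
    """Behavior-by-brain Pearson correlation matrix R (q x p).

    Both inputs must be column-wise z-scored with the n-1 denominator and
    share the subject dimension; then R[j, i] is exactly the Pearson
    correlation of measure j with ROI i.
    """
    if len(Yz) != len(Xz):
        raise ValueError(f"row mismatch: Yz has {len(Yz)}, Xz has {len(Xz)}")
    n = len(Yz)
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    R = Yz.to_numpy().T @ Xz.to_numpy() / (n - 1)
    return pd.DataFrame(R, index=Yz.columns, columns=Xz.columns)


def _fix_signs(U: np.ndarray, V: np.ndarray) -> tuple:
    """Deterministic sign convention: largest-|u| entry positive per component."""
    for k in range(U.shape[1]):
        j = np.argmax(np.abs(U[:, k]))
        if U[j, k] < 0:
            U[:, k] = -U[:, k]
            V[:, k] = -V[:, k]
    return U, V


def decompose(R: pd.DataFrame, K: int | None = None):
    """SVD of the cross-correlation matrix, truncated to K components.

    Returns ``(U, V, s, explained)`` where U diag(s) V' reconstructs the
    rank-K truncation of R. ``explained`` percentages use all singular
    values in the denominator.
    """
    Rv = np.asarray(R, dtype=float)
    if not np.isfinite(Rv).all():
        raise ValueError("cross-correlation matrix contains non-finite entries")
    q, p = Rv.shape
    max_k = min(p, q)
    if K is None:
        K = max_k
    if not 1 <= K <= max_k:
        raise ValueError(f"K={K} outside [1, {max_k}]")

    U, s, Vt = np.linalg.svd(Rv, full_matrices=False)
    total = float(np.sum(s**2))
    if total == 0:
        explained_all = np.zeros_like(s)
    else:
        explained_all = 100.0 * s**2 / total

    U, V = _fix_signs(U[:, :K].copy(), Vt[:K].T.copy())
    if K > 1 and np.any(np.isclose(s[:K][:-1], s[:K][1:], rtol=1e-10, atol=1e-12)):
        logger.warning("near-tied singular values: saliences are not unique under ties")
    Udf = pd.DataFrame(U, index=R.index,
                       columns=[f"comp{k + 1}" for k in range(K)])
    Vdf = pd.DataFrame(V, index=R.columns, columns=Udf.columns)
    return Udf, Vdf, s[:K].copy(), explained_all[:K].copy()


def latent_scores(Xz: pd.DataFrame, Yz: pd.DataFrame,
                  U: pd.DataFrame, V: pd.DataFrame) -> tuple:
    """Project each block onto its saliences: Lx = Xz V, Ly = Yz U."""
    if Xz.shape[1] != V.shape[0] or Yz.shape[1] != U.shape[0]:
        raise ValueError("salience dimensions do not match block dimensions")
    Lx = pd.DataFrame(Xz.to_numpy() @ V.to_numpy(), index=Xz.index, columns=V.columns)
    Ly = pd.DataFrame(Yz.to_numpy() @ U.to_numpy(), index=Yz.index, columns=U.columns)
    return Lx, Ly


def component_correlation(Lx: pd.DataFrame, Ly: pd.DataFrame) -> np.ndarray:
    """Pearson r per matched latent-score column pair; NaN when degenerate."""
    lx, ly = Lx.to_numpy(), Ly.to_numpy()
    r = np.full(lx.shape[1], np.nan)
    for k in range(lx.shape[1]):
        sx, sy = lx[:, k].std(ddof=1), ly[:, k].std(ddof=1)
        if sx > 0 and sy > 0:
            r[k] = np.corrcoef(lx[:, k], ly[:, k])[0, 1]
        else:
            logger.warning("component %d has a constant latent score; r undefined", k + 1)
    return r


def plsc_fit(Xz: pd.DataFrame, Yz: pd.DataFrame, K: int | None = None) -> PLSResult:
    """Full PLSC fit: correlation matrix, SVD, latent scores, per-component r."""
    R = cross_correlation(Yz, Xz)
    U, V, s, explained = decompose(R, K)
    Lx, Ly = latent_scores(Xz, Yz, U, V)
    r = component_correlation(Lx, Ly)
    return PLSResult(U=U, V=V, s=s, explained=explained, Lx=Lx, Ly=Ly, r=r)
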