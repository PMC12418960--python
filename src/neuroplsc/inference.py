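"""Resampling inference for PLSC: permutation tests and bootstrap ratios.

Component-level significance is assessed by permuting the rows of the
behavioral block while holding the brain block fixed, which breaks the
cross-block association but preserves each block's internal covariance.
For each permutation the cross-correlation matrix and its SVD are
recomputed; by default the permuted singular structure is Procrustes-
rotated onto the original saliences before component-wise null singular
values are extracted (axis rotation and reordering under permutation
would otherwise inflate the null for later components). P-values use the
add-one rule p = (1 + #{null >= observed}) / (n_perm + 1).

Variable-level stability is assessed by bootstrap resampling of subjects
with replacement: blocks are re-standardized within each resample, the
SVD recomputed and aligned to the original solution, and each salience
summarized by its bootstrap mean, SD and the ratio Z = mean / SD,
thresholded at |Z| >= z_threshold (default 3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from neuroplsc.plsc import PLSResult, plsc_fit

logger = logging.getLogger(__name__)

ALIGNMENTS = ("procrustes", "sign_only", "naive")


@dataclass(frozen=True)
class InferenceConfig:
    """Resampling settings.

    Defaults follow common PLSC practice in neuroimaging: 1000
    permutations, 500 bootstrap samples, salience threshold |Z| >= 3
    (stricter alternatives to the conventional 2 or 2.57 cutoffs),
    component alpha 0.05. ``perm_alignment`` applies to the permutation
    null (Procrustes by default), ``boot_alignment`` to bootstrap
    resamples (sign flip by dot product with the original saliences).
    ``z_ratio`` selects the numerator of the bootstrap ratio: the
    bootstrap mean ("boot_mean") or the original salience ("original").
    """

    n_perm: int = 1000
    n_boot: int = 500
    z_threshold: float = 3.0
    perm_alignment: str = "procrustes"
    boot_alignment: str = "sign_only"
    z_ratio: str = "boot_mean"
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perm < 1 or self.n_boot < 1:
            raise ValueError("n_perm and n_boot must be >= 1")
        if self.z_threshold < 0:
            raise ValueError("z_threshold must be >= 0")
        for name in ("perm_alignment", "boot_alignment"):
            if getattr(self, name) not in ALIGNMENTS:
                raise ValueError(f"{name} must be one of {ALIGNMENTS}")
        if self.z_ratio not in ("boot_mean", "original"):
            raise ValueError("z_ratio must be 'boot_mean' or 'original'")


@dataclass(frozen=True)
class PermutationResult:
    """Null singular-value distributions and per-component p-values."""

    null_s: np.ndarray  # n_perm x K
    observed_s: np.ndarray  # K
    p: np.ndarray  # K
    n_perm: int
    alignment: str


@dataclass(frozen=True)
class BootstrapResult:
    """Per-variable bootstrap summaries of the saliences of both blocks.

    ``behavior`` and ``brain`` are DataFrames with a two-level column
    index (component, statistic) holding mean, sd, z and significant.
    """

    behavior: pd.DataFrame
    brain: pd.DataFrame
    z_threshold: float
    n_boot: int
    n_redraws: int
    alignment: str

    def masks(self) -> dict:
        """Significance masks (|Z| >= threshold) per block."""
        return {
            "behavior": self.behavior.xs("significant", axis=1, level=1),
            "brain": self.brain.xs("significant", axis=1, level=1),
        }


def _procrustes_rotation(U_ref: np.ndarray, U_new: np.ndarray) -> np.ndarray:
    """Orthogonal rotation aligning the columns of U_new onto U_ref."""
    P, _, Qt = np.linalg.svd(U_ref.T @ U_new)
    return Qt.T @ P.T


def _svd_truncated(R: np.ndarray, K: int):
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    return U[:, :K], s[:K], Vt[:K].T


def permutation_test(Xz: pd.DataFrame, Yz: pd.DataFrame, K: int,
                     cfg: InferenceConfig,
                     permutations=None) -> PermutationResult:
    """Permutation null for the first K singular values.

    Rows of Yz are permuted against a fixed Xz. When ``permutations`` is
    given (an iterable of row-index arrays) those exact permutations are
    used, enabling exhaustive enumeration at small n; otherwise
    ``cfg.n_perm`` uniform random permutations are drawn from a stream
    seeded by ``cfg.seed`` (independent of the bootstrap stream).
    """
    X = Xz.to_numpy(dtype=float)
    Y = Yz.to_numpy(dtype=float)
    n = X.shape[0]
    if Y.shape[0] != n:
        raise ValueError("row mismatch between blocks")
    if K > min(X.shape[1], Y.shape[1]):
        raise ValueError(f"K={K} exceeds min(p, q)={min(X.shape[1], Y.shape[1])}")

    R_obs = Y.T @ X / (n - 1)
    U_obs, s_obs, _ = _svd_truncated(R_obs, K)

    if permutations is None:
        rng = np.random.default_rng([cfg.seed, 1])  # permutation stream
        permutations = [rng.permutation(n) for _ in range(cfg.n_perm)]
    else:
        permutations = [np.asarray(p) for p in permutations]
    n_perm = len(permutations)

    null_s = np.empty((n_perm, K))
    for b, perm in enumerate(permutations):
        Rp = Y[perm].T @ X / (n - 1)
        Up, sp, Vp = _svd_truncated(Rp, K)
        if cfg.perm_alignment == "procrustes":
            rot = _procrustes_rotation(U_obs, Up)
            rotated = Vp @ np.diag(sp) @ rot
            null_s[b] = np.linalg.norm(rotated, axis=0)
        else:  # sign flips never change singular values
            null_s[b] = sp

    p = (1 + np.sum(null_s >= s_obs[None, :], axis=0)) / (n_perm + 1)
    return PermutationResult(null_s=null_s, observed_s=s_obs, p=p,
                             n_perm=n_perm, alignment=cfg.perm_alignment)


def _zscore(M: np.ndarray) -> np.ndarray:
    sd = M.std(axis=0, ddof=1)
    return (M - M.mean(axis=0)) / sd


def bootstrap_stability(Xz: pd.DataFrame, Yz: pd.DataFrame, K: int,
                        cfg: InferenceConfig) -> BootstrapResult:
    """Bootstrap distribution of the saliences of both blocks.

    Subjects are resampled with replacement; each resample is
    re-standardized, decomposed, and aligned to the original solution
    (sign flip or Procrustes rotation). Resamples in which any column
    becomes constant are redrawn; the redraw count is reported.
    """
    X = Xz.to_numpy(dtype=float)
    Y = Yz.to_numpy(dtype=float)
    n = X.shape[0]
    if K > min(X.shape[1], Y.shape[1]):
        raise ValueError(f"K={K} exceeds min(p, q)={min(X.shape[1], Y.shape[1])}")

    fit = plsc_fit(Xz, Yz, K)
    U_obs, V_obs = fit.U.to_numpy(), fit.V.to_numpy()

    rng = np.random.default_rng([cfg.seed, 2])  # bootstrap stream
    U_samples = np.empty((cfg.n_boot, *U_obs.shape))
    V_samples = np.empty((cfg.n_boot, *V_obs.shape))
    n_redraws = 0
    for b in range(cfg.n_boot):
        for attempt in range(cfg.n_boot + 1):
            idx = rng.integers(0, n, size=n)
            Xb, Yb = X[idx], Y[idx]
            if Xb.std(axis=0, ddof=1).min() > 0 and Yb.std(axis=0, ddof=1).min() > 0:
                break
            n_redraws += 1
        else:
            raise RuntimeError(
                f"more than {cfg.n_boot} consecutive degenerate bootstrap resamples")
        Rb = _zscore(Yb).T @ _zscore(Xb) / (n - 1)
        Ub, sb, Vb = _svd_truncated(Rb, K)
        if cfg.boot_alignment == "procrustes":
            rot = _procrustes_rotation(U_obs, Ub)
            Ub, Vb = Ub @ rot, Vb @ rot
        elif cfg.boot_alignment == "sign_only":
            signs = np.sign(np.sum(U_obs * Ub, axis=0) + np.sum(V_obs * Vb, axis=0))
            signs[signs == 0] = 1.0
            Ub, Vb = Ub * signs, Vb * signs
        U_samples[b], V_samples[b] = Ub, Vb
    if n_redraws:
        logger.info("bootstrap redrew %d degenerate resample(s)", n_redraws)

    def summarize(samples: np.ndarray, observed: np.ndarray,
                  index) -> pd.DataFrame:
        mean = samples.mean(axis=0)
        sd = samples.std(axis=0, ddof=1)
        numer = mean if cfg.z_ratio == "boot_mean" else observed
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(sd > 0, numer / sd, np.inf * np.sign(numer))
        sig = np.abs(z) >= cfg.z_threshold
        cols = pd.MultiIndex.from_product(
            [[f"comp{k + 1}" for k in range(samples.shape[2])],
             ["mean", "sd", "z", "significant"]])
        out = pd.DataFrame(index=index, columns=cols, dtype=object)
        for k in range(samples.shape[2]):
            c = f"comp{k + 1}"
            out[(c, "mean")] = mean[:, k]
            out[(c, "sd")] = sd[:, k]
            out[(c, "z")] = z[:, k]
            out[(c, "significant")] = sig[:, k]
        return out

    return BootstrapResult(
        behavior=summarize(U_samples, U_obs, fit.U.index),
        brain=summarize(V_samples, V_obs, fit.V.index),
        z_threshold=cfg.z_threshold,
        n_boot=cfg.n_boot,
        n_redraws=n_redraws,
        alignment=cfg.boot_alignment,
    )


def threshold_saliences(boot: BootstrapResult, z_threshold: float) -> dict:
    """Re-threshold an existing bootstrap result at a different |Z| cutoff."""
    masks = {}
    for block_name, table in (("behavior", boot.behavior), ("brain", boot.brain)):
        z = table.xs("z", axis=1, level=1).astype(float)
        masks[block_name] = np.abs(z) >= z_threshold
    return masks


def normal_tail_probability(z: float, tails: str = "one") -> float:
    """Standard-normal tail probability beyond |z|.

    ``tails="one"`` returns P(N(0,1) > z); ``tails="two"`` returns twice
    that. The conventional |Z| >= 3 salience cutoff corresponds to a
    one-tailed probability of 0.0013 (two-tailed 0.0027); |Z| >= 2.57 to
    a two-tailed probability of 0.01.
    """
    if z < 0:
        raise ValueError("z must be non-negative")
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    tail = float(stats.norm.sf(z))
    return tail if tails == "one" else 2 * tail


def significant_components(perm: PermutationResult, alpha: float = 0.05) -> np.ndarray:
    """Indices (0-based) of components with permutation p < alpha."""
    return np.flatnonzero(perm.p < alpha)
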