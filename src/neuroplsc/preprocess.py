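"""Block preparation: score orientation, confound residualization, z-scoring.

Both blocks are prepared the same way before PLSC: behavioral measures are
first oriented so that higher values always mean better performance, then
each column of each block is replaced by its least-squares residual
against an intercept-plus-confounds design (age, sex, handedness), and
finally columns are z-scored with the n-1 denominator so that the
cross-block product in :mod:`neuroplsc.plsc` is exactly a Pearson
correlation matrix.

Residualization precedes the final z-scoring by default; the reverse
order ("zscore_then_residualize", which leaves residual columns with
non-unit variance unless re-scaled) is available for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from neuroplsc.datamodel import StudyDataset

#: Supported processing orders for prepare_blocks.
ORDERS = ("residualize_then_zscore", "zscore_then_residualize")


@dataclass(frozen=True)
class PreparedBlocks:
    """PLSC-ready matrices and a record of how they were produced.

    Xz / Yz are z-scored (mean 0, sample SD 1, ddof=1), confound-orthogonal
    brain and behavior matrices with aligned subject rows.
    """

    Xz: pd.DataFrame
    Yz: pd.DataFrame
    order: str
    confound_columns: tuple

    @property
    def n_subjects(self) -> int:
        return len(self.Xz)


def orient_scores(Y: pd.DataFrame, directions: dict) -> pd.DataFrame:
    """Negate lower-is-better columns so higher always indicates better.

    Reaction-time-like measures (lower = better) are sign-flipped; all
    other columns pass through unchanged. Applying the operation twice
    with the same flags restores the original values.
    """
    unknown = set(directions) - set(Y.columns)
    if unknown:
        raise ValueError(f"direction flags for unknown columns: {sorted(unknown)}")
    out = Y.copy()
    for col, flag in directions.items():
        if flag == "lower_is_better":
            out[col] = -out[col]
        elif flag != "higher_is_better":
            raise ValueError(f"unknown direction flag {flag!r} for column {col!r}")
    return out


def _design_matrix(confounds: pd.DataFrame) -> np.ndarray:
    X = np.column_stack([np.ones(len(confounds)), confounds.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            "confound design (intercept + "
            f"{list(confounds.columns)}) is rank-deficient (rank {rank} < {X.shape[1]})")
    return X


def residualize(M: pd.DataFrame, confounds: pd.DataFrame) -> pd.DataFrame:
    """Replace each column of M by its OLS residual against the confounds.

    The design is intercept + all confound columns; residuals are exactly
    orthogonal to every design column (up to numerical precision).
    """
    if len(M) != len(confounds):
        raise ValueError(f"row mismatch: M has {len(M)}, confounds {len(confounds)}")
    X = _design_matrix(confounds)
    Y = M.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return pd.DataFrame(resid, index=M.index, columns=M.columns)


def zscore_columns(M: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each column to mean 0, sample SD 1 (ddof=1)."""
    vals = M.to_numpy(dtype=float)
    sd = vals.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        cols = [M.columns[i] for i in zero]
        raise ValueError(f"zero-variance column(s): {cols}")
    z = (vals - vals.mean(axis=0)) / sd
    return pd.DataFrame(z, index=M.index, columns=M.columns)


def prepare_blocks(ds: StudyDataset, order: str = "residualize_then_zscore") -> PreparedBlocks:
    """Orient scores, remove confound variance, and z-score both blocks.

    Requires a complete-case dataset. The processing order applied is
    recorded in the result so downstream reports can echo it.
    """
    if order not in ORDERS:
        raise ValueError(f"unknown order {order!r}; expected one of {ORDERS}")
    if not ds.is_complete():
        raise ValueError("dataset contains missing values; run filter_complete_cases first")

    Y = orient_scores(ds.behavior, ds.directions)
    X = ds.brain
    if order == "residualize_then_zscore":
        Xz = zscore_columns(residualize(X, ds.confounds))
        Yz = zscore_columns(residualize(Y, ds.confounds))
    else:
        Xz = zscore_columns(residualize(zscore_columns(X), ds.confounds))
        Yz = zscore_columns(residualize(zscore_columns(Y), ds.confounds))
    return PreparedBlocks(Xz=Xz, Yz=Yz, order=order,
                          confound_columns=tuple(ds.confounds.columns))
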