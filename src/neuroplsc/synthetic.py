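"""Synthetic two-block data with planted latent structure, and toy volumes.

The participant-level data of ROI-based brain-behavior studies are rarely
shareable, so every pipeline stage here is exercised on simulated data
whose ground truth is known. The generator plants K rank-one cross-block
components: orthogonalized latent scores z_k drive both blocks through
unit-norm sparse salience vectors,

    Y = sum_k lam_k z_k u_k' + C B_Y + noise,
    X = sum_k lam_k z_k v_k' + C B_X + noise,

where C holds centered confounds (age, sex, handedness) and lam_k sets
the strength of component k. With independent unit-variance noise the
population correlation between the paired latent scores is
lam^2 / (lam^2 + noise_sd^2), so a target latent correlation rho maps to
lam = noise_sd * sqrt(rho / (1 - rho)).

Defaults mirror the emulated study: n = 134 subjects, q = 36 behavioral
measures, p = 397 ROIs, one planted component with latent correlation
0.5, a dyslexic-reader-like subgroup of 25/134 (~19%) with lowered means
on a few literacy/multilingualism-like behavioral columns, ages uniform
on 18-47 and sex Bernoulli(0.69).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from neuroplsc.datamodel import StudyDataset
from neuroplsc.roi import LabelVolume

#: Study-scale defaults for the emulated cohort.
DEFAULT_N = 134
DEFAULT_P = 397
DEFAULT_Q = 36
DEFAULT_SUBGROUP_FRACTION = 25 / 134
DEFAULT_TARGET_R = 0.5
DEFAULT_NOISE_SD = 1.0
AGE_RANGE = (18.0, 47.0)
P_FEMALE = 92 / 134


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated two-block dataset.

    U (q x K) and V (p x K) hold unit-norm planted saliences with sparse
    support; ``lam`` the latent strengths; ``confound_B_y``/``confound_B_x``
    the per-column confound loadings; ``subgroup_shifts`` maps behavioral
    column names to the mean shift applied to subgroup (DR) rows.
    """

    U: np.ndarray
    V: np.ndarray
    lam: np.ndarray
    noise_sd: float
    confound_B_y: np.ndarray
    confound_B_x: np.ndarray
    subgroup_fraction: float
    subgroup_shifts: dict
    seed: int
    target_r: float

    @property
    def K_true(self) -> int:
        return self.U.shape[1]

    def support(self, block: str, k: int = 0, tol: float = 1e-12) -> np.ndarray:
        """Boolean planted-support mask of component k for "behavior" or "brain"."""
        W = self.U if block == "behavior" else self.V
        return np.abs(W[:, k]) > tol


@dataclass(frozen=True)
class VolumeSuite:
    """Toy label volume plus per-subject contrast volumes with known ROI signal."""

    labels: LabelVolume
    contrasts: dict  # subject id -> 3-D ndarray
    planted: pd.DataFrame  # n_subjects x n_rois ROI signal matrix
    noise_sd: float


def latent_strength_for_correlation(target_r: float, noise_sd: float) -> float:
    """Latent strength lam giving population latent correlation ``target_r``."""
    if not 0 < target_r < 1:
        raise ValueError("target_r must lie in (0, 1)")
    if noise_sd == 0:  # noiseless limit: latent correlation is 1 for any lam > 0
        return 1.0
    return noise_sd * np.sqrt(target_r / (1 - target_r))


def _sparse_unit_vectors(dim: int, K: int, support_frac: float,
                         rng: np.random.Generator) -> np.ndarray:
    """K unit-norm vectors with disjoint sparse supports of given fraction."""
    size = max(2, int(round(support_frac * dim)))
    if K * size > dim:
        raise ValueError(f"cannot place {K} disjoint supports of size {size} in dim {dim}")
    order = rng.permutation(dim)
    W = np.zeros((dim, K))
    for k in range(K):
        idx = order[k * size:(k + 1) * size]
        w = rng.normal(size=size)
        w += np.sign(w.sum()) or 1.0  # bias away from near-zero entries
        W[idx, k] = w / np.linalg.norm(w)
    return W


def make_truth(p: int = DEFAULT_P, q: int = DEFAULT_Q, K_true: int = 1,
               target_r: float = DEFAULT_TARGET_R,
               noise_sd: float = DEFAULT_NOISE_SD,
               support_frac: float = 0.25,
               confound_strength: float = 0.3,
               subgroup_fraction: float = DEFAULT_SUBGROUP_FRACTION,
               n_shifted_columns: int = 4,
               subgroup_shift: float = -0.8,
               seed: int = 0) -> SyntheticTruth:
    """Draw a ground-truth configuration at study-like conditions.

    ``confound_strength`` scales per-column confound loadings (in SD units
    of the standardized confounds); ``subgroup_shift`` is the mean offset
    of subgroup rows on the first ``n_shifted_columns`` behavioral
    columns, emulating lowered literacy/multilingualism scores in the
    dyslexic subgroup.
    """
    rng = np.random.default_rng(seed)
    lam = np.full(K_true, latent_strength_for_correlation(target_r, noise_sd))
    U = _sparse_unit_vectors(q, K_true, support_frac, rng)
    V = _sparse_unit_vectors(p, K_true, support_frac, rng)
    B_y = confound_strength * rng.normal(size=(3, q))
    B_x = confound_strength * rng.normal(size=(3, p))
    shifts = {f"meas{j + 1:02d}": subgroup_shift for j in range(n_shifted_columns)}
    return SyntheticTruth(U=U, V=V, lam=lam, noise_sd=noise_sd,
                          confound_B_y=B_y, confound_B_x=B_x,
                          subgroup_fraction=subgroup_fraction,
                          subgroup_shifts=shifts, seed=seed, target_r=target_r)


def _draw_confounds(n: int, rng: np.random.Generator) -> pd.DataFrame:
    age = rng.uniform(*AGE_RANGE, size=n)
    sex = rng.binomial(1, P_FEMALE, size=n).astype(float)
    handedness = np.clip(rng.normal(0.7, 0.35, size=n), -1.0, 1.0)
    return pd.DataFrame({"age": age, "sex": sex, "handedness": handedness})


def _orthonormal_latents(n: int, K: int, rng: np.random.Generator) -> np.ndarray:
    """n x K latent score matrix: orthogonal columns, unit sample variance."""
    Z = rng.normal(size=(n, K))
    Z = Z - Z.mean(axis=0)
    Q_, _ = np.linalg.qr(Z)
    return Q_ * np.sqrt(n - 1)


def generate_two_block(n: int = DEFAULT_N, p: int = DEFAULT_P, q: int = DEFAULT_Q,
                       truth: SyntheticTruth | None = None,
                       seed: int | None = None) -> tuple:
    """Generate a planted-structure StudyDataset and its ground truth.

    If ``truth`` is omitted a default one-component truth is drawn from
    ``seed``. The same seed always yields byte-identical data.
    """
    if n < 10:
        raise ValueError("need n >= 10")
    if truth is None:
        truth = make_truth(p=p, q=q, seed=0 if seed is None else seed)
    if truth.U.shape[0] != q or truth.V.shape[0] != p:
        raise ValueError(
            f"truth dimensions (q={truth.U.shape[0]}, p={truth.V.shape[0]}) "
            f"do not match requested (q={q}, p={p})")
    # separate stream from make_truth so data noise is independent of the truth draw
    rng = np.random.default_rng([truth.seed if seed is None else seed, 101])

    Z = _orthonormal_latents(n, truth.K_true, rng)
    confounds = _draw_confounds(n, rng)
    C = confounds.to_numpy() - confounds.to_numpy().mean(axis=0)
    C = C / C.std(axis=0, ddof=1)

    signal_y = Z @ np.diag(truth.lam) @ truth.U.T
    signal_x = Z @ np.diag(truth.lam) @ truth.V.T
    Y = signal_y + C @ truth.confound_B_y + truth.noise_sd * rng.normal(size=(n, q))
    X = signal_x + C @ truth.confound_B_x + truth.noise_sd * rng.normal(size=(n, p))

    n_dr = int(round(truth.subgroup_fraction * n))
    dr_rows = rng.choice(n, size=n_dr, replace=False)
    groups = np.array(["TR"] * n)
    groups[dr_rows] = "DR"

    ids = pd.Index([f"s{i + 1:03d}" for i in range(n)], name="subject_id")
    behavior = pd.DataFrame(Y, index=ids,
                            columns=[f"meas{j + 1:02d}" for j in range(q)])
    for col, shift in truth.subgroup_shifts.items():
        if col in behavior.columns:
            behavior.loc[groups == "DR", col] += shift
    brain = pd.DataFrame(X, index=ids,
                         columns=[f"roi{i + 1:03d}" for i in range(p)])
    confounds.index = ids
    ds = StudyDataset(behavior=behavior, brain=brain, confounds=confounds,
                      groups=pd.Series(groups, index=ids, name="group"),
                      directions={c: "higher_is_better" for c in behavior.columns})
    return ds, truth


def generate_null(n: int, p: int, q: int, seed: int,
                  subgroup_fraction: float = DEFAULT_SUBGROUP_FRACTION) -> StudyDataset:
    """Two independent blocks with no cross-block structure (calibration null).

    Group labels are assigned at the study's subgroup rate but carry no
    effect, so rows are exchangeable.
    """
    rng = np.random.default_rng(seed)
    ids = pd.Index([f"s{i + 1:03d}" for i in range(n)], name="subject_id")
    behavior = pd.DataFrame(rng.normal(size=(n, q)), index=ids,
                            columns=[f"meas{j + 1:02d}" for j in range(q)])
    brain = pd.DataFrame(rng.normal(size=(n, p)), index=ids,
                         columns=[f"roi{i + 1:03d}" for i in range(p)])
    confounds = _draw_confounds(n, rng)
    confounds.index = ids
    n_dr = int(round(subgroup_fraction * n))
    groups = np.array(["TR"] * n)
    groups[rng.choice(n, size=n_dr, replace=False)] = "DR"
    return StudyDataset(behavior=behavior, brain=brain, confounds=confounds,
                        groups=pd.Series(groups, index=ids, name="group"),
                        directions={c: "higher_is_better" for c in behavior.columns})


def generate_volume_suite(n: int, n_rois: int, grid: tuple = (12, 12, 12),
                          noise_sd: float = 0.0, seed: int = 0) -> VolumeSuite:
    """Toy label volume plus per-subject contrast volumes with planted ROI means.

    The grid is partitioned into ``n_rois`` contiguous flat blocks (every
    voxel labeled); each subject's volume holds a per-ROI constant signal
    plus i.i.d. voxel noise. At ``noise_sd=0`` the ROI means of the
    contrast volumes equal the planted signal matrix exactly.
    """
    n_voxels = int(np.prod(grid))
    if n_rois > n_voxels:
        raise ValueError(f"n_rois={n_rois} exceeds {n_voxels} grid cells")
    rng = np.random.default_rng(seed)

    edges = np.linspace(0, n_voxels, n_rois + 1).round().astype(int)
    flat_labels = np.zeros(n_voxels, dtype=np.int32)
    for r in range(n_rois):
        flat_labels[edges[r]:edges[r + 1]] = r + 1
    labels = LabelVolume(data=flat_labels.reshape(grid),
                         names={r + 1: f"roi{r + 1:03d}" for r in range(n_rois)})

    ids = [f"s{i + 1:03d}" for i in range(n)]
    planted = pd.DataFrame(rng.normal(size=(n, n_rois)), index=pd.Index(ids, name="subject_id"),
                           columns=[labels.names[r + 1] for r in range(n_rois)])
    contrasts = {}
    for i, sid in enumerate(ids):
        flat = planted.to_numpy()[i, flat_labels - 1].astype(float)
        if noise_sd > 0:
            flat = flat + noise_sd * rng.normal(size=n_voxels)
        contrasts[sid] = flat.reshape(grid)
    return VolumeSuite(labels=labels, contrasts=contrasts, planted=planted,
                       noise_sd=noise_sd)


def recovery_metrics(result, truth: SyntheticTruth, masks: dict | None = None) -> dict:
    """Compare an estimated PLSC solution against the planted truth.

    Planted components are greedily matched to estimated components by
    maximal |cosine| of the behavioral saliences. Reports per planted
    component the matched index and the |cosine| for both blocks, and —
    when bootstrap significance ``masks`` are given — the sensitivity and
    specificity of the |Z| mask against the planted support.
    """
    U_est, V_est = np.asarray(result.U, dtype=float), np.asarray(result.V, dtype=float)
    report: dict = {"components": []}
    available = list(range(U_est.shape[1]))
    for k in range(truth.K_true):
        cos_u = np.abs(truth.U[:, k] @ U_est[:, available])
        pick = available[int(np.argmax(cos_u))]
        available.remove(pick)
        entry = {
            "planted": k,
            "matched": pick,
            "cosine_behavior": float(np.abs(truth.U[:, k] @ U_est[:, pick])),
            "cosine_brain": float(np.abs(truth.V[:, k] @ V_est[:, pick])),
        }
        if masks is not None:
            for block, W in (("behavior", "U"), ("brain", "V")):
                support = truth.support(block, k)
                mask = np.asarray(masks[block], dtype=bool)
                found = mask[:, pick] if mask.ndim == 2 else mask
                tp = np.sum(found & support)
                tn = np.sum(~found & ~support)
                entry[f"sensitivity_{block}"] = float(tp / max(support.sum(), 1))
                entry[f"specificity_{block}"] = float(tn / max((~support).sum(), 1))
        report["components"].append(entry)
    return report
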