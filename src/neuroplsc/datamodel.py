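"""Study data model: aligned two-block tables and sample-selection rules.

A :class:`StudyDataset` holds four aligned parts sharing one subject index:
the behavioral block ``Y`` (subjects x measures), the brain block ``X``
(subjects x ROIs), a confound table (age, sex, handedness), and a group
label per subject (``TR`` typical reader / ``DR`` dyslexic reader).
All operations in this module preserve that alignment and keep row order
deterministic (sorted by subject id).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Recognised group labels.
GROUPS = ("TR", "DR")

#: Strings treated as missing on read, besides empty cells.
NA_SENTINELS = ("NA", "NaN", "nan", "N/A", "")


@dataclass(frozen=True)
class StudyDataset:
    """Aligned two-block dataset for PLSC.

    Parameters
    ----------
    behavior
        n x q DataFrame of behavioral scores, indexed by subject id.
    brain
        n x p DataFrame of ROI contrast means, same index.
    confounds
        n x c DataFrame of nuisance covariates (age, sex, handedness).
    groups
        Series of group labels ("TR"/"DR"), same index.
    directions
        Mapping measure name -> "higher_is_better" | "lower_is_better".
        Empty mapping means all measures are already oriented.
    """

    behavior: pd.DataFrame
    brain: pd.DataFrame
    confounds: pd.DataFrame
    groups: pd.Series
    directions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.behavior.index
        for name, part in (("brain", self.brain), ("confounds", self.confounds),
                           ("groups", self.groups)):
            if not part.index.equals(idx):
                raise ValueError(f"subject index of {name!r} does not match behavior block")
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate subject ids: {dupes}")
        unknown = set(self.directions) - set(self.behavior.columns)
        if unknown:
            raise ValueError(f"direction flags for unknown measures: {sorted(unknown)}")

    @property
    def n_subjects(self) -> int:
        return len(self.behavior)

    @property
    def subject_ids(self) -> pd.Index:
        return self.behavior.index

    def is_complete(self) -> bool:
        """True if no part contains a missing value."""
        return not (
            self.behavior.isna().any().any()
            or self.brain.isna().any().any()
            or self.confounds.isna().any().any()
            or self.groups.isna().any()
        )

    def take(self, ids) -> "StudyDataset":
        """Row-subset every part to ``ids``, preserving the given order."""
        return replace(
            self,
            behavior=self.behavior.loc[ids],
            brain=self.brain.loc[ids],
            confounds=self.confounds.loc[ids],
            groups=self.groups.loc[ids],
        )


def _read_table(path, id_column: str = "subject_id") -> pd.DataFrame:
    """Read a TSV/CSV table indexed by subject id, with sentinel NA handling."""
    try:
        df = pd.read_csv(path, sep=None, engine="python",
                         na_values=list(NA_SENTINELS), keep_default_na=True)
    except Exception as exc:  # re-raise with the offending file named
        raise ValueError(f"failed to parse {path}: {exc}") from exc
    if id_column not in df.columns:
        if df.columns[0].lower() in (id_column, "subject", "id"):
            df = df.rename(columns={df.columns[0]: id_column})
        else:
            raise ValueError(f"{path}: missing {id_column!r} column")
    df[id_column] = df[id_column].astype(str)
    if df[id_column].duplicated().any():
        dupes = df.loc[df[id_column].duplicated(), id_column].unique().tolist()
        raise ValueError(f"{path}: duplicate subject id(s) {dupes}")
    return df.set_index(id_column)


def load_measure_metadata(path) -> dict:
    """Read the two-column (measure, direction) metadata table."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns (measure, direction)")
    measures, dirs = df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)
    valid = {"higher_is_better", "lower_is_better"}
    bad = sorted(set(dirs) - valid)
    if bad:
        raise ValueError(f"{path}: unknown direction flag(s) {bad}")
    return dict(zip(measures, dirs))


def load_tables(behavior_path, brain_path, confound_path,
                measure_meta_path=None, group_column: str = "group") -> StudyDataset:
    """Load and align the three study tables by subject-id intersection.

    The group label is read from ``group_column`` of the confound table.
    Rows are ordered by sorted subject id. Subjects absent from any file
    are dropped with a logged warning.
    """
    behavior = _read_table(behavior_path)
    brain = _read_table(brain_path)
    confounds = _read_table(confound_path)

    if group_column not in confounds.columns:
        raise ValueError(f"{confound_path}: missing group column {group_column!r}")
    groups = confounds[group_column].astype(str).rename("group")
    confounds = confounds.drop(columns=[group_column])

    common = behavior.index.intersection(brain.index).intersection(confounds.index)
    if len(common) == 0:
        raise ValueError("no subject id is shared by all three tables")
    common = common.sort_values()
    union = behavior.index.union(brain.index).union(confounds.index)
    dropped = union.difference(common)
    if len(dropped):
        logger.warning("dropping %d subject(s) absent from some table: %s",
                       len(dropped), sorted(dropped))

    ds = StudyDataset(
        behavior=behavior.loc[common].astype(float),
        brain=brain.loc[common].astype(float),
        confounds=confounds.loc[common].astype(float),
        groups=groups.loc[common],
        directions=load_measure_metadata(measure_meta_path) if measure_meta_path else {},
    )
    bad_groups = sorted(set(ds.groups.dropna()) - set(GROUPS))
    if bad_groups:
        raise ValueError(f"unknown group label(s) {bad_groups}; expected {GROUPS}")
    return ds


def filter_complete_cases(ds: StudyDataset) -> StudyDataset:
    """Keep only subjects with no missing value in any block or confound.

    Mirrors the complete-case inclusion rule of cohort studies where only
    participants with data on every analyzed measure enter the analysis.
    """
    keep = (
        ~ds.behavior.isna().any(axis=1)
        & ~ds.brain.isna().any(axis=1)
        & ~ds.confounds.isna().any(axis=1)
        & ~ds.groups.isna()
    )
    n_removed = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("no subject has complete data")
    if n_removed:
        logger.info("complete-case filter removed %d of %d subjects", n_removed, len(keep))
    return ds.take(ds.subject_ids[keep])


def proportional_allocation(target_n: int, proportions: dict) -> dict:
    """Largest-remainder allocation of ``target_n`` across groups.

    Each group first receives ``floor(target_n * proportion)``; remaining
    units go to the groups with the largest fractional remainders (ties
    broken by group name for determinism). Counts always sum to target_n.
    """
    total = float(sum(proportions.values()))
    if not np.isclose(total, 1.0, atol=1e-8):
        raise ValueError(f"proportions sum to {total}, expected 1")
    quotas = {g: target_n * p / total for g, p in proportions.items()}
    counts = {g: int(np.floor(q)) for g, q in quotas.items()}
    short = target_n - sum(counts.values())
    by_remainder = sorted(quotas, key=lambda g: (-(quotas[g] - counts[g]), g))
    for g in by_remainder[:short]:
        counts[g] += 1
    return counts


def stratified_subsample(ds: StudyDataset, target_n: int, proportions: dict,
                         seed: int) -> StudyDataset:
    """Draw a verification subsample of size ``target_n`` preserving group mix.

    Emulates the verification analysis in which a reduced sample keeps the
    full sample's TR/DR proportions so that differences between analyses
    can be attributed to sample composition rather than size.
    """
    if target_n > ds.n_subjects:
        raise ValueError(f"target_n={target_n} exceeds available n={ds.n_subjects}")
    counts = proportional_allocation(target_n, proportions)
    rng = np.random.default_rng(seed)
    chosen: list = []
    for group in sorted(counts):
        members = ds.subject_ids[ds.groups == group]
        if counts[group] > len(members):
            raise ValueError(
                f"group {group!r}: requested {counts[group]} subjects, only "
                f"{len(members)} available")
        pick = rng.choice(len(members), size=counts[group], replace=False)
        chosen.extend(members[np.sort(pick)])
    chosen = sorted(chosen)
    return ds.take(pd.Index(chosen, name=ds.subject_ids.name))


def subset_group(ds: StudyDataset, group: str) -> StudyDataset:
    """Keep only subjects with the given group label ("TR" or "DR")."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    keep = ds.subject_ids[ds.groups == group]
    if len(keep) == 0:
        raise ValueError(f"no subject has group {group!r}")
    return ds.take(keep)
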