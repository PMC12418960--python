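"""Multi-atlas parcellation merging and ROI-mean extraction.

The brain block of the study is built by averaging a per-subject contrast
volume (intact minus degraded speech activation) within each region of a
merged whole-brain parcellation. The parcellation combines a cortical
label volume, a subcortical label volume and a probabilistic cerebellar
atlas thresholded at a probability cutoff; labels named on a source's
exclusion list (e.g. hippocampal cortical parcels, superseded by the
subcortical atlas) are removed before merging. All volumes are assumed
pre-registered to one grid; shape equality is the only geometric check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class LabelVolume:
    """3-D integer label grid with a label -> region-name map.

    Label 0 is background by convention and never appears in ``names``.
    """

    data: np.ndarray
    names: dict
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label grid must be 3-D, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label grid must be integer-typed")
        if 0 in self.names:
            raise ValueError("label 0 is reserved for background")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def empty_labels(self) -> list:
        """Mapped labels that occur nowhere in the grid."""
        present = set(np.unique(self.data))
        return sorted(l for l in self.names if l not in present)


@dataclass
class ProbabilisticAtlas:
    """4-D (x, y, z, region) probability grid with per-region names."""

    data: np.ndarray
    names: list
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"probabilistic atlas must be 4-D, got {self.data.shape}")
        if self.data.shape[3] != len(self.names):
            raise ValueError("number of region names must match the 4th axis")
        if self.data.min() < 0 or self.data.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class ParcellationSpec:
    """Ordered recipe for merging label sources into one parcellation.

    ``sources`` lists source names in decreasing precedence (a voxel takes
    its label from the first source that labels it). ``exclude`` maps a
    source name to region names removed from that source before merging.
    ``prob_threshold`` applies when a source is probabilistic.
    """

    sources: list
    exclude: dict = field(default_factory=dict)
    prob_threshold: float = 0.5

    def __post_init__(self) -> None:
        if len(set(self.sources)) != len(self.sources):
            raise ValueError("duplicate source names in precedence list")
        if not 0 < self.prob_threshold < 1:
            raise ValueError("prob_threshold must lie in (0, 1)")


def load_label_volume(path, names: dict) -> LabelVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj).round().astype(np.int32)
    return LabelVolume(data=data, names=names, affine=img.affine)


def load_probabilistic_atlas(path, names: list) -> ProbabilisticAtlas:
    img = nib.load(str(path))
    return ProbabilisticAtlas(data=np.asarray(img.dataobj, dtype=float),
                              names=names, affine=img.affine)


def load_contrast_volume(path) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: contrast volume must be 3-D, got {data.shape}")
    return data


def save_label_volume(vol: LabelVolume, path) -> None:
    nib.save(nib.Nifti1Image(vol.data.astype(np.int16), vol.affine), str(path))


def binarize_probabilistic(atlas: ProbabilisticAtlas, threshold: float) -> LabelVolume:
    """Assign each voxel to the most probable region at or above ``threshold``.

    A voxel is labeled only if at least one region reaches the threshold;
    among those, the region with the highest probability wins, ties going
    to the lowest region index. Region i receives label i + 1.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    probs = atlas.data
    # argmax returns the lowest index on ties, which is the tie-break we want
    best = np.argmax(probs, axis=3)
    best_prob = np.take_along_axis(probs, best[..., None], axis=3)[..., 0]
    labels = np.where(best_prob >= threshold, best + 1, 0).astype(np.int32)
    names = {i + 1: name for i, name in enumerate(atlas.names)}
    return LabelVolume(data=labels, names=names, affine=atlas.affine)


def merge_labels(spec: ParcellationSpec, sources: dict) -> LabelVolume:
    """Merge label sources by precedence into one consecutively-indexed volume.

    ``sources`` maps source name -> LabelVolume or ProbabilisticAtlas (the
    latter binarized at ``spec.prob_threshold`` first). Excluded region
    names are blanked to background before merging. Output labels are
    re-indexed 1..L in precedence order with names "source:region".
    """
    resolved: dict = {}
    for name in spec.sources:
        if name not in sources:
            raise ValueError(f"source {name!r} named in spec but not provided")
        src = sources[name]
        if isinstance(src, ProbabilisticAtlas):
            src = binarize_probabilistic(src, spec.prob_threshold)
        resolved[name] = src

    shapes = {name: v.shape for name, v in resolved.items()}
    if len(set(shapes.values())) > 1:
        raise ValueError(f"label sources disagree on grid shape: {shapes}")
    shape = next(iter(shapes.values()))

    merged = np.zeros(shape, dtype=np.int32)
    names: dict = {}
    next_label = 1
    for source_name in spec.sources:  # decreasing precedence
        vol = resolved[source_name]
        excluded = set(spec.exclude.get(source_name, ()))
        unknown = excluded - set(vol.names.values())
        if unknown:
            logger.warning("exclusion list for %r names absent regions: %s",
                           source_name, sorted(unknown))
        for old_label in sorted(vol.names):
            region = vol.names[old_label]
            if region in excluded:
                continue
            mask = (vol.data == old_label) & (merged == 0)
            if not mask.any():
                logger.info("region %s:%s is empty after merging", source_name, region)
            merged[mask] = next_label
            names[next_label] = f"{source_name}:{region}"
            next_label += 1
    return LabelVolume(data=merged, names=names,
                       affine=next(iter(resolved.values())).affine)


def parcel_means(contrast: np.ndarray, labels: LabelVolume,
                 empty_policy: str = "error") -> pd.Series:
    """Mean of the contrast over each labeled parcel, in label order.

    ``empty_policy`` controls parcels with zero voxels: "error" raises
    (the default — a silently missing ROI would corrupt the PLSC block),
    "emit-missing" records NaN.
    """
    contrast = np.asarray(contrast, dtype=float)
    if contrast.shape != labels.shape:
        raise ValueError(
            f"contrast shape {contrast.shape} != label grid shape {labels.shape}")
    if empty_policy not in ("error", "emit-missing"):
        raise ValueError(f"unknown empty_policy {empty_policy!r}")

    flat_labels = labels.data.ravel()
    flat_vals = contrast.ravel()
    n_labels = max(labels.names) if labels.names else 0
    sums = np.bincount(flat_labels, weights=flat_vals, minlength=n_labels + 1)
    counts = np.bincount(flat_labels, minlength=n_labels + 1)

    means = {}
    for label in sorted(labels.names):
        name = labels.names[label]
        if counts[label] == 0:
            if empty_policy == "error":
                raise ValueError(f"ROI {name!r} (label {label}) has no voxels")
            means[name] = np.nan
        else:
            means[name] = sums[label] / counts[label]
    return pd.Series(means, dtype=float)


def extract_cohort(subject_volumes: dict, labels: LabelVolume,
                   empty_policy: str = "error") -> pd.DataFrame:
    """Per-subject ROI means as an n_subjects x p_rois table.

    ``subject_volumes`` maps subject id -> 3-D contrast array or NIfTI
    path. Rows are ordered by sorted subject id.
    """
    rows = {}
    for subject_id in sorted(subject_volumes, key=str):
        vol = subject_volumes[subject_id]
        if not isinstance(vol, np.ndarray):
            vol = load_contrast_volume(vol)
        try:
            rows[str(subject_id)] = parcel_means(vol, labels, empty_policy)
        except ValueError as exc:
            raise ValueError(f"subject {subject_id!r}: {exc}") from exc
        logger.debug("extracted %d ROI means for subject %s", len(labels.names), subject_id)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "subject_id"
    return table
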