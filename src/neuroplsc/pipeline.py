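"""End-to-end orchestration: tables -> preprocessing -> PLSC -> inference -> report.

A run is described by a :class:`RunConfig` (typically loaded from a YAML
file): input table paths, an optional group filter or verification-
subsample block, resampling settings, and an output directory. The
pipeline writes a component summary, per-variable salience tables for
both blocks, a plain-text component report and a metadata JSON, all
deterministic given the config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from neuroplsc import __version__
from neuroplsc.datamodel import (StudyDataset, load_tables, filter_complete_cases,
                                 stratified_subsample, subset_group)
from neuroplsc.preprocess import prepare_blocks
from neuroplsc.plsc import plsc_fit
from neuroplsc.inference import (InferenceConfig, permutation_test,
                                 bootstrap_stability, significant_components)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Declarative description of one PLSC analysis run."""

    behavior_path: str
    brain_path: str
    confound_path: str
    output_dir: str
    measure_meta_path: str | None = None
    group: str = "all"  # all | TR | DR
    verification: dict | None = None  # {target_n, proportions, seed}
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    preprocess_order: str = "residualize_then_zscore"
    n_components: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        inputs = raw.get("inputs", {})
        inf = InferenceConfig(**raw.get("inference", {}))
        return cls(
            behavior_path=inputs["behavior"],
            brain_path=inputs["brain"],
            confound_path=inputs["confounds"],
            measure_meta_path=inputs.get("measure_metadata"),
            output_dir=raw["output_dir"],
            group=raw.get("group", "all"),
            verification=raw.get("verification"),
            inference=inf,
            preprocess_order=raw.get("preprocess_order", "residualize_then_zscore"),
            n_components=raw.get("n_components"),
        )

    def validate_paths(self) -> None:
        for label, p in (("behavior", self.behavior_path), ("brain", self.brain_path),
                         ("confounds", self.confound_path)):
            if not Path(p).exists():
                raise FileNotFoundError(f"{label} table not found: {p}")
        if self.measure_meta_path and not Path(self.measure_meta_path).exists():
            raise FileNotFoundError(f"measure metadata not found: {self.measure_meta_path}")


@dataclass(frozen=True)
class PipelineResult:
    """In-memory artifacts of one run (also written to the output directory)."""

    component_summary: pd.DataFrame
    behavior_saliences: pd.DataFrame
    brain_saliences: pd.DataFrame
    metadata: dict
    report_text: str


def select_sample(ds: StudyDataset, config: RunConfig) -> StudyDataset:
    """Apply the group filter or the verification-subsample block."""
    if config.verification is not None:
        v = config.verification
        proportions = v.get("proportions")
        if proportions is None:  # default: full-sample group proportions
            counts = ds.groups.value_counts()
            proportions = (counts / counts.sum()).to_dict()
        ds = stratified_subsample(ds, int(v["target_n"]), proportions,
                                  int(v.get("seed", config.inference.seed)))
    if config.group != "all":
        ds = subset_group(ds, config.group)
    return ds


def _salience_table(boot_block: pd.DataFrame) -> pd.DataFrame:
    """Long-format per-variable table: component, variable, mean, sd, z, significant."""
    rows = []
    for comp in boot_block.columns.get_level_values(0).unique():
        sub = boot_block[comp]
        for var in boot_block.index:
            rows.append({
                "component": comp,
                "variable": var,
                "mean": float(sub.loc[var, "mean"]),
                "sd": float(sub.loc[var, "sd"]),
                "z": float(sub.loc[var, "z"]),
                "significant": bool(sub.loc[var, "significant"]),
            })
    return pd.DataFrame(rows)


def analyze_dataset(ds: StudyDataset, config: RunConfig) -> PipelineResult:
    """Run preprocessing, PLSC and inference on an in-memory dataset."""
    ds = filter_complete_cases(ds)
    blocks = prepare_blocks(ds, order=config.preprocess_order)
    K = config.n_components or min(blocks.Xz.shape[1], blocks.Yz.shape[1])
    fit = plsc_fit(blocks.Xz, blocks.Yz, K)
    perm = permutation_test(blocks.Xz, blocks.Yz, K, config.inference)
    boot = bootstrap_stability(blocks.Xz, blocks.Yz, K, config.inference)

    summary = pd.DataFrame({
        "component": [f"comp{k + 1}" for k in range(K)],
        "singular_value": fit.s,
        "explained_pct": fit.explained,
        "latent_r": fit.r,
        "p_perm": perm.p,
        "significant": perm.p < config.inference.alpha,
    })
    group_counts = ds.groups.value_counts().to_dict()
    metadata = {
        "version": __version__,
        "n_subjects": ds.n_subjects,
        "group_counts": {str(k): int(v) for k, v in group_counts.items()},
        "n_behavior": int(blocks.Yz.shape[1]),
        "n_brain": int(blocks.Xz.shape[1]),
        "preprocess_order": blocks.order,
        "confounds": list(blocks.confound_columns),
        "inference": asdict(config.inference),
        "group_filter": config.group,
        "verification": config.verification,
        "bootstrap_redraws": boot.n_redraws,
    }
    result = PipelineResult(
        component_summary=summary,
        behavior_saliences=_salience_table(boot.behavior),
        brain_saliences=_salience_table(boot.brain),
        metadata=metadata,
        report_text="",
    )
    return replace(result, report_text=write_component_report(result))


def write_component_report(result: PipelineResult) -> str:
    """Render the per-component text report.

    For each significant component: permutation p, latent r, explained
    covariance, and the significant variables of both blocks ranked by
    |Z|; followed by an uncorrected listing of every variable. Every
    number shown also appears in a saved table.
    """
    lines = []
    summary = result.component_summary
    sig = summary[summary["significant"]]
    lines.append(f"PLSC component report (n = {result.metadata['n_subjects']}, "
                 f"group filter = {result.metadata['group_filter']})")
    lines.append("")
    if sig.empty:
        lines.append("No component is significant after permutation testing.")
    for _, row in sig.iterrows():
        comp = row["component"]
        lines.append(
            f"Component {comp}: p = {row['p_perm']:.4g}, r = {row['latent_r']:.3f}, "
            f"explained covariance = {row['explained_pct']:.1f}%")
        for block_name, table in (("behavioral measures", result.behavior_saliences),
                                  ("brain ROIs", result.brain_saliences)):
            sub = table[(table["component"] == comp) & table["significant"]]
            sub = sub.reindex(sub["z"].abs().sort_values(ascending=False).index)
            lines.append(f"  significant {block_name} ({len(sub)}):")
            for _, v in sub.iterrows():
                lines.append(f"    {v['variable']:<24s} Z = {v['z']:+8.2f}")
        lines.append("")
    lines.append("Component summary (all components):")
    for _, row in summary.iterrows():
        lines.append(
            f"  {row['component']:<8s} s = {row['singular_value']:.4f}  "
            f"explained = {row['explained_pct']:6.2f}%  r = {row['latent_r']:+.3f}  "
            f"p = {row['p_perm']:.4g}")
    return "\n".join(lines) + "\n"


def save_artifacts(result: PipelineResult, output_dir) -> None:
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.component_summary.to_csv(out / "component_summary.tsv", sep="\t", index=False)
    result.behavior_saliences.to_csv(out / "behavior_saliences.tsv", sep="\t", index=False)
    result.brain_saliences.to_csv(out / "brain_saliences.tsv", sep="\t", index=False)
    with open(out / "metadata.json", "w") as fh:
        json.dump(result.metadata, fh, indent=2, default=str)
    (out / "report.txt").write_text(result.report_text)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Load tables, select the sample, analyze, and write all artifacts."""
    config.validate_paths()
    ds = load_tables(config.behavior_path, config.brain_path, config.confound_path,
                     measure_meta_path=config.measure_meta_path)
    ds = select_sample(ds, config)
    result = analyze_dataset(ds, config)
    save_artifacts(result, config.output_dir)
    logger.info("pipeline artifacts written to %s", config.output_dir)
    return result
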