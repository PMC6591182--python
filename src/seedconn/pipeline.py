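"""End-to-end orchestration: inputs -> assignment -> density -> lateralization.

A single declarative config (YAML or :class:`PipelineConfig`) drives the
whole run.  Inputs are either real data (one TCK per subject, a label
volume per subject or one shared volume, one region table) or a phantom
sub-config, in which case the cohort is generated on the fly.  Outputs are
plain TSV tables (per-subject profiles, group summary, compartment sums,
lateralization) plus a JSON manifest that records the config, seeds and
full streamline accounting; a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assignment import DISCARD_REASONS, assign
from .density import aggregate_compartments, subject_profile, summarize_group
from .io import read_label_volume, read_region_table, read_tck
from .lateralization import tmax_permutation
from .phantom import PhantomConfig, iter_cohort

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline"]

log = logging.getLogger("seedconn")


class ConfigError(ValueError):
    """Invalid or inconsistent pipeline configuration."""


@dataclass
class PipelineConfig:
    """Declarative run description; defaults match the reference analysis
    (density threshold 1 %, 50,000 permutations, alpha 0.05)."""

    out_dir: str = "seedconn-out"
    threshold: float = 1.0
    n_perm: int = 50_000
    alpha: float = 0.05
    seed: int = 0
    strict_seed_traversal: bool = False
    # real-data inputs
    tck_paths: list[str] = field(default_factory=list)
    label_paths: list[str] = field(default_factory=list)
    regions_path: str | None = None
    # phantom inputs
    phantom: PhantomConfig | None = None
    n_subjects: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top-level YAML must be a mapping")
        phantom_raw = raw.pop("phantom", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if phantom_raw is not None:
            pf_known = {f.name for f in dataclasses.fields(PhantomConfig)}
            bad = set(phantom_raw) - pf_known
            if bad:
                raise ConfigError(f"{path}: unknown phantom keys: {sorted(bad)}")
            if "grid_shape" in phantom_raw:
                phantom_raw["grid_shape"] = tuple(phantom_raw["grid_shape"])
            if "true_weights" in phantom_raw and phantom_raw["true_weights"] is not None:
                phantom_raw["true_weights"] = tuple(phantom_raw["true_weights"])
            if "lateralization_shift" in phantom_raw and not np.isscalar(
                phantom_raw["lateralization_shift"]
            ):
                phantom_raw["lateralization_shift"] = tuple(
                    phantom_raw["lateralization_shift"]
                )
            cfg.phantom = PhantomConfig(**phantom_raw)
        cfg.validate()
        return cfg

    def validate(self) -> "PipelineConfig":
        if self.phantom is not None:
            if self.n_subjects < 1:
                raise ConfigError("phantom mode needs n_subjects >= 1")
            self.phantom.validate()
        else:
            if not self.tck_paths:
                raise ConfigError("either real inputs (tck_paths) or a phantom "
                                  "sub-config must be given")
            if self.regions_path is None:
                raise ConfigError("real-data mode needs regions_path")
            if len(self.label_paths) not in (1, len(self.tck_paths)):
                raise ConfigError("label_paths must hold one shared volume or one "
                                  "volume per subject")
        return self

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        if self.phantom is not None:
            d["phantom"] = dataclasses.asdict(self.phantom)
        return d


@dataclass
class PipelineReport:
    out_dir: Path
    profile_paths: list[Path]
    summary_path: Path
    compartments_path: Path
    lateralization_path: Path | None
    manifest_path: Path
    manifest: dict


def _iter_subjects(config: PipelineConfig):
    if config.phantom is not None:
        phantom_cfg = dataclasses.replace(config.phantom, seed=config.seed)
        for volume, table, subject in iter_cohort(phantom_cfg, config.n_subjects):
            yield subject.subject_id, subject.tractogram, volume, table
    else:
        table = read_region_table(config.regions_path)
        shared = (
            read_label_volume(config.label_paths[0])
            if len(config.label_paths) == 1
            else None
        )
        for i, tck in enumerate(config.tck_paths):
            volume = shared if shared is not None else read_label_volume(
                config.label_paths[i]
            )
            yield Path(tck).stem, read_tck(tck), volume, table


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run assignment, density, thresholding, compartments and lateralization.

    Fails before any computation on a missing input; otherwise writes all
    outputs under ``config.out_dir`` and returns their paths plus the
    manifest dict.
    """
    config.validate()
    if config.phantom is None:
        missing = [
            p
            for p in [*config.tck_paths, *config.label_paths, config.regions_path]
            if not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")

    out_dir = Path(config.out_dir)
    (out_dir / "profiles").mkdir(parents=True, exist_ok=True)

    profiles = []
    profile_paths = []
    accounting = []
    table = None
    for subject_id, tractogram, volume, table in _iter_subjects(config):
        result = assign(
            tractogram, volume, table, require_seed=config.strict_seed_traversal
        )
        prof = subject_profile(result, volume, table, subject_id=subject_id)
        profiles.append(prof)
        path = out_dir / "profiles" / f"{subject_id}.tsv"
        prof.table.to_csv(path, sep="\t", index_label="label", float_format="%.6f")
        profile_paths.append(path)
        row = {
            "subject": subject_id,
            "n_streamlines": result.n_streamlines,
            "assigned": result.n_assigned,
        }
        row.update({r: result.discard_counts.get(r, 0) for r in DISCARD_REASONS})
        accounting.append(row)
        log.info(
            "subject %s: %d streamlines, %d assigned, %d discarded",
            subject_id, result.n_streamlines, result.n_assigned, result.n_discarded,
        )

    summary = summarize_group(profiles, threshold=config.threshold)
    summary_path = out_dir / "group_summary.tsv"
    summary.table.to_csv(summary_path, sep="\t", index_label="label", float_format="%.6f")

    comp = aggregate_compartments(
        summary.table["mean_delta_norm"],
        table.df.loc[summary.table.index, "compartment"],
    )
    compartments_path = out_dir / "compartments.tsv"
    comp.rename("mean_delta_norm").to_csv(
        compartments_path, sep="\t", index_label="compartment", float_format="%.6f"
    )

    lateralization_path = None
    pairs = table.bilateral_pairs()
    if pairs and len(profiles) >= 2:
        left = np.column_stack([[p.delta_norm.loc[l] for p in profiles] for _, l, _ in pairs])
        right = np.column_stack([[p.delta_norm.loc[r] for p in profiles] for _, _, r in pairs])
        lat = tmax_permutation(
            left,
            right,
            pair_names=[name for name, _, _ in pairs],
            n_perm=config.n_perm,
            alpha=config.alpha,
            seed=config.seed,
        )
        lateralization_path = out_dir / "lateralization.tsv"
        lat.table.to_csv(lateralization_path, sep="\t", index=False, float_format="%.6f")

    manifest = {
        "seedconn_version": __version__,
        "config": config.to_manifest(),
        "n_subjects": len(profiles),
        "streamline_accounting": accounting,
        "retained_pathways": summary.retained_names,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return PipelineReport(
        out_dir=out_dir,
        profile_paths=profile_paths,
        summary_path=summary_path,
        compartments_path=compartments_path,
        lateralization_path=lateralization_path,
        manifest_path=manifest_path,
        manifest=manifest,
    )
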