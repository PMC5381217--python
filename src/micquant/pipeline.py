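"""End-to-end orchestration: quantify, benchmark and simulate runs.

A run is described by a :class:`RunConfig` (built from CLI flags or a YAML
file) holding *either* input paths (count table + metadata) *or* a
``simulate`` section — never both. ``run_quantify`` executes rarefaction ->
calibration -> consensus filtering -> NEC subtraction -> metrics and writes
corrected profiles, a removal ledger, per-replicate correction factors, an
optional accuracy report and a machine-readable manifest (config echo +
seed + package version) beside the outputs. Outputs carry no timestamps, so
re-running with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import __version__, metrics
from .io_tables import (
    CountTable,
    load_reference_accuracy_table,
    read_count_table,
    read_metadata,
    write_report,
)
from .model import AbsoluteAbundanceModel, AbsoluteAbundanceResults
from .simulator import SimulationConfig, SimulatedExperiment, simulate_experiment

logger = logging.getLogger("micquant")

__all__ = [
    "RunConfig",
    "ConfigError",
    "run_quantify",
    "run_benchmark",
    "benchmark_reports",
    "dataset_from_config",
    "accuracy_report_from_reference",
]


class ConfigError(ValueError):
    """The run configuration is inconsistent or incomplete."""


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    counts_path: str | None = None
    metadata_path: str | None = None
    counts_dialect: str = "tsv"
    simulate: dict[str, Any] | None = None
    rarefaction_depth: int | None = None
    consensus_min_copies: float = 0.0
    nec_sd_multiplier: float = 3.0
    expected_otus: tuple[str, ...] | None = None
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        has_input = self.counts_path is not None or self.metadata_path is not None
        if has_input and self.simulate is not None:
            raise ConfigError("config must contain either input paths or a simulate section, not both")
        if not has_input and self.simulate is None:
            raise ConfigError("config must contain input paths or a simulate section")
        if has_input and (self.counts_path is None or self.metadata_path is None):
            raise ConfigError("both counts and metadata paths are required")
        if self.nec_sd_multiplier < 0:
            raise ConfigError("nec_sd_multiplier must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        if "expected_otus" in raw and raw["expected_otus"] is not None:
            raw["expected_otus"] = tuple(raw["expected_otus"])
        return cls(**raw)


def _simulation_config(section: Mapping[str, Any]) -> tuple[list[float], SimulationConfig, int]:
    section = dict(section)
    levels = section.pop("levels", [2500.0, 250.0, 25.0, 2.5])
    seed = int(section.pop("seed", 0))
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(section) - known
    if unknown:
        raise ConfigError(f"simulate section: unknown keys {sorted(unknown)}")
    for key in ("taxa", "reagent_contaminants"):
        if key in section:
            section[key] = tuple((str(a), float(b)) for a, b in section[key])
    if "env_contaminant_pool" in section:
        section["env_contaminant_pool"] = tuple(section["env_contaminant_pool"])
    if "bulk_efficiency_range" in section:
        section["bulk_efficiency_range"] = tuple(section["bulk_efficiency_range"])
    return [float(x) for x in levels], SimulationConfig(**section), seed


def dataset_from_config(config: RunConfig):
    """Resolve a RunConfig into (CountTable, metadata, experiment|None)."""
    if config.simulate is not None:
        levels, sim_cfg, sim_seed = _simulation_config(config.simulate)
        experiment = simulate_experiment(levels, sim_cfg, sim_seed)
        return experiment.count_table(), experiment.metadata(), experiment
    counts = read_count_table(config.counts_path, config.counts_dialect)
    metadata = read_metadata(config.metadata_path)
    return counts, metadata, None


def run_quantify(config: RunConfig) -> AbsoluteAbundanceResults:
    """Execute the full quantification pipeline for one dataset."""
    counts, metadata, _ = dataset_from_config(config)
    model = AbsoluteAbundanceModel(
        counts,
        metadata,
        rarefaction_depth=config.rarefaction_depth,
        consensus_min_copies=config.consensus_min_copies,
        nec_sd_multiplier=config.nec_sd_multiplier,
    )
    results = model.fit(seed=config.seed, expected_otus=config.expected_otus)
    for sid, factor in sorted(results.correction_factors.items()):
        logger.info("correction factor %s: %.6g copies/read", sid, factor)
    for group, reason in results.skipped_groups.items():
        logger.warning("group %s skipped: %s", group, reason)
    if config.out_dir is not None:
        _write_outputs(results, config)
    return results


def _write_outputs(results: AbsoluteAbundanceResults, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results.abundance_frame().to_csv(out / "corrected_profiles.tsv", sep="\t", index=False, lineterminator="\n")
    results.removal_ledger().to_csv(out / "removal_ledger.tsv", sep="\t", index=False, lineterminator="\n")
    factors = pd.DataFrame(
        sorted(results.correction_factors.items()), columns=["sample_id", "copies_per_read"]
    )
    factors.to_csv(out / "correction_factors.tsv", sep="\t", index=False, lineterminator="\n")
    if results.accuracy is not None:
        write_report(results.accuracy, out / "accuracy_report.tsv")
    manifest = {
        "micquant_version": __version__,
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


# ---------------------------------------------------------------- benchmark


def accuracy_report_from_reference(method: str) -> metrics.AccuracyReport:
    """Accuracy report recomputed from the packaged validation measurements."""
    table = load_reference_accuracy_table()
    table = table[table["method"] == method]
    if table.empty:
        raise ValueError(f"unknown method {method!r} in reference table")
    measurements = {
        (row.taxon, float(row.input_copies), method): (row.rep1, row.rep2, row.rep3)
        for row in table.itertuples()
    }
    return metrics.build_accuracy_report(measurements)


def benchmark_reports(
    arm_a: metrics.AccuracyReport, arm_b: metrics.AccuracyReport, labels: tuple[str, str] = ("A", "B")
) -> dict[str, Any]:
    """Paired method comparison of two accuracy reports.

    Both arms must cover the same (taxon, level) cells. Returns paired
    per-cell CVs, pooled CVs, median folds, LODs and the paired Wilcoxon
    signed-rank test on the per-cell CVs.
    """
    cells_a = {(r.taxon, r.level): r for r in arm_a.rows}
    cells_b = {(r.taxon, r.level): r for r in arm_b.rows}
    if set(cells_a) != set(cells_b):
        raise ValueError(
            "benchmark arms cover different (taxon, level) cells: "
            f"{sorted(set(cells_a) ^ set(cells_b))}"
        )
    keys = sorted(cells_a, key=lambda k: (-k[1], k[0]))
    cv_a = [cells_a[k].precision for k in keys]
    cv_b = [cells_b[k].precision for k in keys]
    wilcoxon = metrics.wilcoxon_signed_rank(cv_a, cv_b)
    la, lb = labels
    return {
        "cells": keys,
        f"cv_{la}": cv_a,
        f"cv_{lb}": cv_b,
        f"pooled_cv_{la}": {lvl: v for (_, lvl), v in _pooled_by_level(arm_a).items()},
        f"pooled_cv_{lb}": {lvl: v for (_, lvl), v in _pooled_by_level(arm_b).items()},
        f"median_fold_{la}": _single_median_fold(arm_a),
        f"median_fold_{lb}": _single_median_fold(arm_b),
        f"lod_{la}": next(iter(arm_a.lod.values()), None),
        f"lod_{lb}": next(iter(arm_b.lod.values()), None),
        "wilcoxon_w": wilcoxon.statistic,
        "wilcoxon_p": wilcoxon.p_value,
        "wilcoxon_exact": wilcoxon.exact,
    }


def _pooled_by_level(report: metrics.AccuracyReport) -> dict[tuple[str, float], float]:
    return report.pooled_cv


def _single_median_fold(report: metrics.AccuracyReport) -> float | None:
    values = list(report.median_fold.values())
    return values[0] if len(values) == 1 else None


def run_benchmark(
    arm_a_dir: str | Path, arm_b_dir: str | Path, out_dir: str | Path | None = None, seed: int = 0
) -> dict[str, Any]:
    """Quantify two dataset directories (counts.tsv + metadata.tsv each) and
    compare them as paired arms."""
    reports = []
    labels = ("a", "b")
    for arm in (arm_a_dir, arm_b_dir):
        arm = Path(arm)
        cfg = RunConfig(
            counts_path=str(arm / "counts.tsv"),
            metadata_path=str(arm / "metadata.tsv"),
            seed=seed,
        )
        result = run_quantify(cfg)
        if result.accuracy is None:
            raise ConfigError(
                f"{arm}: benchmark needs validation metadata (expected_copies_per_taxon)"
            )
        reports.append(result.accuracy)
    comparison = benchmark_reports(reports[0], reports[1], labels)
    if out_dir is not None:
        _write_benchmark(comparison, Path(out_dir), labels)
    return comparison


def _write_benchmark(comparison: Mapping[str, Any], out: Path, labels: tuple[str, str]) -> None:
    out.mkdir(parents=True, exist_ok=True)
    la, lb = labels
    rows = [
        {
            "taxon": taxon,
            "input_copies": level,
            f"cv_{la}": cva,
            f"cv_{lb}": cvb,
        }
        for (taxon, level), cva, cvb in zip(
            comparison["cells"], comparison[f"cv_{la}"], comparison[f"cv_{lb}"]
        )
    ]
    pd.DataFrame(rows).to_csv(out / "benchmark_cells.tsv", sep="\t", index=False, lineterminator="\n")
    summary = {
        k: v
        for k, v in comparison.items()
        if k not in ("cells", f"cv_{la}", f"cv_{lb}")
    }
    summary[f"pooled_cv_{la}"] = {float(k): float(v) for k, v in summary[f"pooled_cv_{la}"].items()}
    summary[f"pooled_cv_{lb}"] = {float(k): float(v) for k, v in summary[f"pooled_cv_{lb}"].items()}
    with open(out / "benchmark_summary.yaml", "w") as fh:
        yaml.safe_dump(
            {k: (float(v) if isinstance(v, (int, float)) and not isinstance(v, bool) else v) for k, v in summary.items()},
            fh,
            sort_keys=True,
        )
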