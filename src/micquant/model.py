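"""Model/Results front end for calibrated absolute microbiota quantification.

:class:`AbsoluteAbundanceModel` is built from an OTU count table plus sample
metadata (which replicates form triplicates, which triplicate is the negative
extraction control, where the internal calibrator sits and how much was
spiked). Its :meth:`~AbsoluteAbundanceModel.fit` runs the full estimation
pipeline — optional rarefaction, calibrator-based conversion of reads to
absolute 16S copies, triplicate-consensus filtering, NEC-threshold
subtraction — and returns an :class:`AbsoluteAbundanceResults` carrying the
decontaminated copy estimates, per-replicate correction factors, per-OTU
precision diagnostics, a removal ledger, and (for validation dilution
series with known inputs) the accuracy statistics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import metrics
from .calibration import (
    CalibratedProfile,
    CalibrationError,
    InsufficientDepthError,
    ReadProfile,
    calibrate,
    rarefy,
)
from .decontamination import (
    DEFAULT_NEC_SD_MULTIPLIER,
    CorrectedProfile,
    NecModel,
    TriplicateSet,
    build_nec_model,
    correct,
)
from .io_tables import CountTable, SampleMetadata, validate_replicate_groups

__all__ = ["AbsoluteAbundanceModel", "AbsoluteAbundanceResults"]


class AbsoluteAbundanceModel:
    """Absolute 16S quantification of triplicate amplicon libraries.

    Parameters
    ----------
    counts
        Dense OTU x sample read-count table covering every sample in
        ``metadata`` (specimens and the NEC triplicate).
    metadata
        One entry per library; replicate groups of exactly 3, one NEC group.
    rarefaction_depth
        If set, every library is subsampled to this depth before
        calibration. Calibrated copies are invariant in expectation to the
        depth (the calibrator rescales with everything else); rarefaction
        only equalizes sampling noise across libraries.
    consensus_min_copies
        Presence threshold for the triplicate-consensus filter (default 0,
        i.e. at least one read).
    nec_sd_multiplier
        k in the mean + k*SD NEC subtraction threshold (default 3).
    min_ic_reads
        Calibrator-read floor below which a warning is emitted.
    """

    def __init__(
        self,
        counts: CountTable,
        metadata: Sequence[SampleMetadata],
        *,
        rarefaction_depth: int | None = None,
        consensus_min_copies: float = 0.0,
        nec_sd_multiplier: float = DEFAULT_NEC_SD_MULTIPLIER,
        min_ic_reads: int = 10,
    ) -> None:
        self.counts = counts
        self.metadata = list(metadata)
        self.groups = validate_replicate_groups(self.metadata)
        self.rarefaction_depth = rarefaction_depth
        self.consensus_min_copies = consensus_min_copies
        self.nec_sd_multiplier = nec_sd_multiplier
        self.min_ic_reads = min_ic_reads

        missing = [m.sample_id for m in self.metadata if m.sample_id not in counts.sample_ids]
        if missing:
            raise ValueError(f"metadata samples missing from count table: {missing}")
        nec_groups = [g for g, ms in self.groups.items() if ms[0].role == "nec"]
        if len(nec_groups) != 1:
            raise ValueError(
                f"exactly one NEC replicate group is required (found {len(nec_groups)}); "
                "the method cannot subtract reagent contamination without it"
            )
        self.nec_group_id = nec_groups[0]

    @classmethod
    def from_files(
        cls, counts_path, metadata_path, dialect: str = "tsv", **kwargs
    ) -> "AbsoluteAbundanceModel":
        from .io_tables import read_count_table, read_metadata

        return cls(read_count_table(counts_path, dialect), read_metadata(metadata_path), **kwargs)

    @classmethod
    def from_simulation(cls, experiment, **kwargs) -> "AbsoluteAbundanceModel":
        """Build directly from a :class:`~micquant.simulator.SimulatedExperiment`."""
        return cls(experiment.count_table(), experiment.metadata(), **kwargs)

    # ------------------------------------------------------------------ fit

    def fit(
        self, seed: int = 0, expected_otus: Sequence[str] | None = None
    ) -> "AbsoluteAbundanceResults":
        """Run the pipeline and return the results object.

        ``seed`` drives rarefaction only (one child stream per library,
        derived deterministically in sample order). ``expected_otus`` names
        the known community taxa of a validation series; when the metadata
        also carries expected input levels, accuracy statistics (trueness,
        precision, pooled CV, median fold, LOD) are computed over them.
        """
        streams = self._rarefaction_streams(seed)
        calibrated: dict[str, CalibratedProfile] = {}
        failures: dict[str, str] = {}
        for meta in sorted(self.metadata, key=lambda m: m.sample_id):
            sample_counts = self.counts.sample_counts(meta.sample_id)
            try:
                if self.rarefaction_depth is not None:
                    sample_counts = rarefy(
                        sample_counts, self.rarefaction_depth, streams[meta.sample_id]
                    )
                sample_counts.setdefault(meta.ic_otu_id, 0)
                profile = ReadProfile(
                    meta.sample_id, sample_counts, meta.ic_otu_id, meta.ic_spike_copies
                )
                calibrated[meta.sample_id] = calibrate(profile, self.min_ic_reads)
            except (CalibrationError, InsufficientDepthError) as exc:
                failures[meta.sample_id] = str(exc)

        skipped: dict[str, str] = {}
        triplicates: dict[str, TriplicateSet] = {}
        for group_id, members in self.groups.items():
            failed = [m.sample_id for m in members if m.sample_id in failures]
            if failed:
                skipped[group_id] = (
                    f"replicate(s) {failed} could not be calibrated: "
                    + "; ".join(failures[s] for s in failed)
                )
                continue
            ordered = sorted(members, key=lambda m: m.replicate_index)
            triplicates[group_id] = TriplicateSet(
                group_id, tuple(calibrated[m.sample_id] for m in ordered)
            )

        if self.nec_group_id in skipped:
            raise CalibrationError(
                f"NEC group {self.nec_group_id!r} failed calibration "
                f"({skipped[self.nec_group_id]}); the NEC triplicate is mandatory"
            )
        nec_model = build_nec_model(
            triplicates[self.nec_group_id], self.nec_sd_multiplier
        )

        corrected: dict[str, CorrectedProfile] = {}
        for group_id, trip in triplicates.items():
            if group_id == self.nec_group_id:
                continue
            corrected[group_id] = correct(trip, nec_model)

        accuracy = self._accuracy(triplicates, corrected, expected_otus)
        return AbsoluteAbundanceResults(
            model=self,
            calibrated=calibrated,
            corrected=corrected,
            nec_model=nec_model,
            skipped_groups=skipped,
            calibration_failures=failures,
            accuracy=accuracy,
            seed=seed,
        )

    def _rarefaction_streams(self, seed: int) -> dict[str, np.random.Generator]:
        order = sorted(m.sample_id for m in self.metadata)
        children = np.random.SeedSequence(int(seed)).spawn(len(order))
        return {sid: np.random.default_rng(ss) for sid, ss in zip(order, children)}

    def _group_level(self, group_id: str) -> float | None:
        levels = {m.expected_copies_per_taxon for m in self.groups[group_id]}
        if len(levels) == 1:
            return levels.pop()
        return None

    def _accuracy(
        self,
        triplicates: Mapping[str, TriplicateSet],
        corrected: Mapping[str, CorrectedProfile],
        expected_otus: Sequence[str] | None,
    ):
        levels: dict[float, str] = {}
        for group_id in corrected:
            level = self._group_level(group_id)
            if level is not None:
                if level in levels:
                    return None  # ambiguous design; accuracy needs one group per level
                levels[level] = group_id
        if not levels:
            return None

        if expected_otus is None:
            top = levels[max(levels)]
            expected_otus = sorted(corrected[top].otu_copies)
        if not expected_otus:
            return None

        measurements = {
            (otu, level, "observed"): triplicates[group_id].copies(otu)
            for level, group_id in levels.items()
            for otu in expected_otus
        }
        lod = metrics.estimate_lod(
            {level: corrected[gid] for level, gid in levels.items()}, expected_otus
        )
        return metrics.build_accuracy_report(measurements, lod={"observed": lod})


@dataclass
class AbsoluteAbundanceResults:
    """Fitted absolute-abundance estimates and their diagnostics."""

    model: AbsoluteAbundanceModel
    calibrated: dict[str, CalibratedProfile]
    corrected: dict[str, CorrectedProfile]
    nec_model: NecModel
    skipped_groups: dict[str, str]
    calibration_failures: dict[str, str]
    accuracy: metrics.AccuracyReport | None
    seed: int

    @property
    def correction_factors(self) -> dict[str, float]:
        """Copies-per-read conversion factor of every calibrated replicate."""
        return {sid: p.correction_factor for sid, p in self.calibrated.items()}

    def uncorrected_totals(self) -> dict[str, float]:
        """Per-replicate total calibrated copies before decontamination
        (the quantity comparable to a total-16S qPCR)."""
        return {sid: p.total_copies for sid, p in self.calibrated.items()}

    def abundance_frame(self) -> pd.DataFrame:
        """Corrected copies as a tidy frame (group_id, otu_id, copies)."""
        rows = [
            {"group_id": g, "otu_id": otu, "copies": copies}
            for g, prof in sorted(self.corrected.items())
            for otu, copies in sorted(prof.otu_copies.items())
        ]
        return pd.DataFrame(rows, columns=["group_id", "otu_id", "copies"])

    def removal_ledger(self) -> pd.DataFrame:
        """Every removed OTU with its removal reason, one row per (group, OTU)."""
        rows = [
            {"group_id": g, "otu_id": otu, "reason": reason}
            for g, prof in sorted(self.corrected.items())
            for otu, reason in sorted(prof.removed_otus.items())
        ]
        return pd.DataFrame(rows, columns=["group_id", "otu_id", "reason"])

    def precision_frame(self) -> pd.DataFrame:
        """Per retained OTU: triplicate mean copies and CV (diagnostic)."""
        rows = []
        for g, prof in sorted(self.corrected.items()):
            members = sorted(self.model.groups[g], key=lambda m: m.replicate_index)
            reps = [self.calibrated[m.sample_id] for m in members]
            for otu in sorted(prof.otu_copies):
                values = [r.otu_copies.get(otu, 0.0) for r in reps]
                mean = float(np.mean(values))
                rows.append(
                    {
                        "group_id": g,
                        "otu_id": otu,
                        "corrected_copies": prof.otu_copies[otu],
                        "replicate_mean": mean,
                        "cv": metrics.cv(values) if mean > 0 else math.nan,
                    }
                )
        return pd.DataFrame(
            rows, columns=["group_id", "otu_id", "corrected_copies", "replicate_mean", "cv"]
        )

    def summary(self) -> str:
        """Human-readable estimation summary."""
        lines = ["Absolute 16S quantification (calibrated, decontaminated)"]
        lines.append("=" * len(lines[0]))
        lines.append(
            f"groups: {len(self.corrected)} specimen + 1 NEC"
            + (f", {len(self.skipped_groups)} skipped" if self.skipped_groups else "")
        )
        factors = self.correction_factors
        if factors:
            vals = np.asarray(list(factors.values()))
            lines.append(
                f"correction factors (copies/read): min {vals.min():.4g}, "
                f"median {np.median(vals):.4g}, max {vals.max():.4g}"
            )
        lines.append(
            f"NEC thresholds: {len(self.nec_model.thresholds)} OTU(s), "
            f"mean + {self.nec_model.sd_multiplier:g}*SD rule"
        )
        frame = self.precision_frame()
        if not frame.empty:
            lines.append("")
            lines.append(frame.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
        ledger = self.removal_ledger()
        lines.append("")
        lines.append(f"removed OTUs: {len(ledger)}")
        if not ledger.empty:
            counts = ledger["reason"].value_counts()
            for reason, n in counts.items():
                lines.append(f"  {reason}: {n}")
        if self.accuracy is not None:
            lines.append("")
            lines.append("validation-series accuracy:")
            for row in self.accuracy.rows:
                lines.append(
                    f"  {row.taxon}@{row.level:g}: trueness "
                    f"{metrics.round_half_away(row.trueness, 1):.1f}, precision "
                    f"{metrics.round_half_away(row.precision, 1):.1f}"
                )
            for method, lod in self.accuracy.lod.items():
                lines.append(f"  LOD: {lod:g} copies per OTU")
        for g, reason in self.skipped_groups.items():
            lines.append(f"skipped {g}: {reason}")
        return "\n".join(lines)
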