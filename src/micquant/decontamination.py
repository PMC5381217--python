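"""Two-step removal of contaminating bacterial DNA from calibrated profiles.

Contamination enters amplicon libraries from two sources with different
statistical signatures, and each gets its own correction step:

1. **Environmental contamination** (DNA picked up from the processing
   environment) hits individual replicates at random. Amplifying every
   sample in triplicate and keeping only OTUs present in *all three*
   replicates removes such sporadic signal (consensus filter).
2. **Reagent/consumable contamination** is lot-dependent and therefore
   reproducible: it appears in every library made with the same reagents,
   including negative extraction controls (NECs). A NEC triplicate is
   calibrated like any sample; for each OTU quantified in all three NEC
   replicates, a subtraction threshold of mean + k*SD (k = 3 by default,
   SD with the n-1 denominator) is computed, and that threshold is
   subtracted from the specimen's triplicate-mean copies.

The consensus filter runs first, then the NEC subtraction — sporadic OTUs
must not survive into the subtraction step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .calibration import CalibratedProfile

__all__ = [
    "TriplicateSet",
    "NecModel",
    "CorrectedProfile",
    "REASON_NOT_REPRODUCIBLE",
    "REASON_BELOW_NEC",
    "consensus_filter",
    "build_nec_model",
    "subtract_nec",
    "correct",
]

REASON_NOT_REPRODUCIBLE = "not_reproducible"
REASON_BELOW_NEC = "below_nec_threshold"

DEFAULT_NEC_SD_MULTIPLIER = 3.0


@dataclass(frozen=True)
class TriplicateSet:
    """Three calibrated replicates of one biological sample."""

    group_id: str
    profiles: tuple[CalibratedProfile, CalibratedProfile, CalibratedProfile]

    def __post_init__(self) -> None:
        if len(self.profiles) != 3:
            raise ValueError(
                f"group {self.group_id!r}: exactly 3 replicates required, got {len(self.profiles)}"
            )

    def otu_union(self) -> set[str]:
        out: set[str] = set()
        for p in self.profiles:
            out.update(p.otu_copies)
        return out

    def copies(self, otu: str) -> tuple[float, float, float]:
        """The OTU's copy estimates across the three replicates (0 if absent)."""
        return tuple(p.otu_copies.get(otu, 0.0) for p in self.profiles)  # type: ignore[return-value]

    def mean_copies(self) -> dict[str, float]:
        """Per-OTU mean copies over the three replicates (union of OTUs)."""
        return {otu: float(np.mean(self.copies(otu))) for otu in self.otu_union()}


@dataclass(frozen=True)
class NecModel:
    """Per-OTU reagent-contamination subtraction thresholds.

    Only OTUs quantified in all three NEC replicates carry a threshold;
    any other OTU implicitly subtracts 0.
    """

    thresholds: dict[str, float]
    source_group: str
    sd_multiplier: float = DEFAULT_NEC_SD_MULTIPLIER

    def __post_init__(self) -> None:
        for otu, thr in self.thresholds.items():
            if thr < 0:
                raise ValueError(f"NEC threshold for {otu!r} must be >= 0")

    def threshold(self, otu: str) -> float:
        return self.thresholds.get(otu, 0.0)

    @classmethod
    def empty(cls, source_group: str = "none") -> "NecModel":
        return cls({}, source_group)


@dataclass(frozen=True)
class CorrectedProfile:
    """Decontaminated absolute-abundance profile of one triplicate group.

    ``otu_copies`` holds strictly positive triplicate-mean copies after both
    correction steps; ``removed_otus`` records every eliminated OTU with its
    removal reason. The two sets are disjoint and together cover every OTU
    seen in any replicate.
    """

    group_id: str
    otu_copies: dict[str, float]
    removed_otus: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.otu_copies) & set(self.removed_otus)
        if overlap:
            raise ValueError(f"OTUs both retained and removed: {sorted(overlap)}")
        for otu, copies in self.otu_copies.items():
            if not copies > 0:
                raise ValueError(f"retained OTU {otu!r} must have copies > 0")

    @property
    def total_copies(self) -> float:
        return float(sum(self.otu_copies.values()))


def consensus_filter(
    trip: TriplicateSet, min_copies: float = 0.0
) -> tuple[set[str], set[str]]:
    """Partition a triplicate's OTUs into reproducible and sporadic sets.

    An OTU is retained iff its copies exceed ``min_copies`` (default 0,
    i.e. at least one read) in **all three** replicates; everything else is
    removed as a presumptive environmental contaminant or stochastic dropout.
    """
    retained: set[str] = set()
    removed: set[str] = set()
    for otu in trip.otu_union():
        if all(c > min_copies for c in trip.copies(otu)):
            retained.add(otu)
        else:
            removed.add(otu)
    return retained, removed


def build_nec_model(
    nec_trip: TriplicateSet, sd_multiplier: float = DEFAULT_NEC_SD_MULTIPLIER
) -> NecModel:
    """Derive per-OTU subtraction thresholds from a NEC triplicate.

    For each OTU quantified (> 0 copies) in all three NEC replicates the
    threshold is mean + ``sd_multiplier``*SD of the three copy values, with
    the sample (n-1) standard deviation. OTUs failing the all-three rule get
    no entry and contribute nothing.
    """
    if sd_multiplier < 0:
        raise ValueError("sd_multiplier must be >= 0")
    present_in_all, _ = consensus_filter(nec_trip)
    thresholds: dict[str, float] = {}
    for otu in present_in_all:
        values = np.asarray(nec_trip.copies(otu), dtype=float)
        thresholds[otu] = float(values.mean() + sd_multiplier * values.std(ddof=1))
    return NecModel(thresholds, nec_trip.group_id, sd_multiplier)


def subtract_nec(
    mean_copies: Mapping[str, float], nec: NecModel
) -> tuple[dict[str, float], set[str]]:
    """Subtract NEC thresholds from triplicate-mean copies.

    Returns the surviving OTUs (strictly positive remainder) and the set of
    OTUs dropped because the remainder was <= 0.
    """
    kept: dict[str, float] = {}
    dropped: set[str] = set()
    for otu, copies in mean_copies.items():
        remainder = copies - nec.threshold(otu)
        if remainder > 0:
            kept[otu] = float(remainder)
        else:
            dropped.add(otu)
    return kept, dropped


def correct(trip: TriplicateSet, nec: NecModel) -> CorrectedProfile:
    """Full two-step decontamination of one specimen triplicate.

    Consensus filter first, then averaging of the retained OTUs' copies over
    the three replicates, then NEC-threshold subtraction of the means.
    """
    retained, sporadic = consensus_filter(trip)
    means = {otu: float(np.mean(trip.copies(otu))) for otu in retained}
    kept, below_nec = subtract_nec(means, nec)
    removed = {otu: REASON_NOT_REPRODUCIBLE for otu in sporadic}
    removed.update({otu: REASON_BELOW_NEC for otu in below_nec})
    return CorrectedProfile(trip.group_id, kept, removed)
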