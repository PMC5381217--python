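"""Internal-calibrator conversion of sequence reads to absolute 16S gene copies.

A known quantity of genomic DNA from a taxon absent from the samples (here a
*Synechococcus* species) is spiked into each reaction before amplification.
After sequencing, the calibrator's read count anchors a per-replicate
correction factor

    copies_per_read = spiked_calibrator_copies / calibrator_reads

and every other OTU's absolute abundance is estimated as

    otu_copies = otu_reads * copies_per_read.

The factor absorbs replicate-wide efficiency differences in the NGS process
(library yield, sequencing depth, rarefaction), so calibrated copies are
invariant to a uniform rescaling of all read counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "ReadProfile",
    "CalibratedProfile",
    "CalibrationError",
    "InsufficientDepthError",
    "correction_factor",
    "calibrate",
    "recommend_spike",
    "rarefy",
]

#: Calibrator read counts below this trigger a precision warning: the
#: correction factor is a ratio estimate and becomes noisy at few reads.
DEFAULT_MIN_IC_READS = 10


class CalibrationError(ValueError):
    """The replicate cannot be calibrated (e.g. zero calibrator reads).

    Such a replicate is unusable and must be dropped or re-run; no value is
    ever substituted for the missing correction factor.
    """


class InsufficientDepthError(ValueError):
    """A sample has fewer total reads than the requested rarefaction depth."""


@dataclass(frozen=True)
class ReadProfile:
    """Per-replicate OTU read counts, including the internal-calibrator OTU."""

    sample_id: str
    otu_reads: dict[str, int]
    ic_otu_id: str
    ic_spike_copies: float

    def __post_init__(self) -> None:
        if self.ic_otu_id not in self.otu_reads:
            raise ValueError(
                f"{self.sample_id}: calibrator OTU {self.ic_otu_id!r} missing from "
                "otu_reads; record it explicitly (0 reads is allowed)"
            )
        if not self.ic_spike_copies > 0:
            raise ValueError(f"{self.sample_id}: ic_spike_copies must be > 0")
        for otu, reads in self.otu_reads.items():
            if reads < 0 or int(reads) != reads:
                raise ValueError(f"{self.sample_id}: read count for {otu!r} must be a non-negative integer")

    @property
    def ic_reads(self) -> int:
        return int(self.otu_reads[self.ic_otu_id])

    @property
    def total_reads(self) -> int:
        return int(sum(self.otu_reads.values()))


@dataclass(frozen=True)
class CalibratedProfile:
    """Per-replicate absolute abundance estimates (16S copies per reaction).

    The calibrator OTU is excluded: it is a spike, not part of the sample.
    """

    sample_id: str
    otu_copies: dict[str, float]
    correction_factor: float

    def __post_init__(self) -> None:
        if not self.correction_factor > 0:
            raise ValueError(f"{self.sample_id}: correction factor must be > 0")
        for otu, copies in self.otu_copies.items():
            if copies < 0:
                raise ValueError(f"{self.sample_id}: negative copies for {otu!r}")

    @property
    def total_copies(self) -> float:
        return float(sum(self.otu_copies.values()))


def correction_factor(ic_spike_copies: float, ic_reads: int) -> float:
    """Copies-per-read conversion factor from the internal calibrator.

    Raises :class:`CalibrationError` when the calibrator yielded no reads.
    """
    if not ic_spike_copies > 0:
        raise CalibrationError(f"ic_spike_copies must be > 0, got {ic_spike_copies}")
    if ic_reads < 1:
        raise CalibrationError(
            "internal calibrator yielded 0 reads; the replicate cannot be "
            "calibrated and must be dropped or re-run"
        )
    return ic_spike_copies / ic_reads


def calibrate(profile: ReadProfile, min_ic_reads: int = DEFAULT_MIN_IC_READS) -> CalibratedProfile:
    """Convert one replicate's read counts to absolute 16S copy estimates.

    Every non-calibrator OTU is scaled by the replicate's correction factor;
    zero reads map to zero copies. Calibrator reads below ``min_ic_reads``
    emit a warning (noisy factor) but the replicate is still processed.
    """
    factor = correction_factor(profile.ic_spike_copies, profile.ic_reads)
    if profile.ic_reads < min_ic_reads:
        warnings.warn(
            f"{profile.sample_id}: only {profile.ic_reads} calibrator reads "
            f"(< {min_ic_reads}); the correction factor is imprecise",
            UserWarning,
            stacklevel=2,
        )
    copies = {
        otu: reads * factor
        for otu, reads in profile.otu_reads.items()
        if otu != profile.ic_otu_id
    }
    return CalibratedProfile(profile.sample_id, copies, factor)


def recommend_spike(total_sample_copies: float) -> float:
    """Recommended calibrator spike: 10% of the sample's total 16S copies,
    with a floor of 50 copies for samples under 500 total copies (including
    blanks, where the total is 0)."""
    if total_sample_copies < 0:
        raise ValueError(f"total_sample_copies must be >= 0, got {total_sample_copies}")
    if total_sample_copies >= 500:
        return 0.10 * total_sample_copies
    return 50.0


def rarefy(
    counts: Mapping[str, int],
    depth: int,
    seed: int | np.random.Generator,
) -> dict[str, int]:
    """Subsample a read-count map to a fixed depth without replacement.

    Multivariate hypergeometric draw: the output sums exactly to ``depth``
    and each OTU's count never exceeds its input. Deterministic given the
    seed. Raises :class:`InsufficientDepthError` when the sample is too
    shallow — the sample is flagged, never silently kept.
    """
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    otus = list(counts)
    values = np.asarray([counts[o] for o in otus], dtype=np.int64)
    if (values < 0).any():
        raise ValueError("read counts must be non-negative")
    total = int(values.sum())
    if total < depth:
        raise InsufficientDepthError(
            f"total reads {total} < rarefaction depth {depth}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    drawn = rng.multivariate_hypergeometric(values, depth)
    return {otu: int(n) for otu, n in zip(otus, drawn)}
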