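"""Assay-validation statistics for absolute 16S quantification.

Implements the accuracy vocabulary of quantitative-assay validation applied
to an equimolar dilution series measured in triplicate:

* **trueness** -- triplicate-mean measured copies divided by the expected
  copies (closeness to truth; 1.0 is perfect);
* **precision / CV** -- sample standard deviation of the replicates divided
  by their mean (closeness of replicates to each other);
* **pooled CV** -- the CV over all replicate measurements of all taxa at one
  equimolar input level (valid only because all share one expected value);
* **median fold** -- the median of per-(taxon, level) trueness values,
  a robust one-number summary of systematic bias;
* **LOD** -- the lowest input level at which every expected taxon survives
  the full decontamination pipeline, requiring detection at every higher
  level too (contiguity);
* **concordance** -- per-sample ratio of calibrated total copies to an
  independent total-16S qPCR estimate;
* a paired exact Wilcoxon signed-rank test (for comparing the per-cell CVs
  of two methods) and a Kolmogorov-Smirnov normality check.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "trueness",
    "cv",
    "pooled_cv",
    "median_fold",
    "estimate_lod",
    "concordance",
    "ConcordanceResult",
    "wilcoxon_signed_rank",
    "WilcoxonResult",
    "ks_normality",
    "round_half_away",
    "ReportRow",
    "AccuracyReport",
    "build_accuracy_report",
]

#: Sentinel returned by estimate_lod when no level is completely detected.
LOD_NOT_REACHED = math.inf


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (display convention for report tables)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def trueness(replicates: Sequence[float], expected: float) -> float:
    """Mean of the replicate copy values divided by the expected copies."""
    if not expected > 0:
        raise ValueError(f"expected copies must be > 0, got {expected}")
    return float(np.mean(np.asarray(replicates, dtype=float))) / expected


def cv(values: Sequence[float]) -> float:
    """Coefficient of variation: sample (n-1) SD divided by the mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = arr.mean()
    if not mean > 0:
        raise ValueError("CV undefined: mean of values is not positive")
    return float(arr.std(ddof=1) / mean)


def pooled_cv(
    values: Sequence[float], expected_values: Sequence[float] | None = None
) -> float:
    """CV over the pooled replicate measurements of one equimolar input level.

    Pooling across taxa is only meaningful when every taxon shares the same
    expected value; if per-taxon expectations are supplied and differ, the
    operation refuses rather than return a statistically invalid number.
    """
    if expected_values is not None:
        uniq = set(float(e) for e in expected_values)
        if len(uniq) > 1:
            raise ValueError(
                f"pooled CV requires an equimolar design; got expected values {sorted(uniq)}"
            )
    return cv(values)


def median_fold(trueness_values: Sequence[float]) -> float:
    """Median of per-(taxon, level) trueness values (mean-of-middle for even n)."""
    arr = np.asarray(trueness_values, dtype=float)
    if arr.size == 0:
        raise ValueError("median_fold needs at least one value")
    return float(np.median(arr))


def _detected_otus(profile) -> set[str]:
    if hasattr(profile, "otu_copies"):
        return set(profile.otu_copies)
    return set(profile)


def estimate_lod(series: Mapping[float, object], expected_otus: Iterable[str]) -> float:
    """Limit of detection from a corrected dilution series.

    ``series`` maps input level (copies per taxon) to the corrected profile
    (or a plain collection of detected OTU ids) at that level. Returns the
    lowest level at which every expected OTU is detected, provided all
    higher levels also detect all of them; ``math.inf`` if even the highest
    level is incomplete.
    """
    if not series:
        raise ValueError("estimate_lod needs a non-empty dilution series")
    expected = set(expected_otus)
    lod = LOD_NOT_REACHED
    for level in sorted(series, reverse=True):
        if expected <= _detected_otus(series[level]):
            lod = level
        else:
            break  # contiguity: a gap resets nothing below it
    return lod


@dataclass(frozen=True)
class ConcordanceResult:
    fold_per_sample: dict[str, float]
    mean: float
    sd: float


def concordance(
    calibrated_totals: Mapping[str, float], qpcr_totals: Mapping[str, float]
) -> ConcordanceResult:
    """Per-sample fold difference between calibrated-NGS and qPCR totals.

    The fold is the signed ratio calibrated/qPCR (not folded around 1), so
    systematic over- and under-estimation remain distinguishable. Totals are
    taken from calibration *without* decontamination, since the qPCR also
    measures contaminating DNA.
    """
    if set(calibrated_totals) != set(qpcr_totals):
        raise ValueError("calibrated and qPCR totals must cover the same samples")
    folds: dict[str, float] = {}
    for sample, cal in calibrated_totals.items():
        ref = qpcr_totals[sample]
        if not cal > 0 or not ref > 0:
            raise ValueError(f"sample {sample!r}: totals must be > 0")
        folds[sample] = cal / ref
    arr = np.asarray(list(folds.values()), dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return ConcordanceResult(folds, float(arr.mean()), sd)


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W = min(W+, W-)
    p_value: float
    n_used: int  # pairs remaining after zero differences are dropped
    exact: bool


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float] | None = None, exact_max_n: int = 20
) -> WilcoxonResult:
    """Paired two-sided Wilcoxon signed-rank test.

    Zero differences are dropped; tied absolute differences receive
    mid-ranks. The statistic is W = min(W+, W-). For n <= ``exact_max_n``
    pairs (after dropping zeros) the p-value is exact, from the full null
    distribution of W+ over all 2^n sign assignments (computed by dynamic
    programming, so ties are handled exactly); for larger n a normal
    approximation with tie correction and continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    if y is not None:
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("paired samples must have equal length")
        diffs = x - y
    else:
        diffs = x
    if diffs.size == 0:
        raise ValueError("wilcoxon_signed_rank needs at least one pair")

    diffs = diffs[diffs != 0.0]
    n = diffs.size
    if n == 0:
        warnings.warn(
            "all paired differences are zero; the test is degenerate",
            UserWarning,
            stacklevel=2,
        )
        return WilcoxonResult(0.0, 1.0, 0, True)

    ranks = stats.rankdata(np.abs(diffs))  # mid-ranks on ties
    w_plus = float(ranks[diffs > 0].sum())
    w_minus = float(ranks[diffs < 0].sum())
    w = min(w_plus, w_minus)

    if n <= exact_max_n:
        p = _exact_wilcoxon_p(ranks, w)
        return WilcoxonResult(w, p, n, True)

    mean_w = n * (n + 1) / 4.0
    counts = np.unique(ranks, return_counts=True)[1]
    tie_term = float(((counts**3 - counts) / 48.0).sum())
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var_w <= 0:
        return WilcoxonResult(w, 1.0, n, False)
    z = (w - mean_w + 0.5) / math.sqrt(var_w)  # continuity correction toward the null
    p = min(1.0, 2.0 * stats.norm.cdf(z))
    return WilcoxonResult(w, p, n, False)


def _exact_wilcoxon_p(ranks: np.ndarray, w_observed: float) -> float:
    """Exact two-sided p = P(min(W+, W-) <= w) under random signs.

    Mid-ranks are half-integers at worst, so doubling makes them integers and
    the null distribution of 2*W+ is a polynomial convolution over sign
    assignments (each rank contributes 0 or its doubled value with equal
    probability).
    """
    doubled = np.rint(2.0 * ranks).astype(np.int64)
    total = int(doubled.sum())
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    w2 = int(math.floor(2.0 * w_observed + 1e-9))
    lower = float(dist[: w2 + 1].sum())
    # symmetry of W+ about total/2: P(min(W+,W-) <= w) = 2*P(W+ <= w), capped
    return min(1.0, 2.0 * lower)


def ks_normality(values: Sequence[float]) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov check against a fitted normal.

    The reference normal uses the sample mean and the n-1 SD, so the p-value
    is approximate (parameters estimated from the data; anti-conservative).
    Returns (D, p).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValueError("ks_normality needs at least 3 values")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ValueError("ks_normality undefined for zero-variance data")
    result = stats.kstest(arr, "norm", args=(arr.mean(), sd))
    return float(result.statistic), float(result.pvalue)


@dataclass(frozen=True)
class ReportRow:
    taxon: str
    level: float
    method: str
    replicates: tuple[float, float, float]
    expected: float
    trueness: float
    precision: float


@dataclass
class AccuracyReport:
    """Accuracy summary of a validation dilution series.

    ``pooled_cv`` maps (method, level) to the pooled coefficient of
    variation; ``median_fold`` and ``lod`` are per method; ``concordance``
    is optional (needs independent qPCR totals).
    """

    rows: list[ReportRow]
    pooled_cv: dict[tuple[str, float], float] = field(default_factory=dict)
    median_fold: dict[str, float] = field(default_factory=dict)
    lod: dict[str, float] = field(default_factory=dict)
    concordance: ConcordanceResult | None = None

    def row(self, taxon: str, level: float, method: str) -> ReportRow:
        for r in self.rows:
            if r.taxon == taxon and r.level == level and r.method == method:
                return r
        raise KeyError((taxon, level, method))


def build_accuracy_report(
    measurements: Mapping[tuple[str, float, str], Sequence[float]],
    expected_by_level: Mapping[float, float] | None = None,
    lod: Mapping[str, float] | None = None,
    concordance_result: ConcordanceResult | None = None,
) -> AccuracyReport:
    """Assemble an AccuracyReport from triplicate measurements.

    ``measurements`` maps (taxon, input level, method) to the three replicate
    copy values; the expected value per level defaults to the level itself
    (equimolar design: input copies per taxon ARE the expectation).
    """
    rows: list[ReportRow] = []
    by_method_level: dict[tuple[str, float], list[float]] = {}
    trueness_by_method: dict[str, list[float]] = {}
    for (taxon, level, method), reps in sorted(measurements.items(), key=lambda kv: (kv[0][2], -kv[0][1], kv[0][0])):
        reps = tuple(float(v) for v in reps)
        if len(reps) != 3:
            raise ValueError(f"{taxon}@{level} ({method}): exactly 3 replicates required")
        expected = (
            expected_by_level[level] if expected_by_level is not None else float(level)
        )
        t = trueness(reps, expected)
        mean = float(np.mean(reps))
        precision = cv(reps) if mean > 0 else math.nan
        rows.append(ReportRow(taxon, float(level), method, reps, expected, t, precision))
        by_method_level.setdefault((method, float(level)), []).extend(reps)
        trueness_by_method.setdefault(method, []).append(t)

    pooled = {
        key: pooled_cv(vals)
        for key, vals in by_method_level.items()
        if float(np.mean(vals)) > 0
    }
    med = {m: median_fold(vals) for m, vals in trueness_by_method.items()}
    return AccuracyReport(
        rows=rows,
        pooled_cv=pooled,
        median_fold=med,
        lod=dict(lod) if lod else {},
        concordance=concordance_result,
    )
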