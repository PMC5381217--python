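"""Reading and writing of OTU count tables, sample metadata and accuracy reports.

Count tables are dense OTU x sample matrices of sequence-read counts. An OTU
that is missing from a sample is an explicit zero: the triplicate-consensus
filter downstream needs to distinguish "not observed" (0 reads) from "not in
the table", so the dense convention is used throughout.

Two count-table dialects are supported:

* ``tsv`` -- first column ``otu_id``, one column per sample, written by
  :func:`write_count_table` (round-trip safe);
* ``mothur_shared`` -- the mothur ``.shared`` layout (``label``/``Group``/
  ``numOtus`` prefix columns, one row per sample), accepted read-only.

The module also packages the published validation-series measurements
(four equimolar taxa at 2,500/250/25/2.5 input 16S copies, triplicate copy
determinations for micelle PCR and traditional bulk PCR), available via
:func:`load_reference_accuracy_table`.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "CountTable",
    "SampleMetadata",
    "TableFormatError",
    "MetadataError",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "load_reference_accuracy_table",
    "write_report",
    "read_report",
]

REFERENCE_LEVELS = (2500.0, 250.0, 25.0, 2.5)
REFERENCE_TAXA = ("Clostridium", "Staphylococcus", "Haemophilus", "Moraxella")
REFERENCE_METHODS = ("micPCR", "traditional")


class TableFormatError(ValueError):
    """A count table violates the format contract (non-integer counts, duplicates...)."""


class MetadataError(ValueError):
    """Sample metadata violates the replicate-group or calibrator invariants."""


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample annotations tying a sequencing library to its replicate group.

    Parameters
    ----------
    sample_id
        Unique library identifier, matching a count-table column.
    replicate_index
        1..3; every biological sample (and every negative extraction control)
        is processed as an amplification triplicate.
    role
        ``"specimen"`` or ``"nec"`` (negative extraction control).
    ic_otu_id
        OTU identifier of the internal calibrator (a taxon absent from the
        samples, spiked as quantified genomic DNA before amplification).
    ic_spike_copies
        16S rRNA gene copies of calibrator added to the reaction; must be > 0
        for any sample entering calibration.
    group_id
        Replicate-group key. If omitted, derived from ``sample_id`` by
        stripping a trailing replicate token (``_r1``, ``-2``, ``.3`` ...).
    expected_copies_per_taxon
        For validation dilution series: the known equimolar input per taxon.
    qpcr_total_copies
        Optional independent total-16S qPCR estimate for concordance checks.
    """

    sample_id: str
    replicate_index: int
    role: str
    ic_otu_id: str
    ic_spike_copies: float
    group_id: str | None = None
    expected_copies_per_taxon: float | None = None
    qpcr_total_copies: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ("specimen", "nec"):
            raise MetadataError(
                f"sample {self.sample_id!r}: role must be 'specimen' or 'nec', got {self.role!r}"
            )
        if not 1 <= int(self.replicate_index) <= 3:
            raise MetadataError(
                f"sample {self.sample_id!r}: replicate_index must be 1..3, got {self.replicate_index}"
            )
        if not self.ic_spike_copies > 0:
            raise MetadataError(
                f"sample {self.sample_id!r}: ic_spike_copies must be > 0 "
                f"(got {self.ic_spike_copies}); calibration is impossible without a spike"
            )

    @property
    def resolved_group_id(self) -> str:
        if self.group_id:
            return self.group_id
        return _strip_replicate_token(self.sample_id)


_REP_TOKEN = re.compile(r"[._-]r?\d+$")


def _strip_replicate_token(sample_id: str) -> str:
    stripped = _REP_TOKEN.sub("", sample_id)
    return stripped or sample_id


@dataclass
class CountTable:
    """Dense OTU x sample matrix of non-negative integer read counts."""

    counts: pd.DataFrame  # index: otu_id, columns: sample_id, dtype: int64
    annotations: dict[str, str] = field(default_factory=dict)  # e.g. OTU -> taxonomy

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate OTU ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate sample ids: {dups}")
        _validate_integral(df)
        self.counts = df.astype("int64")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def sample_counts(self, sample_id: str) -> dict[str, int]:
        """Per-OTU read counts of one sample as a plain dict (dense, zeros kept)."""
        return self.counts[sample_id].astype(int).to_dict()


def _validate_integral(df: pd.DataFrame) -> None:
    for col in df.columns:
        series = df[col]
        for otu, value in series.items():
            if isinstance(value, str) or (isinstance(value, float) and not float(value).is_integer()):
                raise TableFormatError(
                    f"count at OTU {otu!r}, sample {col!r} is not an integer: {value!r}"
                )
            if value < 0:
                raise TableFormatError(
                    f"negative count at OTU {otu!r}, sample {col!r}: {value!r}"
                )


def read_count_table(path: str | Path, dialect: str = "tsv") -> CountTable:
    """Read an OTU count table.

    ``dialect="tsv"``: first column ``otu_id``, remaining columns one per
    sample. ``dialect="mothur_shared"``: mothur shared-file layout
    (label/Group/numOtus prefix columns, samples as rows) transposed into the
    same OTU x sample structure.

    Unparseable cells raise :class:`TableFormatError`; nothing is coerced.
    """
    path = Path(path)
    if dialect == "tsv":
        raw = pd.read_csv(path, sep="\t", dtype=str)
        if raw.columns[0] != "otu_id":
            raise TableFormatError(
                f"{path}: first column must be 'otu_id', got {raw.columns[0]!r}"
            )
        raw = raw.set_index("otu_id")
    elif dialect == "mothur_shared":
        raw = pd.read_csv(path, sep="\t", dtype=str)
        expected = ["label", "Group", "numOtus"]
        if list(raw.columns[:3]) != expected:
            raise TableFormatError(
                f"{path}: mothur shared file must start with columns {expected}, "
                f"got {list(raw.columns[:3])}"
            )
        raw = raw.drop(columns=["label", "numOtus"]).set_index("Group").T
        raw.index.name = "otu_id"
        raw.columns.name = None
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    parsed = pd.DataFrame(index=raw.index.astype(str), columns=raw.columns.astype(str), dtype="int64")
    for col in raw.columns:
        for otu, cell in raw[col].items():
            try:
                value = int(str(cell))
            except (TypeError, ValueError):
                raise TableFormatError(
                    f"{path}: unparseable count at OTU {otu!r}, sample {col!r}: {cell!r}"
                ) from None
            if value < 0:
                raise TableFormatError(
                    f"{path}: negative count at OTU {otu!r}, sample {col!r}: {value}"
                )
            parsed.at[otu, col] = value
    return CountTable(parsed)


def write_count_table(table: CountTable, path: str | Path) -> None:
    """Write a count table in the ``tsv`` dialect (round-trip safe)."""
    out = table.counts.copy()
    out.index.name = "otu_id"
    out.to_csv(Path(path), sep="\t", lineterminator="\n")


_REQUIRED_META_COLS = ("sample_id", "replicate_index", "role", "ic_otu_id", "ic_spike_copies")
_OPTIONAL_META_COLS = ("group_id", "expected_copies_per_taxon", "qpcr_total_copies")


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read sample metadata from TSV and validate replicate-group structure.

    Every replicate group (specimen or NEC) must contain exactly three
    members with a consistent internal-calibrator OTU id.
    """
    raw = pd.read_csv(Path(path), sep="\t", dtype=str)
    missing = [c for c in _REQUIRED_META_COLS if c not in raw.columns]
    if missing:
        raise MetadataError(f"{path}: missing required metadata columns: {missing}")

    entries: list[SampleMetadata] = []
    for _, row in raw.iterrows():
        def _opt_float(col: str) -> float | None:
            if col not in raw.columns:
                return None
            cell = row[col]
            if cell is None or (isinstance(cell, float) and math.isnan(cell)) or str(cell).strip() in ("", "nan"):
                return None
            return float(cell)

        group = row["group_id"] if "group_id" in raw.columns and isinstance(row.get("group_id"), str) else None
        entries.append(
            SampleMetadata(
                sample_id=str(row["sample_id"]),
                replicate_index=int(row["replicate_index"]),
                role=str(row["role"]),
                ic_otu_id=str(row["ic_otu_id"]),
                ic_spike_copies=float(row["ic_spike_copies"]),
                group_id=group,
                expected_copies_per_taxon=_opt_float("expected_copies_per_taxon"),
                qpcr_total_copies=_opt_float("qpcr_total_copies"),
            )
        )
    validate_replicate_groups(entries)
    return entries


def validate_replicate_groups(entries: Iterable[SampleMetadata]) -> dict[str, list[SampleMetadata]]:
    """Group metadata by replicate group and enforce the triplicate contract."""
    groups: dict[str, list[SampleMetadata]] = {}
    seen_ids: set[str] = set()
    for entry in entries:
        if entry.sample_id in seen_ids:
            raise MetadataError(f"duplicate sample_id {entry.sample_id!r}")
        seen_ids.add(entry.sample_id)
        groups.setdefault(entry.resolved_group_id, []).append(entry)

    for group_id, members in groups.items():
        if len(members) != 3:
            raise MetadataError(
                f"replicate group {group_id!r} has {len(members)} members "
                f"({[m.sample_id for m in members]}); exactly 3 are required"
            )
        if len({m.ic_otu_id for m in members}) != 1:
            raise MetadataError(
                f"replicate group {group_id!r} mixes internal-calibrator OTU ids"
            )
        if len({m.role for m in members}) != 1:
            raise MetadataError(f"replicate group {group_id!r} mixes specimen and NEC roles")
        if sorted(m.replicate_index for m in members) != [1, 2, 3]:
            raise MetadataError(
                f"replicate group {group_id!r} replicate indices must be 1,2,3"
            )
    return groups


def write_metadata(entries: Iterable[SampleMetadata], path: str | Path) -> None:
    rows = []
    for e in entries:
        rows.append(
            {
                "sample_id": e.sample_id,
                "replicate_index": e.replicate_index,
                "role": e.role,
                "ic_otu_id": e.ic_otu_id,
                "ic_spike_copies": e.ic_spike_copies,
                "group_id": e.resolved_group_id,
                "expected_copies_per_taxon": e.expected_copies_per_taxon,
                "qpcr_total_copies": e.qpcr_total_copies,
            }
        )
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False, lineterminator="\n")


def load_reference_accuracy_table() -> pd.DataFrame:
    """Packaged validation-series measurements (triplicate 16S copy values).

    Returns a DataFrame with columns ``taxon``, ``input_copies``, ``method``,
    ``rep1..rep3`` (measured 16S copies), ``trueness_printed`` and
    ``precision_printed`` (the published summary statistics, kept for
    cross-checks): 16 taxon/level rows per method.
    """
    with resources.files("micquant.data").joinpath("table1.tsv").open("r") as fh:
        df = pd.read_csv(
            fh,
            sep="\t",
            dtype={
                "taxon": str,
                "input_copies": float,
                "method": str,
                "rep1": int,
                "rep2": int,
                "rep3": int,
                "trueness_printed": float,
                "precision_printed": float,
            },
        )
    assert len(df) == 32, "reference accuracy table must hold 16 rows per method"
    return df


def write_report(report, path: str | Path) -> None:
    """Write an accuracy report as TSV, one row per (taxon, level, method).

    Column order mirrors the reference table: taxon, input level, the three
    replicate copy values, trueness and precision (rounded to 1 decimal,
    half away from zero, which is the display convention; internal values
    are never rounded).
    """
    from .metrics import round_half_away  # local import avoids a cycle

    rows = []
    for row in report.rows:
        rows.append(
            {
                "taxon": row.taxon,
                "input_copies": row.level,
                "method": row.method,
                "rep1": row.replicates[0],
                "rep2": row.replicates[1],
                "rep3": row.replicates[2],
                "expected": row.expected,
                "trueness": round_half_away(row.trueness, 1),
                "precision": round_half_away(row.precision, 1),
            }
        )
    columns = ["taxon", "input_copies", "method", "rep1", "rep2", "rep3", "expected", "trueness", "precision"]
    pd.DataFrame(rows, columns=columns).to_csv(Path(path), sep="\t", index=False, lineterminator="\n")


def read_report(path: str | Path) -> pd.DataFrame:
    """Read back a report written by :func:`write_report`."""
    return pd.read_csv(Path(path), sep="\t")
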