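"""Reading segment-export tables and phenotype tables; BED/report output.

The expected segment input is the tab-separated export of SNP-array
analysis software (one row per called segment: sample, segment type
Gain/Loss/LOH, chromosome, start, end, marker count, copy-number state).
Column names vary between laboratory exports, so a small dialect object
maps them onto the fields we need.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .genome import (
    CoordinateError,
    GenomeBuild,
    GenomicInterval,
    hg19,
    normalize_chromosome,
)

__all__ = [
    "Dialect",
    "SegmentRow",
    "SampleRecord",
    "PhenotypeRecord",
    "ParseResult",
    "FormatError",
    "read_segment_table",
    "read_phenotype_table",
    "group_cohort",
    "write_bed",
]

SEGMENT_TYPES = ("Gain", "Loss", "LOH")


class FormatError(ValueError):
    """Structural problem with an input table (missing columns, duplicates)."""


@dataclass(frozen=True)
class Dialect:
    """Column-name mapping for a laboratory segment export."""

    sample_id: str = "Sample"
    seg_type: str = "Type"
    chromosome: str = "Chromosome"
    start: str = "Start"
    end: str = "End"
    marker_count: str = "Marker Count"
    copy_number: str = "CN State"

    @property
    def mandatory(self) -> tuple[str, ...]:
        return (self.sample_id, self.seg_type, self.chromosome, self.start, self.end)


DEFAULT_DIALECT = Dialect()


@dataclass(frozen=True)
class SegmentRow:
    sample_id: str
    seg_type: str  # Gain | Loss | LOH
    interval: GenomicInterval
    marker_count: int | None = None
    copy_number: int | None = None


@dataclass
class PhenotypeRecord:
    sample_id: str
    sex: str = "unknown"  # male | female | unknown
    age_years: float | None = None
    phenotype_terms: set[str] = field(default_factory=set)
    cnv_classifications: list[str] = field(default_factory=list)


@dataclass
class SampleRecord:
    """One cohort member: phenotype info plus its LCSH and CNV calls."""

    sample_id: str
    sex: str = "unknown"
    age_years: float | None = None
    phenotype_terms: set[str] = field(default_factory=set)
    lcsh_segments: list = field(default_factory=list)  # list[LcshSegment]
    cnv_calls: list = field(default_factory=list)  # list[CnvCall]


@dataclass
class ParseResult:
    rows: list[SegmentRow]
    errors: list[str] = field(default_factory=list)


def _parse_int(value: str) -> int | None:
    value = (value or "").strip()
    if not value or value.lower() in ("na", "nan", "none", "-"):
        return None
    return int(round(float(value.replace(",", ""))))


def read_segment_table(
    path: str | Path,
    dialect: Dialect = DEFAULT_DIALECT,
    build: GenomeBuild | None = None,
) -> ParseResult:
    """Parse a tab-separated segment export into validated SegmentRows.

    Malformed rows are rejected with row-numbered diagnostics collected in
    ``ParseResult.errors``; a missing mandatory column raises FormatError.
    """
    build = build or hg19()
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in dialect.mandatory:
            if col not in header:
                raise FormatError(f"{path.name}: missing mandatory column {col!r}")
        rows: list[SegmentRow] = []
        errors: list[str] = []
        for idx, rec in enumerate(reader, start=2):  # 1-based, after header
            try:
                seg_type = rec[dialect.seg_type].strip()
                if seg_type not in SEGMENT_TYPES:
                    raise ValueError(f"unknown segment type {seg_type!r}")
                interval = GenomicInterval(
                    rec[dialect.chromosome],
                    int(float(rec[dialect.start])),
                    int(float(rec[dialect.end])),
                )
                interval.validate(build)
                markers = (
                    _parse_int(rec.get(dialect.marker_count, ""))
                    if dialect.marker_count in (reader.fieldnames or [])
                    else None
                )
                cn = (
                    _parse_int(rec.get(dialect.copy_number, ""))
                    if dialect.copy_number in (reader.fieldnames or [])
                    else None
                )
                if seg_type == "LOH":
                    cn = None  # LOH rows carry no copy-number state
                rows.append(
                    SegmentRow(
                        sample_id=rec[dialect.sample_id].strip(),
                        seg_type=seg_type,
                        interval=interval,
                        marker_count=markers,
                        copy_number=cn,
                    )
                )
            except (ValueError, CoordinateError, KeyError) as exc:
                errors.append(f"{path.name} row {idx}: {exc}")
    return ParseResult(rows=rows, errors=errors)


def read_phenotype_table(path: str | Path) -> dict[str, PhenotypeRecord]:
    """Parse the per-sample phenotype/classification CSV.

    Expected columns: ``sample_id`` (mandatory), optional ``sex``,
    ``age_years``, ``phenotype_terms`` (semicolon-separated), and
    ``cnv_classifications`` (semicolon-separated labels aligned with the
    sample's CNV rows in segment-file order).
    """
    path = Path(path)
    records: dict[str, PhenotypeRecord] = {}
    duplicates: list[str] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if not reader.fieldnames or "sample_id" not in reader.fieldnames:
            raise FormatError(f"{path.name}: missing mandatory column 'sample_id'")
        for rec in reader:
            sid = rec["sample_id"].strip()
            if sid in records:
                duplicates.append(sid)
                continue
            terms = {
                t.strip().lower()
                for t in (rec.get("phenotype_terms") or "").split(";")
                if t.strip()
            }
            age_raw = (rec.get("age_years") or "").strip()
            labels = [
                t.strip()
                for t in (rec.get("cnv_classifications") or "").split(";")
                if t.strip()
            ]
            records[sid] = PhenotypeRecord(
                sample_id=sid,
                sex=(rec.get("sex") or "unknown").strip().lower() or "unknown",
                age_years=float(age_raw) if age_raw else None,
                phenotype_terms=terms,
                cnv_classifications=labels,
            )
    if duplicates:
        raise FormatError(f"{path.name}: duplicate sample_id(s): {sorted(set(duplicates))}")
    return records


def group_cohort(
    rows: Iterable[SegmentRow],
    phenotypes: dict[str, PhenotypeRecord] | None = None,
    build: GenomeBuild | None = None,
) -> tuple[list[SampleRecord], list[str]]:
    """Group parsed segment rows into per-sample records.

    Gain/Loss rows become CnvCalls (classification labels taken from the
    phenotype table when provided); LOH rows are converted downstream by
    :func:`lcshkit.lcsh.filter_lcsh`.  Returns the cohort sorted by
    sample id plus diagnostics for phenotype-only "orphan" samples.
    """
    from .cnv import CnvCall  # local import to avoid a cycle

    build = build or hg19()
    phenotypes = phenotypes or {}
    by_sample: dict[str, list[SegmentRow]] = {}
    for row in rows:
        by_sample.setdefault(row.sample_id, []).append(row)

    cohort: list[SampleRecord] = []
    for sid in sorted(by_sample, key=str):
        pheno = phenotypes.get(sid, PhenotypeRecord(sample_id=sid))
        record = SampleRecord(
            sample_id=sid,
            sex=pheno.sex,
            age_years=pheno.age_years,
            phenotype_terms=set(pheno.phenotype_terms),
        )
        # stable genomic order so labelling and reports are deterministic
        sample_rows = sorted(
            by_sample[sid],
            key=lambda r: (r.interval.chromosome, r.interval.start, r.interval.end),
        )
        cnv_rows = [r for r in sample_rows if r.seg_type in ("Gain", "Loss")]
        labels = pheno.cnv_classifications
        for i, row in enumerate(cnv_rows):
            record.cnv_calls.append(
                CnvCall.from_segment_row(
                    row, classification=labels[i] if i < len(labels) else "unclassified"
                )
            )
        record.lcsh_segments = [r for r in sample_rows if r.seg_type == "LOH"]
        cohort.append(record)

    orphans = sorted(set(phenotypes) - set(by_sample))
    diagnostics = [f"phenotype-only sample (no segments): {sid}" for sid in orphans]
    return cohort, diagnostics


def write_bed(
    segments: Iterable,
    path: str | Path,
    track_name: str = "lcshkit",
) -> None:
    """Write intervals as BED6 (0-based half-open), sorted genomically.

    Accepts anything with an ``interval`` attribute or bare GenomicIntervals.
    """

    def _interval(seg) -> GenomicInterval:
        return seg if isinstance(seg, GenomicInterval) else seg.interval

    def _name(seg) -> str:
        return getattr(seg, "sample_id", ".")

    items = sorted(segments, key=lambda s: (_interval(s).chromosome, _interval(s).start))
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f'track name="{track_name}"\n')
        for seg in items:
            iv = _interval(seg)
            fh.write(
                f"chr{iv.chromosome}\t{iv.start - 1}\t{iv.end}\t{_name(seg)}\t0\t.\n"
            )


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED intervals back into the 1-based inclusive convention."""
    intervals = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("track", "#", "browser")):
            continue
        chrom, start, end = line.split("\t")[:3]
        intervals.append(GenomicInterval(normalize_chromosome(chrom), int(start) + 1, int(end)))
    return intervals


def segments_to_frame(rows: Iterable[SegmentRow]) -> pd.DataFrame:
    """Tabular view of segment rows (for reports and quick inspection)."""
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in rows],
            "type": [r.seg_type for r in rows],
            "chromosome": [r.interval.chromosome for r in rows],
            "start": [r.interval.start for r in rows],
            "end": [r.interval.end for r in rows],
            "marker_count": [r.marker_count for r in rows],
            "copy_number": [r.copy_number for r in rows],
        }
    )
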