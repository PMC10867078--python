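"""Shared fixtures: the packaged build, worked-example tables, and helpers
for building samples with known LCSH directly in Mbp."""

from __future__ import annotations

import csv
from importlib import resources

import pytest

from lcshkit.genome import GenomicInterval, hg19
from lcshkit.lcsh import LcshSegment
from lcshkit.segment_io import SampleRecord


@pytest.fixture(scope="session")
def build():
    return hg19()


def _packaged_table(filename: str) -> list[dict]:
    text = resources.files("lcshkit.data").joinpath(filename).read_text()
    lines = [l for l in text.splitlines() if l.strip() and not l.startswith("#")]
    reader = csv.DictReader(lines, delimiter="\t")
    return list(reader)


@pytest.fixture(scope="session")
def upd_worked_examples() -> dict[str, list[dict]]:
    """Published single-chromosome LCSH patterns, grouped by case id."""
    cases: dict[str, list[dict]] = {}
    for row in _packaged_table("upd_worked_examples_hg19.tsv"):
        cases.setdefault(row["case"], []).append(row)
    return cases


@pytest.fixture(scope="session")
def kinship_worked_examples() -> list[dict]:
    return _packaged_table("kinship_worked_examples.tsv")


@pytest.fixture(scope="session")
def common_region_reference() -> list[dict]:
    return _packaged_table("common_lcsh_reference_hg19.tsv")


def make_lcsh(sample_id: str, chromosome: str, start: int, end: int) -> LcshSegment:
    iv = GenomicInterval(chromosome, start, end)
    return LcshSegment(
        sample_id=sample_id,
        interval=iv,
        size_mbp=iv.length_bp / 1e6,
        is_autosomal=iv.is_autosomal,
    )


def sample_with_lcsh_sizes(
    sample_id: str, sizes_by_chrom: dict[str, list[float]]
) -> SampleRecord:
    """A sample whose analyzable LCSH have the given sizes (Mbp) per chromosome.

    Segments are placed at spaced, arbitrary coordinates; sizes are what
    the rules consume.
    """
    segs = []
    for chrom, sizes in sizes_by_chrom.items():
        pos = 10_000_000
        for size in sizes:
            end = pos + int(round(size * 1e6)) - 1
            segs.append(make_lcsh(sample_id, chrom, pos, end))
            pos = end + 5_000_000
    return SampleRecord(sample_id=sample_id, lcsh_segments=segs)


def sample_from_worked_example(case: str, rows: list[dict]) -> SampleRecord:
    segs = [
        make_lcsh(case, r["chromosome"], int(r["start"]), int(r["end"])) for r in rows
    ]
    return SampleRecord(sample_id=case, lcsh_segments=segs)
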