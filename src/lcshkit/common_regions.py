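"""Recurrent (common) LCSH regions across a cohort.

Recurrence is counted at cytoband level: for each autosomal band, the
fraction of samples with at least one analyzable LCSH overlapping it.
Bands reaching the frequency threshold (default 5%, inclusive) are
merged with qualifying neighbours into a band span, and the span's
boundaries are delineated as the component-wise median of the member
LCSH start and end coordinates (lower median for even counts, so the
boundary is always an observed coordinate).  Such regions are read as
ancestral haplotype blocks / low-recombination regions rather than
clinically relevant homozygosity.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable

from .genome import (
    GenomeBuild,
    GenomicInterval,
    hg19,
    interval_length_mbp,
    overlap_bp,
)
from .lcsh import LcshSegment, analyzable
from .segment_io import SampleRecord

__all__ = [
    "CommonRegion",
    "DEFAULT_MIN_FREQUENCY",
    "band_frequencies",
    "delineate_common_regions",
    "annotate_common_membership",
    "load_reference_regions",
]

DEFAULT_MIN_FREQUENCY = 0.05
DEFAULT_MEMBERSHIP_OVERLAP_FRACTION = 0.5


@dataclass(frozen=True)
class CommonRegion:
    chromosome: str
    band_span: str  # e.g. "16p11.2" or "11p11.2-p11.11"
    member_sample_ids: frozenset[str]
    frequency: float
    delineated_interval: GenomicInterval

    @property
    def size_mbp(self) -> float:
        return interval_length_mbp(self.delineated_interval)


def _lower_median(values: list[int]) -> int:
    values = sorted(values)
    return values[(len(values) - 1) // 2]


def band_frequencies(
    cohort: Iterable[SampleRecord], build: GenomeBuild | None = None
) -> dict[str, float]:
    """Fraction of samples with >= 1 analyzable LCSH overlapping each autosomal band.

    A sample counts at most once per band regardless of how many of its
    LCSH overlap it.
    """
    build = build or hg19()
    cohort = list(cohort)
    if not cohort:
        raise ValueError("band_frequencies needs a non-empty cohort")
    hits: dict[str, set[str]] = {}
    for sample in cohort:
        for seg in analyzable(sample.lcsh_segments, autosomal_only=True):
            for band in build.bands_on(seg.interval.chromosome):
                if overlap_bp(seg.interval, band.interval) > 0:
                    hits.setdefault(band.full_name, set()).add(sample.sample_id)
    n = len(cohort)
    return {band: len(samples) / n for band, samples in hits.items()}


def delineate_common_regions(
    cohort: Iterable[SampleRecord],
    build: GenomeBuild | None = None,
    min_frequency: float = DEFAULT_MIN_FREQUENCY,
) -> list[CommonRegion]:
    """Merge qualifying adjacent bands and delineate median boundaries.

    Returns regions sorted by frequency descending (then genomic order
    for ties).  Region frequency is the fraction of samples contributing
    at least one member LCSH to the merged span.
    """
    build = build or hg19()
    cohort = list(cohort)
    freqs = band_frequencies(cohort, build)
    n = len(cohort)

    regions: list[CommonRegion] = []
    for chrom in build.autosomes:
        bands = sorted(build.bands_on(chrom), key=lambda b: b.start)
        runs: list[list] = []
        for band in bands:
            if freqs.get(band.full_name, 0.0) >= min_frequency:
                if runs and runs[-1][-1].end + 1 == band.start:
                    runs[-1].append(band)
                else:
                    runs.append([band])
        for run in runs:
            span = GenomicInterval(chrom, run[0].start, run[-1].end)
            members = [
                seg
                for sample in cohort
                for seg in analyzable(sample.lcsh_segments, autosomal_only=True)
                if overlap_bp(seg.interval, span) > 0
            ]
            if not members:
                continue
            start = _lower_median([m.interval.start for m in members])
            end = _lower_median([m.interval.end for m in members])
            if end < start:  # degenerate under heterogeneous members
                continue
            sample_ids = frozenset(m.sample_id for m in members)
            name = (
                f"{chrom}{run[0].name}"
                if len(run) == 1
                else f"{chrom}{run[0].name}-{run[-1].name}"
            )
            regions.append(
                CommonRegion(
                    chromosome=chrom,
                    band_span=name,
                    member_sample_ids=sample_ids,
                    frequency=len(sample_ids) / n,
                    delineated_interval=GenomicInterval(chrom, start, end),
                )
            )
    regions.sort(
        key=lambda r: (
            -r.frequency,
            _genomic_rank(r.chromosome),
            r.delineated_interval.start,
        )
    )
    return regions


def _genomic_rank(chrom: str) -> int:
    return int(chrom) if chrom.isdigit() else 98 + ("XY".index(chrom))


def annotate_common_membership(
    segments: Iterable[LcshSegment],
    regions: Iterable[CommonRegion | GenomicInterval],
    min_overlap_fraction: float = DEFAULT_MEMBERSHIP_OVERLAP_FRACTION,
) -> list[tuple[LcshSegment, bool]]:
    """Flag each LCSH as common when a region covers >= half of its length."""
    region_intervals = [
        r if isinstance(r, GenomicInterval) else r.delineated_interval
        for r in regions
    ]
    out = []
    for seg in segments:
        frac = max(
            (overlap_bp(seg.interval, iv) / seg.interval.length_bp for iv in region_intervals),
            default=0.0,
        )
        out.append((seg, frac >= min_overlap_fraction))
    return out


def load_reference_regions() -> list[CommonRegion]:
    """The packaged reference list of ten published common-LCSH regions (hg19)."""
    text = resources.files("lcshkit.data").joinpath(
        "common_lcsh_reference_hg19.tsv"
    ).read_text()
    regions = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("chromosome"):
            continue
        chrom, span, start, end = line.split("\t")
        regions.append(
            CommonRegion(
                chromosome=chrom,
                band_span=f"{chrom}{span}",
                member_sample_ids=frozenset(),
                frequency=float("nan"),
                delineated_interval=GenomicInterval(chrom, int(start), int(end)),
            )
        )
    return regions
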