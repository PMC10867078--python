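"""Selection of analyzable LCSH.

Applies the clinical >= 3 Mbp size threshold, separates autosomal from
sex-chromosomal runs, and masks "loss of heterozygosity" artifacts that
are really hemizygosity over a single-copy deletion rather than true
homozygosity.  Array software reports absence of heterozygosity, which
conflates the two; masking against same-sample deletions recovers the
distinction automatically.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple

from .genome import GenomicInterval, interval_length_mbp, overlap_bp
from .segment_io import SampleRecord, SegmentRow

__all__ = [
    "LcshSegment",
    "LcshSummary",
    "DEFAULT_MIN_SIZE_MBP",
    "DEFAULT_HEMIZYGOUS_OVERLAP_FRACTION",
    "filter_lcsh",
    "mask_hemizygous",
    "analyzable",
    "per_sample_lcsh_summary",
    "attach_lcsh",
]

#: Clinical-analysis size threshold for a run of homozygosity (Mbp, inclusive).
DEFAULT_MIN_SIZE_MBP = 3.0
#: Fraction of an LCSH that must be covered by same-sample deletions for it
#: to be masked as a hemizygous artifact.
DEFAULT_HEMIZYGOUS_OVERLAP_FRACTION = 0.5


@dataclass(frozen=True)
class LcshSegment:
    sample_id: str
    interval: GenomicInterval
    size_mbp: float
    is_autosomal: bool
    masked_reason: str = "none"  # none | hemizygous-overlap | below-threshold

    @property
    def is_analyzable(self) -> bool:
        return self.masked_reason == "none"


class LcshSummary(NamedTuple):
    count: int
    largest_mbp: float
    sum_mbp: float
    has_only_sub5: bool
    has_ge5: bool


def filter_lcsh(
    rows: Iterable[SegmentRow],
    min_size_mbp: float = DEFAULT_MIN_SIZE_MBP,
) -> list[LcshSegment]:
    """Keep LOH rows at or above the size threshold as LcshSegments.

    The threshold is inclusive (a run of exactly ``min_size_mbp`` is
    analyzable).  Sex-chromosome runs are retained but flagged; they are
    excluded later from consanguinity sums and UPD calling.
    """
    if min_size_mbp <= 0:
        raise ValueError("min_size_mbp must be positive")
    out = []
    for row in rows:
        if row.seg_type != "LOH":
            continue
        size = interval_length_mbp(row.interval)
        if size < min_size_mbp:
            continue
        out.append(
            LcshSegment(
                sample_id=row.sample_id,
                interval=row.interval,
                size_mbp=size,
                is_autosomal=row.interval.is_autosomal,
            )
        )
    return out


def mask_hemizygous(
    lcsh: Iterable[LcshSegment],
    losses: Iterable,
    min_overlap_fraction: float = DEFAULT_HEMIZYGOUS_OVERLAP_FRACTION,
) -> list[LcshSegment]:
    """Mask LCSH explained by same-sample single-copy deletions.

    An LCSH is masked when the union of overlapping copy-number <= 1
    deletion intervals of the *same sample* covers at least
    ``min_overlap_fraction`` of its length.  Idempotent; raises when
    asked to compare segments across samples.
    """
    lcsh = list(lcsh)
    losses = [
        l
        for l in losses
        if getattr(l, "cnv_type", "loss") == "loss"
        and (l.copy_number is None or l.copy_number <= 1)
    ]
    sample_ids = {s.sample_id for s in lcsh} | {l.sample_id for l in losses}
    if len(sample_ids) > 1:
        raise ValueError(
            "mask_hemizygous operates within one sample; got ids "
            f"{sorted(sample_ids)}"
        )
    out = []
    for seg in lcsh:
        covered = _union_overlap_bp(seg.interval, [l.interval for l in losses])
        if covered / seg.interval.length_bp >= min_overlap_fraction:
            out.append(replace(seg, masked_reason="hemizygous-overlap"))
        else:
            out.append(seg)
    return out


def _union_overlap_bp(target: GenomicInterval, others: list[GenomicInterval]) -> int:
    """bp of `target` covered by the union of `others`."""
    pieces = sorted(
        (max(o.start, target.start), min(o.end, target.end))
        for o in others
        if overlap_bp(o, target) > 0
    )
    covered = 0
    cursor = 0  # last covered position
    for lo, hi in pieces:
        lo = max(lo, cursor + 1)
        if hi >= lo:
            covered += hi - lo + 1
            cursor = max(cursor, hi)
    return covered


def analyzable(segments: Iterable[LcshSegment], autosomal_only: bool = False) -> list[LcshSegment]:
    """The analyzable subset: unmasked (and optionally autosomal) LCSH."""
    return [
        s
        for s in segments
        if s.is_analyzable and (s.is_autosomal or not autosomal_only)
    ]


def per_sample_lcsh_summary(sample: SampleRecord) -> LcshSummary:
    """Count/size summary over the sample's analyzable autosomal LCSH."""
    segs = analyzable(sample.lcsh_segments, autosomal_only=True)
    sizes = [s.size_mbp for s in segs]
    return LcshSummary(
        count=len(sizes),
        largest_mbp=max(sizes) if sizes else 0.0,
        sum_mbp=sum(sizes),
        has_only_sub5=bool(sizes) and all(s < 5.0 for s in sizes),
        has_ge5=any(s >= 5.0 for s in sizes),
    )


def attach_lcsh(
    sample: SampleRecord,
    min_size_mbp: float = DEFAULT_MIN_SIZE_MBP,
    hemizygous_overlap_fraction: float = DEFAULT_HEMIZYGOUS_OVERLAP_FRACTION,
) -> SampleRecord:
    """Replace the sample's raw LOH rows with filtered, masked LcshSegments."""
    raw = [r for r in sample.lcsh_segments if isinstance(r, SegmentRow)]
    if not raw:  # already converted
        return sample
    segs = filter_lcsh(raw, min_size_mbp=min_size_mbp)
    losses = [c for c in sample.cnv_calls if c.cnv_type == "loss"]
    sample.lcsh_segments = mask_hemizygous(
        segs, losses, min_overlap_fraction=hemizygous_overlap_fraction
    )
    return sample
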