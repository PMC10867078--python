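"""Inbreeding-coefficient estimation and degree-of-kinship classification.

The estimator is the classical runs-of-homozygosity fraction: the sum of
analyzable autosomal LCSH (>= 3 Mbp) divided by the 2881-Mbp GRCh37
autosomal genome.  F is computed at full precision; reports round to
three decimals.

Kinship degrees form a geometric series of expected identity-by-descent
fractions (first degree 1/4, second 1/8, ... seventh 1/128).  Class
boundaries sit at the geometric means of consecutive class values, so a
measured F is assigned to the nearest class on a log scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .genome import AUTOSOMAL_GENOME_MBP
from .lcsh import analyzable
from .segment_io import SampleRecord

__all__ = [
    "KINSHIP_CLASSES",
    "EXPECTED_IBD_PERCENT",
    "DEFAULT_BOUNDARIES",
    "ConsanguinityReport",
    "inbreeding_coefficient",
    "classify_kinship",
    "sample_report",
    "cohort_consanguinity_profile",
]

KINSHIP_CLASSES = (
    "first",
    "second",
    "third",
    "fourth",
    "fifth",
    "seventh-or-more",
    "none",
)

#: Nominal expected identity-by-descent fraction per class, as a percentage.
EXPECTED_IBD_PERCENT = {
    "first": 25.0,
    "second": 12.5,
    "third": 6.0,
    "fourth": 3.0,
    "fifth": 1.5,
    "seventh-or-more": 0.5,
    "none": 0.0,
}

# Lower F bound per class: geometric means between the halving class
# values 1/4, 1/8, ..., 1/64; the tail class starts at 0.005.
DEFAULT_BOUNDARIES: dict[str, float] = {
    "first": (0.25 * 0.125) ** 0.5,  # 0.176777
    "second": (0.125 * 0.0625) ** 0.5,  # 0.088388
    "third": (0.0625 * 0.03125) ** 0.5,  # 0.044194
    "fourth": (0.03125 * 0.015625) ** 0.5,  # 0.022097
    "fifth": (0.015625 * 0.0078125) ** 0.5,  # 0.011049
    "seventh-or-more": 0.005,
}


@dataclass(frozen=True)
class ConsanguinityReport:
    sample_id: str
    sum_autosomal_lcsh_mbp: float
    f_hat: float
    kinship_class: str
    expected_ibd_percent: float
    upd_excluded: bool = False  # pattern is a single-chromosome UPD candidate


def inbreeding_coefficient(
    sum_mbp: float, genome_mbp: float = AUTOSOMAL_GENOME_MBP
) -> float:
    """F estimate: summed autosomal LCSH divided by the autosomal genome size."""
    if sum_mbp < 0:
        raise ValueError(f"sum_mbp must be non-negative, got {sum_mbp}")
    return sum_mbp / genome_mbp


def classify_kinship(
    f: float, boundaries: dict[str, float] = DEFAULT_BOUNDARIES
) -> str:
    """Assign the nearest kinship class on a log scale (see module docs)."""
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"F must lie in [0, 1], got {f}")
    for cls in KINSHIP_CLASSES[:-1]:
        if f >= boundaries[cls]:
            return cls
    return "none"


def sample_report(
    sample: SampleRecord,
    boundaries: dict[str, float] = DEFAULT_BOUNDARIES,
    upd_excluded: bool = False,
) -> ConsanguinityReport:
    """Per-sample report from its analyzable autosomal LCSH."""
    total = sum(s.size_mbp for s in analyzable(sample.lcsh_segments, autosomal_only=True))
    f = inbreeding_coefficient(total)
    cls = classify_kinship(f, boundaries)
    return ConsanguinityReport(
        sample_id=sample.sample_id,
        sum_autosomal_lcsh_mbp=total,
        f_hat=f,
        kinship_class=cls,
        expected_ibd_percent=EXPECTED_IBD_PERCENT[cls],
        upd_excluded=upd_excluded,
    )


def cohort_consanguinity_profile(
    reports: Iterable[ConsanguinityReport],
) -> dict:
    """Per-class counts and fractions over the analyzable cohort.

    Samples whose homozygosity pattern is a single-chromosome UPD
    candidate (``upd_excluded``) stay in the denominator but are not
    counted toward any inbreeding class: their LCSH reflect one
    chromosomal event, not genome-wide parental relatedness.
    """
    reports = list(reports)
    n = len(reports)
    counts = {cls: 0 for cls in KINSHIP_CLASSES}
    excluded = 0
    for rep in reports:
        if rep.upd_excluded:
            excluded += 1
            continue
        counts[rep.kinship_class] += 1
    fractions = {cls: (counts[cls] / n if n else 0.0) for cls in counts}
    relevant = sum(counts[c] for c in ("first", "second", "third", "fourth", "fifth"))
    any_inbreeding = relevant + counts["seventh-or-more"]
    return {
        "n": n,
        "counts": counts,
        "fractions": fractions,
        "upd_excluded": excluded,
        "first_to_fifth_count": relevant,
        "first_to_fifth_fraction": relevant / n if n else 0.0,
        "any_inbreeding_count": any_inbreeding,
        "any_inbreeding_fraction": any_inbreeding / n if n else 0.0,
    }
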