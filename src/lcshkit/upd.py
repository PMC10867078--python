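"""Rule-based screening for potential uniparental disomy (UPD).

Isodisomy (or an isodisomic tract after recombination) shows up on a
SNP array as homozygosity confined to one chromosome.  Two patterns are
screened, operating on the analyzable (masked, >= 3 Mbp) autosomal LCSH:

* rule B — one single autosome carries LCSH over 5 Mbp (no other
  autosome does) and that autosome's LCSH total at least 10 Mbp;
* rule A — no LCSH over 5 Mbp anywhere, but one autosome accumulates
  two or more sub-5 Mbp LCSH summing to at least 10 Mbp (arithmetic
  forces at least three such segments).

If two or more autosomes carry LCSH over 5 Mbp the pattern suggests
parental relatedness rather than UPD and no candidate is raised.
Heterodisomy leaves no homozygosity and is invisible to this screen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .lcsh import LcshSegment, analyzable
from .segment_io import SampleRecord

__all__ = [
    "IMPRINTED_CHROMOSOMES",
    "UpdCandidate",
    "call_upd_candidates",
    "flag_imprinted",
    "cohort_upd_rate",
]

#: Autosomes with clinically established imprinting disorders, with the
#: canonical syndromes UPD can cause there.
IMPRINTED_CHROMOSOMES: dict[str, str] = {
    "6": "Transient neonatal diabetes mellitus (UPD(6)pat)",
    "7": "Silver-Russell syndrome (UPD(7)mat)",
    "11": "Beckwith-Wiedemann syndrome (UPD(11)pat); Silver-Russell syndrome (UPD(11)mat)",
    "14": "Temple syndrome (UPD(14)mat); Kagami-Ogata syndrome (UPD(14)pat)",
    "15": "Prader-Willi syndrome (UPD(15)mat); Angelman syndrome (UPD(15)pat)",
    "20": "Mulchandani-Bhoj-Conlin syndrome (UPD(20)mat)",
}

DEFAULT_MIN_TOTAL_MBP = 10.0
DEFAULT_OVER_THRESHOLD_MBP = 5.0


@dataclass(frozen=True)
class UpdCandidate:
    sample_id: str
    chromosome: str
    segments: tuple[LcshSegment, ...]
    total_mbp: float
    rule: str  # "A" (sub-5 sum) | "B" (>5 Mbp present)

    @property
    def imprinted_chromosome(self) -> bool:
        return self.chromosome in IMPRINTED_CHROMOSOMES


def call_upd_candidates(
    sample: SampleRecord,
    min_total_mbp: float = DEFAULT_MIN_TOTAL_MBP,
    over_threshold_mbp: float = DEFAULT_OVER_THRESHOLD_MBP,
) -> list[UpdCandidate]:
    """Return the sample's UPD candidate (at most one) per the rules above.

    Operates on analyzable autosomal LCSH only; hemizygous-masked
    segments must already be flagged (attach_lcsh does this).  The
    "over 5 Mbp" comparisons are strict; the 10 Mbp total is inclusive.
    """
    segs = analyzable(sample.lcsh_segments, autosomal_only=True)
    if not segs:
        return []
    by_chrom: dict[str, list[LcshSegment]] = {}
    for seg in segs:
        by_chrom.setdefault(seg.interval.chromosome, []).append(seg)

    chroms_over = [
        c
        for c, items in by_chrom.items()
        if any(s.size_mbp > over_threshold_mbp for s in items)
    ]
    if len(chroms_over) > 1:
        return []  # multiple chromosomes with large LCSH: consanguinity pattern

    if len(chroms_over) == 1:
        chrom = chroms_over[0]
        total = sum(s.size_mbp for s in by_chrom[chrom])
        if total >= min_total_mbp:
            return [
                UpdCandidate(
                    sample_id=sample.sample_id,
                    chromosome=chrom,
                    segments=tuple(
                        sorted(by_chrom[chrom], key=lambda s: s.interval.start)
                    ),
                    total_mbp=total,
                    rule="B",
                )
            ]
        return []

    # rule A: nothing over 5 Mbp anywhere (also no segment of exactly 5 Mbp,
    # which would make the pattern ambiguous); one autosome accumulates
    # multiple sub-5 segments summing to >= 10 Mbp
    if any(s.size_mbp >= over_threshold_mbp for s in segs):
        return []
    candidates = []
    for chrom, items in by_chrom.items():
        total = sum(s.size_mbp for s in items)
        if len(items) >= 2 and total >= min_total_mbp:
            candidates.append((total, chrom, items))
    if not candidates:
        return []
    # at most one candidate per sample: the largest sum wins (chromosome
    # order breaks exact ties deterministically)
    total, chrom, items = max(
        candidates, key=lambda t: (t[0], -_chrom_rank(t[1]))
    )
    return [
        UpdCandidate(
            sample_id=sample.sample_id,
            chromosome=chrom,
            segments=tuple(sorted(items, key=lambda s: s.interval.start)),
            total_mbp=total,
            rule="A",
        )
    ]


def _chrom_rank(chrom: str) -> int:
    return int(chrom)  # autosomes only reach this point


def flag_imprinted(candidate: UpdCandidate) -> tuple[bool, str]:
    """Imprinted-chromosome flag plus a note naming the relevant syndromes."""
    note = IMPRINTED_CHROMOSOMES.get(candidate.chromosome, "")
    return candidate.chromosome in IMPRINTED_CHROMOSOMES, note


def cohort_upd_rate(candidate_lists: Iterable[list[UpdCandidate]]) -> float:
    """Fraction of analyzable samples with a UPD candidate."""
    lists = list(candidate_lists)
    if not lists:
        return 0.0
    return sum(1 for lst in lists if lst) / len(lists)
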