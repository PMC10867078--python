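"""Genome build, genomic intervals and cytoband arithmetic.

Everything downstream (LCSH filtering, consanguinity, UPD calling,
common-region delineation) works in GRCh37/hg19 coordinates.  Intervals
are 1-based inclusive internally, the convention of SNP-array segment
export tables; BED output converts to 0-based half-open at the boundary.

The consanguinity denominator is the fixed constant 2881 Mbp (the
conventional size of the GRCh37 autosomal genome used for estimating the
inbreeding coefficient from summed runs of homozygosity).  It is a
constant of the method, deliberately not recomputed from the chromosome
length table.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

__all__ = [
    "AUTOSOMAL_GENOME_MBP",
    "GenomicInterval",
    "Cytoband",
    "GenomeBuild",
    "CoordinateError",
    "normalize_chromosome",
    "interval_length_mbp",
    "overlap_bp",
    "bands_overlapping",
]

#: Size of the GRCh37/hg19 autosomal genome used as the denominator of
#: the inbreeding-coefficient estimate (megabase pairs).
AUTOSOMAL_GENOME_MBP: float = 2881.0

_AUTOSOMES = tuple(str(i) for i in range(1, 23))
_SEX_CHROMOSOMES = ("X", "Y")


class CoordinateError(ValueError):
    """An interval violates the coordinate system of the active build."""


def normalize_chromosome(name: str) -> str:
    """Return the chromosome name without a ``chr`` prefix ('1'..'22', 'X', 'Y').

    Accepts ``chr1``/``1`` and lower-case ``x``/``y``.
    """
    name = str(name).strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    if name.lower() in ("x", "y"):
        return name.upper()
    return name


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based inclusive interval on a chromosome."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosome", normalize_chromosome(self.chromosome))
        if self.start < 1:
            raise CoordinateError(f"start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise CoordinateError(
                f"start {self.start} exceeds end {self.end} on chromosome {self.chromosome}"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def is_autosomal(self) -> bool:
        return self.chromosome in _AUTOSOMES

    def validate(self, build: "GenomeBuild") -> None:
        if self.chromosome not in build.chromosomes:
            raise CoordinateError(f"unknown chromosome {self.chromosome!r} for build {build.name}")
        limit = build.chromosomes[self.chromosome]
        if self.end > limit:
            raise CoordinateError(
                f"end {self.end} exceeds {self.chromosome} length {limit} ({build.name})"
            )


@dataclass(frozen=True)
class Cytoband:
    chromosome: str
    name: str  # e.g. "p11.2"
    start: int  # 1-based inclusive
    end: int
    stain: str = "gneg"

    @property
    def full_name(self) -> str:
        return f"{self.chromosome}{self.name}"

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chromosome, self.start, self.end)


@dataclass
class GenomeBuild:
    """Chromosome lengths plus a cytoband tiling for one reference build."""

    name: str
    chromosomes: dict[str, int]
    cytobands: list[Cytoband] = field(default_factory=list)
    autosomal_total_mbp: float = AUTOSOMAL_GENOME_MBP

    def __post_init__(self) -> None:
        missing = [c for c in (*_AUTOSOMES, *_SEX_CHROMOSOMES) if c not in self.chromosomes]
        if missing:
            raise ValueError(f"build {self.name} is missing chromosomes: {missing}")

    @property
    def autosomes(self) -> tuple[str, ...]:
        return _AUTOSOMES

    def is_autosome(self, chromosome: str) -> bool:
        return normalize_chromosome(chromosome) in _AUTOSOMES

    def bands_on(self, chromosome: str) -> list[Cytoband]:
        chromosome = normalize_chromosome(chromosome)
        return [b for b in self.cytobands if b.chromosome == chromosome]

    def validate_cytoband_tiling(self) -> None:
        """Check that cytobands tile each chromosome without gaps or overlaps."""
        if not self.cytobands:
            raise ValueError("cytoband table is empty")
        for chrom, length in self.chromosomes.items():
            bands = sorted(self.bands_on(chrom), key=lambda b: b.start)
            if not bands:
                raise ValueError(f"no cytobands on chromosome {chrom}")
            if bands[0].start != 1 or bands[-1].end != length:
                raise ValueError(f"cytobands do not span chromosome {chrom}")
            for prev, cur in zip(bands, bands[1:]):
                if cur.start != prev.end + 1:
                    raise ValueError(
                        f"cytoband gap/overlap on {chrom} between {prev.name} and {cur.name}"
                    )


def interval_length_mbp(interval: GenomicInterval) -> float:
    """Interval length in megabase pairs under the 1-based inclusive convention."""
    return interval.length_bp / 1e6


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Length of the intersection of two intervals in bp (0 when disjoint)."""
    if a.chromosome != b.chromosome:
        return 0
    lo = max(a.start, b.start)
    hi = min(a.end, b.end)
    return max(0, hi - lo + 1)


def bands_overlapping(interval: GenomicInterval, build: GenomeBuild) -> list[str]:
    """All cytoband full names with >= 1 bp overlap, in genomic order."""
    if not build.cytobands:
        raise ValueError("cytoband table is empty; load a build with cytobands")
    hits = [
        b
        for b in build.bands_on(interval.chromosome)
        if overlap_bp(interval, b.interval) > 0
    ]
    hits.sort(key=lambda b: b.start)
    return [b.full_name for b in hits]


def _read_packaged_tsv(filename: str) -> list[list[str]]:
    text = resources.files("lcshkit.data").joinpath(filename).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


def load_cytoband_table(lines: Iterable[str]) -> list[Cytoband]:
    """Parse a UCSC ``cytoBand.txt``-format table (0-based half-open input)."""
    bands = []
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        chrom, start, end, name, stain = line.split("\t")[:5]
        bands.append(
            Cytoband(
                chromosome=normalize_chromosome(chrom),
                name=name,
                start=int(start) + 1,
                end=int(end),
                stain=stain,
            )
        )
    return bands


@functools.lru_cache(maxsize=1)
def hg19() -> GenomeBuild:
    """The packaged GRCh37/hg19 build: real chromosome lengths, synthetic cytobands.

    The bundled cytoband tiling is a synthetic stand-in for the UCSC
    table (see the data file header); chromosome lengths are the real
    GRCh37 values.
    """
    chroms: dict[str, int] = {}
    for row in _read_packaged_tsv("hg19_chromosomes.tsv"):
        chroms[normalize_chromosome(row[0])] = int(row[1])
    cyto_text = resources.files("lcshkit.data").joinpath(
        "cytobands_synthetic_hg19.tsv"
    ).read_text()
    bands = load_cytoband_table(cyto_text.splitlines())
    build = GenomeBuild(name="GRCh37/hg19", chromosomes=chroms, cytobands=bands)
    return build
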