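"""Synthetic cohort generator with known truth labels.

Emulates the structure of a clinical SNP-array cohort so every pipeline
stage can be validated without patient data:

* autozygosity of inbred samples — block count ~ Poisson(F_d * G / mu_d)
  and block lengths ~ mu_d-mean exponential truncated below at 0.5 Mbp,
  placed uniformly without overlap across autosomes proportional to
  length, so the expected total is about F_d * G (G = 2881 Mbp).  The
  per-degree mean block length mu_d follows the ~100/m heuristic for a
  consanguinity loop of m meioses (first cousins: m = 4, mu = 25 Mbp);
* background LCSH — the short runs (mostly 3-5 Mbp) nearly every sample
  shows, drawn 3 + Exp(1.1) Mbp at Poisson rate 2.4 and placed on
  distinct chromosomes (ancestral haplotypes at distinct loci): this
  matches a cohort where ~9% of samples show no run at all and roughly
  a third carry something over 5 Mbp;
* UPD events — whole-chromosome isodisomy, partial iso/heterodisomy
  mixes, and segmental events;
* recurrent population regions at configurable frequencies with
  boundary jitter; optional hemizygous LOH artifacts co-located with
  large single-copy deletions; CNV calls with class labels; phenotype
  terms with a configurable pathogenic-CNV odds multiplier.

Identical config + seed produce byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome import AUTOSOMAL_GENOME_MBP, GenomeBuild, hg19

__all__ = [
    "DEGREE_F",
    "DEFAULT_MU_MBP",
    "SimulationConfig",
    "simulate_inbred_autozygosity",
    "simulate_upd_sample",
    "simulate_cohort",
]

#: True inbreeding coefficient per kinship degree of the parents.
DEGREE_F = {
    "first": 1 / 4,
    "second": 1 / 8,
    "third": 1 / 16,
    "fourth": 1 / 32,
    "fifth": 1 / 64,
}

#: Mean autozygous block length per degree (Mbp), ~100/m for m meioses.
DEFAULT_MU_MBP = {"first": 50.0, "second": 33.0, "third": 25.0, "fourth": 20.0, "fifth": 17.0}

MIN_BLOCK_MBP = 0.5  # array-callable segment floor


@dataclass
class SimulationConfig:
    n_samples: int = 100
    seed: int = 0
    #: fraction of the cohort per kinship degree; the rest are outbred
    class_mixture: dict[str, float] = field(default_factory=dict)
    segment_length_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MU_MBP))
    #: fraction of samples carrying a UPD event, and the event type:
    #: whole-iso | iso-het-mix | segmental (chromosome None = random)
    upd_fraction: float = 0.0
    upd_type: str = "whole-iso"
    upd_chromosome: str | None = None
    #: (chromosome, start, end, population frequency, boundary jitter Mbp)
    common_regions: list[tuple] = field(default_factory=list)
    background_rate: float = 2.4
    background_scale_mbp: float = 1.1
    background_min_mbp: float = 3.0
    background_max_mbp: float | None = None
    #: classification -> (per-sample Poisson rate, median size kbp, lognormal sigma)
    cnv_spec: dict[str, tuple] = field(
        default_factory=lambda: {
            "benign": (0.8, 150.0, 0.9),
            "VUS": (0.12, 400.0, 1.0),
            "LPCNV": (0.015, 700.0, 1.0),
            "PCNV": (0.2, 2000.0, 1.3),
        }
    )
    #: fraction of samples with a large deletion plus a co-located LOH artifact
    hemizygous_artifact_fraction: float = 0.0
    #: term -> (baseline prevalence, odds multiplier when a PCNV is present)
    phenotype_model: dict[str, tuple] = field(
        default_factory=lambda: {"dd": (0.5, 2.0), "id": (0.3, 1.5), "asd": (0.33, 0.6)}
    )

    def validate(self) -> None:
        total = sum(self.class_mixture.values()) + self.upd_fraction
        if total > 1.0 + 1e-9:
            raise ValueError("class mixture + UPD fraction exceed 1")
        for deg in self.class_mixture:
            if deg not in DEGREE_F:
                raise ValueError(f"unknown kinship degree {deg!r}")
            if self.segment_length_means[deg] <= 3.0:
                raise ValueError(
                    f"mean block length for degree {deg} must exceed the 3 Mbp threshold"
                )
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")


def _place_blocks(
    lengths_bp: list[int],
    rng: np.random.Generator,
    build: GenomeBuild,
    occupied: dict[str, list[tuple[int, int]]],
    chromosomes: list[str] | None = None,
    max_tries: int = 200,
) -> list[tuple[str, int, int]]:
    """Place blocks uniformly without overlap, chromosome chosen ~ length."""
    chroms = chromosomes or list(build.autosomes)
    placed = []
    for length in lengths_bp:
        # a homozygous tract cannot exceed its chromosome
        length = min(length, max(build.chromosomes[c] for c in chroms) - 1)
        eligible = [c for c in chroms if build.chromosomes[c] > length]
        weights = np.array([build.chromosomes[c] for c in eligible], dtype=float)
        weights /= weights.sum()
        for attempt in range(max_tries):
            chrom = eligible[int(rng.choice(len(eligible), p=weights))]
            limit = build.chromosomes[chrom] - length
            start = int(rng.integers(1, limit + 1))
            end = start + length - 1
            if all(end < s or start > e for s, e in occupied.get(chrom, [])):
                occupied.setdefault(chrom, []).append((start, end))
                placed.append((chrom, start, end))
                break
        else:
            raise RuntimeError(
                "could not place autozygous block without overlap; "
                "lower the block rate or mean length"
            )
    return placed


def simulate_inbred_autozygosity(
    degree: str,
    rng: np.random.Generator,
    build: GenomeBuild | None = None,
    mu_mbp: dict[str, float] | None = None,
    occupied: dict[str, list[tuple[int, int]]] | None = None,
) -> list[tuple[str, int, int]]:
    """Autozygous blocks for one offspring of related parents.

    Returns (chromosome, start, end) tuples; ``degree`` may be
    "outbred" (empty list).
    """
    if degree in (None, "outbred"):
        return []
    if degree not in DEGREE_F:
        raise ValueError(f"unknown kinship degree {degree!r}")
    build = build or hg19()
    mu = (mu_mbp or DEFAULT_MU_MBP)[degree]
    lam = DEGREE_F[degree] * AUTOSOMAL_GENOME_MBP / mu
    n_blocks = int(rng.poisson(lam))
    lengths_mbp = MIN_BLOCK_MBP + rng.exponential(mu, size=n_blocks)
    lengths_bp = [max(1, int(round(x * 1e6))) for x in lengths_mbp]
    occupied = occupied if occupied is not None else {}
    return _place_blocks(lengths_bp, rng, build, occupied)


def simulate_upd_sample(
    kind: str,
    chromosome: str | None,
    rng: np.random.Generator,
    build: GenomeBuild | None = None,
    segmental_size_mbp: tuple[float, float] = (10.0, 20.0),
) -> list[tuple[str, int, int]]:
    """LCSH pattern of a single-chromosome isodisomy event.

    whole-iso: one run spanning >= 90% of the chromosome.
    iso-het-mix: 1-3 runs, each > 5 Mbp, totalling >= 10 Mbp.
    segmental: one terminal run (size range configurable; sizes below
    10 Mbp make a negative control that must not trigger the caller).
    """
    build = build or hg19()
    if chromosome is None:
        chromosome = str(rng.choice([int(c) for c in build.autosomes]))
    if not build.is_autosome(chromosome):
        raise ValueError(f"UPD simulation requires an autosome, got {chromosome!r}")
    length = build.chromosomes[chromosome]

    if kind == "whole-iso":
        frac = rng.uniform(0.90, 0.98)
        size = int(length * frac)
        start = int(rng.integers(1, length - size + 1))
        return [(chromosome, start, start + size - 1)]
    if kind == "iso-het-mix":
        k = int(rng.integers(1, 4))
        if k == 1:
            sizes = [rng.uniform(10.0, 30.0)]
        else:
            sizes = list(rng.uniform(5.2, 15.0, size=k))
        blocks_bp = [int(s * 1e6) for s in sizes]
        occupied: dict[str, list[tuple[int, int]]] = {}
        return _place_blocks(blocks_bp, rng, build, occupied, chromosomes=[chromosome])
    if kind == "segmental":
        size = int(rng.uniform(*segmental_size_mbp) * 1e6)
        if size >= length:
            raise ValueError(f"segment exceeds chromosome {chromosome} length")
        if rng.uniform() < 0.5:  # p-terminal or q-terminal
            return [(chromosome, 1, size)]
        return [(chromosome, length - size + 1, length)]
    raise ValueError(f"unknown UPD type {kind!r}")


def _assign_roles(config: SimulationConfig, rng: np.random.Generator) -> list[dict]:
    """Deterministic per-sample role assignment (degree / UPD / outbred)."""
    n = config.n_samples
    roles = [{"degree": "outbred", "upd": None} for _ in range(n)]
    order = list(rng.permutation(n))
    cursor = 0
    for degree, frac in sorted(config.class_mixture.items()):
        count = int(round(frac * n))
        for idx in order[cursor : cursor + count]:
            roles[idx]["degree"] = degree
        cursor += count
    upd_count = int(round(config.upd_fraction * n))
    for idx in order[cursor : cursor + upd_count]:
        roles[idx]["upd"] = {
            "type": config.upd_type,
            "chromosome": config.upd_chromosome,
        }
    return roles


def _simulate_sample(
    sid: str,
    role: dict,
    config: SimulationConfig,
    rng: np.random.Generator,
    build: GenomeBuild,
) -> tuple[list[dict], dict, dict]:
    """Emit segment rows (as dialect dicts), phenotype record and truth."""
    rows: list[dict] = []
    truth: dict = {
        "degree": role["degree"],
        "true_f": DEGREE_F.get(role["degree"], 0.0),
        "upd": None,
        "common_regions": [],
        "cnv_classes": [],
        "hemizygous_artifact": False,
    }
    occupied: dict[str, list[tuple[int, int]]] = {}

    def add_loh(chrom: str, start: int, end: int) -> None:
        size_bp = end - start + 1
        rows.append(
            {
                "Sample": sid,
                "Type": "LOH",
                "Chromosome": chrom,
                "Start": start,
                "End": end,
                "Marker Count": max(10, size_bp // 2000),
                "CN State": "",
            }
        )

    # autozygosity from parental relatedness
    for chrom, start, end in simulate_inbred_autozygosity(
        role["degree"], rng, build, config.segment_length_means, occupied=occupied
    ):
        add_loh(chrom, start, end)

    # UPD event
    if role["upd"] is not None:
        blocks = simulate_upd_sample(role["upd"]["type"], role["upd"]["chromosome"], rng, build)
        for chrom, start, end in blocks:
            occupied.setdefault(chrom, []).append((start, end))
            add_loh(chrom, start, end)
        truth["upd"] = {"type": role["upd"]["type"], "chromosome": blocks[0][0]}

    # recurrent population regions
    for chrom, start, end, freq, jitter in config.common_regions:
        if rng.uniform() < freq:
            shift = int(rng.uniform(-jitter, jitter) * 1e6)
            shift2 = int(rng.uniform(-jitter, jitter) * 1e6)
            s = max(1, start + shift)
            e = min(build.chromosomes[str(chrom)], end + shift2)
            if e - s + 1 >= 3_000_000:
                occupied.setdefault(str(chrom), []).append((s, e))
                add_loh(str(chrom), s, e)
                truth["common_regions"].append(f"{chrom}:{start}-{end}")

    # background runs on distinct chromosomes
    n_bg = min(int(rng.poisson(config.background_rate)), len(build.autosomes))
    if n_bg:
        weights = np.array([build.chromosomes[c] for c in build.autosomes], dtype=float)
        weights /= weights.sum()
        chosen = rng.choice(len(build.autosomes), size=n_bg, replace=False, p=weights)
        for ci in chosen:
            chrom = build.autosomes[int(ci)]
            size_mbp = config.background_min_mbp + rng.exponential(config.background_scale_mbp)
            if config.background_max_mbp is not None:
                size_mbp = min(size_mbp, config.background_max_mbp)
            size = int(size_mbp * 1e6)
            limit = build.chromosomes[chrom] - size
            for _ in range(50):
                s = int(rng.integers(1, max(2, limit)))
                e = s + size - 1
                if all(e < a or s > b for a, b in occupied.get(chrom, [])):
                    occupied.setdefault(chrom, []).append((s, e))
                    add_loh(chrom, s, e)
                    break

    # CNV calls
    classifications: list[str] = []
    has_pcnv = False
    for cls in sorted(config.cnv_spec):
        rate, median_kbp, sigma = config.cnv_spec[cls]
        for _ in range(int(rng.poisson(rate))):
            size_kbp = float(rng.lognormal(np.log(median_kbp), sigma))
            size = max(1000, int(size_kbp * 1e3))
            cnv_type = "Loss" if rng.uniform() < 0.6 else "Gain"
            weights = np.array([build.chromosomes[c] for c in build.autosomes], dtype=float)
            chrom = build.autosomes[int(rng.choice(len(build.autosomes), p=weights / weights.sum()))]
            limit = max(2, build.chromosomes[chrom] - size)
            s = int(rng.integers(1, limit))
            rows.append(
                {
                    "Sample": sid,
                    "Type": cnv_type,
                    "Chromosome": chrom,
                    "Start": s,
                    "End": s + size - 1,
                    "Marker Count": max(10, size // 2000),
                    "CN State": 1 if cnv_type == "Loss" else 3,
                }
            )
            classifications.append(cls)
            has_pcnv = has_pcnv or cls == "PCNV"

    # hemizygous LOH artifact over a large single-copy deletion
    if rng.uniform() < config.hemizygous_artifact_fraction:
        size = int(rng.uniform(5.0, 15.0) * 1e6)
        weights = np.array([build.chromosomes[c] for c in build.autosomes], dtype=float)
        chrom = build.autosomes[int(rng.choice(len(build.autosomes), p=weights / weights.sum()))]
        for _ in range(50):
            s = int(rng.integers(1, build.chromosomes[chrom] - size))
            e = s + size - 1
            if all(e < a or s > b for a, b in occupied.get(chrom, [])):
                occupied.setdefault(chrom, []).append((s, e))
                rows.append(
                    {
                        "Sample": sid,
                        "Type": "Loss",
                        "Chromosome": chrom,
                        "Start": s,
                        "End": e,
                        "Marker Count": max(10, size // 2000),
                        "CN State": 1,
                    }
                )
                add_loh(chrom, s, e)
                classifications.append("PCNV")
                has_pcnv = True
                truth["hemizygous_artifact"] = True
                break

    # phenotype terms under the logistic carrier model
    terms = []
    for term, (baseline, multiplier) in sorted(config.phenotype_model.items()):
        odds = baseline / (1 - baseline)
        if has_pcnv:
            odds *= multiplier
        if rng.uniform() < odds / (1 + odds):
            terms.append(term)

    truth["cnv_classes"] = classifications
    truth["phenotype_terms"] = terms
    phenotype = {
        "sample_id": sid,
        "sex": "male" if rng.uniform() < 0.6 else "female",
        "age_years": round(float(min(55.0, rng.lognormal(np.log(8.0), 0.6))), 1),
        "phenotype_terms": ";".join(terms),
        "cnv_classifications": "",  # aligned to genomic row order below
    }
    return rows, phenotype, truth


def simulate_cohort(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> dict:
    """Generate a cohort; optionally write segments.tsv / phenotypes.csv / truth.json.

    Returns {"segment_rows": [...], "phenotypes": [...], "truth": {...}}.
    Classification labels in the phenotype file are aligned with each
    sample's Gain/Loss rows sorted genomically, the order in which the
    parser attaches them.
    """
    config.validate()
    build = hg19()
    master = np.random.default_rng((config.seed, 0))
    roles = _assign_roles(config, master)

    all_rows: list[dict] = []
    phenotypes: list[dict] = []
    truths: dict[str, dict] = {}
    width = len(str(config.n_samples))
    for i, role in enumerate(roles):
        sid = f"S{i + 1:0{width}d}"
        rng = np.random.default_rng((config.seed, 1, i))
        rows, pheno, truth = _simulate_sample(sid, role, config, rng, build)
        # align classification labels with genomic CNV-row order
        cnv_rows = [r for r in rows if r["Type"] in ("Gain", "Loss")]
        labels = truth["cnv_classes"]
        order = sorted(
            range(len(cnv_rows)),
            key=lambda j: (str(cnv_rows[j]["Chromosome"]), cnv_rows[j]["Start"], cnv_rows[j]["End"]),
        )
        pheno["cnv_classifications"] = ";".join(labels[j] for j in order)
        truth["cnv_classes"] = [labels[j] for j in order]
        all_rows.extend(rows)
        phenotypes.append(pheno)
        truths[sid] = truth

    result = {"segment_rows": all_rows, "phenotypes": phenotypes, "truth": truths}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        header = ["Sample", "Type", "Chromosome", "Start", "End", "Marker Count", "CN State"]
        with (out / "segments.tsv").open("w") as fh:
            fh.write("\t".join(header) + "\n")
            for row in all_rows:
                fh.write("\t".join(str(row[h]) for h in header) + "\n")
        pheno_header = ["sample_id", "sex", "age_years", "phenotype_terms", "cnv_classifications"]
        with (out / "phenotypes.csv").open("w") as fh:
            fh.write(",".join(pheno_header) + "\n")
            for rec in phenotypes:
                fh.write(",".join(str(rec[h]) for h in pheno_header) + "\n")
        with (out / "truth.json").open("w") as fh:
            json.dump(truths, fh, indent=1, sort_keys=True)
    return result
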