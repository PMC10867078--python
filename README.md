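# lcshkit

Analysis of **long contiguous stretches of homozygosity (LCSH**, also
called runs of homozygosity**)** from SNP-array segment exports, for
clinical-cytogenetics cohorts.

Modern chromosomal-microarray platforms genotype SNPs alongside
copy-number probes, so their segment tables report "LOH" intervals —
stretches with no heterozygous calls. Interpreted carefully, these
stretches reveal three very different things:

* **parental consanguinity** — many large LCSH spread across several
  chromosomes; quantified by the inbreeding coefficient
  *F̂ = Σ LCSH / 2881 Mbp* (summed autosomal LCSH ≥ 3 Mbp over the
  GRCh37 autosomal genome) and mapped to a degree of kinship
  (first degree F ≈ 1/4, … , third degree / first cousins F ≈ 1/16, …);
* **uniparental disomy (UPD)** — homozygosity confined to a *single*
  chromosome: flagged when one autosome carries LCSH over 5 Mbp
  totalling ≥ 10 Mbp (and no other autosome has a run over 5 Mbp), or
  when several sub-5 Mbp runs on one autosome sum to ≥ 10 Mbp with
  nothing large elsewhere; candidates on imprinted chromosomes
  (6, 7, 11, 14, 15, 20) are annotated with the relevant syndromes;
* **population structure** — recurrent LCSH present in ≥ 5% of a cohort
  are ancestral-haplotype / low-recombination blocks of negligible
  clinical significance; their boundaries are delineated as the median
  of the member segments' starts and ends.

Because array software reports *absence of heterozygosity*, a deletion
also produces an "LOH" call; lcshkit masks LCSH that are ≥ 50% covered
by same-sample copy-number ≤ 1 losses before any interpretation.

The package also carries the CNV side of such cohorts — size/marker
filters (research: > 10 Kbp, ≥ 10 markers; clinical: > 100/150 Kbp,
≥ 50 markers), per-sample most-relevant-class assignment
(PCNV > LPCNV > VUS > benign), diagnostic yield, Fisher-exact
phenotype association with odds ratios, and Tukey HSD comparisons of
per-class CNV metrics — plus a synthetic-cohort generator with known
truth labels (inbreeding degree, UPD events, common regions, CNV
classes, phenotype effects) so every stage is testable without patient
data.

## Worked example

Simulate a small cohort containing two offspring of first cousins
(true F = 1/16) and one maternal/paternal isodisomy of chromosome 15,
then screen it:

```sh
lcshkit simulate --seed 11 --n 8 --out demo   # (plus mixture config; see docs)
lcshkit consanguinity --segments demo/segments.tsv --out demo/consang.tsv
lcshkit upd --segments demo/segments.tsv --out demo/upd.tsv
```

`consang.tsv`:

```
sample_id  sum_mbp  F      kinship_class    expected_ibd_percent
S1         16.8     0.006  seventh-or-more  0.5
S2         259.7    0.09   second           12.5
S3         8.4      0.003  none             0.0
S4         185.8    0.064  third            6.0
S5         4.4      0.002  none             0.0
S6         0.0      0.0    none             0.0
S7         7.7      0.003  none             0.0
S8         99.4     0.034  fourth           3.0
```

S2 and S4 are the injected first-cousin offspring: S4's 185.8 Mbp of
autosomal LCSH gives F̂ = 0.064, squarely in the third-degree
(first-cousin) class whose expected identity-by-descent is ~6%; S2
drifted high (F̂ = 0.090), illustrating the sampling spread of
block-based estimates. The remaining samples carry only the short
background runs common in any cohort.

`upd.tsv`:

```
sample_id  chromosome  n_segments  total_mbp  rule  imprinted  imprinting_note
S8         15          1           95.0       B     True       Prader-Willi syndrome (UPD(15)mat); Angelman syndrome (UPD(15)pat)
```

S8's 95 Mbp of homozygosity sits on chromosome 15 alone — a rule-B UPD
candidate on an imprinted chromosome. Note S8 also appears in the
consanguinity table (a single-chromosome pattern inflates Σ LCSH); the
full pipeline (`lcshkit run`) therefore excludes UPD-candidate samples
from the cohort's inbreeding fractions.

## Layout

| module | role |
| --- | --- |
| `lcshkit.genome` | GRCh37/hg19 build, 1-based inclusive intervals, cytoband arithmetic |
| `lcshkit.segment_io` | segment-export (TSV) and phenotype (CSV) parsing, BED output |
| `lcshkit.lcsh` | ≥ 3 Mbp selection, sex-chromosome flagging, hemizygous masking |
| `lcshkit.consanguinity` | F̂ estimation and kinship classification |
| `lcshkit.upd` | rule-based UPD candidate calling, imprinting annotation |
| `lcshkit.common_regions` | band-level recurrence, median delineation, membership flags |
| `lcshkit.cnv` | CNV filters, most-relevant class, diagnostic yield |
| `lcshkit.cohort_stats` | Fisher exact association, Tukey HSD comparisons |
| `lcshkit.simulate` | synthetic cohorts with truth labels |
| `lcshkit.pipeline` / `lcshkit.cli` | orchestration, manifests, `lcshkit` command |

See `docs/methods.md` for the models, thresholds and design choices.
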