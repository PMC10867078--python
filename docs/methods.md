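# Methods

## Coordinate conventions

Intervals are 1-based inclusive internally — the convention of SNP-array
segment export tables — so a segment printed as `start–end` has length
`end − start + 1` bp. BED export converts to 0-based half-open. At the
precisions used in reports (0.1 Mbp for UPD tables, 0.001 Mbp for
common-region tables) the ±1 bp difference between conventions is
invisible. Chromosome names are stored without a `chr` prefix; both
forms are accepted on input.

The autosomal genome size used as the denominator of the inbreeding
coefficient is the fixed constant **2881 Mbp** (GRCh37). It is a
constant of the estimator, deliberately *not* recomputed from the
chromosome-length table, so that published per-sample sums reproduce
published coefficients exactly.

### Cytobands

The packaged cytoband tiling (`cytobands_synthetic_hg19.tsv`) is a
synthetic stand-in for the UCSC table: real GRCh37 chromosome lengths
and approximate centromere positions, ISCN-style numbering outward from
the centromere, with the proximal p-arms of chromosomes 16 and 11
pinned to widely known coordinates (16p11.2, 11p11.2/p11.12/p11.11).
Band *identities* therefore match the real karyotype only around those
anchors; band-level recurrence counting is unaffected because it only
requires a gap-free tiling, which is validated at load time. Users with
a real `cytoBand.txt` can load it via `genome.load_cytoband_table`.

## LCSH selection

* Size threshold **≥ 3 Mbp**, inclusive — the conventional clinical
  cut-off (population studies go far lower, but short runs are
  uninformative for consanguinity/UPD and dominated by common
  haplotypes).
* Sex-chromosome runs are kept but flagged; they never enter
  consanguinity sums or UPD calling (X homozygosity in males is
  hemizygosity, and X inactivation patterns confound interpretation).
* **Hemizygous masking**: an LCSH is discarded when same-sample
  copy-number ≤ 1 losses cover ≥ 50% of its length (union over
  possibly-split deletion calls). The 50% fraction is configurable;
  masking is applied to every LCSH rather than only the largest,
  a conservative automation of what is usually a manual review step.
  Masking and threshold filtering commute, and masking is idempotent.
* Segments are taken as the source software called them — never merged,
  split or re-segmented. No SNP-level or B-allele-frequency analysis.

## Inbreeding coefficient and kinship classes

F̂ = Σ(analyzable autosomal LCSH, Mbp) / 2881. Computed at full
precision; reports round to 3 decimals.

Degrees of kinship form a geometric series of expected
identity-by-descent fractions: 1/4 (first), 1/8, 1/16, 1/32, 1/64,
1/128 (seventh). Class boundaries are the **geometric means** of
consecutive class values — first ≥ 0.17678, second ≥ 0.08839, third
≥ 0.04419, fourth ≥ 0.02210, fifth ≥ 0.01105, seventh-or-more ≥ 0.005,
none below — i.e. nearest class on a log scale. Published tables are
consistent with this rule except at exact boundary sittings
(F = 0.0215 is fifth here, one published row lists its equivalent as
fourth); since no explicit boundary rule accompanies such tables, ours
is documented rather than inferred, and the boundaries are exposed as
configuration.

Samples whose homozygosity pattern is a single-chromosome UPD candidate
are excluded from cohort inbreeding *fractions* (the pattern reflects
one chromosomal event, not parental relatedness) but stay in the
denominator; the per-sample report carries an `upd_excluded` flag.

## UPD screening rules

Operating on analyzable autosomal LCSH only:

* **Rule B** — exactly one autosome carries LCSH *over* 5 Mbp (strict)
  and that autosome's LCSH sum to **≥ 10 Mbp** (inclusive): candidate,
  regardless of sub-5 Mbp runs elsewhere.
* **Rule A** — no run of 5 Mbp or more anywhere, but one autosome
  accumulates ≥ 2 sub-5 Mbp runs summing ≥ 10 Mbp: candidate. (Two
  sub-5 runs cannot reach 10, so in practice rule A needs three or
  more; the rule is kept literal.)
* Two or more autosomes with runs over 5 Mbp → no candidate (the
  pattern indicates relatedness). At most one candidate per sample; if
  several autosomes qualify under rule A, the largest sum wins.

Candidates on chromosomes 6, 7, 11, 14, 15, 20 are flagged imprinted
with the canonical syndromes (e.g. UPD(15)mat → Prader-Willi,
UPD(15)pat → Angelman). Heterodisomy produces no homozygosity and is
undetectable here; parental origin and mechanism are out of scope.

## Common regions

Recurrence is counted per cytoband: the fraction of cohort samples with
≥ 1 analyzable autosomal LCSH overlapping the band (each sample counted
once per band). Bands at or above the threshold — **5%, inclusive**
(one source phrase says "more than 5%", the same source's summary says
"5% or more"; inclusive was chosen and is configurable) — are merged
with adjacent qualifying bands, and the merged span's boundaries are
the **lower median** of member LCSH starts and of ends, keeping
boundaries at observed coordinates. Membership flagging of an
individual LCSH requires ≥ 50% of its length inside a region. A
packaged reference file carries ten published common-region coordinate
sets for annotation without a cohort.

## CNV handling

Filters: research mode keeps calls > 10 Kbp with ≥ 10 markers;
clinical mode keeps losses > 100 Kbp and gains > 150 Kbp with ≥ 50
markers (size strict, marker count inclusive). Classification labels
(benign / VUS / LPCNV / PCNV) are **inputs** produced by external
curation; no scoring or database lookup is performed. A sample's
result is its most relevant class (PCNV > LPCNV > VUS > benign > none);
diagnostic yield is the fraction whose result is PCNV.

## Association and comparisons

Per phenotype term, a 2×2 Fisher exact test compares the "negative"
group (no CNV or benign only) with the "pathogenic" group (result =
PCNV); VUS/LPCNV-best samples are excluded as inconclusive. The p-value
is the two-sided exact sum of hypergeometric probabilities ≤ the
observed table's. The *sample* odds ratio (a·d)/(b·c) is reported — not
the conditional-MLE estimate some tools print — with 0.5 added to all
cells when any cell is zero (Haldane–Anscombe, noted in the output).
Because OR < 1 in the negative/pathogenic orientation means enrichment
in the pathogenic group, both orientations are emitted with explicit
column names. Raw p-values are the headline (matching single-term
reporting practice); Benjamini–Hochberg adjusted values are provided
alongside. Per-class CNV metric comparisons use one-way ANOVA followed
by Tukey HSD.

## Synthetic cohort model

The generator emulates the *segment-level* signatures of each
phenomenon, not the underlying genetics:

* **Autozygosity** for degree d: block count ~ Poisson(λ) with
  λ = F_d · 2881 / μ_d; block lengths ~ Exponential(mean μ_d Mbp)
  truncated below at 0.5 Mbp (the callable-segment floor); blocks
  placed uniformly without overlap, chromosome chosen proportional to
  length and capped at chromosome size. Defaults
  μ = 50/33/25/20/17 Mbp for degrees 1–5, the ~100 cM/m heuristic with
  1 cM ≈ 1 Mbp. The expected analyzable total is ≈ F_d · 2881 Mbp;
  the compound-Poisson spread means single-sample estimates scatter
  around the true class (adjacent-class calls are expected, as in real
  cohorts).
* **Background LCSH**: count ~ Poisson(2.4), sizes 3 + Exp(1.1) Mbp,
  placed on *distinct* chromosomes (ancestral haplotypes sit at
  distinct loci). These rates were chosen analytically so a default
  cohort shows ~91% of samples with ≥ 1 run, ~59% with only sub-5 Mbp
  runs and ~31% with something at/over 5 Mbp — the structure reported
  for a large clinical cohort. A `background_max_mbp` cap produces
  "clean" cohorts for specificity testing.
* **UPD events**: whole-chromosome isodisomy (one run covering
  90–98% of an autosome), iso/hetero mixes (1–3 runs > 5 Mbp totalling
  ≥ 10 Mbp) and segmental events (terminal run, configurable size —
  sizes below 10 Mbp give negative controls).
* **Common regions, CNVs, phenotypes**: carrier status Bernoulli at the
  configured frequency with uniform boundary jitter; CNV counts Poisson
  per class with lognormal sizes; phenotype terms drawn from a logistic
  model whose odds multiply by a configurable factor when the sample
  carries a PCNV.

Per-sample RNG streams are seeded as (cohort seed, sample index), so
output is reproducible and byte-identical across runs, and samples are
independent of cohort-level configuration order.

What the generator does **not** model: recombination maps, SNP-level
genotypes, B-allele frequencies, mosaicism, array noise or batch
effects. Passing tests therefore demonstrate the *rules and estimators*
behave correctly on segment lists shaped like real exports — not that
segment calling itself is reliable.

## Problem sizes and numerics

The validation suite uses 200 replicates for F-recovery, cohorts of
500 for UPD recall/specificity and common-region frequency recovery,
and 1000 for odds-ratio recovery — sizes at which binomial error is
well inside the asserted tolerances. The exhaustive Fisher cross-check
covers every 2×2 table with both margins ≤ 30. Exact-test p-values are
compared at 1e-8 relative tolerance; medians use the lower-median
convention; degenerate inputs (empty cohorts, all-zero tables,
single-value classes) return empty results or raise explicit errors as
documented per function.

## Known limitations

* GRCh37/hg19 only; no liftover.
* The hemizygous mask needs the deletion to be *called* in the same
  input; an uncalled deletion leaves its artifact LCSH in place.
* Band names away from the pinned anchors of the synthetic cytoband
  table will not match the real karyotype (coordinates always do).
* The kinship class boundaries are a documented convention; borderline
  samples (near a geometric-mean boundary) can differ from other
  groups' manual assignments.
* Rule-based UPD screening cannot see heterodisomy and does not
  distinguish UPD from other causes of single-chromosome homozygosity
  (e.g. repair events); candidates are screening calls, not diagnoses.
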