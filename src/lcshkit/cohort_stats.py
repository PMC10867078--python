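"""Phenotype-genotype association and multi-class mean comparisons.

The association design compares, per phenotype term, the "negative"
group (samples with no CNV or only benign CNVs) against the "pathogenic"
group (samples whose most relevant CNV is a PCNV).  Samples whose best
finding is a VUS or LPCNV are excluded as inconclusive.  Each term gets
a two-sided Fisher exact p-value and the sample odds ratio; because an
odds ratio below 1 in this orientation means the phenotype is *enriched*
in the pathogenic group, both orientations are emitted with explicit
labels.  Raw p-values are the headline (single-phenotype testing
convention); a Benjamini-Hochberg column is provided alongside.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .cnv import most_relevant_class
from .segment_io import SampleRecord

__all__ = [
    "fisher_exact_2x2",
    "phenotype_association_table",
    "class_mean_comparison",
]


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float, str]:
    """Two-sided Fisher exact p and the sample odds ratio for a 2x2 table.

    Table layout: rows are groups, columns are phenotype present/absent
    (a, b = group 1; c, d = group 2).  The sample OR is (a*d)/(b*c); when
    any cell is zero, 0.5 is added to every cell (Haldane-Anscombe) and
    the returned note says so.
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells) or any(int(x) != x for x in cells):
        raise ValueError(f"cell counts must be non-negative integers, got {cells}")
    if sum(cells) == 0:
        raise ValueError("all-zero 2x2 table has no defined test")
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    note = ""
    if min(cells) == 0:
        a, b, c, d = (x + 0.5 for x in cells)
        note = "Haldane-Anscombe 0.5 added to all cells"
    odds_ratio = (a * d) / (b * c)
    return p, float(odds_ratio), note


def phenotype_association_table(
    cohort: Iterable[SampleRecord],
    terms: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-term Fisher association between phenotype and pathogenic CNV carriage.

    Returns one row per phenotype term with counts, the p-value, both OR
    orientations and a Benjamini-Hochberg adjusted p column.  Terms
    present in nobody are skipped.
    """
    cohort = list(cohort)
    negative, pathogenic = [], []
    for sample in cohort:
        cls = most_relevant_class(sample.cnv_calls)
        if cls in ("none", "benign"):
            negative.append(sample)
        elif cls == "PCNV":
            pathogenic.append(sample)
        # VUS / LPCNV best findings are inconclusive and excluded
    if terms is None:
        terms = sorted({t for s in (*negative, *pathogenic) for t in s.phenotype_terms})

    rows = []
    for term in terms:
        a = sum(1 for s in negative if term in s.phenotype_terms)
        b = len(negative) - a
        c = sum(1 for s in pathogenic if term in s.phenotype_terms)
        d = len(pathogenic) - c
        if a + c == 0:
            continue  # term absent from both groups
        p, or_neg_over_path, note = fisher_exact_2x2(a, b, c, d)
        rows.append(
            {
                "phenotype_term": term,
                "n_negative": len(negative),
                "n_pathogenic": len(pathogenic),
                "term_pos_negative": a,
                "term_pos_pathogenic": c,
                "p_value": p,
                "odds_ratio_negative_vs_pathogenic": or_neg_over_path,
                "odds_ratio_pathogenic_vs_negative": 1.0 / or_neg_over_path,
                "or_note": note,
            }
        )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["p_bh"] = multipletests(table["p_value"], method="fdr_bh")[1]
        table["significant"] = table["p_value"] <= alpha
        table = table.sort_values("p_value", kind="stable").reset_index(drop=True)
    return table


def class_mean_comparison(
    values_by_class: dict[str, Sequence[float]], alpha: float = 0.05
) -> dict:
    """One-way ANOVA plus Tukey HSD pairwise comparisons across classes.

    Classes with fewer than two values are excluded (and listed in
    ``excluded``).  Returns the ANOVA F/p and a DataFrame of pairwise
    adjusted p-values and mean differences.
    """
    usable = {k: list(v) for k, v in values_by_class.items() if len(v) >= 2}
    excluded = sorted(set(values_by_class) - set(usable))
    if len(usable) < 2:
        raise ValueError("need at least two classes with >= 2 values each")
    f_stat, p_anova = stats.f_oneway(*usable.values())
    values = np.concatenate([np.asarray(v, dtype=float) for v in usable.values()])
    labels = np.concatenate([[k] * len(v) for k, v in usable.items()])
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    frame = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return {
        "anova_f": float(f_stat),
        "anova_p": float(p_anova),
        "pairwise": frame,
        "excluded": excluded,
    }
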