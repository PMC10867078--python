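"""Fisher exact association and Tukey mean comparisons."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcshkit.cnv import CnvCall
from lcshkit.cohort_stats import (
    class_mean_comparison,
    fisher_exact_2x2,
    phenotype_association_table,
)
from lcshkit.genome import GenomicInterval
from lcshkit.segment_io import SampleRecord


def brute_force_fisher_p(a: int, b: int, c: int, d: int) -> float:
    """Independent oracle: exhaust every 2x2 table with the observed margins
    and sum hypergeometric probabilities <= the observed table's."""
    r1, r2, k = a + b, c + d, a + c
    n = r1 + r2

    def prob(x: int) -> float:
        return math.comb(r1, x) * math.comb(r2, k - x) / math.comb(n, k)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, k - r2), min(r1, k) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


class TestFisher:
    def test_symmetric_table(self):
        p, odds_ratio, note = fisher_exact_2x2(5, 5, 5, 5)
        assert p == pytest.approx(1.0)
        assert odds_ratio == pytest.approx(1.0)
        assert note == ""

    def test_against_enumeration_example(self):
        p, _, _ = fisher_exact_2x2(1, 9, 11, 3)
        assert p == pytest.approx(brute_force_fisher_p(1, 9, 11, 3), rel=1e-9)
        assert p == pytest.approx(0.0027595, abs=2e-5)

    def test_zero_cell_uses_haldane_correction(self):
        _, odds_ratio, note = fisher_exact_2x2(0, 10, 5, 5)
        assert "Haldane" in note
        assert odds_ratio == pytest.approx((0.5 * 5.5) / (10.5 * 5.5))

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(0, 0, 0, 0)

    def test_exhaustive_small_tables_match_enumeration(self):
        """Every 2x2 table with all cells <= 6 (margins <= 12)."""
        for a in range(7):
            for b in range(7):
                for c in range(7):
                    for d in range(7):
                        if a + b == 0 or c + d == 0 or a + b + c + d == 0:
                            continue
                        p, _, _ = fisher_exact_2x2(a, b, c, d)
                        assert p == pytest.approx(
                            brute_force_fisher_p(a, b, c, d), rel=1e-8, abs=1e-12
                        ), (a, b, c, d)

    @given(
        a=st.integers(0, 30), b=st.integers(0, 30),
        c=st.integers(0, 30), d=st.integers(0, 30),
    )
    @settings(max_examples=300, deadline=None)
    def test_random_tables_match_enumeration(self, a, b, c, d):
        if a + b == 0 or c + d == 0:
            return
        p, _, _ = fisher_exact_2x2(a, b, c, d)
        assert p == pytest.approx(brute_force_fisher_p(a, b, c, d), rel=1e-8, abs=1e-12)

    @given(
        a=st.integers(1, 20), b=st.integers(1, 20),
        c=st.integers(1, 20), d=st.integers(1, 20),
    )
    @settings(max_examples=100, deadline=None)
    def test_transposing_groups_inverts_odds_ratio(self, a, b, c, d):
        p1, or1, _ = fisher_exact_2x2(a, b, c, d)
        p2, or2, _ = fisher_exact_2x2(c, d, a, b)
        assert p1 == pytest.approx(p2, rel=1e-9)
        assert or2 == pytest.approx(1.0 / or1, rel=1e-9)


def cohort_with_effect(n, rng, multiplier=2.0, baseline=0.3, carrier_rate=0.3):
    samples = []
    for i in range(n):
        carrier = rng.uniform() < carrier_rate
        odds = baseline / (1 - baseline) * (multiplier if carrier else 1.0)
        terms = {"dd"} if rng.uniform() < odds / (1 + odds) else set()
        calls = []
        if carrier:
            calls = [CnvCall(f"S{i}", GenomicInterval("1", 1_000_000, 2_000_000),
                             "loss", classification="PCNV")]
        samples.append(SampleRecord(sample_id=f"S{i}", phenotype_terms=terms, cnv_calls=calls))
    return samples


class TestAssociationTable:
    def test_term_absent_from_everyone_skipped(self):
        cohort = [SampleRecord(sample_id="S1"), SampleRecord(sample_id="S2")]
        table = phenotype_association_table(cohort, terms=["ghost"])
        assert table.empty

    def test_vus_best_samples_excluded(self):
        vus = SampleRecord(
            sample_id="V1",
            phenotype_terms={"dd"},
            cnv_calls=[CnvCall("V1", GenomicInterval("1", 1_000_000, 2_000_000),
                               "loss", classification="VUS")],
        )
        cohort = cohort_with_effect(50, np.random.default_rng(0)) + [vus]
        table = phenotype_association_table(cohort)
        assert (table["n_negative"] + table["n_pathogenic"]).iloc[0] == 50

    def test_label_shuffle_gives_uniformish_p(self):
        """Permuting carrier labels should kill the association signal."""
        rng = np.random.default_rng(0)
        cohort = cohort_with_effect(300, rng, multiplier=1.0)
        hits = 0
        n_shuffles = 100
        for _ in range(n_shuffles):
            perm = rng.permutation(len(cohort))
            shuffled = [
                SampleRecord(
                    sample_id=s.sample_id,
                    phenotype_terms=cohort[j].phenotype_terms,
                    cnv_calls=s.cnv_calls,
                )
                for s, j in zip(cohort, perm)
            ]
            table = phenotype_association_table(shuffled, terms=["dd"])
            if not table.empty and table["p_value"].iloc[0] <= 0.05:
                hits += 1
        assert hits / n_shuffles <= 0.12


class TestMeanComparison:
    def test_identical_groups_not_significant(self):
        values = {"a": [1.0, 2.0, 3.0, 4.0], "b": [1.0, 2.0, 3.0, 4.0]}
        result = class_mean_comparison(values)
        assert float(result["pairwise"]["p-adj"].iloc[0]) > 0.9

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        significant = 0
        for _ in range(20):
            values = {
                "a": rng.normal(0, 1, 50).tolist(),
                "b": rng.normal(5, 1, 50).tolist(),
            }
            result = class_mean_comparison(values)
            if float(result["pairwise"]["p-adj"].iloc[0]) < 0.001:
                significant += 1
        assert significant >= 19

    def test_degenerate_groups_listed_and_excluded(self):
        values = {"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0], "tiny": [1.0]}
        result = class_mean_comparison(values)
        assert result["excluded"] == ["tiny"]

    def test_fewer_than_two_usable_groups_is_an_error(self):
        with pytest.raises(ValueError):
            class_mean_comparison({"a": [1.0, 2.0], "b": [3.0]})
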