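"""Synthetic cohort generator: determinism, model calibration, recoverability."""

import filecmp

import numpy as np
import pytest

from lcshkit.genome import hg19
from lcshkit.lcsh import attach_lcsh, per_sample_lcsh_summary
from lcshkit.segment_io import group_cohort, read_phenotype_table, read_segment_table
from lcshkit.simulate import (
    DEGREE_F,
    SimulationConfig,
    simulate_cohort,
    simulate_inbred_autozygosity,
    simulate_upd_sample,
)
from lcshkit.upd import call_upd_candidates

from conftest import make_lcsh
from lcshkit.segment_io import SampleRecord


def load_cohort(out_dir):
    parsed = read_segment_table(out_dir / "segments.tsv")
    assert not parsed.errors  # emitted files must parse cleanly
    phenos = read_phenotype_table(out_dir / "phenotypes.csv")
    cohort, _ = group_cohort(parsed.rows, phenos)
    for sample in cohort:
        attach_lcsh(sample)
    return cohort


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        config = SimulationConfig(n_samples=20, seed=5, class_mixture={"third": 0.2},
                                  upd_fraction=0.1)
        simulate_cohort(config, out_dir=tmp_path / "a")
        simulate_cohort(config, out_dir=tmp_path / "b")
        for name in ("segments.tsv", "phenotypes.csv", "truth.json"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False)

    def test_different_seed_differs(self, tmp_path):
        simulate_cohort(SimulationConfig(n_samples=20, seed=1), out_dir=tmp_path / "a")
        simulate_cohort(SimulationConfig(n_samples=20, seed=2), out_dir=tmp_path / "b")
        assert not filecmp.cmp(tmp_path / "a" / "segments.tsv",
                               tmp_path / "b" / "segments.tsv", shallow=False)


class TestAutozygosityModel:
    def test_outbred_has_no_blocks(self):
        rng = np.random.default_rng(0)
        assert simulate_inbred_autozygosity("outbred", rng) == []

    def test_unknown_degree_rejected(self):
        with pytest.raises(ValueError):
            simulate_inbred_autozygosity("sixth", np.random.default_rng(0))

    def test_third_degree_total_matches_expectation(self):
        """Mean autozygous total over replicates ~ F * 2881 = 180 Mbp (within 10%)."""
        rng = np.random.default_rng(0)
        totals = []
        for _ in range(400):
            blocks = simulate_inbred_autozygosity("third", rng)
            totals.append(sum(e - s + 1 for _, s, e in blocks) / 1e6)
        expected = DEGREE_F["third"] * 2881
        assert np.mean(totals) == pytest.approx(expected, rel=0.10)

    def test_blocks_do_not_overlap(self):
        rng = np.random.default_rng(1)
        blocks = simulate_inbred_autozygosity("first", rng)
        by_chrom = {}
        for chrom, s, e in blocks:
            by_chrom.setdefault(chrom, []).append((s, e))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 < s2


class TestUpdModel:
    def test_whole_iso_spans_most_of_chromosome(self):
        build = hg19()
        rng = np.random.default_rng(0)
        [(chrom, start, end)] = simulate_upd_sample("whole-iso", "15", rng, build)
        assert chrom == "15"
        assert (end - start + 1) / build.chromosomes["15"] >= 0.90

    def test_whole_iso_is_called_with_rule_b(self):
        rng = np.random.default_rng(0)
        blocks = simulate_upd_sample("whole-iso", "15", rng)
        sample = SampleRecord(
            sample_id="U1",
            lcsh_segments=[make_lcsh("U1", c, s, e) for c, s, e in blocks],
        )
        (cand,) = call_upd_candidates(sample)
        assert cand.rule == "B" and cand.imprinted_chromosome

    def test_iso_het_mix_reaches_total_threshold(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            blocks = simulate_upd_sample("iso-het-mix", "9", rng)
            total = sum(e - s + 1 for _, s, e in blocks) / 1e6
            assert total >= 10.0
            assert all(c == "9" for c, _, _ in blocks)

    def test_sub10_segmental_event_is_a_negative_control(self):
        rng = np.random.default_rng(0)
        blocks = simulate_upd_sample("segmental", "4", rng, segmental_size_mbp=(8.0, 8.0))
        sample = SampleRecord(
            sample_id="U1",
            lcsh_segments=[make_lcsh("U1", c, s, e) for c, s, e in blocks],
        )
        assert call_upd_candidates(sample) == []

    def test_sex_chromosome_rejected(self):
        with pytest.raises(ValueError):
            simulate_upd_sample("whole-iso", "X", np.random.default_rng(0))


class TestCohortCalibration:
    def test_background_reproduces_cohort_lcsh_structure(self, tmp_path):
        """Defaults target the observed clinical-cohort split: ~91% of
        samples with >= 1 autosomal LCSH, ~59% with only sub-5 Mbp runs."""
        config = SimulationConfig(n_samples=953, seed=0)
        simulate_cohort(config, out_dir=tmp_path)
        cohort = load_cohort(tmp_path)
        summaries = [per_sample_lcsh_summary(s) for s in cohort]
        frac_any = np.mean([s.count > 0 for s in summaries])
        frac_only_sub5 = np.mean([s.has_only_sub5 for s in summaries])
        frac_ge5 = np.mean([s.has_ge5 for s in summaries])
        assert frac_any == pytest.approx(0.91, abs=0.05)
        assert frac_only_sub5 == pytest.approx(0.59, abs=0.05)
        assert frac_ge5 == pytest.approx(0.31, abs=0.05)

    def test_truth_aligns_with_emitted_samples(self, tmp_path):
        config = SimulationConfig(n_samples=30, seed=2, upd_fraction=0.1)
        result = simulate_cohort(config, out_dir=tmp_path)
        assert len(result["truth"]) == 30
        upd_truth = [sid for sid, t in result["truth"].items() if t["upd"]]
        assert len(upd_truth) == 3

    def test_invalid_mixture_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_samples=10, class_mixture={"first": 0.9}, upd_fraction=0.2).validate()
        with pytest.raises(ValueError):
            SimulationConfig(n_samples=0).validate()


class TestHemizygousArtifacts:
    def test_artifact_loh_is_masked_by_pipeline(self, tmp_path):
        config = SimulationConfig(
            n_samples=40, seed=4, hemizygous_artifact_fraction=0.5,
            background_rate=0.0, cnv_spec={},
        )
        result = simulate_cohort(config, out_dir=tmp_path)
        cohort = load_cohort(tmp_path)
        artifact_ids = {sid for sid, t in result["truth"].items() if t["hemizygous_artifact"]}
        assert artifact_ids
        for sample in cohort:
            if sample.sample_id in artifact_ids:
                assert any(
                    seg.masked_reason == "hemizygous-overlap" for seg in sample.lcsh_segments
                ), sample.sample_id
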