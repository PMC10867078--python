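"""Parsing of segment exports and phenotype tables; BED round trips."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcshkit.genome import GenomicInterval
from lcshkit.segment_io import (
    FormatError,
    group_cohort,
    read_bed,
    read_phenotype_table,
    read_segment_table,
    write_bed,
)

HEADER = "Sample\tType\tChromosome\tStart\tEnd\tMarker Count\tCN State\n"


def write_segments(path, rows):
    with path.open("w") as fh:
        fh.write(HEADER)
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return path


class TestSegmentTable:
    def test_well_formed_rows(self, tmp_path):
        path = write_segments(
            tmp_path / "seg.tsv",
            [
                ("S1", "Gain", "1", 1000, 200000, 25, 3),
                ("S1", "Loss", "2", 5000, 120000, 30, 1),
                ("S2", "LOH", "3", 1_000_000, 5_000_000, 800, ""),
            ],
        )
        result = read_segment_table(path)
        assert len(result.rows) == 3 and not result.errors
        loh = [r for r in result.rows if r.seg_type == "LOH"][0]
        assert loh.copy_number is None  # LOH carries no copy-number state

    def test_reversed_coordinates_rejected_with_row_number(self, tmp_path):
        path = write_segments(
            tmp_path / "seg.tsv", [("S1", "LOH", "1", 9_000_000, 1_000_000, 10, "")]
        )
        result = read_segment_table(path)
        assert not result.rows
        assert "row 2" in result.errors[0]

    def test_unknown_chromosome_rejected(self, tmp_path):
        path = write_segments(tmp_path / "seg.tsv", [("S1", "LOH", "99", 1, 10, 5, "")])
        result = read_segment_table(path)
        assert not result.rows and "99" in result.errors[0]

    def test_missing_mandatory_column(self, tmp_path):
        path = tmp_path / "seg.tsv"
        path.write_text("Sample\tType\tStart\tEnd\nS1\tLOH\t1\t10\n")
        with pytest.raises(FormatError, match="Chromosome"):
            read_segment_table(path)

    def test_published_three_segment_case_sums_to_88_8(self, tmp_path):
        rows = [
            ("147", "LOH", "2", 79_211_952, 89_129_064, 500, ""),
            ("147", "LOH", "2", 95_341_387, 128_342_675, 500, ""),
            ("147", "LOH", "2", 22_170_065, 68_067_589, 500, ""),
        ]
        result = read_segment_table(write_segments(tmp_path / "seg.tsv", rows))
        assert len(result.rows) == 3
        total = sum(r.interval.length_bp for r in result.rows) / 1e6
        assert round(total, 1) == 88.8

    def test_grouping_is_order_independent(self, tmp_path):
        rows = [
            ("S2", "LOH", "3", 1_000_000, 5_000_000, 10, ""),
            ("S1", "Loss", "2", 5000, 120000, 30, 1),
            ("S1", "LOH", "4", 2_000_000, 9_000_000, 10, ""),
        ]
        shuffled = rows[::-1]
        c1, _ = group_cohort(read_segment_table(write_segments(tmp_path / "a.tsv", rows)).rows)
        c2, _ = group_cohort(read_segment_table(write_segments(tmp_path / "b.tsv", shuffled)).rows)
        assert [s.sample_id for s in c1] == [s.sample_id for s in c2]
        for s1, s2 in zip(c1, c2):
            assert s1.lcsh_segments == s2.lcsh_segments
            assert s1.cnv_calls == s2.cnv_calls


class TestPhenotypeTable:
    def test_two_sample_csv(self, tmp_path):
        path = tmp_path / "ph.csv"
        path.write_text(
            "sample_id,sex,age_years,phenotype_terms\n"
            "S1,male,4,DD; ASD\nS2,female,7,ID\n"
        )
        records = read_phenotype_table(path)
        assert set(records) == {"S1", "S2"}
        assert records["S1"].phenotype_terms == {"dd", "asd"}  # normalized

    def test_duplicate_sample_rejected(self, tmp_path):
        path = tmp_path / "ph.csv"
        path.write_text("sample_id,sex\nS1,male\nS1,female\n")
        with pytest.raises(FormatError, match="S1"):
            read_phenotype_table(path)

    def test_phenotype_only_sample_reported_as_orphan(self, tmp_path):
        seg = write_segments(
            tmp_path / "seg.tsv", [("S1", "LOH", "1", 1_000_000, 5_000_000, 10, "")]
        )
        ph = tmp_path / "ph.csv"
        ph.write_text("sample_id,sex\nS1,male\nS9,female\n")
        cohort, notes = group_cohort(
            read_segment_table(seg).rows, read_phenotype_table(ph)
        )
        assert len(cohort) == 1
        assert any("S9" in n for n in notes)


class TestBed:
    def test_convention_conversion(self, tmp_path):
        path = tmp_path / "out.bed"
        write_bed([GenomicInterval("1", 1, 10)], path)
        line = [l for l in path.read_text().splitlines() if not l.startswith("track")][0]
        assert line.split("\t")[1:3] == ["0", "10"]

    def test_empty_input_writes_header_only(self, tmp_path):
        path = tmp_path / "out.bed"
        write_bed([], path)
        assert path.read_text().startswith("track")
        assert read_bed(path) == []

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=20, deadline=None)
    def test_round_trip_identity(self, seed, tmp_path_factory):
        rng = random.Random(seed)
        intervals = []
        for _ in range(100):
            chrom = str(rng.randint(1, 22))
            start = rng.randint(1, 10**7)
            intervals.append(GenomicInterval(chrom, start, start + rng.randint(0, 10**6)))
        path = tmp_path_factory.mktemp("bed") / "rt.bed"
        write_bed(intervals, path)
        assert read_bed(path) == sorted(intervals, key=lambda i: (i.chromosome, i.start))
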