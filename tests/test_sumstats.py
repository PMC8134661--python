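"""Summary-statistics I/O, filtering, allele harmonization and study pairing."""

import gzip
import math

import pytest
from hypothesis import given, settings, strategies as st

from btob import (
    HarmonizationError,
    SumstatsFormatError,
    filter_by_n,
    harmonize_pair,
    merge_studies,
    read_sumstats,
    write_sumstats,
)
from conftest import make_record


class TestReadSumstats:
    def test_reads_all_valid_rows_in_order(self, sumstats_file):
        records = [make_record(snp_id=f"rs{i}", pos=1000 * (i + 1)) for i in range(3)]
        out = read_sumstats(sumstats_file(records))
        assert [r.snp_id for r in out] == ["rs0", "rs1", "rs2"]

    def test_parses_published_row_faithfully(self, tmp_path):
        path = tmp_path / "giant.txt"
        path.write_text(
            "MarkerName Chr Pos Allele1 Allele2 Effect StdErr P-value N\n"
            "rs12073056 1 119000000 A G -0.022 0.0049 6.7e-06 90142\n"
        )
        (rec,) = read_sumstats(path)
        assert rec.beta == -0.022
        assert rec.se == 0.0049
        assert rec.pvalue == 6.7e-06
        assert rec.n == 90142

    def test_header_only_file_yields_empty(self, tmp_path):
        path = tmp_path / "empty.txt"
        path.write_text("MarkerName Chr Pos Allele1 Allele2 Effect StdErr P-value N\n")
        assert read_sumstats(path) == []

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("MarkerName Chr Pos Allele1 Allele2 Effect StdErr N\nx 1 1 A G 0.1 0.01 100\n")
        with pytest.raises(SumstatsFormatError, match="P-value"):
            read_sumstats(path)

    def test_na_rows_skipped_and_counted(self, tmp_path, caplog):
        path = tmp_path / "na.txt"
        path.write_text(
            "MarkerName Chr Pos Allele1 Allele2 Effect StdErr P-value N\n"
            "rs1 1 100 A G 0.1 0.01 0.5 50000\n"
            "rs2 1 200 A G NA NA NA 50000\n"
        )
        with caplog.at_level("INFO"):
            out = read_sumstats(path)
        assert [r.snp_id for r in out] == ["rs1"]
        assert "1 rows" in caplog.text

    def test_unparsable_row_skips_by_default_raises_in_strict(self, tmp_path):
        path = tmp_path / "junk.txt"
        path.write_text(
            "MarkerName Chr Pos Allele1 Allele2 Effect StdErr P-value N\n"
            "rs1 1 100 A G zero 0.01 0.5 50000\n"
            "rs2 1 200 A G 0.1 0.01 0.5 50000\n"
        )
        assert [r.snp_id for r in read_sumstats(path)] == ["rs2"]
        with pytest.raises(SumstatsFormatError, match="line 2"):
            read_sumstats(path, strict=True)

    def test_custom_dialect_and_gzip(self, tmp_path):
        path = tmp_path / "alt.txt.gz"
        with gzip.open(path, "wt") as fh:
            fh.write("SNP CHR BP A1 A2 BETA SE P NMISS\nrs9 2 500 C T 0.2 0.05 0.01 40000\n")
        dialect = {
            "snp_id": "SNP", "chrom": "CHR", "pos": "BP", "effect_allele": "A1",
            "other_allele": "A2", "beta": "BETA", "se": "SE", "pvalue": "P", "n": "NMISS",
        }
        (rec,) = read_sumstats(path, dialect=dialect)
        assert (rec.snp_id, rec.chrom, rec.n) == ("rs9", "2", 40000)


@given(
    beta=st.floats(-1, 1, allow_nan=False),
    se=st.floats(1e-6, 1, allow_nan=False, exclude_min=True),
    pvalue=st.floats(1e-300, 1, allow_nan=False),
    n=st.integers(1, 10**7),
    pos=st.integers(0, 2**31),
)
@settings(max_examples=50, deadline=None)
def test_write_read_round_trip(tmp_path_factory, beta, se, pvalue, n, pos):
    """Writing then reading reproduces ids/alleles exactly, numerics to 12 s.d."""
    rec = make_record(beta=beta, se=se, pvalue=pvalue, n=n, pos=pos)
    path = tmp_path_factory.mktemp("rt") / "roundtrip.txt"
    write_sumstats([rec], path)
    (back,) = read_sumstats(path)
    assert (back.snp_id, back.chrom, back.pos) == (rec.snp_id, rec.chrom, rec.pos)
    assert (back.effect_allele, back.other_allele) == (rec.effect_allele, rec.other_allele)
    for attr in ("beta", "se", "pvalue"):
        assert getattr(back, attr) == pytest.approx(getattr(rec, attr), rel=1e-11)
    assert back.n == rec.n


class TestFilterByN:
    def test_strictly_greater_than_threshold(self):
        records = [make_record(snp_id=f"rs{n}", n=n) for n in (29999, 30000, 30001)]
        assert [r.n for r in filter_by_n(records, 30000)] == [30001]

    def test_zero_threshold_keeps_all_and_empty_passes_through(self):
        records = [make_record(snp_id=f"rs{i}") for i in range(3)]
        assert filter_by_n(records, 0) == records
        assert filter_by_n([], 30000) == []

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_by_n([], -1)


class TestHarmonize:
    def test_matching_alleles_pass_through(self):
        m = harmonize_pair(make_record(beta=0.1), make_record(beta=-0.2, pvalue=0.1))
        assert not m.sign_flipped
        assert m.study2.beta == -0.2

    def test_swapped_alleles_flip_sign(self):
        r2 = make_record(ea="G", oa="A", beta=-0.2)
        m = harmonize_pair(make_record(beta=0.1), r2)
        assert m.sign_flipped
        assert m.study2.beta == 0.2
        assert m.study2.effect_allele == "A"

    def test_irreconcilable_alleles_raise_with_snp_id(self):
        with pytest.raises(HarmonizationError, match="rs1"):
            harmonize_pair(make_record(), make_record(ea="A", oa="C"))

    def test_strand_ambiguous_flagged_not_dropped(self):
        r1 = make_record(ea="A", oa="T")
        r2 = make_record(ea="A", oa="T", beta=0.3)
        m = harmonize_pair(r1, r2)
        assert m.strand_ambiguous and not m.sign_flipped

    @given(beta2=st.floats(-1, 1, allow_nan=False))
    @settings(max_examples=30, deadline=None)
    def test_involution_preflipped_record_recovers_original(self, beta2):
        """Harmonizing an allele-swapped copy gives the same merged pair."""
        r1 = make_record(beta=0.1)
        r2 = make_record(beta=beta2)
        pre_flipped = make_record(ea="G", oa="A", beta=-beta2)
        direct = harmonize_pair(r1, r2)
        via_flip = harmonize_pair(r1, pre_flipped)
        assert via_flip.study2.beta == pytest.approx(direct.study2.beta)
        assert via_flip.study2.effect_allele == direct.study2.effect_allele


class TestMergeStudies:
    def test_intersection_of_shared_snps(self):
        s1 = [make_record(snp_id=f"rs{i}", pos=100 * i) for i in (1, 2, 3)]
        s2 = [make_record(snp_id=f"rs{i}", pos=100 * i) for i in (2, 3, 4)]
        merged = merge_studies(s1, s2, min_n=0)
        assert [m.snp_id for m in merged] == ["rs2", "rs3"]

    def test_identical_studies_merge_completely(self):
        s = [make_record(snp_id=f"rs{i}", pos=100 * i) for i in range(5)]
        merged = merge_studies(s, s, min_n=0)
        assert len(merged) == len(s)
        assert all(m.snp_id in {r.snp_id for r in s} for m in merged)

    def test_example_pair_survives_default_n_filter(self, example_pair):
        merged = merge_studies(*example_pair, min_n=30_000)
        assert len(merged) == 8

    def test_zero_overlap_warns_not_raises(self, caplog):
        s1 = [make_record(snp_id="rsA")]
        s2 = [make_record(snp_id="rsB")]
        with caplog.at_level("WARNING"):
            assert merge_studies(s1, s2, min_n=0) == []
        assert "no overlapping" in caplog.text

    def test_output_sorted_by_genome_coordinates(self):
        s = [
            make_record(snp_id="a", chrom="2", pos=50),
            make_record(snp_id="b", chrom="1", pos=900),
            make_record(snp_id="c", chrom="1", pos=100),
            make_record(snp_id="d", chrom="X", pos=10),
        ]
        merged = merge_studies(s, s, min_n=0)
        assert [m.snp_id for m in merged] == ["c", "b", "a", "d"]
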