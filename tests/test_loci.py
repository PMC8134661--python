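"""Gene windows, lead SNPs and novelty calls."""

import random
from dataclasses import dataclass

import pytest

from btob import GeneWindow, assign_to_windows, call_novel, lead_snp, read_gene_windows
from btob.datasets import example_study_pair, example_gene_windows
from btob.sumstats import merge_studies
from btob.core import run_btob


@dataclass(frozen=True)
class Snp:
    snp_id: str
    chrom: str
    pos: int
    pvalue: float


GENE = GeneWindow(gene="G1", chrom="1", start=1_000_000, end=1_010_000, flank=400_000)


class TestWindows:
    def test_flank_boundary_inclusive(self):
        assert GENE.contains("1", 600_000)
        assert not GENE.contains("1", 599_999)
        assert GENE.contains("1", 1_410_000)
        assert not GENE.contains("1", 1_410_001)

    def test_zero_flank_keeps_gene_body_only(self):
        bare = GeneWindow(gene="G1", chrom="1", start=1_000_000, end=1_010_000, flank=0)
        assert bare.contains("1", 1_000_000) and not bare.contains("1", 999_999)

    def test_chromosome_must_match(self):
        assert not GENE.contains("2", 1_005_000)

    def test_window_clamped_at_one(self):
        w = GeneWindow(gene="tel", chrom="1", start=100, end=200, flank=1000)
        assert w.window == (1, 1200)

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            GeneWindow(gene="bad", chrom="1", start=10, end=5)

    def test_assignment_allows_multiple_windows(self):
        other = GeneWindow(gene="G2", chrom="1", start=1_005_000, end=1_020_000, flank=0)
        snp = Snp("rs1", "1", 1_006_000, 1e-9)
        assigned = assign_to_windows([snp], [GENE, other])
        assert assigned["G1"] == [snp] and assigned["G2"] == [snp]

    def test_read_gene_windows_roundtrip(self, tmp_path):
        path = tmp_path / "genes.bed"
        path.write_text("# chrom start end gene (1-based inclusive)\n1\t1000000\t1010000\tG1\n")
        (w,) = read_gene_windows(path, flank=0)
        assert (w.gene, w.start, w.end) == ("G1", 1_000_000, 1_010_000)


class TestLeadSnp:
    def test_smallest_p_wins(self):
        a, b = Snp("rsA", "1", 10, 1e-9), Snp("rsB", "1", 20, 1e-5)
        assert lead_snp([b, a]) is a

    def test_tie_broken_by_position_then_id(self):
        a, b = Snp("rsA", "1", 20, 1e-9), Snp("rsB", "1", 10, 1e-9)
        assert lead_snp([a, b]) is b
        c, d = Snp("rsC", "1", 10, 1e-9), Snp("rsD", "1", 10, 1e-9)
        assert lead_snp([d, c]) is c

    def test_single_and_empty(self):
        only = Snp("rs1", "1", 5, 0.5)
        assert lead_snp([only]) is only
        with pytest.raises(ValueError):
            lead_snp([])


class TestCallNovel:
    def _toy(self, uni_p=1e-6):
        biv = [Snp("rsLead", "1", 1_005_000, 1e-9)]
        uni1 = [Snp("rsLead", "1", 1_005_000, uni_p)]
        uni2 = [Snp("rsOther", "1", 1_200_000, 0.5)]
        return biv, uni1, uni2

    def test_novel_when_univariate_quiet(self):
        (call,) = call_novel(*self._toy(), windows=[GENE])
        assert call.is_novel and call.lead_snp_bivariate == "rsLead"

    def test_vetoed_by_any_significant_window_snp(self):
        (call,) = call_novel(*self._toy(uni_p=1e-9), windows=[GENE])
        assert not call.is_novel

    def test_lead_only_mode_checks_bivariate_lead_not_whole_window(self):
        biv = [Snp("rsLead", "1", 1_005_000, 1e-9)]
        # bivariate lead is univariately quiet; another flank SNP is significant
        uni1 = [Snp("rsLead", "1", 1_005_000, 1e-6), Snp("rsNoise", "1", 700_000, 1e-9)]
        strict = call_novel(biv, uni1, [], [GENE])
        loose = call_novel(biv, uni1, [], [GENE], lead_only=True)
        assert not strict[0].is_novel
        assert loose[0].is_novel

    def test_gene_without_bivariate_snps_omitted(self, caplog):
        empty_gene = GeneWindow(gene="far", chrom="9", start=1, end=10, flank=0)
        with caplog.at_level("WARNING"):
            calls = call_novel(*self._toy(), windows=[GENE, empty_gene])
        assert [c.gene for c in calls] == ["G1"]
        assert "far" in caplog.text

    def test_threshold_monotonicity(self):
        biv, uni1, uni2 = self._toy(uni_p=3e-8)
        loose = call_novel(biv, uni1, uni2, [GENE], alpha_uni=2.5e-8)
        tight = call_novel(biv, uni1, uni2, [GENE], alpha_uni=5e-8)
        assert loose[0].is_novel and not tight[0].is_novel  # raising alpha_uni shrinks
        small = call_novel(biv, uni1, uni2, [GENE], alpha_biv=1e-10)
        assert not small[0].is_novel  # lowering alpha_biv shrinks

    def test_flank_monotonicity_more_flank_never_adds_novel(self):
        biv = [Snp("rsLead", "1", 1_005_000, 1e-9)]
        uni1 = [Snp("rsFar", "1", 650_000, 1e-9)]  # only inside the wide flank
        wide = call_novel(biv, uni1, [], [GENE])
        narrow_windows = [GeneWindow(gene="G1", chrom="1", start=1_000_000,
                                     end=1_010_000, flank=0)]
        narrow = call_novel(biv, uni1, [], narrow_windows)
        assert narrow[0].is_novel and not wide[0].is_novel

    def test_order_invariance(self):
        biv, uni1, uni2 = self._toy()
        base = call_novel(biv, uni1, uni2, [GENE])
        rng = random.Random(0)
        for seq in (biv, uni1, uni2):
            rng.shuffle(seq)
        assert call_novel(biv, uni1, uni2, [GENE]) == base

    def test_example_loci_called_novel_end_to_end(self):
        """Six of the bundled eight loci are novel at (5e-8, 2.5e-8); the two
        whose chi-square recomputed from rounded inputs misses the threshold
        are not."""
        s1, s2 = example_study_pair()
        results = run_btob(merge_studies(s1, s2, min_n=30_000))
        calls = call_novel(results, s1, s2, example_gene_windows())
        assert len(calls) == 8
        novel = {c.gene for c in calls if c.is_novel}
        assert {"WARS2", "TBX15", "HCG23", "HLA-DRA", "SLC38A11", "KLF14"} <= novel
        assert "POC5" not in novel
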