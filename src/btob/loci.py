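"""Gene-window annotation and novel-locus calling.

A gene's window is its body extended by a flank (default 400 kb per side).
The lead SNP of a window is its smallest-p SNP. A gene is called novel when
the bivariate lead SNP is genome-wide significant (default 5e-8) while no
SNP in the window reaches the Bonferroni-corrected univariate threshold
(default 2.5e-8) in either input scan — i.e. the combined test finds the
locus, the separate scans do not.

Coordinates are 1-based inclusive throughout, matching GWAS summary files;
the gene table is BED-like tab-delimited (chrom, start, end, gene) but with
1-based inclusive intervals, stated in the expected header comment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Protocol, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "GeneWindow",
    "NoveltyCall",
    "read_gene_windows",
    "assign_to_windows",
    "lead_snp",
    "call_novel",
]

DEFAULT_FLANK = 400_000
GENOME_WIDE_ALPHA = 5e-8
UNIVARIATE_ALPHA = 2.5e-8  # 5e-8 Bonferroni-corrected over two traits


class SnpLike(Protocol):
    """Anything with an id, coordinates and a p-value (association record or result)."""

    snp_id: str
    chrom: str
    pos: int
    pvalue: float


@dataclass(frozen=True)
class GeneWindow:
    """A gene interval plus symmetric flank."""

    gene: str
    chrom: str
    start: int
    end: int
    flank: int = DEFAULT_FLANK

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"{self.gene}: invalid interval [{self.start}, {self.end}]")
        if self.flank < 0:
            raise ValueError(f"{self.gene}: negative flank {self.flank}")

    @property
    def window(self) -> tuple[int, int]:
        """Flanked interval, clamped at position 1, inclusive both ends."""
        return (max(1, self.start - self.flank), self.end + self.flank)

    def contains(self, chrom: str, pos: int) -> bool:
        lo, hi = self.window
        return str(chrom) == self.chrom and lo <= pos <= hi


@dataclass(frozen=True)
class NoveltyCall:
    gene: str
    lead_snp_bivariate: str
    p_bivariate: float
    lead_p_univariate_min: float
    is_novel: bool


def read_gene_windows(path, flank: int = DEFAULT_FLANK) -> list[GeneWindow]:
    """Read a BED-like gene table: chrom, start, end, gene (1-based inclusive)."""
    windows = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}, line {line_no}: expected chrom, start, end, gene")
            chrom, start, end, gene = parts[0], int(parts[1]), int(parts[2]), parts[3]
            windows.append(GeneWindow(gene=gene, chrom=chrom, start=start, end=end, flank=flank))
    return windows


def assign_to_windows(
    results: Sequence[SnpLike],
    windows: Sequence[GeneWindow],
) -> dict[str, list[SnpLike]]:
    """Map each gene to the SNPs inside its flanked window.

    A SNP may belong to several overlapping windows; SNPs in no window are
    counted in the log. Genes with no SNPs map to empty lists.
    """
    assigned: dict[str, list[SnpLike]] = {w.gene: [] for w in windows}
    n_unplaced = 0
    for snp in results:
        hit = False
        for w in windows:
            if w.contains(snp.chrom, snp.pos):
                assigned[w.gene].append(snp)
                hit = True
        if not hit:
            n_unplaced += 1
    if n_unplaced:
        logger.info("%d of %d SNPs fall in no gene window", n_unplaced, len(results))
    return assigned


def lead_snp(snps: Sequence[SnpLike]) -> SnpLike:
    """The smallest-p SNP; ties broken by (chrom, pos), then id."""
    if not snps:
        raise ValueError("lead_snp requires a nonempty SNP set")
    return min(snps, key=lambda s: (s.pvalue, str(s.chrom), s.pos, s.snp_id))


def call_novel(
    bivariate: Sequence[SnpLike],
    univariate1: Sequence[SnpLike],
    univariate2: Sequence[SnpLike],
    windows: Sequence[GeneWindow],
    alpha_biv: float = GENOME_WIDE_ALPHA,
    alpha_uni: float = UNIVARIATE_ALPHA,
    lead_only: bool = False,
) -> list[NoveltyCall]:
    """Call genes whose signal is bivariate-only.

    Per gene: the bivariate lead SNP must have p < ``alpha_biv`` while the
    univariate scans show nothing at ``alpha_uni`` in the window. By default
    *every* window SNP of both scans is checked (equivalently, each scan's
    own lead SNP — the window minimum); with ``lead_only`` only the
    bivariate lead SNP's univariate p-values are checked, the looser
    reading. Genes with no bivariate SNPs in the window are omitted with a
    warning. Input order never affects the calls.
    """
    if not 0 < alpha_biv < 1 or not 0 < alpha_uni < 1:
        raise ValueError("significance thresholds must be in (0, 1)")
    biv_by_gene = assign_to_windows(bivariate, windows)
    uni1_by_gene = assign_to_windows(univariate1, windows)
    uni2_by_gene = assign_to_windows(univariate2, windows)

    calls = []
    for w in sorted(windows, key=lambda w: w.gene):
        biv_snps = biv_by_gene[w.gene]
        if not biv_snps:
            logger.warning("gene %s: no bivariate SNPs in window; call omitted", w.gene)
            continue
        lead = lead_snp(biv_snps)
        uni_ps: list[float] = []
        for uni_snps in (uni1_by_gene[w.gene], uni2_by_gene[w.gene]):
            if lead_only:
                uni_ps.extend(s.pvalue for s in uni_snps if s.snp_id == lead.snp_id)
            else:
                uni_ps.extend(s.pvalue for s in uni_snps)
        min_uni = min(uni_ps) if uni_ps else math.inf
        calls.append(
            NoveltyCall(
                gene=w.gene,
                lead_snp_bivariate=lead.snp_id,
                p_bivariate=lead.pvalue,
                lead_p_univariate_min=min_uni,
                is_novel=(lead.pvalue < alpha_biv) and (min_uni >= alpha_uni),
            )
        )
    return calls
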