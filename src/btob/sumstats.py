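"""Reading, validating, harmonizing and pairing GWAS summary-statistics tables.

Input files follow the GIANT convention: whitespace- or tab-delimited text
with a header row, one line per SNP carrying marker name, chromosome,
position, effect/other allele, effect estimate (beta), its standard error,
the association p-value and the per-SNP sample size. Column headers vary
across releases, so the mapping from logical fields to file columns is
configurable; :data:`DEFAULT_DIALECT` matches the most common header set.
Gzip-compressed files are read transparently (by extension).

Two studies enter the bivariate test: the marginal GWAS of the heritable
covariate (study 1) and the GWAS of the focal trait adjusted for that
covariate (study 2). :func:`merge_studies` pairs them SNP-by-SNP, flipping
study 2's effect sign where the effect allele is reported on the opposite
allele. The downstream 2-df statistic is sign-free, so harmonization cannot
change p-values, but reported effect directions depend on it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: Logical field -> column header for GIANT-style releases.
DEFAULT_DIALECT: dict[str, str] = {
    "snp_id": "MarkerName",
    "chrom": "Chr",
    "pos": "Pos",
    "effect_allele": "Allele1",
    "other_allele": "Allele2",
    "beta": "Effect",
    "se": "StdErr",
    "pvalue": "P-value",
    "n": "N",
}

_REQUIRED_FIELDS = tuple(DEFAULT_DIALECT)


class SumstatsFormatError(ValueError):
    """A summary-statistics file violates the expected table format."""


class HarmonizationError(ValueError):
    """Alleles of two records for one SNP cannot be reconciled."""

    def __init__(self, snp_id: str, message: str):
        super().__init__(f"{snp_id}: {message}")
        self.snp_id = snp_id


@dataclass(frozen=True)
class AssocRecord:
    """One SNP's summary statistics from a single GWAS.

    ``beta`` is the per-allele effect of ``effect_allele`` on the
    (standardized) trait, ``se`` its standard error, ``pvalue`` the reported
    association p-value and ``n`` the per-SNP sample size. Positions are
    1-based base pairs.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    n: int

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        if self.pos < 0:
            raise ValueError(f"{self.snp_id}: negative position {self.pos}")
        if not self.se > 0:
            raise ValueError(f"{self.snp_id}: SE must be positive, got {self.se}")
        if not 0 < self.pvalue <= 1:
            raise ValueError(f"{self.snp_id}: p-value must be in (0, 1], got {self.pvalue}")
        if self.n < 1:
            raise ValueError(f"{self.snp_id}: sample size must be >= 1, got {self.n}")

    @property
    def alleles(self) -> frozenset:
        return frozenset((self.effect_allele, self.other_allele))

    @property
    def strand_ambiguous(self) -> bool:
        """A/T and C/G pairs cannot be resolved without strand information."""
        return self.alleles in (frozenset("AT"), frozenset("CG"))


@dataclass(frozen=True)
class MergedRecord:
    """An allele-harmonized pair of records for one SNP across the two studies.

    ``study1`` is the marginal covariate GWAS, ``study2`` the adjusted focal
    GWAS; after harmonization both report their beta on the same effect
    allele. ``sign_flipped`` records whether study 2's beta was negated.
    ``strand_ambiguous`` flags A/T and C/G SNPs, which are kept (the 2-df
    test is sign-free) but marked in the provenance.
    """

    snp_id: str
    study1: AssocRecord
    study2: AssocRecord
    sign_flipped: bool = False
    strand_ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.study1.snp_id != self.study2.snp_id:
            raise ValueError(
                f"paired records disagree on SNP id: "
                f"{self.study1.snp_id} vs {self.study2.snp_id}"
            )
        if self.study1.effect_allele != self.study2.effect_allele:
            raise ValueError(f"{self.snp_id}: effect alleles differ after harmonization")


def _parse_row(raw: Mapping[str, str], line_no: int) -> AssocRecord:
    try:
        return AssocRecord(
            snp_id=str(raw["snp_id"]),
            chrom=str(raw["chrom"]),
            pos=int(float(raw["pos"])),
            effect_allele=str(raw["effect_allele"]).upper(),
            other_allele=str(raw["other_allele"]).upper(),
            beta=float(raw["beta"]),
            se=float(raw["se"]),
            pvalue=float(raw["pvalue"]),
            n=int(float(raw["n"])),
        )
    except (TypeError, ValueError) as exc:
        raise SumstatsFormatError(f"line {line_no}: {exc}") from exc


def read_sumstats(
    path,
    dialect: Mapping[str, str] | None = None,
    strict: bool = False,
) -> list[AssocRecord]:
    """Read a summary-statistics table into a list of :class:`AssocRecord`.

    Rows with a missing beta, SE, p-value or N are skipped; the skip count is
    logged. Rows whose numeric fields fail to parse are skipped with a
    warning by default, or raise :class:`SumstatsFormatError` (carrying the
    line number) when ``strict`` is true. A missing required column always
    raises, naming the column.
    """
    dialect = dict(DEFAULT_DIALECT, **(dialect or {}))
    df = pd.read_csv(path, sep=r"\s+", dtype=str, comment="#")
    for logical in _REQUIRED_FIELDS:
        if dialect[logical] not in df.columns:
            raise SumstatsFormatError(
                f"{path}: required column {dialect[logical]!r} (field {logical!r}) "
                f"not found; columns present: {list(df.columns)}"
            )

    col_idx = {logical: df.columns.get_loc(dialect[logical]) for logical in _REQUIRED_FIELDS}
    records: list[AssocRecord] = []
    n_missing = 0
    n_bad = 0
    for i, row in enumerate(df.itertuples(index=False, name=None)):
        raw = {logical: row[col_idx[logical]] for logical in _REQUIRED_FIELDS}
        line_no = i + 2  # header is line 1
        if any(_is_missing(raw[k]) for k in ("beta", "se", "pvalue", "n")):
            n_missing += 1
            continue
        try:
            records.append(_parse_row(raw, line_no))
        except SumstatsFormatError:
            if strict:
                raise
            n_bad += 1
            logger.warning("%s: skipping unparsable row at line %d", path, line_no)
    if n_missing:
        logger.info("%s: skipped %d rows with missing beta/SE/p/N", path, n_missing)
    if n_bad:
        logger.warning("%s: skipped %d rows that failed validation", path, n_bad)
    return records


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and value.strip().upper() in ("", "NA", "NAN", ".")


def write_sumstats(records: Sequence[AssocRecord], path, dialect: Mapping[str, str] | None = None) -> None:
    """Write records as a tab-delimited table (round-trips to 12 s.d.)."""
    dialect = dict(DEFAULT_DIALECT, **(dialect or {}))
    df = pd.DataFrame(
        {
            dialect["snp_id"]: [r.snp_id for r in records],
            dialect["chrom"]: [r.chrom for r in records],
            dialect["pos"]: [r.pos for r in records],
            dialect["effect_allele"]: [r.effect_allele for r in records],
            dialect["other_allele"]: [r.other_allele for r in records],
            dialect["beta"]: [f"{r.beta:.12g}" for r in records],
            dialect["se"]: [f"{r.se:.12g}" for r in records],
            dialect["pvalue"]: [f"{r.pvalue:.12g}" for r in records],
            dialect["n"]: [r.n for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def filter_by_n(records: Sequence[AssocRecord], min_n: int) -> list[AssocRecord]:
    """Keep records with per-SNP sample size strictly greater than ``min_n``."""
    if min_n < 0:
        raise ValueError(f"min_n must be >= 0, got {min_n}")
    return [r for r in records if r.n > min_n]


def harmonize_pair(rec1: AssocRecord, rec2: AssocRecord) -> MergedRecord:
    """Pair two studies' records for one SNP on a common effect allele.

    If study 2 reports its effect on study 1's other allele, its beta is
    negated and its alleles swapped. Irreconcilable allele sets raise
    :class:`HarmonizationError`. Strand-ambiguous SNPs (A/T, C/G) are kept
    but flagged, since without strand information a silent flip cannot be
    excluded; the combined test is unaffected either way.
    """
    if rec1.snp_id != rec2.snp_id:
        raise ValueError(f"cannot harmonize different SNPs: {rec1.snp_id} vs {rec2.snp_id}")
    ambiguous = rec1.strand_ambiguous or rec2.strand_ambiguous
    if rec2.effect_allele == rec1.effect_allele and rec2.other_allele == rec1.other_allele:
        return MergedRecord(rec1.snp_id, rec1, rec2, sign_flipped=False, strand_ambiguous=ambiguous)
    if rec2.effect_allele == rec1.other_allele and rec2.other_allele == rec1.effect_allele:
        flipped = replace(
            rec2,
            effect_allele=rec2.other_allele,
            other_allele=rec2.effect_allele,
            beta=-rec2.beta,
        )
        return MergedRecord(rec1.snp_id, rec1, flipped, sign_flipped=True, strand_ambiguous=ambiguous)
    raise HarmonizationError(
        rec1.snp_id,
        f"allele sets irreconcilable: {rec1.effect_allele}/{rec1.other_allele} "
        f"vs {rec2.effect_allele}/{rec2.other_allele}",
    )


def chrom_sort_key(chrom: str):
    """Natural chromosome order: 1..22 numerically, then X, Y, MT, others."""
    c = str(chrom).removeprefix("chr")
    if c.isdigit():
        return (0, int(c), "")
    return (1, 0, c)


def merge_studies(
    study1: Sequence[AssocRecord],
    study2: Sequence[AssocRecord],
    min_n: int = 30_000,
) -> list[MergedRecord]:
    """Intersect two studies on SNP id, filter on N, and harmonize alleles.

    Both members of a pair must individually have n > ``min_n`` (the default
    mirrors the HapMap-representativeness filter used with GIANT files).
    Output is sorted by (chromosome, position). Zero overlap yields an empty
    list with a logged warning, not an error.
    """
    idx1 = {r.snp_id: r for r in filter_by_n(study1, min_n)}
    idx2 = {r.snp_id: r for r in filter_by_n(study2, min_n)}
    shared = idx1.keys() & idx2.keys()
    if not shared:
        logger.warning(
            "no overlapping SNPs after filtering (|study1|=%d, |study2|=%d)",
            len(study1), len(study2),
        )
        return []
    merged = [harmonize_pair(idx1[s], idx2[s]) for s in shared]
    merged.sort(key=lambda m: (chrom_sort_key(m.study1.chrom), m.study1.pos, m.snp_id))
    n_amb = sum(m.strand_ambiguous for m in merged)
    if n_amb:
        logger.info("%d of %d merged SNPs are strand-ambiguous (A/T or C/G)", n_amb, len(merged))
    return merged
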