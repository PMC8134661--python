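"""The 2-df chi-square combination test for bivariate GWAS from summary statistics.

A GWAS of a focal trait Y2 that adjusts for a heritable covariate Y1 yields
a biased genotype effect beta2* whenever the covariate is genetic and the
residuals are correlated. Rather than discarding such a scan, its z-score
can be combined with the z-score of the marginal GWAS of Y1: the two
estimators are independent (the adjusted fit conditions on Y1), so under
the joint null "G associates with neither trait"

    (beta1/se1)^2 + (beta2*/se2*)^2  ~  chi^2 with 2 df.

This turns the pair of univariate scans — exactly what consortia such as
GIANT release — into a bivariate test without individual-level data.

p-values are computed in log space (``chi2.logsf``) so statistics far past
genome-wide significance do not underflow; each result also carries
-log10(p) for reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import MergedRecord

__all__ = [
    "BtobResult",
    "btob_statistic",
    "chi2_upper_tail",
    "p_to_abs_z",
    "run_btob",
    "gc_lambda",
    "results_to_frame",
]

#: smallest subnormal double; reported when exp(logsf) underflows
_TINY = 5e-324


@dataclass(frozen=True)
class BtobResult:
    """Combined test result for one SNP.

    ``z1``/``z2`` are the per-study Wald z-scores, ``chi2 = z1^2 + z2^2`` is
    referred to a chi-square distribution with ``df`` = 2.
    """

    snp_id: str
    z1: float
    z2: float
    chi2: float
    pvalue: float
    neg_log10_p: float
    df: int = 2
    chrom: str | None = None
    pos: int | None = None
    pair: MergedRecord | None = None


def btob_statistic(beta1: float, se1: float, beta2: float, se2: float) -> float:
    """Sum of squared z-scores from the two studies: (b1/se1)^2 + (b2/se2)^2.

    Invariant to the sign of either beta, hence to allele harmonization.
    """
    if not se1 > 0:
        raise ValueError(f"se1 must be positive, got {se1}")
    if not se2 > 0:
        raise ValueError(f"se2 must be positive, got {se2}")
    return (beta1 / se1) ** 2 + (beta2 / se2) ** 2


def chi2_upper_tail(x: float, df: int = 2) -> float:
    """Upper-tail probability of chi-square(df) at ``x``.

    For df=2 this equals exp(-x/2) exactly.
    """
    if x < 0:
        raise ValueError(f"chi-square statistic must be >= 0, got {x}")
    if df < 1:
        raise ValueError(f"df must be a positive integer, got {df}")
    return float(stats.chi2.sf(x, df))


def _log_pvalue(chi2_value: float, df: int = 2) -> float:
    """Natural-log upper-tail probability; exact -x/2 for df=2."""
    if df == 2:
        return -chi2_value / 2.0
    return float(stats.chi2.logsf(chi2_value, df))


def p_to_abs_z(p: float) -> float:
    """|z| whose two-sided standard-normal p-value equals ``p``.

    Fallback entry point for files whose beta/SE are on incompatible scales
    but whose p-values are trustworthy.
    """
    if not 0 < p <= 1:
        raise ValueError(f"p-value must be in (0, 1], got {p}")
    return float(stats.norm.isf(p / 2.0))


def run_btob(
    pairs: Sequence[MergedRecord],
    mode: Literal["beta_se", "pvalue"] = "beta_se",
) -> list[BtobResult]:
    """Apply the 2-df combination test to every merged SNP pair.

    ``beta_se`` mode forms z = beta/se per study; ``pvalue`` mode inverts
    each study's two-sided p-value to |z| instead (signed by the beta). The
    two modes agree whenever the stored p equals the Wald p of beta/se.
    """
    if mode not in ("beta_se", "pvalue"):
        raise ValueError(f"unknown mode {mode!r}")
    results = []
    for m in pairs:
        try:
            if mode == "beta_se":
                z1 = m.study1.beta / m.study1.se
                z2 = m.study2.beta / m.study2.se
            else:
                z1 = math.copysign(p_to_abs_z(m.study1.pvalue), m.study1.beta)
                z2 = math.copysign(p_to_abs_z(m.study2.pvalue), m.study2.beta)
        except ValueError as exc:
            raise ValueError(f"{m.snp_id}: {exc}") from exc
        chi2 = z1 * z1 + z2 * z2
        logp = _log_pvalue(chi2, df=2)
        results.append(
            BtobResult(
                snp_id=m.snp_id,
                z1=z1,
                z2=z2,
                chi2=chi2,
                pvalue=math.exp(logp) or _TINY,
                neg_log10_p=-logp / math.log(10),
                chrom=m.study1.chrom,
                pos=m.study1.pos,
                pair=m,
            )
        )
    return results


def gc_lambda(chi2_values: Sequence[float], df: int = 1) -> float:
    """Genomic-control inflation factor: median statistic over the null median.

    The chi-square(df) median is 0.454936... for df=1 and 2*ln 2 for df=2. A
    value near 1 indicates a calibrated scan; values well above 1 indicate
    inflation (confounding or polygenicity).
    """
    values = np.asarray(chi2_values, dtype=float)
    if values.size == 0:
        raise ValueError("gc_lambda requires at least one statistic")
    if df < 1:
        raise ValueError(f"df must be a positive integer, got {df}")
    return float(np.median(values) / stats.chi2.ppf(0.5, df))


_FRAME_COLUMNS = ["snp_id", "chrom", "pos", "z1", "z2", "chi2", "df", "p_btob", "neg_log10_p"]


def results_to_frame(results: Sequence[BtobResult]) -> pd.DataFrame:
    """Tabulate results, passing through per-study beta/se/p/n when present."""
    if not results:
        return pd.DataFrame(columns=_FRAME_COLUMNS)
    rows = []
    for r in results:
        row = {
            "snp_id": r.snp_id,
            "chrom": r.chrom,
            "pos": r.pos,
            "z1": r.z1,
            "z2": r.z2,
            "chi2": r.chi2,
            "df": r.df,
            "p_btob": r.pvalue,
            "neg_log10_p": r.neg_log10_p,
        }
        if r.pair is not None:
            for k, rec in (("1", r.pair.study1), ("2", r.pair.study2)):
                row[f"beta{k}"] = rec.beta
                row[f"se{k}"] = rec.se
                row[f"p{k}"] = rec.pvalue
                row[f"n{k}"] = rec.n
            row["effect_allele"] = r.pair.study1.effect_allele
            row["other_allele"] = r.pair.study1.other_allele
            row["sign_flipped"] = r.pair.sign_flipped
            row["strand_ambiguous"] = r.pair.strand_ambiguous
        rows.append(row)
    return pd.DataFrame(rows)


def read_btob_table(path) -> list[BtobResult]:
    """Read back a table written from :func:`results_to_frame` output."""
    df = pd.read_csv(path, sep="\t")
    required = {"snp_id", "chrom", "pos", "chi2", "p_btob"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        BtobResult(
            snp_id=str(row.snp_id),
            z1=float(getattr(row, "z1", float("nan"))),
            z2=float(getattr(row, "z2", float("nan"))),
            chi2=float(row.chi2),
            pvalue=float(row.p_btob),
            neg_log10_p=float(getattr(row, "neg_log10_p", -math.log10(row.p_btob))),
            chrom=str(row.chrom),
            pos=int(row.pos),
        )
        for row in df.itertuples(index=False)
    ]
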