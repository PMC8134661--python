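"""Baseline multi-trait tests: MANOVA on the overlap sample, univariate Bonferroni.

Classical multivariate tests need individual-level data on individuals
measured for both traits, so MANOVA here deliberately uses only the overlap
sample — that restriction, against the summary-statistics test's use of the
full cohorts, is the comparison of interest.

With two responses and a single predictor the MANOVA statistics (Wilks,
Pillai, Hotelling-Lawley) coincide, and Wilks' Lambda admits an exact F
transform: for p = 2 responses and q = 1 hypothesis df,

    F = (1 - Lambda) / Lambda * (n - 3) / 2   ~   F(2, n - 3)   under H0.

Lambda is computed from the 2x2 error and total SSCP determinants; tests
cross-check against statsmodels' MANOVA and a brute-force multivariate-
normal likelihood ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ComparatorResult", "BonferroniDecision", "manova_test", "univariate_bonferroni"]


@dataclass(frozen=True)
class ComparatorResult:
    method: str
    statistic: float
    pvalue: float
    n_used: int
    wilks_lambda: float | None = None


@dataclass(frozen=True)
class BonferroniDecision:
    """Univariate testing with Bonferroni correction over the two traits."""

    method: str
    reject: bool
    min_p: float
    per_test_alpha: float


def manova_test(y1, y2, g) -> ComparatorResult:
    """Joint test of genotype against two responses via Wilks' Lambda.

    Regresses (y1, y2) on [intercept, g] and refers the exact F transform of
    Lambda to F(2, n-3). All vectors must cover the same (overlap) sample.
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    g = np.asarray(g, dtype=float)
    if not (y1.shape[0] == y2.shape[0] == g.shape[0]):
        raise ValueError("y1, y2, g must have equal length (the overlap sample)")
    n = y1.shape[0]
    if n <= 3:
        raise ValueError(f"MANOVA needs n > 3 observations, got {n}")
    gc = g - g.mean()
    gg = float(gc @ gc)
    if gg == 0.0:
        raise ValueError("genotype is constant; MANOVA statistic undefined")

    Y = np.column_stack([y1 - y1.mean(), y2 - y2.mean()])
    T = Y.T @ Y                      # total SSCP (after intercept)
    b = Y.T @ gc / gg
    H = gg * np.outer(b, b)          # hypothesis SSCP, rank 1
    E = T - H
    det_T = float(np.linalg.det(T))
    det_E = float(np.linalg.det(E))
    if det_T <= 0:
        raise ValueError("responses are collinear; Wilks' Lambda undefined")
    lam = det_E / det_T
    lam = min(max(lam, 0.0), 1.0)
    df2 = n - 3
    if lam == 0.0:
        return ComparatorResult("manova", np.inf, 5e-324, n, wilks_lambda=0.0)
    f_stat = (1.0 - lam) / lam * df2 / 2.0
    p = float(stats.f.sf(f_stat, 2, df2))
    return ComparatorResult("manova", f_stat, p or 5e-324, n, wilks_lambda=lam)


def univariate_bonferroni(p1: float, p2: float, alpha: float) -> BonferroniDecision:
    """Reject if either univariate p-value clears alpha/2.

    At the genome-wide family level alpha = 5e-8 this is the conventional
    2.5e-8 per-trait threshold.
    """
    for name, p in (("p1", p1), ("p2", p2)):
        if not 0 < p <= 1:
            raise ValueError(f"{name} must be in (0, 1], got {p}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    per_test = alpha / 2.0
    min_p = min(p1, p2)
    return BonferroniDecision(
        method="univariate_bonferroni",
        reject=min_p < per_test,
        min_p=min_p,
        per_test_alpha=per_test,
    )
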