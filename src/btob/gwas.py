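"""Per-SNP least-squares fits that generate the summary statistics.

Two single-variant regressions are supported: the marginal fit of the
covariate trait on genotype, and the adjusted fit of the focal trait on
genotype with the heritable covariate as a regressor — the model whose
genotype coefficient is biased whenever the covariate is genetic and the
residuals correlate. Both return the genotype coefficient, its
homoskedastic OLS standard error, and a Wald p-value from the standard
normal reference (GWAS-scale n makes the t/normal distinction negligible).

The solver is plain normal-equations linear algebra rather than a model
framework: these fits sit in the inner loop of Monte-Carlo power studies,
where per-call overhead dominates. Tests verify the coefficients and SEs
against statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["FitResult", "RankDeficientError", "fit_marginal", "fit_adjusted"]


class RankDeficientError(ValueError):
    """The design matrix is rank-deficient (e.g. constant genotype)."""


@dataclass(frozen=True)
class FitResult:
    beta: float
    se: float
    z: float
    pvalue: float
    n_used: int


def _ols_coef(y: np.ndarray, X: np.ndarray, index: int) -> FitResult:
    """OLS of y on X; returns coefficient ``index`` with homoskedastic SE."""
    n, k = X.shape
    if n <= k:
        raise RankDeficientError(f"n={n} observations cannot identify {k} parameters")
    xtx = X.T @ X
    # cheap conditioning check on the small Gram matrix; catches constant g
    if not np.isfinite(xtx).all() or np.linalg.cond(xtx) > 1e12:
        raise RankDeficientError("design matrix is (numerically) rank deficient")
    xty = X.T @ y
    coef = np.linalg.solve(xtx, xty)
    resid = y - X @ coef
    sigma2 = float(resid @ resid) / (n - k)
    inv_ii = float(np.linalg.inv(xtx)[index, index])
    se = float(np.sqrt(sigma2 * inv_ii))
    beta = float(coef[index])
    if se == 0.0:
        # perfect fit: degenerate limit se -> 0, p -> 0 (kept strictly positive)
        if beta == 0.0:
            return FitResult(beta=0.0, se=np.finfo(float).tiny, z=0.0, pvalue=1.0, n_used=n)
        z = np.inf if beta > 0 else -np.inf
        return FitResult(beta=beta, se=np.finfo(float).tiny, z=z, pvalue=5e-324, n_used=n)
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return FitResult(beta=beta, se=se, z=z, pvalue=p or 5e-324, n_used=n)


def _drop_missing(*arrays: np.ndarray) -> tuple[np.ndarray, ...]:
    mask = np.ones(arrays[0].shape[0], dtype=bool)
    for a in arrays:
        if a.ndim == 1:
            mask &= np.isfinite(a)
        else:
            mask &= np.isfinite(a).all(axis=1)
    return tuple(a[mask] for a in arrays)


def _as_matrix(covariates) -> np.ndarray | None:
    if covariates is None:
        return None
    c = np.asarray(covariates, dtype=float)
    return c[:, None] if c.ndim == 1 else c


def fit_marginal(y, g, covariates=None) -> FitResult:
    """OLS of the trait on [intercept, genotype, covariates].

    Individuals with any missing value are dropped listwise; ``n_used``
    reports the remainder. With an intercept only, the genotype coefficient
    equals Cov(g, y)/Var(g).
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    if y.shape[0] != g.shape[0]:
        raise ValueError(f"length mismatch: |y|={y.shape[0]}, |g|={g.shape[0]}")
    cov = _as_matrix(covariates)
    arrays = (y, g) if cov is None else (y, g, cov)
    arrays = _drop_missing(*arrays)
    y, g = arrays[0], arrays[1]
    cols = [np.ones_like(g), g]
    if cov is not None:
        cols.append(arrays[2])
    X = np.column_stack(cols)
    return _ols_coef(y, X, index=1)


def fit_adjusted(y2, g, y1, covariates=None) -> FitResult:
    """OLS of the focal trait on [intercept, genotype, covariate trait, covariates].

    The genotype coefficient is the covariate-adjusted effect — biased for
    the marginal effect when the covariate is heritable and residuals
    correlate, but exactly the quantity adjusted GWAS releases report.
    ``y1`` must be present for every individual with ``y2``.
    """
    y2 = np.asarray(y2, dtype=float)
    g = np.asarray(g, dtype=float)
    y1 = np.asarray(y1, dtype=float)
    if not (y2.shape[0] == g.shape[0] == y1.shape[0]):
        raise ValueError(
            f"length mismatch: |y2|={y2.shape[0]}, |g|={g.shape[0]}, |y1|={y1.shape[0]}"
        )
    n_missing_y1 = int((~np.isfinite(y1) & np.isfinite(y2)).sum())
    if n_missing_y1:
        raise ValueError(
            f"covariate trait missing for {n_missing_y1} individuals with focal trait values"
        )
    cov = _as_matrix(covariates)
    arrays = (y2, g, y1) if cov is None else (y2, g, y1, cov)
    arrays = _drop_missing(*arrays)
    y2, g, y1 = arrays[0], arrays[1], arrays[2]
    cols = [np.ones_like(g), g, y1]
    if cov is not None:
        cols.append(arrays[3])
    X = np.column_stack(cols)
    return _ols_coef(y2, X, index=1)
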