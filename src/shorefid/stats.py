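"""Inferential procedures: exact 2x2 tests and fractional logit regression.

Two species are compared throughout the analysis: dichotomous outcomes
(moved vs stayed, revisited vs not) with Fisher's exact test, and the
proportion of southward staging time spent at revisited sites with a
fractional (quasi-binomial logit) regression.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import statsmodels.api as sm
from scipy.special import gammaln
from scipy.stats import mannwhitneyu, norm

from .core import Contingency2x2, logger

__all__ = ["FisherResult", "FracRegResult", "fisher_exact_two_sided", "fractional_logit"]

#: Relative tolerance for the "as or less probable" comparison: tables whose
#: point probability exceeds the observed one by at most this factor still
#: count toward the two-sided p (guards against floating-point ties).
TIE_RTOL = 1e-7


@dataclass(frozen=True)
class FisherResult:
    """Two-sided exact test result with the table it was computed from."""

    p_two_sided: float
    odds_ratio: float
    table: Contingency2x2


@dataclass(frozen=True)
class FracRegResult:
    """Group-effect estimate from a fractional logit fit."""

    intercept: float
    group_coefficient: float
    se_intercept: float
    se_group: float
    p_group: float
    dispersion: float
    n: int
    separated: bool = False


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact_two_sided(table: Contingency2x2) -> FisherResult:
    """Fisher's exact test, two-sided by the probability-mass convention.

    With both margins fixed, every feasible table's hypergeometric point
    probability is computed via log-gamma; the p-value is the sum of the
    probabilities of all tables as or less probable than the observed one
    (relative tie tolerance 1e-7).  A zero row or column margin makes the
    table degenerate and returns p = 1.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1 = a + c
    n = table.total
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        logger.debug("degenerate contingency table (zero margin): p = 1")
        odds = math.nan
        return FisherResult(1.0, odds, table)
    xs = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    logp = _log_binom(r1, xs) + _log_binom(r2, c1 - xs) - _log_binom(n, c1)
    p_obs = logp[xs == a][0]
    mask = logp <= p_obs + math.log1p(TIE_RTOL)
    p = float(np.exp(logp[mask]).sum())
    p = min(1.0, p)
    odds = (a * d) / (b * c) if b * c > 0 else math.inf
    return FisherResult(p, odds, table)


def fractional_logit(y, group) -> FracRegResult:
    """Quasi-binomial logit regression of a fraction on a binary group label.

    ``y`` holds fractions in [0, 1] (exact 0 and 1 allowed); ``group`` is a
    binary indicator.  The mean model is ``logit(E[y]) = b0 + b1 * group``,
    fitted by iteratively reweighted least squares; the variance is
    ``phi * mu * (1 - mu)`` with the dispersion ``phi`` estimated by Pearson
    chi-square over residual degrees of freedom, giving robust Wald
    inference for the group effect.

    Perfect separation (one group all 0, the other all 1) has no finite MLE;
    the result is flagged and the p-value falls back to an exact rank test.
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group, dtype=float)
    if y.shape != group.shape or y.ndim != 1:
        raise ValueError("y and group must be 1-D arrays of equal length")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("y must lie in [0, 1]")
    labels = np.unique(group)
    if len(labels) != 2:
        raise ValueError("group must take exactly two values")
    g = (group == labels[1]).astype(float)
    y0, y1 = y[g == 0], y[g == 1]
    separated = (np.all(y0 == 0) and np.all(y1 == 1)) or (np.all(y0 == 1) and np.all(y1 == 0))
    if separated:
        logger.warning("perfect separation in fractional logit; "
                       "reporting an exact rank-test p-value instead")
        p = float(mannwhitneyu(y0, y1, alternative="two-sided", method="exact").pvalue)
        sign = 1.0 if y1.mean() > y0.mean() else -1.0
        return FracRegResult(
            intercept=math.nan, group_coefficient=sign * math.inf,
            se_intercept=math.nan, se_group=math.nan, p_group=p,
            dispersion=math.nan, n=len(y), separated=True,
        )
    X = sm.add_constant(g)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")   # statsmodels warns about non-integer binomial y
        model = sm.GLM(y, X, family=sm.families.Binomial())
        fit = model.fit(tol=1e-8, maxiter=100)
    params = np.asarray(fit.params)
    # quasi-binomial dispersion by Pearson chi-square / df; the point
    # estimates are scale-free, so it only inflates the standard errors.
    # (A perfectly fitted response gives phi = 0 and an undefined Wald test.)
    phi = float(fit.pearson_chi2) / fit.df_resid if fit.df_resid > 0 else float("nan")
    bse = np.asarray(fit.bse) * math.sqrt(phi) if phi > 0 else np.full(2, float("nan"))
    if phi > 0:
        z = params[1] / bse[1]
        p_group = float(2.0 * norm.sf(abs(z)))
    else:
        p_group = float("nan")
    return FracRegResult(
        intercept=float(params[0]), group_coefficient=float(params[1]),
        se_intercept=float(bse[0]), se_group=float(bse[1]),
        p_group=p_group, dispersion=phi, n=len(y),
    )
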