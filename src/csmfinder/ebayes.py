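"""Empirical-Bayes beta-binomial layer.

For a region r and cell i with c_ri CpG sites, the methylated count at
site j is m_jri ~ Binomial(n_jri, theta_ri) with a shared latent
methylation probability theta_ri ~ Beta(alpha_ri, beta_ri).  By
conjugacy the posterior is

    theta_ri | data ~ Beta(sum_j m_jri + alpha_ri,
                           sum_j n_jri - sum_j m_jri + beta_ri).

The prior is estimated per region-cell by the method of moments on the
site-level observed levels e_jri = m_jri / n_jri: with the weighted mean
mu = sum n_j e_j / sum n_j and weighted variance s2 = sum n_j (e_j -
mu)^2 / sum n_j, the precision M = alpha + beta is

    M_hat = (mu (1 - mu) - s2) / (s2 - mu (1 - mu) * correction)

where the correction term is the mean reciprocal site depth
mean_j(1 / n_j): the CpG sites within the region-cell act as the
replicate groups of the binomial moment estimator.  A pooled variant
(correction averaged over the cells of the region, using each cell's
total count) is available via ``pooled_term``.  Whenever M_hat is
negative, zero or non-finite — e.g. a single site, or identical levels
at every site — the prior falls back to the flat Beta(1, 1).  Sites
with no data contribute zero methylated and zero total counts, i.e.
drop out of every sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import SiteCount


@dataclass(frozen=True)
class BetaPrior:
    """Per region-cell beta prior with its moment-estimation byproducts."""

    alpha: float
    beta: float
    mu: float  # weighted mean level; NaN when no data
    precision: float  # M_hat; NaN when the moment estimate is invalid
    s2: float
    site_levels: tuple[float, ...]
    valid: bool  # False -> flat Beta(1,1) fallback
    no_data: bool = False


@dataclass(frozen=True)
class PosteriorBeta:
    """Conjugate posterior Beta(a, b) of a region-cell methylation probability."""

    a: float
    b: float

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def var(self) -> float:
        s = self.a + self.b
        return self.a * self.b / (s * s * (s + 1.0))


FLAT = (1.0, 1.0)


def estimate_prior(
    sites: Sequence[SiteCount], pooled_term: float | None = None
) -> BetaPrior:
    """Method-of-moments beta prior for one region-cell.

    ``pooled_term`` overrides the correction term of the precision
    estimator with a region-level average of reciprocal per-cell totals
    (the pooled reading of the printed estimator); by default the
    correction is the mean reciprocal site depth of this cell.
    """
    observed = [(s.meth, s.total) for s in sites if s.total > 0]
    if not observed:
        return BetaPrior(*FLAT, math.nan, math.nan, math.nan, (), False, no_data=True)
    m = np.array([x[0] for x in observed], dtype=float)
    n = np.array([x[1] for x in observed], dtype=float)
    return estimate_prior_arrays(m, n, pooled_term=pooled_term)


def estimate_prior_arrays(
    m: np.ndarray, n: np.ndarray, pooled_term: float | None = None
) -> BetaPrior:
    """Array-level moment estimation; ``m``/``n`` must exclude zero-depth sites."""
    if m.size == 0:
        return BetaPrior(*FLAT, math.nan, math.nan, math.nan, (), False, no_data=True)
    e = m / n
    n_sum = n.sum()
    mu = float(m.sum() / n_sum)
    s2 = float((n * (e - mu) ** 2).sum() / n_sum)
    correction = float(np.mean(1.0 / n)) if pooled_term is None else pooled_term
    v = mu * (1.0 - mu)
    denom = s2 - v * correction
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = (v - s2) / denom if denom != 0.0 else math.nan
    if not math.isfinite(precision) or precision <= 0.0:
        return BetaPrior(*FLAT, mu, math.nan, s2, tuple(e), False)
    alpha = mu * precision
    beta = (1.0 - mu) * precision
    if alpha <= 0.0 or beta <= 0.0:  # mu at 0 or 1 with a finite precision
        return BetaPrior(*FLAT, mu, math.nan, s2, tuple(e), False)
    return BetaPrior(alpha, beta, mu, float(precision), s2, tuple(e), True)


def estimate_region_prior(cell_sites: Sequence[Sequence[SiteCount]]) -> BetaPrior:
    """Region-level moment prior with cells as the replicate groups.

    The same moment machinery, applied to the cell-level methylation
    fractions e_i = sum_j m_ji / sum_j n_ji weighted by the per-cell
    totals T_i = sum_j n_ji (the precision correction term becomes
    mean_i(1 / T_i), i.e. the across-cell sum of the printed
    estimator).  One shared (alpha, beta) results for every cell of the
    region; cells without data are excluded.  This is the default prior
    scope: a prior estimated per cell from that same cell's handful of
    sites re-enters the mixture likelihood as if it were independent
    information and overstates between-cell differences.
    """
    m = []
    n = []
    for sites in cell_sites:
        total = sum(s.total for s in sites)
        if total > 0:
            m.append(sum(s.meth for s in sites))
            n.append(total)
    return estimate_prior_arrays(np.array(m, dtype=float), np.array(n, dtype=float))


def pooled_precision_term(cell_sites: Sequence[Sequence[SiteCount]]) -> float:
    """Region-level correction term: (1/N) * sum_i 1 / (sum_j n_jri).

    Cells with no observed counts are excluded from the average.
    """
    totals = [
        sum(s.total for s in sites)
        for sites in cell_sites
        if any(s.total > 0 for s in sites)
    ]
    if not totals:
        return math.nan
    return float(np.mean([1.0 / t for t in totals]))


def posterior(prior: BetaPrior, sites: Sequence[SiteCount]) -> PosteriorBeta:
    """Conjugate update: Beta(sum m + alpha, sum n - sum m + beta)."""
    meth = sum(s.meth for s in sites)
    total = sum(s.total for s in sites)
    return PosteriorBeta(meth + prior.alpha, total - meth + prior.beta)
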