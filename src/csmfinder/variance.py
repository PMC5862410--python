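"""Cell-to-cell methylation variance via a random-effects model.

Each cell i in region r supplies a posterior mean theta_ri and posterior
variance V_ri of its methylation probability (the conjugate beta
posterior moments).  The observed theta_ri are modelled as the abstract
region-level probability mu_r plus a between-cell deviation with
variance Delta^2_r plus within-cell noise with variance V_ri.  The
between-cell variance is estimated by the non-iterative
DerSimonian-Laird moment estimator (truncated at zero); mu_r is the
weighted mean with weights w*_ri = 1 / (V_ri + Delta^2_r), and the
region's methylation variance is V_r = 1 / sum_i w*_ri, with a 95%
percentile bootstrap confidence interval from resampling cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .ebayes import PosteriorBeta


@dataclass
class VarianceFit:
    """Random-effects fit for one region."""

    mu: float  # weighted mean methylation probability
    delta2: float  # between-cell variance, truncated at 0
    weights: np.ndarray  # w*_i = 1 / (V_i + delta2)
    v_hat: float  # 1 / sum(w*)
    n_cells: int
    ci95: tuple[float, float] | None = None

    @property
    def defined(self) -> bool:
        return self.n_cells >= 2


class RandomEffectsVariance(BaseEstimator):
    """DerSimonian-Laird random-effects estimator over cells.

    ``fit`` expects ``X`` of shape (n_cells, 2) holding per-cell
    posterior means and variances [theta_i, V_i].  Fitted attributes:
    ``mu_``, ``delta2_``, ``weights_``, ``v_hat_``.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have shape (n_cells, 2): [theta, V]")
        theta, V = X[:, 0], X[:, 1]
        if X.shape[0] < 2:
            raise ValueError("need >= 2 cells")
        if np.any(V <= 0):
            raise ValueError("posterior variances must be positive")
        self.delta2_ = _dersimonian_laird(theta, V)
        self.weights_ = 1.0 / (V + self.delta2_)
        wsum = self.weights_.sum()
        self.mu_ = float((self.weights_ * theta).sum() / wsum)
        self.v_hat_ = float(1.0 / wsum)
        self.n_cells_ = X.shape[0]
        return self

    def score(self, X=None, y=None):
        check_is_fitted(self, "v_hat_")
        return -self.v_hat_


def _dersimonian_laird(theta: np.ndarray, V: np.ndarray) -> float:
    w = 1.0 / V
    wsum = w.sum()
    mu_fixed = (w * theta).sum() / wsum
    q = (w * (theta - mu_fixed) ** 2).sum()
    df = theta.size - 1
    c = wsum - (w**2).sum() / wsum
    if c <= 0:
        return 0.0
    return float(max(0.0, (q - df) / c))


def variance_fit(
    posteriors: Sequence[PosteriorBeta] | np.ndarray,
    delta2: float | None = None,
) -> VarianceFit:
    """Fit the random-effects variance for one region.

    ``posteriors`` is either a sequence of per-cell conjugate posteriors
    or an (n_cells, 2) array of [theta_i, V_i].  Fewer than 2 cells
    yields an undefined-variance sentinel (NaN fields).  ``delta2``
    forces the between-cell variance (e.g. 0 for the fixed-effect,
    inverse-variance limit).
    """
    X = _as_theta_v(posteriors)
    if X.shape[0] < 2:
        return VarianceFit(math.nan, math.nan, np.array([]), math.nan, X.shape[0])
    theta, V = X[:, 0], X[:, 1]
    d2 = _dersimonian_laird(theta, V) if delta2 is None else float(delta2)
    w = 1.0 / (V + d2)
    wsum = w.sum()
    return VarianceFit(
        mu=float((w * theta).sum() / wsum),
        delta2=d2,
        weights=w,
        v_hat=float(1.0 / wsum),
        n_cells=X.shape[0],
    )


def variance_ci(
    posteriors: Sequence[PosteriorBeta] | np.ndarray,
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """95% percentile bootstrap CI of V_r (resampling cells, refitting).

    Deterministic for a given ``seed``.
    """
    X = _as_theta_v(posteriors)
    n = X.shape[0]
    if n < 2:
        return (math.nan, math.nan)
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        stats[b] = variance_fit(X[idx]).v_hat
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return (float(lo), float(hi))


def _as_theta_v(posteriors) -> np.ndarray:
    if isinstance(posteriors, np.ndarray):
        return np.atleast_2d(posteriors.astype(float))
    return np.array([[p.mean, p.var] for p in posteriors], dtype=float)
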