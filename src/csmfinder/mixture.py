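"""Two-state beta mixture model over cells within a region.

Each cell i contributes aggregate counts (sum_j m_ji, sum_j n_ji) and an
empirical-Bayes prior (alpha_i, beta_i), giving the posterior
Beta(a_i, b_i) with a_i = sum m + alpha_i and b_i = sum n - sum m +
beta_i.  Cells are assumed to come from K=2 latent methylation states
with state probabilities theta^(1) >= theta^(2) and mixing proportions
lambda_k; the likelihood of cell i under state k is the cell's posterior
beta density evaluated at theta^(k):

    Pr(i | theta) = theta^(a_i - 1) (1 - theta)^(b_i - 1) / B(a_i, b_i).

The EM algorithm iterates the usual responsibilities (E-step) with the
closed-form M-step

    lambda_k = mean_i gamma_ik
    theta^(k) = sum_i gamma_ik (a_i - 1) / sum_i gamma_ik (a_i + b_i - 2),

clamped to [eps, 1 - eps].  A likelihood-ratio test against the
one-state null (single theta maximizing the same per-cell likelihood)
yields a p-value from chi2 with 2 df by default (3 free parameters vs
1); mixture LRT regularity fails at the boundary, so the chi-square
reference is a convention — a parametric bootstrap is available.
P-values are BH-adjusted across regions, and a region is called CSM iff
the adjusted p is significant, theta^(1)-theta^(2) exceeds the cutoff
(0.3, set by simulation), and data come from at least 8 cells.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import betaln, logsumexp
from scipy.stats import chi2
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from .ebayes import BetaPrior
from .io import RegionCellData

EPS = 1e-6


@dataclass
class MixtureFit:
    """Fitted two-state mixture for one region."""

    region_id: str
    lam: np.ndarray  # state proportions, ordered with theta
    theta: np.ndarray  # state methylation probabilities, theta[0] >= theta[1]
    membership: np.ndarray  # (n_cells, 2) posterior state probabilities
    cell_ids: list[str]
    loglik: float
    loglik_null: float
    p_value: float
    theta_diff: float
    n_cells_with_data: int
    observed_diff: float  # mean posterior level of state-1 cells minus state-2 cells
    converged: bool
    degenerate: bool
    p_adjusted: float | None = None
    n_iter: int = 0

    @property
    def statistic(self) -> float:
        return 2.0 * (self.loglik - self.loglik_null)


@dataclass
class CSMCall:
    """Calling decision for one region with the criteria it failed."""

    region_id: str
    is_csm: bool
    theta_diff: float
    p_adjusted: float
    n_cells: int
    reasons: list[str] = field(default_factory=list)


class BetaBinomialMixture(BaseEstimator):
    """Two-state empirical-Bayes beta-binomial mixture fitted by EM.

    Parameters
    ----------
    n_states:
        Number of latent methylation states (the model targets the
        bimodal case; only 2 is supported).
    n_init:
        Number of EM initializations.  The first splits cells at the
        median posterior mean, the second starts at the one-state
        optimum (guaranteeing loglik >= null loglik), the rest draw
        memberships uniformly at random.
    tol, max_iter:
        EM convergence tolerance on the log-likelihood and iteration cap.
    random_state:
        Seed for the random initializations.

    Attributes (after ``fit``)
    --------------------------
    weights_ : ndarray (2,) -- mixing proportions, ordered with thetas_.
    thetas_ : ndarray (2,) -- state methylation probabilities, descending.
    membership_ : ndarray (n_cells, 2) -- responsibilities.
    log_likelihood_, null_log_likelihood_, p_value_ : floats.
    converged_, degenerate_ : bool flags.
    """

    def __init__(
        self,
        n_states: int = 2,
        n_init: int = 10,
        tol: float = 1e-6,
        max_iter: int = 500,
        random_state: int | None = None,
    ):
        self.n_states = n_states
        self.n_init = n_init
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None, priors=None):
        """Fit the mixture.

        Parameters
        ----------
        X : array-like (n_cells, 2)
            Aggregate [methylated, total] counts per cell.
        priors : array-like (n_cells, 2), optional
            Per-cell beta prior (alpha, beta); defaults to the flat
            Beta(1, 1).
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have shape (n_cells, 2): [meth, total]")
        if self.n_states != 2:
            raise ValueError("only the two-state model is supported")
        n_cells = X.shape[0]
        if n_cells < 2:
            raise ValueError("need at least 2 cells with data")
        if np.any(X[:, 0] > X[:, 1]) or np.any(X < 0):
            raise ValueError("need 0 <= meth <= total")
        if priors is None:
            priors = np.ones((n_cells, 2))
        priors = np.asarray(priors, dtype=float)

        a = X[:, 0] + priors[:, 0]
        b = X[:, 1] - X[:, 0] + priors[:, 1]
        a1 = a - 1.0
        b1 = b - 1.0
        const = -betaln(a, b)  # per-cell, state-independent

        theta0, ll_null = _null_fit(a1, b1, const)
        rng = np.random.default_rng(self.random_state)

        best = None
        n_inits = max(2, self.n_init)
        for init in range(n_inits):
            gamma = self._initial_membership(init, a, b, n_cells, theta0, rng)
            result = _em(a1, b1, const, gamma, self.tol, self.max_iter)
            if best is None or result[2] > best[2]:
                best = result
        lam, theta, ll, gamma, n_iter, converged, history = best

        order = np.argsort(-theta)  # theta[0] >= theta[1]
        self.weights_ = lam[order]
        self.thetas_ = theta[order]
        self.membership_ = gamma[:, order]
        self.log_likelihood_ = ll
        self.null_log_likelihood_ = ll_null
        self.null_theta_ = theta0
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.loglik_history_ = history
        self.degenerate_ = bool(np.min(self.membership_.sum(axis=0)) < EPS)
        stat = 2.0 * (ll - ll_null)
        if stat < -1e-8:
            raise RuntimeError(
                f"negative LRT statistic {stat:.3g}: EM did not converge"
            )
        self.p_value_ = lrt_pvalue(max(stat, 0.0))
        self.posterior_means_ = a / (a + b)
        return self

    def _initial_membership(self, init, a, b, n_cells, theta0, rng):
        gamma = np.full((n_cells, 2), 0.5)
        if init == 0:  # split cells at the median posterior mean
            means = a / (a + b)
            hi = means >= np.median(means)
            gamma = np.column_stack([hi, ~hi]).astype(float)
            if hi.all() or not hi.any():
                gamma = np.full((n_cells, 2), 0.5)
        elif init == 1:  # one-state optimum: EM fixed point at the null
            return gamma
        else:
            g = rng.uniform(size=n_cells)
            gamma = np.column_stack([g, 1.0 - g])
        return gamma

    def predict_proba(self, X=None):
        """Posterior state membership probabilities of the fitted cells."""
        check_is_fitted(self, "membership_")
        return self.membership_

    def predict(self, X=None):
        """Hard state labels (0 = hyper-methylated state, 1 = hypo).

        Ties go to the hyper-methylated state (Pr equal -> state 0).
        """
        check_is_fitted(self, "membership_")
        return (self.membership_[:, 0] < self.membership_[:, 1]).astype(int)

    def score(self, X=None, y=None):
        check_is_fitted(self, "log_likelihood_")
        return self.log_likelihood_


def _cell_loglik(theta: np.ndarray, a1, b1, const) -> np.ndarray:
    """(n_cells, K) log posterior-density of each cell at each state value."""
    t = np.clip(theta, EPS, 1.0 - EPS)
    return (
        a1[:, None] * np.log(t)[None, :]
        + b1[:, None] * np.log1p(-t)[None, :]
        + const[:, None]
    )


def _null_fit(a1, b1, const) -> tuple[float, float]:
    denom = (a1 + b1).sum()
    theta0 = a1.sum() / denom if denom > 0 else 0.5
    theta0 = float(np.clip(theta0, EPS, 1.0 - EPS))
    ll = float(_cell_loglik(np.array([theta0]), a1, b1, const).sum())
    return theta0, ll


def _em(a1, b1, const, gamma, tol, max_iter):
    lam = gamma.mean(axis=0)
    theta = _m_step_theta(gamma, a1, b1)
    prev_ll = -np.inf
    ll = -np.inf
    converged = False
    it = 0
    history = []
    for it in range(1, max_iter + 1):
        # E-step
        log_w = np.log(np.clip(lam, EPS, None))[None, :] + _cell_loglik(
            theta, a1, b1, const
        )
        norm = logsumexp(log_w, axis=1)
        gamma = np.exp(log_w - norm[:, None])
        ll = float(norm.sum())
        history.append(ll)
        # M-step
        lam = gamma.mean(axis=0)
        theta = _m_step_theta(gamma, a1, b1)
        if abs(ll - prev_ll) < tol:
            converged = True
            break
        prev_ll = ll
    return lam, theta, ll, gamma, it, converged, history


def _m_step_theta(gamma, a1, b1):
    num = gamma.T @ a1
    den = gamma.T @ (a1 + b1)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.5)
    return np.clip(theta, EPS, 1.0 - EPS)


def lrt_pvalue(statistic: float, df: int = 2) -> float:
    """Chi-square tail p-value for the two-state vs one-state LRT."""
    return float(chi2.sf(statistic, df))


def parametric_bootstrap_pvalue(
    X,
    priors,
    statistic: float,
    n_boot: int = 200,
    random_state: int | None = None,
) -> float:
    """Bootstrap LRT reference: simulate counts under the fitted null.

    Totals and priors are held fixed; methylated counts are redrawn as
    Binomial(total_i, theta0) and both models refitted.
    """
    X = np.asarray(X, dtype=float)
    priors = np.asarray(priors, dtype=float)
    a = X[:, 0] + priors[:, 0]
    b = X[:, 1] - X[:, 0] + priors[:, 1]
    theta0, _ = _null_fit(a - 1.0, b - 1.0, -betaln(a, b))
    rng = np.random.default_rng(random_state)
    exceed = 0
    for bi in range(n_boot):
        meth = rng.binomial(X[:, 1].astype(int), theta0)
        model = BetaBinomialMixture(n_init=3, random_state=int(rng.integers(2**31)))
        model.fit(np.column_stack([meth, X[:, 1]]), priors=priors)
        if model.log_likelihood_ - model.null_log_likelihood_ >= statistic / 2.0:
            exceed += 1
    return (1 + exceed) / (n_boot + 1)


def fit_mixture(
    region_id: str,
    cells: dict[str, RegionCellData],
    priors: dict[str, BetaPrior],
    n_init: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | None = None,
) -> MixtureFit:
    """Fit the two-state mixture for one region from per-cell site counts.

    Cells with no observed counts are dropped (they carry no likelihood).
    The per-region random seed is derived from ``seed`` and a stable hash
    of ``region_id`` so that fits are reproducible region by region.
    """
    cell_ids = sorted(c for c in cells if cells[c].total_sum > 0)
    if len(cell_ids) < 2:
        raise ValueError(f"{region_id}: need >=2 cells with data")
    X = np.array(
        [[cells[c].meth_sum, cells[c].total_sum] for c in cell_ids], dtype=float
    )
    P = np.array(
        [[priors[c].alpha, priors[c].beta] for c in cell_ids], dtype=float
    )
    region_seed = None
    if seed is not None:
        # stable across processes (builtin str hash is salted per run)
        region_seed = (seed + zlib.crc32(region_id.encode())) % (2**31)
    model = BetaBinomialMixture(
        n_init=n_init, tol=tol, max_iter=max_iter, random_state=region_seed
    )
    model.fit(X, priors=P)
    labels = model.predict()
    means = model.posterior_means_
    obs_diff = float(
        means[labels == 0].mean() - means[labels == 1].mean()
        if (labels == 0).any() and (labels == 1).any()
        else 0.0
    )
    return MixtureFit(
        region_id=region_id,
        lam=model.weights_,
        theta=model.thetas_,
        membership=model.membership_,
        cell_ids=cell_ids,
        loglik=model.log_likelihood_,
        loglik_null=model.null_log_likelihood_,
        p_value=model.p_value_,
        theta_diff=float(model.thetas_[0] - model.thetas_[1]),
        n_cells_with_data=len(cell_ids),
        observed_diff=obs_diff,
        converged=model.converged_,
        degenerate=model.degenerate_,
        n_iter=model.n_iter_,
    )


def assign_membership(fit: MixtureFit) -> np.ndarray:
    """Hard state labels per cell: 1 if Pr(Y=1) >= Pr(Y=2), else 2."""
    return np.where(fit.membership[:, 0] >= fit.membership[:, 1], 1, 2)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_csm(
    fits: Sequence[MixtureFit],
    theta_diff_cutoff: float = 0.3,
    min_cells_call: int = 8,
    alpha: float = 0.05,
    delta_min: float | None = None,
) -> list[CSMCall]:
    """CSM calls after BH adjustment across the full region set.

    A region is CSM iff adjusted p < ``alpha``, theta difference >=
    ``theta_diff_cutoff`` and >= ``min_cells_call`` cells carry data.
    ``delta_min`` optionally also screens the observed (posterior-mean)
    methylation difference between the two assigned groups; it is
    reported but not applied unless set.
    """
    adjusted = bh_adjust([f.p_value for f in fits])
    calls = []
    for fit, p_adj in zip(fits, adjusted):
        fit.p_adjusted = float(p_adj)
        reasons = []
        if not p_adj < alpha:
            reasons.append("p_adjusted")
        if not fit.theta_diff >= theta_diff_cutoff:
            reasons.append("theta_diff")
        if not fit.n_cells_with_data >= min_cells_call:
            reasons.append("n_cells")
        if delta_min is not None and not fit.observed_diff >= delta_min:
            reasons.append("delta_min")
        calls.append(
            CSMCall(
                region_id=fit.region_id,
                is_csm=not reasons,
                theta_diff=fit.theta_diff,
                p_adjusted=float(p_adj),
                n_cells=fit.n_cells_with_data,
                reasons=reasons,
            )
        )
    return calls
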