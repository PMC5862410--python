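import numpy as np
import pytest
from scipy.special import betaln, logsumexp
from scipy.stats import chi2

from csmfinder.ebayes import BetaPrior
from csmfinder.io import GenomicInterval, RegionCellData, SiteCount
from csmfinder.mixture import (
    BetaBinomialMixture,
    MixtureFit,
    assign_membership,
    bh_adjust,
    call_csm,
    fit_mixture,
)

FLAT = np.ones((0, 2))


def flat_priors(n):
    return np.ones((n, 2))


def mixture_loglik_grid(X, priors, n_grid=200, n_lam_iter=40):
    """Independent grid-search maximizer of the mixture likelihood.

    Evaluates every (theta1, theta2) pair on an n_grid x n_grid lattice,
    profiling lambda by fixed-point iteration (the lambda update is the
    EM E/M step with thetas held fixed, which converges to the
    conditional maximizer).
    """
    a = X[:, 0] + priors[:, 0]
    b = X[:, 1] - X[:, 0] + priors[:, 1]
    a1, b1 = a - 1.0, b - 1.0
    const = -betaln(a, b)
    grid = (np.arange(n_grid) + 0.5) / n_grid
    # (n_grid, n_cells) log density of each cell at each theta
    L = (
        a1[None, :] * np.log(grid)[:, None]
        + b1[None, :] * np.log1p(-grid)[:, None]
        + const[None, :]
    )
    best = (-np.inf, None)
    for i in range(n_grid):
        l1 = L[i]  # theta1 value
        # vectorize over theta2 choices
        lam = np.full(n_grid, 0.5)
        for _ in range(n_lam_iter):
            w1 = np.log(lam)[:, None] + l1[None, :]
            w2 = np.log1p(-lam)[:, None] + L
            norm = np.logaddexp(w1, w2)
            gamma1 = np.exp(w1 - norm)
            lam = np.clip(gamma1.mean(axis=1), 1e-9, 1 - 1e-9)
        ll = norm.sum(axis=1)
        j = int(np.argmax(ll))
        if ll[j] > best[0]:
            best = (float(ll[j]), (float(grid[i]), float(grid[j]), float(lam[j])))
    return best


def simulate_counts(rng, n_cells=20, lam=0.5, theta=(0.9, 0.1), depth=20, sites=4):
    states = (rng.uniform(size=n_cells) >= lam).astype(int)
    t = np.where(states == 0, theta[0], theta[1])
    totals = rng.poisson(depth, size=(n_cells, sites))
    meths = rng.binomial(totals, t[:, None])
    return np.column_stack([meths.sum(1), totals.sum(1)]).astype(float), states


class TestEMFit:
    def test_recovers_planted_parameters_and_matches_grid_oracle(self):
        rng = np.random.default_rng(21)
        X, states = simulate_counts(rng)
        priors = flat_priors(20)
        model = BetaBinomialMixture(n_init=10, random_state=0).fit(X, priors=priors)
        lam_true = float((states == 0).mean())
        assert abs(model.weights_[0] - lam_true) < 1e-2
        assert abs(model.thetas_[0] - 0.9) < 2e-2
        assert abs(model.thetas_[1] - 0.1) < 2e-2
        ll_grid, (t1g, t2g, _) = mixture_loglik_grid(X, priors)
        t1g, t2g = max(t1g, t2g), min(t1g, t2g)  # likelihood is label-symmetric
        assert model.log_likelihood_ >= ll_grid - 1e-6
        assert abs(model.thetas_[0] - t1g) <= 1e-2
        assert abs(model.thetas_[1] - t2g) <= 1e-2

    def test_identical_cells_collapse_to_common_mode(self):
        X = np.tile([10.0, 20.0], (6, 1))
        model = BetaBinomialMixture(random_state=0).fit(X, priors=flat_priors(6))
        assert abs(model.thetas_[0] - model.thetas_[1]) < 1e-6
        assert model.thetas_[0] == pytest.approx(0.5, abs=1e-6)

    def test_perfect_split_membership_recovered_by_both_labelings(self):
        X = np.array([[20.0, 20.0]] * 5 + [[0.0, 20.0]] * 5)
        priors = flat_priors(10)
        model = BetaBinomialMixture(random_state=0).fit(X, priors=priors)
        proba = model.predict_proba()
        assert (proba[:5, 0] > 0.99).all()
        assert (proba[5:, 1] > 0.99).all()
        # enumeration oracle: the correct labeling beats the swapped one
        a1 = X[:, 0] + priors[:, 0] - 1
        b1 = X[:, 1] - X[:, 0] + priors[:, 1] - 1
        const = -betaln(a1 + 1, b1 + 1)

        def assigned_ll(theta_by_cell):
            t = np.array(theta_by_cell)
            return float(
                (a1 * np.log(t) + b1 * np.log1p(-t) + const).sum()
                + 10 * np.log(0.5)
            )

        t1, t2 = model.thetas_
        good = assigned_ll([t1] * 5 + [t2] * 5)
        swapped = assigned_ll([t2] * 5 + [t1] * 5)
        assert good > swapped

    def test_loglik_never_decreases_across_iterations(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            X, _ = simulate_counts(rng, lam=float(rng.uniform(0.2, 0.8)))
            model = BetaBinomialMixture(n_init=3, random_state=1).fit(
                X, priors=flat_priors(len(X))
            )
            history = np.array(model.loglik_history_)
            assert (np.diff(history) >= -1e-8).all()

    def test_mixture_loglik_at_least_null(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            X, _ = simulate_counts(rng, theta=(0.5, 0.5))
            model = BetaBinomialMixture(n_init=2, random_state=2).fit(
                X, priors=flat_priors(len(X))
            )
            assert model.log_likelihood_ >= model.null_log_likelihood_ - 1e-8

    def test_label_order_is_theta_descending(self):
        rng = np.random.default_rng(7)
        X, _ = simulate_counts(rng)
        model = BetaBinomialMixture(random_state=3).fit(X, priors=flat_priors(len(X)))
        assert model.thetas_[0] >= model.thetas_[1]

    def test_requires_two_cells(self):
        with pytest.raises(ValueError, match="2 cells"):
            BetaBinomialMixture().fit(np.array([[1.0, 2.0]]))

    def test_sklearn_param_interface(self):
        model = BetaBinomialMixture(n_init=3, tol=1e-5)
        assert model.get_params()["n_init"] == 3
        model.set_params(max_iter=123)
        assert model.max_iter == 123


class TestLRT:
    def test_identical_cells_give_statistic_zero_and_p_one(self):
        X = np.tile([10.0, 20.0], (8, 1))
        model = BetaBinomialMixture(random_state=0).fit(X, priors=flat_priors(8))
        stat = 2 * (model.log_likelihood_ - model.null_log_likelihood_)
        assert stat == pytest.approx(0.0, abs=1e-6)
        assert model.p_value_ == pytest.approx(1.0, abs=1e-6)

    def test_bimodal_region_is_overwhelmingly_significant(self):
        rng = np.random.default_rng(8)
        X, _ = simulate_counts(rng, theta=(0.95, 0.05))
        model = BetaBinomialMixture(random_state=0).fit(X, priors=flat_priors(len(X)))
        stat = 2 * (model.log_likelihood_ - model.null_log_likelihood_)
        assert model.p_value_ < 1e-6
        assert model.p_value_ == pytest.approx(float(chi2.sf(stat, 2)))


class TestBH:
    def test_closed_form_triplet(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_matches_textbook_step_up_oracle(self):
        def oracle(p):
            p = np.asarray(p, dtype=float)
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                idx = order[rank - 1]
                running = min(running, p[idx] * m / rank)
                adj[idx] = running
            return adj

        rng = np.random.default_rng(9)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 40))
            assert bh_adjust(p) == pytest.approx(oracle(p))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def make_fit(region_id="r", p=0.001, diff=0.6, n_cells=10):
    membership = np.tile([0.9, 0.1], (n_cells, 1))
    return MixtureFit(
        region_id=region_id,
        lam=np.array([0.5, 0.5]),
        theta=np.array([0.7, 0.7 - diff]),
        membership=membership,
        cell_ids=[f"c{i}" for i in range(n_cells)],
        loglik=0.0,
        loglik_null=-5.0,
        p_value=p,
        theta_diff=diff,
        n_cells_with_data=n_cells,
        observed_diff=diff,
        converged=True,
        degenerate=False,
    )


class TestMembershipAndCalling:
    def test_tie_goes_to_state_one(self):
        fit = make_fit()
        fit.membership = np.array([[0.5, 0.5], [0.2, 0.8], [1.0, 0.0]])
        assert assign_membership(fit).tolist() == [1, 2, 1]

    def test_call_requires_all_three_criteria(self):
        fits = [
            make_fit("below_diff", p=1e-4, diff=0.25, n_cells=10),
            make_fit("too_few_cells", p=1e-4, diff=0.6, n_cells=7),
            make_fit("weak_p", p=0.9, diff=0.6, n_cells=10),
            make_fit("good", p=1e-4, diff=0.6, n_cells=10),
        ]
        calls = {c.region_id: c for c in call_csm(fits)}
        assert not calls["below_diff"].is_csm
        assert calls["below_diff"].reasons == ["theta_diff"]
        assert not calls["too_few_cells"].is_csm
        assert calls["too_few_cells"].reasons == ["n_cells"]
        assert not calls["weak_p"].is_csm
        assert "p_adjusted" in calls["weak_p"].reasons
        assert calls["good"].is_csm

    def test_bh_applied_across_full_region_set(self):
        fits = [make_fit(f"r{i}", p=0.04) for i in range(10)]
        calls = call_csm(fits)
        # ten tied p-values of 0.04 stay at 0.04 after BH -> significant
        assert all(c.p_adjusted == pytest.approx(0.04) for c in calls)
        fits = [make_fit(f"r{i}", p=0.01 * (i + 1)) for i in range(10)]
        calls = call_csm(fits)
        assert calls[-1].p_adjusted == pytest.approx(0.1)

    def test_delta_min_screen_optional(self):
        fit = make_fit(p=1e-4, diff=0.6)
        fit.observed_diff = 0.2
        assert call_csm([fit])[0].is_csm
        assert not call_csm([fit], delta_min=0.4)[0].is_csm


class TestFitMixtureWrapper:
    def test_region_fit_from_site_counts(self):
        region = GenomicInterval("chr1", 0, 100)
        cells = {}
        priors = {}
        for i in range(10):
            m = 5 if i < 5 else 0
            cells[f"c{i}"] = RegionCellData(
                region, f"c{i}", [SiteCount(j * 10, m, 5) for j in range(4)]
            )
            priors[f"c{i}"] = BetaPrior(1.0, 1.0, 0.5, 2.0, 0.1, (), True)
        fit = fit_mixture("chr1:0-100", cells, priors, seed=0)
        assert fit.theta_diff > 0.9
        assert fit.n_cells_with_data == 10
        assert fit.p_value < 1e-6
        labels = assign_membership(fit)
        assert set(labels[:5]) == {1} and set(labels[5:]) == {2}

    def test_seeded_fit_is_reproducible(self):
        region = GenomicInterval("chr1", 0, 100)
        rng = np.random.default_rng(2)
        cells = {
            f"c{i}": RegionCellData(
                region,
                f"c{i}",
                [SiteCount(j * 10, int(rng.integers(0, 6)), 5) for j in range(4)],
            )
            for i in range(8)
        }
        priors = {c: BetaPrior(1.0, 1.0, 0.5, 2.0, 0.1, (), True) for c in cells}
        fit1 = fit_mixture("chr1:0-100", cells, priors, seed=3)
        fit2 = fit_mixture("chr1:0-100", cells, priors, seed=3)
        assert fit1.loglik == fit2.loglik
        assert (fit1.membership == fit2.membership).all()
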