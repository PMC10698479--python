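"""Correlation tests, beta regression, AIC selection, node-swap permutation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import optimize, stats

from focalscan.sampcompare import (
    BetaRegressionResult,
    compare_models,
    correlation_pvalue,
    fit_beta_regression,
    global_comparison,
    node_swap_test,
    pearson_test,
    squeeze_unit_interval,
)


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(8.0)
        res = pearson_test(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0)
        assert pearson_test(x, -x).r == pytest.approx(-1.0)

    def test_t_statistic_identity(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        res = pearson_test(x, y)
        assert res.t == pytest.approx(res.r * np.sqrt(res.df / (1 - res.r**2)))
        # agrees with the scipy reference implementation
        ref = stats.pearsonr(x, y)
        assert res.r == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_r_zero_gives_p_one(self):
        assert correlation_pvalue(0.0, 10) == pytest.approx(1.0)

    def test_boundary_r_gives_p_zero(self):
        assert correlation_pvalue(1.0, 10) == 0.0
        assert correlation_pvalue(-1.0, 10) == 0.0

    @given(st.floats(0.05, 0.9), st.floats(0.05, 0.9))
    def test_p_decreasing_in_abs_r(self, r1, r2):
        lo, hi = sorted([r1, r2])
        if hi - lo < 1e-6:
            return
        assert correlation_pvalue(hi, 10) < correlation_pvalue(lo, 10)

    @given(st.integers(4, 50), st.integers(4, 50))
    def test_p_decreasing_in_n(self, n1, n2):
        lo, hi = sorted([n1, n2])
        if lo == hi:
            return
        assert correlation_pvalue(0.5, hi) < correlation_pvalue(0.5, lo)


class TestSqueeze:
    @pytest.mark.parametrize("y, N, expected", [
        (0.0, 100, 0.005), (1.0, 100, 0.995), (0.5, 100, 0.5), (0.5, 7, 0.5),
    ])
    def test_formula(self, y, N, expected):
        assert squeeze_unit_interval(np.array([y]), N)[0] == pytest.approx(expected)

    def test_output_strictly_interior(self, rng):
        y = np.concatenate([[0.0, 1.0], rng.random(30)])
        z = squeeze_unit_interval(y)
        assert np.all((z > 0) & (z < 1))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            squeeze_unit_interval(np.array([1.2]))


def simulate_beta(rng, n=500, beta=(-2.0, 5.0), phi=50.0, x_scale=0.5):
    x = rng.uniform(0, x_scale, n)
    eta = beta[0] + beta[1] * x
    mu = 1 / (1 + np.exp(-eta))
    y = rng.beta(mu * phi, (1 - mu) * phi)
    X = np.column_stack([np.ones(n), x])
    return y, X, x


def independent_beta_fit(y, X):
    """Oracle: independently coded likelihood (scipy.stats.beta.logpdf)
    optimized by Nelder-Mead."""

    def nll(theta):
        beta, logphi = theta[:-1], theta[-1]
        phi = np.exp(logphi)
        mu = np.clip(1 / (1 + np.exp(-(X @ beta))), 1e-10, 1 - 1e-10)
        return -np.sum(stats.beta.logpdf(y, mu * phi, (1 - mu) * phi))

    ystar = np.log(y / (1 - y))
    b0, *_ = np.linalg.lstsq(X, ystar, rcond=None)
    start = np.append(b0, np.log(5.0))
    res = optimize.minimize(nll, start, method="Nelder-Mead",
                            options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12})
    return res.x, -res.fun


class TestBetaRegression:
    def test_constant_half_gives_zero_intercept(self):
        y = np.full(40, 0.5)
        y = squeeze_unit_interval(y)  # keep strictly interior (already is)
        X = np.ones((40, 1))
        res = fit_beta_regression(y, X, names=["intercept"])
        assert res.coef("intercept") == pytest.approx(0.0, abs=1e-6)

    def test_simulation_recovery_within_three_se(self, rng):
        y, X, _ = simulate_beta(rng)
        res = fit_beta_regression(y, X, names=["intercept", "x"])
        assert abs(res.coef("intercept") - (-2.0)) < 3 * res.coef_se("intercept")
        assert abs(res.coef("x") - 5.0) < 3 * res.coef_se("x")
        assert res.phi == pytest.approx(50.0, rel=0.25)

    def test_matches_independent_optimizer(self, rng):
        y, X, _ = simulate_beta(rng, n=300)
        res = fit_beta_regression(y, X)
        theta_ref, ll_ref = independent_beta_fit(y, X)
        assert np.allclose(res.params, theta_ref[:2], atol=1e-4)
        assert np.exp(theta_ref[2]) == pytest.approx(res.phi, abs=1e-2)
        assert res.loglik == pytest.approx(ll_ref, abs=1e-6)

    def test_loglik_at_ml_beats_truth(self, rng):
        from focalscan.sampcompare import _fixed_nll_grad

        y, X, _ = simulate_beta(rng, n=200)
        res = fit_beta_regression(y, X)
        ystar = np.log(y) - np.log1p(-y)
        truth = np.array([-2.0, 5.0, np.log(50.0)])
        nll_truth, _ = _fixed_nll_grad(truth, y, X, ystar, np.log(y), np.log1p(-y))
        assert res.loglik >= -nll_truth - 1e-8

    def test_mixed_model_recovers_variance_component(self, rng):
        G, m, phi, sigma = 8, 40, 50.0, 0.5
        g = np.repeat(np.arange(G), m)
        u = rng.normal(0, sigma, G)
        x = rng.uniform(0, 0.5, G * m)
        eta = -2 + 5 * x + u[g]
        mu = 1 / (1 + np.exp(-eta))
        y = rng.beta(mu * phi, (1 - mu) * phi)
        X = np.column_stack([np.ones(G * m), x])
        res = fit_beta_regression(y, X, groups=g, random_intercept=True,
                                  names=["intercept", "x"])
        assert res.random_intercept
        assert abs(res.coef("x") - 5.0) < 3 * res.coef_se("x")
        assert 0.02 < res.sigma2_group < 2.0
        # marginal likelihood must beat the fixed-effects model's when the
        # grouping is real
        fixed = fit_beta_regression(y, X)
        assert res.aic < fixed.aic

    def test_boundary_outcomes_rejected(self):
        with pytest.raises(ValueError, match="squeeze"):
            fit_beta_regression(np.array([0.0, 0.5, 0.7]), np.ones((3, 1)))


def _dummy_result(name_suffix, aic, nparams, checksum=(10, 1.0, 2.0)):
    k = nparams
    return BetaRegressionResult(
        names=[f"b{i}" for i in range(k - 1)], params=np.zeros(k - 1),
        se=np.ones(k - 1), z=np.zeros(k - 1), p=np.ones(k - 1),
        conf_int=np.zeros((k - 1, 2)), phi=10.0, sigma2_group=0.0,
        loglik=(2 * k - aic) / 2.0, aic=aic, nobs=10, nparams=k,
        random_intercept=False, converged=True, outcome_checksum=checksum,
    )


class TestCompareModels:
    def test_clear_winner_selected(self):
        comp = compare_models(
            null=_dummy_result("n", aic=100.0, nparams=2),
            main=_dummy_result("m", aic=95.0, nparams=4),
            interaction=_dummy_result("i", aic=85.0, nparams=6),
        )
        assert comp.selected == "interaction"

    def test_parsimony_tie_break(self):
        comp = compare_models(
            null=_dummy_result("n", aic=100.0, nparams=2),
            main=_dummy_result("m", aic=90.0, nparams=4),
            interaction=_dummy_result("i", aic=89.5, nparams=6),
        )
        assert comp.selected == "main"  # dAIC = 0.5 < 2: fewer parameters win

    def test_mismatched_outcomes_rejected(self):
        with pytest.raises(ValueError, match="different outcomes"):
            compare_models(
                null=_dummy_result("n", 100.0, 2, checksum=(10, 1.0, 2.0)),
                main=_dummy_result("m", 90.0, 4, checksum=(11, 1.0, 2.0)),
            )

    def test_true_interaction_detected(self, rng):
        # species-specific slope: the interaction model should win
        G, m, phi = 6, 30, 60.0
        g = np.repeat(np.arange(G), m)
        species = np.where(g < 3, "A", "B")
        x = rng.uniform(0, 0.5, G * m)
        slope = np.where(species == "A", 6.0, 1.0)
        eta = -2 + slope * x
        mu = 1 / (1 + np.exp(-eta))
        y = rng.beta(mu * phi, (1 - mu) * phi)
        df = pd.DataFrame({"y": y, "fas": x, "species": species, "group": g})
        from focalscan.sampcompare import build_design

        Xn, nn = build_design(df, "fas", include_predictor=False, species="species")
        Xm, nm = build_design(df, "fas", species="species")
        Xi, ni = build_design(df, "fas", species="species", interaction=True)
        fits = {
            "null": fit_beta_regression(y, Xn, names=nn),
            "main": fit_beta_regression(y, Xm, names=nm),
            "interaction": fit_beta_regression(y, Xi, names=ni),
        }
        assert compare_models(**fits).selected == "interaction"


class TestNodeSwap:
    def make_data(self, rng, slope=8.0, G=6, m=12, phi=40.0):
        g = np.repeat([f"g{k}" for k in range(G)], m)
        x = rng.uniform(0, 0.4, G * m)
        eta = -1.5 + slope * x
        mu = 1 / (1 + np.exp(-eta))
        y = rng.beta(mu * phi, (1 - mu) * phi)
        return pd.DataFrame({"abs": y, "fas": x, "group": g})

    def test_identity_permutation_gives_p_one(self, rng):
        data = self.make_data(rng)
        res = node_swap_test(data, "abs", "fas", "group", random_intercept=False,
                             B=10, seed=0, permute_fn=lambda n: np.arange(n))
        assert res.p == 1.0
        assert np.allclose(res.null, res.observed)

    def test_strong_effect_attains_minimum_p(self, rng):
        data = self.make_data(rng, slope=10.0)
        res = node_swap_test(data, "abs", "fas", "group", random_intercept=False,
                             B=19, seed=0)
        assert res.p == pytest.approx(1 / 20)

    def test_doubling_B_halves_minimum_p(self, rng):
        data = self.make_data(rng, slope=10.0)
        p19 = node_swap_test(data, "abs", "fas", "group", random_intercept=False,
                             B=19, seed=0).p
        p39 = node_swap_test(data, "abs", "fas", "group", random_intercept=False,
                             B=39, seed=0).p
        assert p39 == pytest.approx(p19 / 2)

    def test_permutation_is_within_group(self, rng):
        """Null refits must see the same multiset of outcomes per group."""
        data = self.make_data(rng, G=3, m=6)
        seen = []
        orig = np.random.default_rng

        res = node_swap_test(data, "abs", "fas", "group", random_intercept=False,
                             B=5, seed=1, permute_fn=lambda n: np.roll(np.arange(n), 1))
        # a cyclic within-group shift preserves each group's outcome multiset,
        # so every null estimate is finite and the test completes
        assert res.n_failed == 0
        assert len(res.null) == 5


class TestGlobalComparison:
    def groups_frame(self, values):
        return pd.DataFrame({"density": values},
                            index=[f"G{k}" for k in range(len(values))])

    def test_identical_values_r_one(self):
        fas = self.groups_frame([0.1, 0.3, 0.5, 0.7, 0.9])
        out = global_comparison(fas, fas.copy())
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_outlier_breaks_and_exclusion_restores(self, rng):
        base = np.linspace(0.1, 0.8, 8)
        fas = self.groups_frame(base)
        abs_vals = base + rng.normal(0, 0.02, 8)
        abs_vals[0] = 0.9  # the lowest-density group wildly off
        abs_ = self.groups_frame(abs_vals)
        out = global_comparison(fas, abs_, exclusions={"density": ["G0"]})
        with_outlier = out[out["excluded"] == ""].iloc[0]
        without = out[out["excluded"] == "G0"].iloc[0]
        assert with_outlier["p"] > 0.05
        assert without["p"] < 0.05

    def test_leave_one_out_finds_injected_outlier(self, rng):
        base = np.linspace(0.1, 0.8, 8)
        abs_vals = base + rng.normal(0, 0.02, 8)
        abs_vals[5] = 1.0 - base[5]
        names = [f"G{k}" for k in range(8)]
        # jackknife: dropping the true outlier yields the largest |r|
        rs = {}
        for drop in names:
            keep = [n for n in names if n != drop]
            idx = [names.index(n) for n in keep]
            rs[drop] = abs(pearson_test(base[idx], abs_vals[idx]).r)
        assert max(rs, key=rs.get) == "G5"

    def test_too_few_groups_refused(self):
        fas = self.groups_frame([0.1, 0.2])
        with pytest.raises(ValueError, match="fewer than 3"):
            global_comparison(fas, fas.copy())
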