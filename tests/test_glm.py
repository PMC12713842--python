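"""Estimation engines: OLS, cumulative/multinomial logit, LRT, VIF, OR."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from scipy.special import expit

from ordmediate import (
    CumulativeLogit,
    SingularDesignError,
    ValidationError,
    default_config,
    fit_cumulative_logit,
    fit_multinomial,
    fit_ols,
    generate,
    likelihood_ratio_test,
    odds_ratio,
    standardize,
    vif,
)

from conftest import make_dataset

COUNTS = (212, 396, 131, 123)  # worked-example outcome category frequencies


def expand_counts(counts):
    return np.repeat(np.arange(len(counts)), counts)


class TestOLS:
    def test_perfect_fit(self):
        x = np.arange(10.0)
        ds = make_dataset({"x": x, "y": 2 * x}, {"x": "covariate", "y": "covariate"})
        fit = fit_ols(ds, "y", ["x"])
        assert fit.coefficients["x"] == pytest.approx(2.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_five_row_normal_equations_oracle(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        X = np.column_stack([np.ones(5), x])
        expected = np.linalg.pinv(X) @ y  # explicit least-squares solution
        ds = make_dataset({"x": x, "y": y}, {"x": "covariate", "y": "covariate"})
        fit = fit_ols(ds, "y", ["x"])
        assert fit.coefficients["(Intercept)"] == pytest.approx(expected[0], abs=1e-10)
        assert fit.coefficients["x"] == pytest.approx(expected[1], abs=1e-10)
        assert fit.t["x"] == pytest.approx(fit.coefficients["x"] / fit.se["x"], abs=1e-8)

    def test_pinv_oracle_on_random_designs(self, rng):
        for _ in range(100):
            n, p = 30, 4
            X = rng.standard_normal((n, p))
            y = rng.standard_normal(n)
            ds = make_dataset(
                {**{f"x{j}": X[:, j] for j in range(p)}, "y": y},
                {**{f"x{j}": "covariate" for j in range(p)}, "y": "covariate"})
            fit = fit_ols(ds, "y", [f"x{j}" for j in range(p)])
            expected = np.linalg.pinv(np.column_stack([np.ones(n), X])) @ y
            got = [fit.coefficients["(Intercept)"]] + [
                fit.coefficients[f"x{j}"] for j in range(p)]
            assert np.allclose(got, expected, atol=1e-8)

    def test_rank_deficiency_names_collinear_set(self, rng):
        x = rng.standard_normal(50)
        ds = make_dataset({"a": x, "b": 2 * x, "y": rng.standard_normal(50)},
                          {"a": "covariate", "b": "covariate", "y": "covariate"})
        with pytest.raises(SingularDesignError) as exc:
            fit_ols(ds, "y", ["a", "b"])
        assert {"a", "b"} <= set(exc.value.columns)

    def test_scale_invariance_after_standardization(self, rng):
        x = rng.normal(10, 2, 300)
        y = 0.4 * x + rng.standard_normal(300)
        base = make_dataset({"x": x, "y": y}, {"x": "exposure", "y": "covariate"})
        scaled = make_dataset({"x": 37.0 * x, "y": y},
                              {"x": "exposure", "y": "covariate"})
        f1 = fit_ols(standardize(base, ["x"]), "y", ["x"])
        f2 = fit_ols(standardize(scaled, ["x"]), "y", ["x"])
        assert f1.coefficients["x"] == pytest.approx(f2.coefficients["x"], abs=1e-8)


class TestCumulativeLogit:
    def test_intercept_only_closed_form(self):
        y = expand_counts(COUNTS)
        m = CumulativeLogit().fit(np.empty((len(y), 0)), y)
        n = sum(COUNTS)
        surv = np.cumsum(COUNTS[::-1])[::-1][1:]
        expected = np.log(surv / (n - surv))
        assert np.allclose(list(m.thresholds_.values()), expected, atol=1e-6)

    def test_binary_predictor_against_likelihood_search_oracle(self):
        # grouped data, one binary x; oracle = independent derivative-free
        # likelihood search plus a local grid scan over the slope
        counts0 = np.array([40, 30, 20, 10])
        counts1 = np.array([15, 25, 30, 30])
        y = np.concatenate([expand_counts(counts0), expand_counts(counts1)])
        x = np.concatenate([np.zeros(counts0.sum()), np.ones(counts1.sum())])
        fit = CumulativeLogit().fit(x[:, None], y, feature_names=["x"])

        def nll(params):
            a = params[:3]
            b = params[3]
            out = 0.0
            for grp, counts in ((0.0, counts0), (1.0, counts1)):
                g = expit(a + b * grp)
                p = np.diff(np.concatenate([[1.0], g, [0.0]])) * -1
                if np.any(p <= 0):
                    return np.inf
                out -= (counts * np.log(p)).sum()
            return out

        res = optimize.minimize(nll, [0.5, -0.5, -1.5, 0.0], method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 20000, "maxfev": 20000})
        assert fit.slopes_["x"] == pytest.approx(res.x[3], abs=1e-4)
        # local grid scan: no nearby slope value improves the likelihood
        best = nll(np.concatenate([res.x[:3], [fit.slopes_["x"]]]))
        for db in (-5e-4, 5e-4):
            assert nll(np.concatenate([res.x[:3], [fit.slopes_["x"] + db]])) >= best - 1e-9

    def test_all_zero_predictor_is_singular(self):
        y = expand_counts((10, 10, 10, 10))
        with pytest.raises(SingularDesignError):
            CumulativeLogit().fit(np.zeros((len(y), 1)), y, feature_names=["z"])

    def test_fitted_survivors_monotone_and_cells_positive(self, simple_xy):
        fit = fit_cumulative_logit(simple_xy, "y", ["x", "m"], nonparallel=("m",))
        P = fit.predict_proba(simple_xy.table[["x", "m"]])
        assert np.all(P > 0)
        G = np.cumsum(P[:, ::-1], axis=1)[:, ::-1][:, 1:]  # P(Y > j)
        assert np.all(np.diff(G, axis=1) < 1e-12)

    def test_wald_output_consistency(self, simple_xy):
        fit = fit_cumulative_logit(simple_xy, "y", ["x", "m"])
        for nm, beta in fit.slopes_.items():
            assert np.exp(beta) == pytest.approx(fit.odds_ratios_[nm][0], abs=1e-8)
            assert fit.z_[nm] == pytest.approx(beta / fit.se_[nm], abs=1e-8)
            lo, hi = fit.ci95_[nm]
            assert lo < beta < hi

    def test_parallel_slope_recovery(self):
        # 100 seeds, n = 5000, fitting the data-generating outcome equation
        # (focal predictors plus covariates): each estimated slope within
        # 3 SEs of its configured truth in >= 95% of cases
        hits = total = 0
        focal = ["gratitude", "hse", "stress", "anxiety", "depression"]
        covs = ["age", "sex", "education", "conditions"]
        for seed in range(100):
            cfg = default_config(n=5000, seed=seed, nonparallel={})
            ds = standardize(generate(cfg), focal + covs)
            fit = fit_cumulative_logit(ds, "sleep", focal + covs)
            for nm in focal:
                truth = cfg.paths[(nm, "sleep")]
                hits += abs(fit.slopes_[nm] - truth) <= 3 * fit.se_[nm]
                total += 1
        assert hits / total >= 0.95


class TestMultinomial:
    def test_intercept_only_matches_cumulative(self):
        y = expand_counts(COUNTS)
        ds = make_dataset({"y": y.astype(float)}, {"y": "outcome"})
        mn = fit_multinomial(ds, "y", [])
        cum = CumulativeLogit().fit(np.empty((len(y), 0)), y)
        assert mn.log_likelihood_ == pytest.approx(cum.log_likelihood_, abs=1e-6)

    def test_binary_predictor_saturates_cell_proportions(self):
        counts0, counts1 = (40, 30, 20, 10), (15, 25, 30, 30)
        y = np.concatenate([expand_counts(counts0), expand_counts(counts1)])
        x = np.concatenate([np.zeros(100), np.ones(100)]).astype(float)
        ds = make_dataset({"x": x, "y": y.astype(float)},
                          {"x": "covariate", "y": "outcome"})
        mn = fit_multinomial(ds, "y", ["x"])
        obs0 = np.array(counts0) / 100
        assert np.allclose(mn.fitted_probs[0], obs0, atol=1e-5)

    def test_parameter_count(self):
        rng = np.random.default_rng(3)
        y = expand_counts((30, 30, 30, 30))
        ds = make_dataset(
            {"y": y.astype(float), "a": rng.standard_normal(120),
             "b": rng.standard_normal(120)},
            {"y": "outcome", "a": "covariate", "b": "covariate"})
        mn = fit_multinomial(ds, "y", ["a", "b"])
        assert mn.n_params_ == 3 * (2 + 1)


class TestLRT:
    def test_identical_models(self, simple_xy):
        fit = fit_cumulative_logit(simple_xy, "y", ["x", "m"])
        res = likelihood_ratio_test(fit, fit)
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_relaxed_slope_df(self, simple_xy):
        par = fit_cumulative_logit(simple_xy, "y", ["x", "m"])
        rel = fit_cumulative_logit(simple_xy, "y", ["x", "m"], nonparallel=("m",))
        res = likelihood_ratio_test(par, rel)
        assert res.df == 2  # one relaxed predictor, 4-level outcome
        assert res.chi2 >= 0.0

    def test_mismatched_samples_rejected(self, simple_xy):
        full = fit_cumulative_logit(simple_xy, "y", ["x", "m"])
        sub = simple_xy.table.iloc[:300]
        small = CumulativeLogit().fit(sub[["x", "m"]], sub["y"].astype(int))
        with pytest.raises(ValidationError):
            likelihood_ratio_test(small, full)

    def test_nested_ols_type_one_error(self):
        # LRT machinery on nested linear fits: size close to nominal
        rng = np.random.default_rng(11)
        n, reps, alpha = 100, 1000, 0.05
        rejections = 0
        for _ in range(reps):
            x = rng.standard_normal((n, 2))
            y = 1.0 + x[:, 0] + rng.standard_normal(n)  # x1 is null
            ds = make_dataset({"x0": x[:, 0], "x1": x[:, 1], "y": y},
                              {"x0": "covariate", "x1": "covariate", "y": "covariate"})
            f0 = fit_ols(ds, "y", ["x0"])
            f1 = fit_ols(ds, "y", ["x0", "x1"])
            rejections += likelihood_ratio_test(f0, f1).p < alpha
        assert 0.03 <= rejections / reps <= 0.07


class TestVIF:
    def test_orthogonal_predictors(self):
        ds = make_dataset({"a": [1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0],
                           "b": [1.0, 1.0, -1.0, -1.0, 1.0, 1.0, -1.0, -1.0]},
                          {"a": "covariate", "b": "covariate"})
        out = vif(ds, ["a", "b"])
        assert out["a"] == pytest.approx(1.0, abs=1e-10)
        assert out["b"] == pytest.approx(1.0, abs=1e-10)

    def test_near_collinear_pair(self, rng):
        x = rng.standard_normal(500)
        ds = make_dataset({"a": x, "b": x + 1e-3 * rng.standard_normal(500)},
                          {"a": "covariate", "b": "covariate"})
        out = vif(ds, ["a", "b"])
        assert out["a"] > 5 and out["b"] > 5

    def test_equicorrelated_closed_form(self):
        # three predictors with pairwise correlation 0.5:
        # R^2 = 2 rho^2 / (1 + rho) -> VIF = 1.5
        rng = np.random.default_rng(5)
        n, rho = 10_000, 0.5
        f = rng.standard_normal(n)
        cols = {f"x{i}": np.sqrt(rho) * f + np.sqrt(1 - rho) * rng.standard_normal(n)
                for i in range(3)}
        ds = make_dataset(cols, {k: "covariate" for k in cols})
        out = vif(ds, list(cols))
        expected = 1.0 / (1.0 - 2 * rho**2 / (1 + rho))
        for v in out.values():
            assert v == pytest.approx(expected, abs=0.05)


class TestOddsRatio:
    @pytest.mark.parametrize("beta,expected", [(0.217, 1.242), (0.0, 1.0),
                                               (0.471, 1.602)])
    def test_printed_conversions(self, beta, expected):
        assert round(odds_ratio(beta), 3) == expected

    def test_ci_exponentiated_endpointwise(self):
        or_, (lo, hi) = odds_ratio(0.217, (0.087, 0.346))
        assert (round(lo, 3), round(hi, 3)) == (1.091, 1.413)
        assert lo < or_ < hi

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            odds_ratio(np.inf)
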