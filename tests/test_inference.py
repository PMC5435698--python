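"""Likelihood machinery: mean surfaces, Gaussian NLL, fitting, AIC, F comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from reprodyn import (
    FecundityModelParams,
    aic,
    fit,
    load_reaction_surface,
    lrt_f,
    mean_fecundity_conventional,
    mean_fecundity_generalized,
    negative_log_likelihood,
    predict_per_female,
)
from reprodyn.inference import FitResult, profiled_sigma2, validate_reaction_surface
from reprodyn import DesignSpec, default_true_params, make_design, simulate_dataset


def row(n_pairs, n_het_males, date_day=230, total_eggs=np.nan, rep=1):
    return pd.DataFrame(
        {
            "date_day": [date_day],
            "n_pairs": [n_pairs],
            "n_het_males": [n_het_males],
            "total_eggs": [total_eggs],
            "replicate_id": [rep],
        }
    )


FIG2_GEN = dict(R0=58.3, c=0.0162, a=0.119, b=0.275)


class TestMeanSurfaces:
    def test_generalized_baseline_is_date_adjusted_fecundity(self):
        # one pair, no interferers, day 230: R = 58.3 + 0.0162*230 = 62.026
        mu = mean_fecundity_generalized(row(1, 0), **FIG2_GEN)
        assert mu[0] == pytest.approx(62.026, abs=1e-3)

    def test_generalized_interference_hand_value(self):
        # exponent -0.119*2 / (1 + 0.275*2/2) = -0.238/1.275
        mu = mean_fecundity_generalized(row(1, 2), **FIG2_GEN)
        expected = 62.026 * math.exp(-0.238 / 1.275)
        assert mu[0] == pytest.approx(expected, rel=1e-6)
        assert mu[0] == pytest.approx(51.46, abs=0.02)

    def test_no_interference_efficiency_ignores_males(self):
        mu0 = mean_fecundity_generalized(row(3, 0), R0=50, c=0.0, a=0.0, b=0.4)
        mu9 = mean_fecundity_generalized(row(3, 9), R0=50, c=0.0, a=0.0, b=0.4)
        assert mu0[0] == mu9[0] == pytest.approx(150.0)

    def test_conventional_hand_value(self):
        # N_i = 2, one male, i = 0.272: 60 * 2 / (2 + 0.544)
        mu = mean_fecundity_conventional(row(1, 1, date_day=0), R0=60.0, c=0.0, i=0.272)
        assert mu[0] == pytest.approx(60.0 * 2.0 / 2.544, rel=1e-9)
        assert mu[0] == pytest.approx(47.17, abs=0.01)

    def test_conventional_per_female_mean_is_frequency_only(self):
        mu1 = mean_fecundity_conventional(row(2, 3, date_day=0), R0=60, c=0.0, i=0.5)
        mu2 = mean_fecundity_conventional(row(4, 6, date_day=0), R0=60, c=0.0, i=0.5)
        assert mu2[0] / 4.0 == pytest.approx(mu1[0] / 2.0)


class TestNegativeLogLikelihood:
    def test_zero_residual_unit_variance(self):
        params = FecundityModelParams(
            family="generalized", R0=62.026, c=0.0, a=0.0, b=0.0, sigma2=1.0
        )
        df = row(1, 0, total_eggs=62.026)
        assert negative_log_likelihood(df, params) == pytest.approx(
            0.5 * math.log(2 * math.pi), rel=1e-9
        )

    def test_sigma2_doubling_closed_form(self):
        params = FecundityModelParams(
            family="generalized", R0=50.0, c=0.0, a=0.1, b=0.2, sigma2=4.0
        )
        df = pd.concat([row(1, 0, total_eggs=40.0), row(2, 3, total_eggs=70.0)])
        n = len(df)
        nll1 = negative_log_likelihood(df, params, sigma2=4.0)
        nll2 = negative_log_likelihood(df, params, sigma2=8.0)
        mu = mean_fecundity_generalized(df, 50.0, 0.0, 0.1, 0.2)
        quad = float(np.sum((df["total_eggs"].to_numpy() - mu) ** 2 / (2 * 4.0 * df["n_pairs"])))
        assert nll2 - nll1 == pytest.approx(n / 2 * math.log(2) - quad / 2, rel=1e-9)

    def test_matches_gaussian_density_product(self, rng):
        """Oracle: direct product of normal densities on a small toy table."""
        df = pd.concat(
            [row(p, m, total_eggs=e) for p, m, e in
             [(1, 0, 55.0), (2, 1, 90.0), (3, 5, 60.0), (1, 10, 12.0), (5, 2, 240.0)]],
            ignore_index=True,
        )
        params = FecundityModelParams(
            family="generalized", R0=58.3, c=0.0162, a=0.119, b=0.275, sigma2=80.0
        )
        mu = mean_fecundity_generalized(df, 58.3, 0.0162, 0.119, 0.275)
        sd = np.sqrt(80.0 * df["n_pairs"].to_numpy(float))
        oracle = -float(
            np.sum(stats.norm.logpdf(df["total_eggs"].to_numpy(float), mu, sd))
        )
        assert negative_log_likelihood(df, params) == pytest.approx(oracle, rel=1e-12)


@pytest.fixture(scope="module")
def gen_dataset():
    design = make_design(DesignSpec(), seed=7)
    return simulate_dataset(design, default_true_params("generalized"), seed=7)


class TestFit:
    def test_null_interference_recovered_near_boundary(self):
        design = make_design(DesignSpec(), seed=3)
        truth = FecundityModelParams(
            family="generalized", R0=58.3, c=0.0162, a=0.0, b=0.0, sigma2=100.0
        )
        df = simulate_dataset(design, truth, seed=3)
        res = fit(df, "generalized", n_starts=8, seed=0)
        assert res.params.a < 0.02

    def test_recovers_generating_parameters(self, gen_dataset):
        res = fit(gen_dataset, "generalized", n_starts=8, seed=0)
        assert res.converged
        assert res.params.R0 == pytest.approx(58.3, rel=0.05)
        assert res.params.a == pytest.approx(0.119, rel=0.25)
        assert res.params.b == pytest.approx(0.275, rel=0.35)
        assert res.params.c == pytest.approx(0.0162, rel=0.25)

    def test_deterministic_given_seed_and_basin(self, gen_dataset):
        res1 = fit(gen_dataset, "generalized", n_starts=6, seed=0)
        res2 = fit(gen_dataset, "generalized", n_starts=12, seed=5)
        assert abs(res1.loglik - res2.loglik) < 1e-6

    def test_profiled_sigma2_is_joint_optimum(self, gen_dataset):
        """Joint optimization over (mean params, sigma2) agrees with profiling."""
        res = fit(gen_dataset, "generalized", n_starts=6, seed=0)
        p = res.params
        df = gen_dataset

        def joint_nll(theta):
            try:
                params = FecundityModelParams(
                    family="generalized", R0=theta[0], c=theta[1],
                    a=max(theta[2], 0.0), b=max(theta[3], 0.0), sigma2=theta[4],
                )
            except ValueError:
                return 1e12
            return negative_log_likelihood(df, params)

        x0 = np.array([p.R0, p.c, p.a, p.b, p.sigma2 * 1.3])
        sol = optimize.minimize(joint_nll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        assert -sol.fun == pytest.approx(res.loglik, abs=1e-6)

    def test_zero_fecundity_toggle_changes_only_n_obs(self, gen_dataset):
        df = gen_dataset.copy()
        df.loc[df.index[:4], "total_eggs"] = 0.0
        full = fit(df, "conventional", n_starts=6, seed=0)
        dropped = fit(
            df[df["total_eggs"] > 0].reset_index(drop=True),
            "conventional", n_starts=6, seed=0,
        )
        assert full.n_obs - dropped.n_obs == 4
        assert full.n_params == dropped.n_params == 4

    def test_too_few_rows_rejected(self):
        df = row(1, 0, total_eggs=50.0)
        with pytest.raises(ValueError):
            fit(df, "generalized")


class TestAic:
    def test_definition(self):
        p = FecundityModelParams(family="conventional", R0=50, i=0.1, sigma2=1.0)
        res = FitResult(
            params=p, loglik=-100.0, aic=208.0, n_obs=10, n_params=4,
            weighted_rss=1.0, converged=True, n_starts_used=1,
        )
        assert aic(res) == 208.0
        res5 = FitResult(
            params=p, loglik=-100.0, aic=210.0, n_obs=10, n_params=5,
            weighted_rss=1.0, converged=True, n_starts_used=1,
        )
        assert aic(res5) == 210.0

    def test_family_parameter_counts(self, gen_dataset):
        fg = fit(gen_dataset, "generalized", n_starts=4, seed=0)
        fc = fit(gen_dataset, "conventional", n_starts=4, seed=0)
        assert fg.n_params == 5 and fc.n_params == 4
        assert fg.aic == pytest.approx(2 * 5 - 2 * fg.loglik)
        assert (fg.aic - fc.aic) == pytest.approx(2 - 2 * (fg.loglik - fc.loglik))


def _dummy_result(wrss, n_obs, n_params):
    p = FecundityModelParams(family="conventional", R0=1.0, i=0.0, sigma2=1.0)
    return FitResult(
        params=p, loglik=0.0, aic=0.0, n_obs=n_obs, n_params=n_params,
        weighted_rss=wrss, converged=True, n_starts_used=1,
    )


class TestLrtF:
    def test_identical_fits_give_zero(self):
        a = _dummy_result(10.0, 30, 5)
        b = _dummy_result(10.0, 30, 4)
        out = lrt_f(a, b, None)
        assert out["F"] == 0.0 and out["p"] == 1.0

    def test_matches_weighted_anova_oracle(self):
        """Extra-sum-of-squares F on a toy weighted linear problem, checked
        against statsmodels' ANOVA of the same nested WLS fits."""
        import statsmodels.api as sm

        rng = np.random.default_rng(42)
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        w = np.array([1.0, 2.0, 1.0, 3.0, 1.0, 2.0])  # variance ∝ 1/weight... F_k = 1/w
        y = 2.0 + 0.8 * x + rng.normal(0, 0.3, 6)
        sw = np.sqrt(w)
        X_full = sm.add_constant(x)
        fit_red = sm.OLS(y * sw, np.ones((6, 1)) * sw[:, None]).fit()
        fit_full = sm.OLS(y * sw, X_full * sw[:, None]).fit()
        table = sm.stats.anova_lm(fit_red, fit_full)
        F_oracle, p_oracle = table["F"][1], table["Pr(>F)"][1]

        wrss_red = float(np.sum(fit_red.resid ** 2))  # already sqrt-weighted
        wrss_full = float(np.sum(fit_full.resid ** 2))
        # parameter counts chosen so df2 matches the classical ANOVA table;
        # the sigma2-counting df convention is checked separately below
        ours = lrt_f(_dummy_result(wrss_full, 6, 2), _dummy_result(wrss_red, 6, 1), None)
        assert ours["F"] == pytest.approx(float(F_oracle), rel=1e-9)
        assert ours["p"] == pytest.approx(float(p_oracle), rel=1e-9)
        assert ours["df1"] == 1

    def test_denominator_df_convention(self, gen_dataset):
        # n - 5 residual degrees of freedom when the full model is the
        # five-parameter generalized family (sigma2 counted)
        fg = fit(gen_dataset, "generalized", n_starts=4, seed=0)
        fc = fit(gen_dataset, "conventional", n_starts=4, seed=0)
        out = lrt_f(fg, fc, gen_dataset)
        assert out["df1"] == 1
        assert out["df2"] == fg.n_obs - 5

    def test_perfect_fit_reports_infinite_f(self):
        out = lrt_f(_dummy_result(0.0, 20, 5), _dummy_result(3.0, 20, 4), None)
        assert out["F"] == math.inf and out["p"] == 0.0


class TestFittedSurfaceShape:
    def test_generalized_declines_along_constant_ratio_rays(self, gen_dataset):
        fg = fit(gen_dataset, "generalized", n_starts=6, seed=0)
        fc = fit(gen_dataset, "conventional", n_starts=6, seed=0)
        pairs = np.array([1.0, 2.0, 4.0, 8.0])
        males = 2.0 * pairs  # fixed 1:1 pair:male ratio, rising total density
        per_female_g = predict_per_female(fg.params, pairs, males)
        per_female_c = predict_per_female(fc.params, pairs, males)
        assert np.all(np.diff(per_female_g) < 0)
        assert np.allclose(np.diff(per_female_c), 0.0, atol=1e-9)


class TestDataIO:
    def test_csv_round_trip(self, tmp_path, gen_dataset):
        path = tmp_path / "dishes.csv"
        gen_dataset.to_csv(path, index=False)
        df = load_reaction_surface(path)
        assert len(df) == len(gen_dataset)
        assert list(df.columns[:5]) == [
            "date_day", "n_pairs", "n_het_males", "total_eggs", "replicate_id",
        ]

    def test_contract_violations_rejected(self):
        with pytest.raises(ValueError):
            validate_reaction_surface(pd.DataFrame({"n_pairs": [1]}))
        bad = row(0, 0, total_eggs=10.0)
        with pytest.raises(ValueError):
            validate_reaction_surface(bad)
        neg = row(1, -1, total_eggs=10.0)
        with pytest.raises(ValueError):
            validate_reaction_surface(neg)
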