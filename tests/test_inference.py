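"""Statistical layer: BEST comparison, correlations, residual regressions,
and the recursive path model (checked against per-equation OLS oracles)."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from tritroph import (
    BestModel,
    ConfigurationError,
    PathModel,
    TritrophError,
    best_compare,
    residual_regression,
    species_interaction_correlation,
)

BEST_KW = dict(draws=600, tune=600)


class TestBest:
    def test_identical_groups_diff_straddles_zero(self, rng):
        x = rng.normal(5, 2, size=150)
        res = best_compare(x, x.copy(), rng=1, **BEST_KW)
        lo, hi = res.hdi(res.mean_diff)
        assert lo < 0 < hi

    def test_effect_size_recovers_separated_normals(self, rng):
        a = rng.normal(0, 1, size=200)
        b = rng.normal(10, 1, size=200)
        res = best_compare(a, b, rng=2, **BEST_KW)
        # analytic standardized difference, from the sample moments
        expected = (a.mean() - b.mean()) / np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        assert np.mean(res.effect_size) == pytest.approx(expected, rel=0.05)
        assert np.mean(res.mu_a) == pytest.approx(a.mean(), abs=0.3)
        assert np.mean(res.mu_b) == pytest.approx(b.mean(), abs=0.3)

    def test_effect_size_scale_invariant(self, rng):
        a = rng.normal(1, 1, size=150)
        b = rng.normal(2, 1.5, size=150)
        res1 = best_compare(a, b, rng=3, **BEST_KW)
        res2 = best_compare(10 * a, 10 * b, rng=3, **BEST_KW)
        e1, e2 = np.mean(res1.effect_size), np.mean(res2.effect_size)
        assert e1 == pytest.approx(e2, abs=0.08)

    def test_summary_and_hdi_ordering(self, rng):
        a = rng.normal(0, 1, size=80)
        b = rng.normal(1, 1, size=80)
        res = best_compare(a, b, rng=4, **BEST_KW)
        summ = res.summary()
        for q in summ.index:
            assert summ.loc[q, "hdi_low"] <= summ.loc[q, "mean"] <= summ.loc[q, "hdi_high"]

    def test_bad_inputs_rejected(self):
        with pytest.raises(TritrophError):
            BestModel([1.0], [1.0, 2.0])
        with pytest.raises(TritrophError):
            BestModel([1.0, np.inf], [1.0, 2.0])


class TestCorrelation:
    def test_perfect_linear_relation(self):
        sp = np.linspace(1, 10, 30)
        df = pd.DataFrame({"spdiv_PH": sp, "intdiv_PH": 2 * sp})
        out = species_interaction_correlation(df, networks=("PH",))
        assert out.loc["PH", "r"] == pytest.approx(1.0)
        assert out.loc["PH", "slope"] == pytest.approx(2.0)

    def test_independent_noise_near_zero(self, rng):
        n = 10_000
        df = pd.DataFrame({"spdiv_PH": rng.normal(size=n),
                           "intdiv_PH": rng.normal(size=n)})
        out = species_interaction_correlation(df, networks=("PH",))
        assert abs(out.loc["PH", "r"]) < 2 / np.sqrt(n) * 2.5

    def test_zero_variance_flagged(self):
        df = pd.DataFrame({"spdiv_PH": np.ones(10), "intdiv_PH": np.arange(10.0)})
        with pytest.raises(TritrophError):
            species_interaction_correlation(df, networks=("PH",))


class TestResidualRegression:
    def test_exact_linear_gives_zero_beta(self, rng):
        sp = rng.uniform(1, 10, 200)
        df = pd.DataFrame({"spdiv_PH": sp, "intdiv_PH": 3 * sp + 1,
                           "pred": rng.uniform(0, 5, 200)})
        res = residual_regression(df, "PH", "pred")
        assert res.beta == pytest.approx(0.0, abs=1e-10)

    def test_recovers_planted_effect(self, rng):
        n = 2000
        sp = rng.uniform(1, 10, n)
        pred = rng.uniform(0, 4, n)
        pred_c = pred - pred.mean()
        intdiv = 2 * sp + 1.5 * pred_c + rng.normal(0, 1e-3, n)
        df = pd.DataFrame({"spdiv_PH": sp, "intdiv_PH": intdiv, "pred": pred})
        res = residual_regression(df, "PH", "pred")
        assert res.beta == pytest.approx(1.5, rel=0.02)
        assert res.p_value < 1e-6

    def test_uncorrelated_predictor_beta_within_noise(self, rng):
        n = 1000
        sp = rng.uniform(1, 10, n)
        intdiv = 2 * sp + rng.normal(0, 1, n)
        pred = rng.uniform(0, 5, n)
        df = pd.DataFrame({"spdiv_PH": sp, "intdiv_PH": intdiv, "pred": pred})
        res = residual_regression(df, "PH", "pred")
        fit = sm.OLS(sm.OLS(intdiv, sm.add_constant(sp)).fit().resid,
                     sm.add_constant(pred)).fit()
        assert abs(res.beta) < 3 * fit.bse[1]

    def test_orientation_switch(self, rng):
        n = 500
        sp = rng.uniform(1, 10, n)
        intdiv = 2 * sp + rng.normal(0, 1, n)
        pred = rng.uniform(0, 5, n)
        df = pd.DataFrame({"spdiv_PH": sp, "intdiv_PH": intdiv, "pred": pred})
        a = residual_regression(df, "PH", "pred")
        b = residual_regression(df, "PH", "pred",
                                residuals_from="species_on_interaction")
        assert a.beta != b.beta  # different residual definitions


def simulate_recursive(n, rng, b_xy=0.6, b_yz=-0.4, b_xz=0.3):
    x = rng.standard_normal(n)
    y = b_xy * x + np.sqrt(1 - b_xy**2) * rng.standard_normal(n)
    ez = np.sqrt(max(1e-6, 1 - (b_yz**2 + b_xz**2 + 2 * b_yz * b_xz * b_xy)))
    z = b_yz * y + b_xz * x + ez * rng.standard_normal(n)
    return pd.DataFrame({"x": x, "y": y, "z": z})


class TestPathModel:
    EDGES = [("x", "y"), ("y", "z"), ("x", "z")]

    def test_saturated_model_fits_perfectly(self, rng):
        data = simulate_recursive(500, rng)
        res = PathModel(data, self.EDGES).fit()
        assert res.df == 0
        assert res.chi_square == pytest.approx(0.0, abs=1e-8)

    def test_recovers_known_coefficients(self, rng):
        data = simulate_recursive(5000, rng)
        res = PathModel(data, self.EDGES).fit()
        assert res.coef("x", "y") == pytest.approx(0.6, abs=0.05)
        assert res.coef("y", "z") == pytest.approx(-0.4, abs=0.05)
        assert res.coef("x", "z") == pytest.approx(0.3, abs=0.05)

    def test_equals_standardized_ols_oracle(self, rng):
        data = simulate_recursive(800, rng)
        res = PathModel(data, self.EDGES).fit()
        z = (data - data.mean()) / data.std(ddof=1)
        for target, parents in (("y", ["x"]), ("z", ["x", "y"])):
            fit = sm.OLS(z[target], z[parents]).fit()
            for p in parents:
                assert res.coef(p, target) == pytest.approx(fit.params[p], abs=1e-8)

    def test_affine_invariance(self, rng):
        data = simulate_recursive(600, rng)
        res1 = PathModel(data, self.EDGES).fit()
        rescaled = data.copy()
        rescaled["x"] = 100 * rescaled["x"] - 7
        rescaled["z"] = 0.01 * rescaled["z"] + 3
        res2 = PathModel(rescaled, self.EDGES).fit()
        for edge, coef in res1.coefficients.items():
            assert res2.coefficients[edge] == pytest.approx(coef, abs=1e-10)

    def test_correctly_specified_restriction_calibrated(self, rng):
        # x -> y -> z with x -> z omitted, and the true x->z effect is 0:
        # the chi-square test should rarely reject
        reject = 0
        n_rep = 60
        for _ in range(n_rep):
            data = simulate_recursive(300, rng, b_xz=0.0)
            res = PathModel(data, [("x", "y"), ("y", "z")]).fit()
            assert res.df == 1
            if res.p_value < 0.05:
                reject += 1
        assert reject / n_rep <= 0.10

    def test_misspecification_detected(self, rng):
        data = simulate_recursive(3000, rng, b_xz=0.5)
        res = PathModel(data, [("x", "y"), ("y", "z")]).fit()
        assert res.p_value < 0.01

    def test_indirect_effects_are_products(self, rng):
        data = simulate_recursive(1000, rng)
        res = PathModel(data, self.EDGES).fit()
        ind = res.indirect_effects()
        assert ind.loc["x", "z"] == pytest.approx(
            res.coef("x", "y") * res.coef("y", "z"), abs=1e-10
        )
        tot = res.total_effects()
        assert tot.loc["x", "z"] == pytest.approx(
            res.coef("x", "z") + res.coef("x", "y") * res.coef("y", "z"), abs=1e-10
        )

    def test_cycle_rejected(self, rng):
        data = simulate_recursive(100, rng)
        with pytest.raises(ConfigurationError):
            PathModel(data, [("x", "y"), ("y", "x")])

    def test_headline_structure_has_four_df(self, rng):
        from tritroph.experiment import FULL_PATH_EDGES, SWEEP_PATH_EDGES

        cols = sorted({v for e in FULL_PATH_EDGES for v in e})
        data = pd.DataFrame(rng.standard_normal((200, len(cols))), columns=cols)
        assert PathModel(data, FULL_PATH_EDGES).fit().df == 4
        cols2 = sorted({v for e in SWEEP_PATH_EDGES for v in e})
        data2 = pd.DataFrame(rng.standard_normal((200, len(cols2))), columns=cols2)
        assert PathModel(data2, SWEEP_PATH_EDGES).fit().df == 2
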