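"""Response-surface fitting, ANOVA, prediction and optimization."""

import warnings

import numpy as np
import pandas as pd
import pytest

from fermdoe import rsm
from fermdoe.designs import build_ccd
from fermdoe.io import ResponseTable
from fermdoe.rsm import QuadraticModel, SingularDesignError
from fermdoe.synthetic import QuadraticTruth, simulate_ccd

from conftest import random_quadratic


def _design():
    return build_ccd(4, 2.0, 6)


class TestFitQuadratic:
    def test_noiseless_recovery(self):
        model = random_quadratic(7)
        table = simulate_ccd(QuadraticTruth(model, sigma=0.0), _design())
        fit, _ = rsm.fit_quadratic(table, "y")
        assert np.allclose(fit.coefficients(), model.coefficients(), atol=1e-8)

    def test_matches_statsmodels_on_seeded_datasets(self):
        # dual-route check: internal lstsq vs statsmodels OLS, 50 seeds
        import statsmodels.api as sm

        d = _design()
        X = d.coded.to_numpy()
        M = rsm.model_matrix(X)
        for seed in range(50):
            table = simulate_ccd(QuadraticTruth(random_quadratic(seed), 0.5, seed), d)
            fit, stats_df = rsm.fit_quadratic(table, "y")
            y = table.response("y").to_numpy()
            ref = sm.OLS(y, M).fit()
            assert np.allclose(fit.coefficients(), ref.params, atol=1e-8)
            assert np.allclose(stats_df["se"], ref.bse, atol=1e-8)
            assert np.allclose(stats_df["p"], ref.pvalues, atol=1e-8)

    def test_mean_estimates_near_truth_with_noise(self):
        # over 200 replicates each coefficient's mean estimate sits well
        # inside 3 standard errors of the generating value
        d = _design()
        truth_model = random_quadratic(3)
        sigma = 0.5
        est = []
        for seed in range(200):
            table = simulate_ccd(QuadraticTruth(truth_model, sigma, seed), d)
            fit, _ = rsm.fit_quadratic(table, "y")
            est.append(fit.coefficients().to_numpy())
        est = np.array(est)
        M = rsm.model_matrix(d.coded.to_numpy())
        se_mean = sigma * np.sqrt(np.diag(np.linalg.inv(M.T @ M))) / np.sqrt(200)
        bias = est.mean(axis=0) - truth_model.coefficients().to_numpy()
        assert np.all(np.abs(bias) < 3 * se_mean + 1e-12)

    def test_coefficient_rmse_matches_ols_theory(self):
        # RMSE of each coefficient ~ sqrt(sigma^2 (X'X)^-1_jj), within 15%,
        # and scales linearly in sigma
        d = _design()
        truth_model = random_quadratic(11)
        M = rsm.model_matrix(d.coded.to_numpy())
        theory_unit = np.sqrt(np.diag(np.linalg.inv(M.T @ M)))
        rmse_by_sigma = {}
        for sigma in (0.1, 0.5, 1.0):
            errs = []
            for seed in range(200):
                table = simulate_ccd(QuadraticTruth(truth_model, sigma, seed), d)
                fit, _ = rsm.fit_quadratic(table, "y")
                errs.append(fit.coefficients().to_numpy()
                            - truth_model.coefficients().to_numpy())
            rmse = np.sqrt((np.array(errs) ** 2).mean(axis=0))
            rmse_by_sigma[sigma] = rmse
            assert np.all(np.abs(rmse / (sigma * theory_unit) - 1.0) < 0.15), sigma
        ratio = rmse_by_sigma[1.0] / rmse_by_sigma[0.1]
        assert np.all(np.abs(ratio / 10.0 - 1.0) < 0.2)

    def test_bundled_ccd_fit_differs_from_printed_model(self, ccd_table, eq6_model):
        # the printed responses do not reproduce the printed coefficients
        # (documented inconsistency): the refitted x2 effect is ~0.34
        fit, _ = rsm.fit_quadratic(ccd_table, "PGase")
        assert fit.coefficients()["x2"] == pytest.approx(0.34, abs=0.02)
        assert abs(fit.coefficients()["x2"] - eq6_model.coefficients()["x2"]) > 0.5

    def test_singular_design_names_aliased_columns(self):
        d = _design()
        coded = d.coded.copy()
        coded["x4"] = coded["x3"]  # alias two columns
        design = type(d)(coded, d.point_type)
        table = ResponseTable(design, pd.DataFrame({"y": np.arange(30.0)},
                                                   index=coded.index))
        with pytest.raises(SingularDesignError, match="aliased"):
            rsm.fit_quadratic(table, "y")


class TestPredict:
    def test_intercept_at_center(self):
        m = random_quadratic(1)
        assert rsm.predict(m, np.zeros(4)) == pytest.approx(m.intercept)

    def test_vectorized_matches_scalar(self):
        m = random_quadratic(2)
        X = np.random.default_rng(0).uniform(-2, 2, (10, 4))
        vec = rsm.predict(m, X)
        assert np.allclose(vec, [rsm.predict(m, x) for x in X])

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            rsm.predict(random_quadratic(1), np.zeros(3))

    def test_warns_outside_design_region(self):
        m = random_quadratic(1)  # alpha = 2
        with pytest.warns(UserWarning):
            rsm.predict(m, np.array([2.5, 0, 0, 0]))

    def test_model_from_terms_round_trip(self, eq6_model):
        terms = eq6_model.coefficients().to_dict()
        again = QuadraticModel.from_terms(terms, eq6_model.symbols, alpha=2.0)
        assert np.allclose(again.coefficients(), eq6_model.coefficients())


class TestAnova:
    def test_additivity_invariants(self):
        # SS(Linear)+SS(Square)+SS(Interaction)=SS(Regression);
        # SS(LoF)+SS(PE)=SS(Residual); dfs additive -- on every seeded fit
        d = _design()
        for seed in range(10):
            table = simulate_ccd(QuadraticTruth(random_quadratic(seed), 0.7, seed), d)
            fit, _ = rsm.fit_quadratic(table, "y")
            res = rsm.rsm_anova(fit, table, "y")
            t = res["table"]
            assert t.loc["Linear", "SS"] + t.loc["Square", "SS"] + t.loc[
                "Interaction", "SS"] == pytest.approx(t.loc["Regression", "SS"], abs=1e-9)
            assert t.loc["Lack of fit", "SS"] + t.loc["Pure error", "SS"] == pytest.approx(
                t.loc["Residual error", "SS"], abs=1e-9)
            assert t.loc["Regression", "SS"] + t.loc["Residual error", "SS"] == pytest.approx(
                t.loc["Total", "SS"], abs=1e-9)
            assert (t.loc["Regression", "df"] + t.loc["Residual error", "df"]
                    == t.loc["Total", "df"])
            assert (t["SS"].dropna() >= -1e-12).all()

    def test_noiseless_fit_is_perfect(self):
        table = simulate_ccd(QuadraticTruth(random_quadratic(5), 0.0), _design())
        fit, _ = rsm.fit_quadratic(table, "y")
        res = rsm.rsm_anova(fit, table, "y")
        assert res["table"].loc["Residual error", "SS"] == pytest.approx(0.0, abs=1e-9)
        assert res["r2"] == pytest.approx(1.0, abs=1e-9)

    def test_press_hat_shortcut_equals_literal_loo(self):
        d = _design()
        table = simulate_ccd(QuadraticTruth(random_quadratic(9), 0.5, 9), d)
        fit, _ = rsm.fit_quadratic(table, "y")
        res = rsm.rsm_anova(fit, table, "y")
        X = d.coded.to_numpy()
        y = table.response("y").to_numpy()
        M = rsm.model_matrix(X)
        press = 0.0
        for i in range(len(y)):
            keep = np.arange(len(y)) != i
            beta, *_ = np.linalg.lstsq(M[keep], y[keep], rcond=None)
            press += float((y[i] - M[i] @ beta) ** 2)
        assert res["press"] == pytest.approx(press, rel=1e-8)

    def test_no_replicates_omits_lack_of_fit(self):
        d = build_ccd(4, 2.0, 1)  # single center point: no replicate group
        table = simulate_ccd(QuadraticTruth(random_quadratic(2), 0.5, 0), d)
        fit, _ = rsm.fit_quadratic(table, "y")
        res = rsm.rsm_anova(fit, table, "y")
        assert not res["has_replicates"]
        assert "Lack of fit" not in res["table"].index

    def test_adequate_precision_positive(self, ccd_table):
        fit, _ = rsm.fit_quadratic(ccd_table, "PGase")
        res = rsm.rsm_anova(fit, ccd_table, "PGase")
        assert res["adequate_precision"] > 4.0  # adequate-signal convention


class TestOptima:
    def test_separable_concave_maximum(self):
        m = QuadraticModel(["x1", "x2"], 10.0, np.zeros(2), np.array([-1.0, -1.0]),
                           np.zeros(1))
        opt = rsm.stationary_point(m)
        assert opt.nature == "maximum"
        assert np.allclose(opt.coded, 0.0, atol=1e-9)
        assert opt.predicted == pytest.approx(10.0)

    def test_saddle_detected(self):
        m = QuadraticModel(["x1", "x2"], 0.0, np.zeros(2), np.array([1.0, -1.0]),
                           np.zeros(1))
        assert rsm.stationary_point(m, bounds=[(-5, 5)] * 2).nature in ("saddle", "boundary")
        B = m.b_matrix()
        eig = np.linalg.eigvalsh(B)
        assert eig[0] < 0 < eig[1]

    def test_boundary_optimum(self):
        m = QuadraticModel(["x1"], 10.0 - 25.0, np.array([10.0]), np.array([-1.0]),
                           np.zeros(0))  # y = 10 - (x-5)^2
        opt = rsm.optimize_bounded(m, [(-2.0, 2.0)])
        assert opt.coded[0] == pytest.approx(2.0, abs=1e-6)
        assert opt.predicted == pytest.approx(1.0, abs=1e-6)
        assert opt.nature == "boundary"

    def test_interior_consistency_with_stationary_point(self):
        m = random_quadratic(21, concave=True)
        sp = rsm.stationary_point(m, bounds=[(-4, 4)] * 4)
        if np.all(np.abs(sp.coded) < 4):
            opt = rsm.optimize_bounded(m, [(-4, 4)] * 4)
            assert np.allclose(opt.coded, sp.coded, atol=1e-5)
            assert opt.predicted == pytest.approx(sp.predicted, abs=1e-6)

    def test_against_dense_grid_oracle(self):
        # indefinite seeded model on [-2,2]^4 vs a 41^4 grid argmax
        m = random_quadratic(33)
        grid1 = np.linspace(-2, 2, 41)
        step = grid1[1] - grid1[0]
        G = np.stack(np.meshgrid(*[grid1] * 4, indexing="ij"), axis=-1).reshape(-1, 4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vals = rsm.predict(m, G)
        gx = G[int(np.argmax(vals))]
        opt = rsm.optimize_bounded(m, [(-2.0, 2.0)] * 4)
        assert np.all(np.abs(opt.coded - gx) <= step + 1e-9)
        assert opt.predicted >= vals.max() - 1e-9

    def test_ridge_falls_back_to_bounded(self):
        m = QuadraticModel(["x1", "x2"], 0.0, np.array([1.0, 0.0]),
                           np.array([0.0, -1.0]), np.zeros(1))  # singular B
        with pytest.warns(UserWarning, match="ridge"):
            opt = rsm.stationary_point(m, bounds=[(-2, 2)] * 2)
        assert opt.coded[0] == pytest.approx(2.0, abs=1e-6)
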