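"""Collinearity screen, GLM machinery, AIC suites and the penalized GAM."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import gammaln

from oceangap import ecomodels as em


class TestCollinearityScreen:
    def test_duplicated_covariate_dropped(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "a_copy": x, "b": rng.normal(size=50)})
        kept, corr = em.collinearity_screen(df)
        assert len(kept) == 2 and "b" in kept
        assert corr.shape == (3, 3)

    def test_independent_noise_none_dropped(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(200, 5)),
                          columns=list("abcde"))
        kept, _ = em.collinearity_screen(df)
        assert kept == list("abcde")

    def test_o2_dropped_in_favour_of_temperature(self):
        rng = np.random.default_rng(2)
        t = rng.normal(15, 5, 100)
        df = pd.DataFrame({"o2_mean": 350 - 5 * t, "temperature_mean": t,
                           "nitrate_mean": rng.normal(size=100)})
        kept, _ = em.collinearity_screen(df)
        assert "temperature_mean" in kept and "o2_mean" not in kept

    def test_constant_covariate_warns_and_excluded(self):
        df = pd.DataFrame({"a": np.ones(10), "b": np.arange(10.0),
                           "c": np.arange(10.0) ** 2})
        with pytest.warns(UserWarning):
            kept, _ = em.collinearity_screen(df)
        assert "a" not in kept


class TestFitGLM:
    def test_intercept_only_closed_form(self):
        fit = em.fit_glm(np.array([1, 2, 3]), None, family="poisson")
        assert fit.coefficients["const"] == pytest.approx(np.log(2.0), abs=1e-8)

    def test_poisson_score_equation_saturates_mean(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        y = rng.poisson(np.exp(0.5 + 0.3 * x))
        fit = em.fit_glm(y, pd.DataFrame({"x": x}), family="poisson")
        mu = fit._impl.fittedvalues
        assert mu.sum() == pytest.approx(y.sum(), rel=1e-8)

    def test_matches_direct_newton_optimizer(self):
        # independent oracle: maximize the handwritten Poisson log-likelihood
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        y = rng.poisson(np.exp(1.0 + 0.4 * x))
        X = np.column_stack([np.ones(30), x])

        def nll(b):
            eta = X @ b
            return -(y @ eta - np.exp(eta).sum() - gammaln(y + 1).sum())

        opt = minimize(nll, np.zeros(2), method="BFGS", tol=1e-12)
        fit = em.fit_glm(y, pd.DataFrame({"x": x}), family="poisson")
        assert np.allclose(fit.coefficients.to_numpy(), opt.x, atol=1e-6)
        assert fit.loglik == pytest.approx(-opt.fun, abs=1e-6)

    def test_nb_with_huge_theta_reproduces_poisson(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=50)
        y = rng.poisson(np.exp(1.0 + 0.5 * x))
        fp = em.fit_glm(y, pd.DataFrame({"x": x}), family="poisson")
        fnb = em.fit_glm(y, pd.DataFrame({"x": x}),
                         family="negative_binomial", theta=1e8)
        assert np.allclose(fp.coefficients, fnb.coefficients, atol=1e-3)

    def test_count_family_rejects_non_integers(self):
        with pytest.raises(ValueError):
            em.fit_glm(np.array([1.5, 2.0]), None, family="poisson")


class TestCandidateSuite:
    def _table(self, rng, beta=1.0, n=36):
        x = rng.normal(size=n)
        y = rng.poisson(np.exp(1.0 + beta * x))
        return pd.DataFrame({"s_obs": y, "x": x, "noise": rng.normal(size=n),
                             "n_records": rng.integers(60, 600, n),
                             "es50": 10 + 2 * x + rng.normal(0, 0.5, n)})

    def test_weights_normalized_and_rank0_delta_zero(self):
        suite = em.candidate_suite(self._table(np.random.default_rng(6)),
                                   "s_obs", ["x", "noise"])
        t = suite.table()
        assert t["akaike_weight"].sum() == pytest.approx(1.0)
        assert t["delta_aic"].iloc[0] == 0.0
        assert "intercept" in set(t["model"])

    def test_aic_identity(self):
        suite = em.candidate_suite(self._table(np.random.default_rng(7)),
                                   "s_obs", ["x", "noise"])
        for f in suite.fits:
            assert f.aic == pytest.approx(-2 * f.loglik + 2 * f.k_effective)

    def test_effort_is_candidate_for_counts_but_not_es50(self):
        tab = self._table(np.random.default_rng(8))
        s1 = em.candidate_suite(tab, "s_obs", ["x"])
        s2 = em.candidate_suite(tab, "es50", ["x"])
        assert any("log_n_records" in f.name for f in s1.fits)
        assert not any("log_n_records" in f.name for f in s2.fits)
        assert all(f.family == "gaussian" for f in s2.fits)

    def test_strong_effect_ranks_true_covariate_first(self):
        rng = np.random.default_rng(9)
        wins = sum(
            em.candidate_suite(self._table(rng, beta=1.0), "s_obs",
                               ["x", "noise"]).fits[0].name == "x"
            for _ in range(20))
        assert wins >= 18

    def test_too_few_bands_raises(self):
        tab = self._table(np.random.default_rng(10)).iloc[:2]
        with pytest.raises(ValueError):
            em.candidate_suite(tab, "s_obs", ["x"])


def _gam_data(seed, n=300, effect=1.2):
    rng = np.random.default_rng(seed)
    lat = rng.uniform(-80, 80, n)
    eta = 1.0 + effect * np.exp(-0.5 * (lat / 30) ** 2)
    th = 5.0
    y = rng.negative_binomial(th, th / (th + np.exp(eta)))
    return pd.DataFrame({"s_obs": y, "center_lat": lat,
                         "center_lon": rng.uniform(-180, 180, n),
                         "noise": rng.normal(size=n)})


class TestFitGAM:
    def test_smooth_latitude_effect_recovered(self):
        for seed in (0, 1, 2):
            df = _gam_data(seed)
            fit = em.fit_gam(df, "s_obs", ["center_lat", "noise"], spatial=None)
            cur = fit.term_curve("center_lat")
            truth = np.exp(-0.5 * (cur["x"] / 30) ** 2)
            assert np.corrcoef(cur["effect"], truth)[0, 1] > 0.9

    def test_pure_noise_smooth_shrinks(self):
        hits = 0
        for seed in range(5):
            fit = em.fit_gam(_gam_data(seed), "s_obs", ["center_lat", "noise"],
                             spatial=None)
            hits += fit.edf_by_term["noise"] < 1.5
        assert hits >= 4

    def test_infinite_penalty_collapses_smooths(self):
        df = _gam_data(3)
        fit = em.fit_gam(df, "s_obs", ["center_lat"], spatial=None,
                         lambda_grid=np.array([1e9]), theta_grid=np.array([5.0]))
        assert fit.edf_by_term["center_lat"] < 0.1

    def test_requires_enough_cells(self):
        with pytest.raises(ValueError):
            em.fit_gam(_gam_data(0, n=20), "s_obs", ["center_lat"], spatial=None)

    def test_aic_identity_and_theta_reported(self):
        fit = em.fit_gam(_gam_data(4), "s_obs", ["center_lat"], spatial=None)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.k_effective)
        assert fit.theta is not None and fit.theta > 0


class TestPredictResponse:
    def test_training_points_match_fitted_values(self):
        df = _gam_data(5)
        fit = em.fit_gam(df, "s_obs", ["center_lat"], spatial=None)
        pred = em.predict_response(fit, df)
        mu = np.exp(np.clip(fit.design.design(df) @ fit.beta, -30, 30))
        assert np.allclose(pred["predicted"], mu)
        assert not pred["extrapolation"].any()

    def test_glm_prediction_intervals(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=40)
        y = rng.poisson(np.exp(1 + 0.5 * x))
        fit = em.fit_glm(y, pd.DataFrame({"x": x}), family="poisson")
        pred = em.predict_response(fit, pd.DataFrame({"x": x}))
        assert np.allclose(pred["predicted"], fit._impl.fittedvalues, rtol=1e-8)
        assert (pred["upper"] >= pred["predicted"]).all()

    def test_interval_widens_away_from_data(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(-1, 1, 100)
        y = rng.poisson(np.exp(1 + x))
        fit = em.fit_glm(y, pd.DataFrame({"x": x}), family="poisson")
        grid = pd.DataFrame({"x": [0.0, 2.0, 4.0]})
        pred = em.predict_response(fit, grid)
        rel = (pred["upper"] - pred["lower"]) / pred["predicted"]
        assert rel.is_monotonic_increasing

    def test_unknown_covariate_raises(self):
        fit = em.fit_gam(_gam_data(6), "s_obs", ["center_lat"], spatial=None)
        with pytest.raises(KeyError):
            em.predict_response(fit, pd.DataFrame({"wrong": [1.0]}))

    def test_extrapolation_flagged(self):
        fit = em.fit_gam(_gam_data(7), "s_obs", ["center_lat"], spatial=None)
        pred = em.predict_response(fit, pd.DataFrame({"center_lat": [89.5]}))
        assert pred["extrapolation"].iloc[0]
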