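"""Estimation correctness of the five likelihood-based trend models.

Simulation oracles generate data from each model's own specification and
check recovery; closed-form oracles pin down degenerate special cases.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from tha_forecast.models import (
    FitError,
    ModelFit,
    TimeIndex,
    fit_ip,
    fit_lm,
    fit_logm,
    fit_pln,
    fit_pm,
    loglik_gradient_norm,
    pln_loglik,
)

YEARS = np.arange(2001, 2020)
T = YEARS - 2000


def as_series(values, years=YEARS):
    return pd.Series(np.asarray(values), index=pd.Index(years, name="year"))


@pytest.fixture(scope="module")
def flat_pop():
    return as_series(np.full(len(YEARS), 5_000_000.0))


class TestLM:
    def test_deterministic_self_consistency(self, flat_pop):
        # exact logistic pseudo-data: recover (-6, 0.03) within 1%
        p = special.expit(-6 + 0.03 * T)
        counts = as_series(np.round(flat_pop.values * p))
        fit = fit_lm(counts, flat_pop)
        assert fit.params["b0"] == pytest.approx(-6.0, rel=0.01)
        assert fit.params["b1"] == pytest.approx(0.03, rel=0.01)

    def test_fitted_rates_in_unit_interval(self, flat_pop):
        rng = np.random.default_rng(0)
        counts = as_series(rng.binomial(int(5e6), 2e-3, len(YEARS)))
        fit = fit_lm(counts, flat_pop)
        p_hat = special.expit(fit.params["b0"] + fit.params["b1"] * T)
        assert ((p_hat > 0) & (p_hat < 1)).all()

    def test_zero_slope_truth_unbiased(self, flat_pop):
        rng = np.random.default_rng(1)
        b1 = np.empty(200)
        for i in range(200):
            counts = as_series(rng.binomial(int(5e6), 2e-3, len(YEARS)))
            b1[i] = fit_lm(counts, flat_pop).params["b1"]
        assert abs(b1.mean()) < 3 * b1.std(ddof=1) / np.sqrt(len(b1))


class TestPM:
    def test_flat_data_closed_form_rate(self, flat_pop):
        counts = as_series(np.full(len(YEARS), 10_000.0))
        fit = fit_pm(counts, flat_pop)
        # constant counts + flat offset: slope 0, rate = total/total exactly
        assert abs(fit.params["b1"]) < 1e-8
        rate = np.exp(fit.params["b0"])
        assert rate == pytest.approx(counts.sum() / flat_pop.sum(), abs=1e-8 * rate)

    def test_offset_property(self, flat_pop):
        rng = np.random.default_rng(2)
        counts = as_series(rng.poisson(5e6 * np.exp(-6.5 + 0.02 * T)))
        f1 = fit_pm(counts, flat_pop)
        f2 = fit_pm(counts, 2 * flat_pop)
        assert f2.params["b0"] == pytest.approx(f1.params["b0"] - np.log(2), abs=1e-8)
        assert f2.params["b1"] == pytest.approx(f1.params["b1"], abs=1e-10)

    def test_wald_ci_coverage(self, flat_pop):
        rng = np.random.default_rng(3)
        covered = 0
        n_rep = 200
        for _ in range(n_rep):
            lam = flat_pop.values * np.exp(-6.5 + 0.02 * T)
            fit = fit_pm(as_series(rng.poisson(lam)), flat_pop)
            se = np.sqrt(fit.cov[1, 1])
            lo, hi = fit.params["b1"] - 1.96 * se, fit.params["b1"] + 1.96 * se
            covered += lo <= 0.02 <= hi
        assert 0.91 <= covered / n_rep <= 0.99


class TestLogM:
    def test_noise_free_interpolation(self):
        counts = as_series(70_000 + 12_000 * np.log(T))
        fit = fit_logm(counts)
        assert fit.params["alpha"] == pytest.approx(70_000, rel=1e-10)
        assert fit.params["gamma"] == pytest.approx(12_000, rel=1e-10)
        assert fit.params["sigma"] == pytest.approx(0.0, abs=1e-6)

    def test_zero_gamma_gives_sample_mean(self):
        rng = np.random.default_rng(4)
        counts = as_series(rng.normal(80_000, 500, len(YEARS)))
        fit = fit_logm(counts)
        pred_at_mean_lnt = fit.params["alpha"] + fit.params["gamma"] * fit.meta["mean_lnt"]
        assert pred_at_mean_lnt == pytest.approx(counts.mean(), rel=1e-10)

    def test_simulation_recovery(self):
        rng = np.random.default_rng(5)
        gam = np.empty(500)
        for i in range(500):
            y = 70_000 + 12_000 * np.log(T) + rng.normal(0, 800, len(T))
            gam[i] = fit_logm(as_series(y)).params["gamma"]
        assert abs(gam.mean() - 12_000) < 3 * gam.std(ddof=1) / np.sqrt(len(gam))

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError):
            fit_logm(as_series([1.0, 2.0], years=[2001, 2002]))


class TestIP:
    def test_exact_power_law(self):
        counts = as_series(1000.0 * T**0.5)
        fit = fit_ip(counts)
        assert fit.params["a"] == pytest.approx(1000.0, rel=1e-12)
        assert fit.params["b"] == pytest.approx(0.5, rel=1e-12)

    def test_flat_exponent_gives_geometric_mean(self):
        rng = np.random.default_rng(6)
        counts = as_series(np.exp(rng.normal(11, 0.05, len(YEARS))))
        fit = fit_ip(counts)
        lnt = np.log(T)
        pred_at_mean = fit.params["log_a"] + fit.params["b"] * lnt.mean()
        assert pred_at_mean == pytest.approx(np.log(counts).mean(), rel=1e-10)

    def test_simulation_recovery(self):
        rng = np.random.default_rng(7)
        bs = np.empty(500)
        for i in range(500):
            y = 65_000 * T**0.18 * np.exp(rng.normal(0, 0.01, len(T)))
            bs[i] = fit_ip(as_series(y)).params["b"]
        assert abs(bs.mean() - 0.18) < 3 * bs.std(ddof=1) / np.sqrt(len(bs))

    def test_zero_counts_rejected(self):
        with pytest.raises(FitError, match="floor"):
            fit_ip(as_series(np.r_[0.0, np.ones(len(YEARS) - 1)]))


class TestPLN:
    def test_collapses_to_pm_when_sigma_zero(self, flat_pop):
        rng = np.random.default_rng(8)
        counts = as_series(rng.poisson(flat_pop.values * np.exp(-6.0 + 0.02 * T)))
        pln = fit_pln(counts, flat_pop)
        pm = fit_pm(counts, flat_pop)
        assert pln.params["sigma"] < 1e-3
        assert pln.meta["degenerate_sigma"]
        assert pln.params["b0"] == pytest.approx(pm.params["b0"], abs=1e-3)
        assert pln.params["b1"] == pytest.approx(pm.params["b1"], abs=1e-3)

    def test_sigma_recovery(self, flat_pop):
        rng = np.random.default_rng(9)
        n_rep = 150
        sig = np.empty(n_rep)
        for i in range(n_rep):
            eps = rng.normal(0, 0.1, len(T))
            lam = flat_pop.values * np.exp(-6.0 + 0.02 * T + eps)
            sig[i] = fit_pln(as_series(rng.poisson(lam)), flat_pop).params["sigma"]
        se = sig.std(ddof=1) / np.sqrt(n_rep)
        # small-sample ML bias of a scale parameter at n=19 is O(1/n);
        # allow it on top of the Monte-Carlo band
        assert abs(sig.mean() - 0.1) < 3 * se + 0.1 / len(T)

    def test_quadrature_matches_monte_carlo(self):
        # 5-year toy series: fixed-node quadrature vs brute-force MC integral
        rng = np.random.default_rng(10)
        y = np.array([900.0, 1000.0, 1100.0, 1050.0, 1200.0])
        log_n = np.log(np.full(5, 1e6))
        t = np.arange(1.0, 6.0)
        theta = np.array([-6.9, 0.05, 0.08])
        ll_quad = pln_loglik(theta, y, log_n, t)
        n_mc = 1_000_000
        z = rng.standard_normal(n_mc)
        ll_mc = 0.0
        var_terms = []
        for yi, ln_i, ti in zip(y, log_n, t):
            lam = np.exp(ln_i + theta[0] + theta[1] * ti + theta[2] * z)
            pmf = stats.poisson.pmf(yi, lam)
            m = pmf.mean()
            ll_mc += np.log(m)
            var_terms.append(pmf.var(ddof=1) / n_mc / m**2)  # delta method on log
        se = np.sqrt(np.sum(var_terms))
        assert abs(ll_quad - ll_mc) < 3 * se

    def test_pln_loglik_dominates_pm(self, mle_fits):
        assert mle_fits["PLN"].loglik >= mle_fits["PLN"].meta["pm_loglik"] - 1e-6


class TestFitContracts:
    def test_score_vanishes_at_optimum(self, mle_fits, train, population):
        for mid, fit in mle_fits.items():
            pop = population["pop50"] if mid in ("LM", "PM", "PLN") else None
            assert loglik_gradient_norm(fit, train, pop) < 1e-4, mid

    def test_covariance_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            ModelFit("PM", {"b0": 0.0, "b1": 0.0}, ["b0", "b1"],
                     np.array([[1.0, 0.5], [0.0, 1.0]]), (2001, 2019),
                     TimeIndex(2001))

    def test_time_index_guards_origin(self):
        with pytest.raises(ValueError, match="origin"):
            TimeIndex(2001).t([2000])

    def test_serialization_round_trip(self, tmp_path, mle_fits):
        fit = mle_fits["PLN"]
        path = tmp_path / "fit.json"
        fit.to_json(path)
        back = ModelFit.from_json(path)
        assert back.params == fit.params
        np.testing.assert_allclose(back.cov, fit.cov)
        assert back.train_years == fit.train_years
        assert back.time_index == fit.time_index
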