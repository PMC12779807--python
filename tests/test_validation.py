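"""Error battery and the two validation protocols."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tha_forecast.models import fit_logm, fit_pm
from tha_forecast.validation import (
    MetricsReport,
    compute_metrics,
    fit_model,
    in_sample_metrics,
    naive_scale,
    out_of_sample_eval,
    point_forecast,
    rolling_origin,
)


def brute_force_metrics(obs, pred, scale):
    """Independent direct-formula implementation (pure python)."""
    e = [o - p for o, p in zip(obs, pred)]
    se = [x * x for x in e]
    n = len(se)
    mse = sum(se) / n
    rmse = mse**0.5
    mae = sum(abs(x) for x in e) / n
    mean_se = sum(se) / n
    sd_se = (sum((x - mean_se) ** 2 for x in se) / (n - 1)) ** 0.5 if n > 1 else 0.0

    def quantile7(xs, q):
        xs = sorted(xs)
        h = (len(xs) - 1) * q
        lo = int(h // 1)
        hi = min(lo + 1, len(xs) - 1)
        return xs[lo] + (h - lo) * (xs[hi] - xs[lo])

    iqr = quantile7(se, 0.75) - quantile7(se, 0.25)
    return dict(mse=mse, rmse=rmse, mae=mae, sd_se=sd_se, iqr_se=iqr,
                ratio_rmse=rmse / scale, ratio_mae=mae / scale)


class TestComputeMetrics:
    def test_perfect_prediction_all_zero(self):
        rep = compute_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], scale=10.0)
        assert all(v == 0.0 for v in rep.as_dict().values())

    def test_hand_arithmetic(self):
        rep = compute_metrics([3.0, 0.0], [0.0, 4.0], scale=2.0)
        assert rep.mse == pytest.approx(12.5)
        assert rep.rmse == pytest.approx(3.5355339059)
        assert rep.mae == pytest.approx(3.5)
        # squared errors (9, 16): sample SD with the n-1 denominator
        assert rep.sd_se == pytest.approx(4.9497474683)
        assert rep.ratio_rmse == pytest.approx(rep.rmse / 2.0)

    def test_against_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(2, 12))
            obs = rng.normal(0, 100, n)
            pred = rng.normal(0, 100, n)
            scale = float(rng.uniform(0.5, 50))
            ours = compute_metrics(obs, pred, scale).as_dict()
            ref = brute_force_metrics(obs.tolist(), pred.tolist(), scale)
            for k, v in ref.items():
                assert ours[k] == pytest.approx(v, rel=1e-10, abs=1e-10), k

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(st.floats(-1e5, 1e5), min_size=2, max_size=30),
        st.integers(0, 2**32 - 1),
    )
    def test_metric_inequalities(self, errors, seed):
        obs = np.asarray(errors)
        pred = np.zeros_like(obs)
        rep = compute_metrics(obs, pred, scale=1.0)
        assert rep.rmse**2 == pytest.approx(rep.mse, rel=1e-12, abs=1e-12)
        assert rep.mae <= rep.rmse + 1e-12
        assert min(rep.as_dict().values()) >= 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([1.0], [1.0, 2.0], scale=1.0)

    def test_naive_scale(self):
        s = pd.Series([10.0, 13.0, 9.0], index=[2001, 2002, 2003])
        assert naive_scale(s) == pytest.approx(3.5)


class TestRollingOrigin:
    def test_fold_count_arithmetic(self, train, population):
        res = rolling_origin(train, population, ["LogM"], initial_window=10,
                             horizon=1, step=1)
        assert len(res.folds) == 9
        origins = [f.origin_year for f in res.folds]
        assert origins == list(range(2010, 2019))
        spans = [f.train_span for f in res.folds]
        assert all(s[0] == 2001 for s in spans)  # expanding window

    def test_naive_model_matches_hand_rolled_oracle(self, train, population):
        res = rolling_origin(train, population, ["Naive"], initial_window=10,
                             horizon=1, step=1, scale=100.0)
        for fold in res.folds:
            last = float(train.loc[fold.origin_year])
            obs = train.loc[fold.test_years].to_numpy(float)
            expected = brute_force_metrics(obs.tolist(),
                                           [last] * len(obs), 100.0)
            got = fold.metrics["Naive"].as_dict()
            for k, v in expected.items():
                assert got[k] == pytest.approx(v, rel=1e-10), k

    def test_post_cutoff_years_never_trained(self, series, population):
        res = rolling_origin(series, population, ["LogM"], initial_window=10,
                             cutoff_year=2019)
        assert max(f.train_span[1] for f in res.folds) <= 2018
        assert max(y for f in res.folds for y in f.test_years) <= 2019

    def test_well_specified_model_wins(self, flat_world):
        # PM truth: PM's rolling-origin MSE beats LogM's in >= 80% of runs
        pop, _ = flat_world
        years = np.arange(2001, 2020)
        t = years - 2000
        lam = 8_000_000 * np.exp(-6.3 + 0.025 * t)
        rng = np.random.default_rng(21)
        p50 = pd.DataFrame({"pop50": pd.Series(8_000_000.0, index=years)})
        wins = 0
        n_rep = 50
        for _ in range(n_rep):
            s = pd.Series(rng.poisson(lam), index=years)
            res = rolling_origin(s, p50, ["PM", "LogM"], initial_window=10)
            wins += res.summary.loc["PM", "mse"] <= res.summary.loc["LogM", "mse"]
        assert wins / n_rep >= 0.8

    def test_fit_failure_recorded_not_fatal(self, population):
        years = np.arange(2001, 2020)
        s = pd.Series(np.r_[np.zeros(5), np.ones(14) * 50_000], index=years)
        res = rolling_origin(s, population, ["IP", "LogM"], initial_window=10)
        # IP cannot fit windows containing zero counts; LogM still scored
        assert any("IP" in f.failures for f in res.folds)
        assert all("LogM" in f.metrics for f in res.folds)


class TestOutOfSample:
    def _fits(self, series, population):
        train = series.loc[2001:2019]
        return {
            "PM": fit_pm(train, population["pop50"]),
            "LogM": fit_logm(train),
        }

    def test_perfect_forecast_zero_metrics(self, population):
        # exact log-linear data lie on the PM manifold, so the fit and its
        # out-of-sample predictions reproduce the series exactly
        years = np.arange(2001, 2024)
        t = years - 2000
        exact = 5_000_000 * np.exp(-6.0 + 0.02 * t)
        s = pd.Series(exact, index=years)
        p50 = pd.DataFrame({"pop50": pd.Series(5_000_000.0, index=years)})
        fits = {"PM": fit_pm(s.loc[2001:2019], p50["pop50"])}
        out = out_of_sample_eval(fits, s, p50)
        for frame in out.values():
            assert frame.loc["PM", "mse"] == pytest.approx(0.0, abs=1e-6)

    def test_constant_bias_closed_form(self):
        from tha_forecast.validation import compute_metrics

        obs = np.array([100.0, 110.0])
        pred = obs + 7.0
        rep = compute_metrics(obs, pred, scale=1.0)
        assert rep.mse == pytest.approx(49.0)
        assert rep.sd_se == pytest.approx(0.0)

    def test_windows_mirror_pandemic_split(self, shock_series, population):
        fits = self._fits(shock_series, population)
        out = out_of_sample_eval(fits, shock_series, population)
        assert set(out) == {(2020, 2021), (2022, 2023)}
        for m in fits:
            assert out[(2020, 2021)].loc[m, "mse"] > out[(2022, 2023)].loc[m, "mse"]

    def test_missing_observations_rejected(self, train, population):
        fits = self._fits(train.loc[2001:2019].combine_first(train), population)
        with pytest.raises(ValueError, match="missing"):
            out_of_sample_eval(fits, train, population)


class TestInSample:
    def test_training_fit_quality_ranking_consistency(self, mle_fits, train,
                                                      population):
        frame = in_sample_metrics(mle_fits, train, population)
        assert set(frame.index) == set(mle_fits)
        assert (frame["rmse"] == np.sqrt(frame["mse"])).all()
        assert (frame["mae"] <= frame["rmse"] + 1e-9).all()


class TestExpandingWindowTendency:
    def test_generating_model_mse_shrinks_with_window(self):
        # stationary truth: as the window expands the parameter-estimation
        # component of the one-step forecast error shrinks, so late folds
        # score lower MSE than early folds on average over replicates
        rng = np.random.default_rng(31)
        years = np.arange(2001, 2020)
        p50 = pd.DataFrame({"pop50": pd.Series(6_000_000.0, index=years)})
        lam = np.full(len(years), 6_000_000 * np.exp(-6.4))
        early, late = [], []
        for _ in range(150):
            s = pd.Series(rng.poisson(lam), index=years)
            res = rolling_origin(s, p50, ["PM"], initial_window=10, scale=100.0)
            mses = [f.metrics["PM"].mse for f in res.folds]
            early.append(np.mean(mses[: len(mses) // 2]))
            late.append(np.mean(mses[len(mses) // 2 :]))
        assert np.mean(late) <= np.mean(early)
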