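"""Generator contracts: determinism, conservation, Poisson structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tha_forecast.extraction import build_annual_series
from tha_forecast.synthetic import (
    AgeClassCurve,
    PopulationScenario,
    RateScenario,
    ScenarioInfeasibleError,
    SimConfig,
    counts_to_series,
    generate_annual_counts,
    generate_discharge_records,
    generate_population,
)


def _single_class_scenario(curve, start=2001, end=2010):
    return PopulationScenario(curves={"65-74": curve}, start_year=start, end_year=end)


class TestGeneratePopulation:
    def test_constant_curve_is_flat(self):
        pop = generate_population(_single_class_scenario(AgeClassCurve(10_000)))
        assert (pop["65-74"] == 10_000).all()

    def test_peak_year_is_series_maximum(self):
        pop = generate_population(
            _single_class_scenario(AgeClassCurve(10_000, 500, peak_year=2006),
                                   end=2015)
        )
        assert pop["65-74"].idxmax() == 2006
        assert pop["65-74"].max() == 10_000 + 500 * 5

    def test_aggregate_is_sum_of_classes(self):
        pop = generate_population(
            PopulationScenario(
                curves={"55-64": AgeClassCurve(5_000), "65-74": AgeClassCurve(5_000)},
                start_year=2001, end_year=2005,
            )
        )
        assert (pop["pop50"] == 10_000).all()

    def test_under50_excluded_from_aggregate(self):
        pop = generate_population(
            PopulationScenario(
                curves={"<50": AgeClassCurve(9_999), "65-74": AgeClassCurve(5_000)},
                start_year=2001, end_year=2002,
            )
        )
        assert (pop["pop50"] == 5_000).all()

    def test_infeasible_scenario_rejected(self):
        with pytest.raises(ScenarioInfeasibleError):
            generate_population(_single_class_scenario(AgeClassCurve(100, -50)))


class TestGenerateAnnualCounts:
    def test_zero_rates_give_zero_counts(self, flat_world):
        pop, _ = flat_world
        rates = RateScenario(
            base_rate={"<50": 0.0, "55-64": 0.0, "65-74": 0.0},
            female_share={"<50": 0.5, "55-64": 0.5, "65-74": 0.5},
        )
        bd = generate_annual_counts(pop, rates, seed=0)
        assert (bd["count"] == 0).all()

    def test_poisson_mean_oracle(self):
        # flat 1e6 population at rate 1e-3 over 2000 replicate years:
        # the empirical mean must sit within 3 standard errors of 1000
        pop = generate_population(
            PopulationScenario(curves={"65-74": AgeClassCurve(1_000_000)},
                               start_year=1, end_year=2000)
        )
        rates = RateScenario(base_rate={"65-74": 1e-3},
                             female_share={"65-74": 0.5}, origin_year=1)
        s = counts_to_series(generate_annual_counts(pop, rates, seed=42))
        se = np.sqrt(1000.0 / len(s))
        assert abs(s.mean() - 1000.0) < 3 * se

    def test_shock_multiplier_scales_expected_count(self):
        # flat population and rate; counts large so the Poisson CV is small
        pop = generate_population(
            PopulationScenario(curves={"65-74": AgeClassCurve(100_000_000)},
                               start_year=2018, end_year=2021)
        )
        rates = RateScenario(
            base_rate={"65-74": 1e-3}, female_share={"65-74": 0.5},
            shock_multipliers={2020: 0.84}, origin_year=2018,
        )
        s = counts_to_series(generate_annual_counts(pop, rates, seed=9))
        ratio = s[2020] / s[2019]
        se = ratio * np.sqrt(1 / s[2020] + 1 / s[2019])
        assert abs(ratio - 0.84) < 4 * se

    def test_missing_age_class_named_in_error(self, flat_world):
        pop, _ = flat_world
        rates = RateScenario(base_rate={"55-64": 1e-3},
                             female_share={"55-64": 0.5})
        with pytest.raises(KeyError, match="65-74"):
            generate_annual_counts(pop, rates, seed=0)

    def test_dispersion_consistent_with_poisson(self, flat_world):
        # overdispersion_sd = 0, no shock: the index of dispersion of
        # replicate counts must fall inside the chi-square Monte-Carlo band
        pop = generate_population(
            PopulationScenario(curves={"65-74": AgeClassCurve(2_000_000)},
                               start_year=1, end_year=600)
        )
        rates = RateScenario(base_rate={"65-74": 5e-4},
                             female_share={"65-74": 0.5}, origin_year=1)
        s = counts_to_series(generate_annual_counts(pop, rates, seed=7))
        n = len(s)
        disp = s.var(ddof=1) / s.mean()
        lo = stats.chi2.ppf(0.001, n - 1) / (n - 1)
        hi = stats.chi2.ppf(0.999, n - 1) / (n - 1)
        assert lo < disp < hi

    def test_breakdown_sums_to_total(self, breakdown, series):
        total = breakdown.groupby("year")["count"].sum()
        assert (total == series).all()


class TestGenerateDischargeRecords:
    def test_exact_record_count_no_decoys(self):
        bd = pd.DataFrame(
            {"year": [2001, 2001], "age_class": ["65-74", "75-84"],
             "sex": ["F", "M"], "count": [2, 1]}
        )
        rec = generate_discharge_records(
            bd, SimConfig(seed=0, n_distractor_per_year=0, fracture_fraction=0.0)
        )
        assert len(rec) == 3
        assert (rec[["proc_main"] + [f"proc_sec_{i}" for i in range(1, 11)]]
                .eq("81.51").any(axis=1)).all()
        diag_cols = ["diag_main"] + [f"diag_sec_{i}" for i in range(1, 6)]
        assert not rec[diag_cols].apply(
            lambda s: s.str.startswith("820")).any().any()

    def test_fracture_records_never_extracted(self):
        bd = pd.DataFrame({"year": [2005], "age_class": ["65-74"],
                           "sex": ["F"], "count": [50]})
        rec = generate_discharge_records(
            bd, SimConfig(seed=3, n_distractor_per_year=0, fracture_fraction=1.0)
        )
        assert len(rec) == 100  # n elective + n fracture
        assert build_annual_series(rec)[2005] == 50

    def test_same_seed_byte_identical(self, tmp_path, breakdown):
        sub = breakdown[breakdown["year"] <= 2002]
        cfg = SimConfig(seed=4)
        paths = []
        for i in range(2):
            p = tmp_path / f"r{i}.csv"
            generate_discharge_records(sub, cfg).to_csv(p, index=False)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_extraction_round_trip_recovers_generating_counts(self, breakdown):
        # conservation contract: no fracture or distractor leaks, no losses
        sub = breakdown[breakdown["year"].between(2001, 2004)]
        rec = generate_discharge_records(
            sub, SimConfig(seed=2, n_distractor_per_year=200, fracture_fraction=0.15)
        )
        extracted = build_annual_series(rec)
        truth = sub.groupby("year")["count"].sum()
        assert (extracted == truth).all()
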