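"""Shared fixtures: one default synthetic registry world per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tha_forecast.hpte import HPTEConfig, age_stratified_counts, fit_hpte
from tha_forecast.models import fit_ip, fit_lm, fit_logm, fit_pln, fit_pm
from tha_forecast.synthetic import (
    AgeClassCurve,
    PopulationScenario,
    RateScenario,
    counts_to_series,
    default_population_scenario,
    default_rate_scenario,
    generate_annual_counts,
    generate_population,
)

#: reduced-but-honest sampler settings used where several HPTE fits are needed
FAST_HPTE = dict(n_chains=2, n_walkers=64, n_warmup=1200, n_draws=1000, thin=25,
                 rhat_threshold=1.2)


@pytest.fixture(scope="session")
def population() -> pd.DataFrame:
    return generate_population(default_population_scenario())


@pytest.fixture(scope="session")
def rates() -> RateScenario:
    return default_rate_scenario()


@pytest.fixture(scope="session")
def breakdown(population, rates) -> pd.DataFrame:
    return generate_annual_counts(population, rates, seed=1,
                                  start_year=2001, end_year=2023)


@pytest.fixture(scope="session")
def series(breakdown) -> pd.Series:
    return counts_to_series(breakdown)


@pytest.fixture(scope="session")
def train(series) -> pd.Series:
    return series.loc[2001:2019]


@pytest.fixture(scope="session")
def counts_by_age(breakdown) -> pd.DataFrame:
    return age_stratified_counts(breakdown)


@pytest.fixture(scope="session")
def mle_fits(train, population) -> dict:
    p50 = population["pop50"]
    return {
        "LM": fit_lm(train, p50),
        "PM": fit_pm(train, p50),
        "LogM": fit_logm(train),
        "IP": fit_ip(train),
        "PLN": fit_pln(train, p50),
    }


@pytest.fixture(scope="session")
def hpte_fit(counts_by_age, population):
    return fit_hpte(
        counts_by_age.loc[2001:2019], population,
        HPTEConfig(seed=11, **FAST_HPTE), check=False,
    )


@pytest.fixture(scope="session")
def flat_world():
    """Stationary-rate world: one dominant class, no trend, no shock."""
    scenario = PopulationScenario(
        curves={"<50": AgeClassCurve(30_000_000),
                "55-64": AgeClassCurve(5_000_000),
                "65-74": AgeClassCurve(5_000_000)},
        start_year=2001, end_year=2030,
    )
    pop = generate_population(scenario)
    rates = RateScenario(
        base_rate={"<50": 0.0, "55-64": 2.0e-3, "65-74": 4.0e-3},
        female_share={"<50": 0.5, "55-64": 0.5, "65-74": 0.5},
    )
    return pop, rates


def shock_rate_scenario() -> RateScenario:
    """Pandemic-shock scenario used for the out-of-sample pattern checks.

    Stationary age-specific rates (the volume trend is purely demographic
    and nearly linear, so every trend form extrapolates it closely), a
    -16% suspension shock in 2020 with partial recovery in 2021 and a
    return to trend from 2022 - the error pattern the two validation
    windows are meant to separate.
    """
    base = default_rate_scenario()
    return RateScenario(
        base_rate=base.base_rate,
        female_share=base.female_share,
        trend=1.0,
        shock_multipliers={2020: 0.84, 2021: 0.96},
        overdispersion_sd=0.02,
        origin_year=2001,
    )


@pytest.fixture(scope="session")
def shock_series(population):
    return counts_to_series(
        generate_annual_counts(population, shock_rate_scenario(), seed=5,
                               start_year=2001, end_year=2023)
    )


def rng_for(test_seed: int) -> np.random.Generator:
    return np.random.default_rng(test_seed)
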