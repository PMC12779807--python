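"""Synthetic hospital-discharge-registry generator.

Emulates the statistical structure of a national administrative discharge
database for elective total hip arthroplasty (THA): demographic trajectories
by age class, age/sex-specific procedure rates with a multiplicative annual
trend, a pandemic-style shock year with rebound, Poisson (optionally
log-normal over-dispersed) annual counts, and record-level ICD9-CM-coded
discharge rows including fracture-coded exclusions and non-THA distractors.

Nothing here is fitted to restricted data: the defaults are loose,
documented calibrations to published national margins (annual volumes
rising from roughly 68k to 123k over 2001-2023, a -16% shock in 2020 with
rapid rebound, an age distribution concentrated in the 65-74 class).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Age classes used for population denominators. Modelling restricts to the
#: resident population aged >=50; the single "<50" class exists so that the
#: small share of younger patients seen in discharge data can be emulated.
POP_AGE_CLASSES = ["<50", "50-54", "55-64", "65-74", "75-84", ">84"]

#: Age classes of the patient demographics table (applied to record ages).
TABLE_AGE_CLASSES = ["<45", "45-54", "55-64", "65-74", "75-84", ">84"]

#: Inclusive age ranges used when drawing an integer age within a class.
_AGE_RANGES = {
    "<50": (25, 49),
    "50-54": (50, 54),
    "55-64": (55, 64),
    "65-74": (65, 74),
    "75-84": (75, 84),
    ">84": (85, 99),
}

SEXES = ["F", "M"]

THA_CODE = "81.51"
#: Distractor procedure codes: partial hip, hip revision, knee replacement,
#: femoral fixation - plausible neighbours that must never be extracted.
DISTRACTOR_PROCS = ["81.52", "81.53", "81.54", "79.35", "81.40"]
OSTEOARTHRITIS_DIAGS = ["715.15", "715.35", "715.95", "714.0"]
FRACTURE_DIAGS = ["820.21", "820.8", "820.02", "820.20"]

RECORD_COLUMNS = (
    ["year", "age", "sex", "proc_main"]
    + [f"proc_sec_{i}" for i in range(1, 11)]
    + ["diag_main"]
    + [f"diag_sec_{i}" for i in range(1, 6)]
)


class ScenarioInfeasibleError(ValueError):
    """A population scenario produced a non-positive count."""


@dataclass(frozen=True)
class AgeClassCurve:
    """Piecewise-linear population trajectory for one age class.

    ``level`` persons at the first year, changing by ``growth`` persons/yr;
    if ``peak_year`` is set, growth reverses sign after that year, producing
    a peak (for positive growth) at ``peak_year``.
    """

    level: float
    growth: float = 0.0
    peak_year: int | None = None

    def value(self, year: int, start_year: int) -> float:
        if self.peak_year is None or year <= self.peak_year:
            return self.level + self.growth * (year - start_year)
        at_peak = self.level + self.growth * (self.peak_year - start_year)
        return at_peak - self.growth * (year - self.peak_year)


@dataclass(frozen=True)
class PopulationScenario:
    """Deterministic per-age-class population trajectories over a year span."""

    curves: dict[str, AgeClassCurve]
    start_year: int = 2001
    end_year: int = 2050

    @property
    def years(self) -> range:
        return range(self.start_year, self.end_year + 1)


@dataclass(frozen=True)
class RateScenario:
    """Age/sex-specific procedure-rate surface with trend and shocks.

    ``base_rate`` is procedures per person per year in ``origin_year`` for
    each age class; ``female_share`` splits each class's expected count by
    sex; ``trend`` multiplies the rate each successive year; each entry of
    ``shock_multipliers`` scales that single year's expected count; and
    ``overdispersion_sd`` is the SD of a log-normal perturbation of the
    yearly log-mean (the over-dispersion mechanism of a Poisson log-normal
    count model).
    """

    base_rate: dict[str, float]
    female_share: dict[str, float]
    trend: float = 1.0
    shock_multipliers: dict[int, float] = field(default_factory=dict)
    overdispersion_sd: float = 0.0
    origin_year: int = 2001

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.base_rate.values()):
            raise ValueError("base rates must be >= 0")
        if any(m <= 0 for m in self.shock_multipliers.values()):
            raise ValueError("shock multipliers must be > 0")
        if self.overdispersion_sd < 0:
            raise ValueError("overdispersion_sd must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Record-level generation controls.

    ``fracture_fraction`` sets how many fracture-coded THA records (code
    81.51 accompanied by an 820.xx femoral-neck-fracture diagnosis) are
    added per year, as a fraction of the elective count for that year.
    ``n_distractor_per_year`` adds that many non-THA records per year.
    """

    seed: int = 0
    n_distractor_per_year: int = 100
    fracture_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.fracture_fraction <= 1.0:
            raise ValueError("fracture_fraction must be in [0, 1]")
        if self.n_distractor_per_year < 0:
            raise ValueError("n_distractor_per_year must be >= 0")


def default_population_scenario() -> PopulationScenario:
    """Italy-like demographic scenario, 2001-2050.

    Levels and growth are round numbers on the order of the national
    resident population by age band; peak years are staggered so the
    aggregate >=50 population rises until the mid-2030s (peak 2036) and
    declines afterwards, the demographic turning point the hierarchical
    model's forecasts should be able to track.
    """
    return PopulationScenario(
        curves={
            "<50": AgeClassCurve(34_000_000, -120_000),
            "50-54": AgeClassCurve(3_800_000, 40_000, peak_year=2028),
            "55-64": AgeClassCurve(6_900_000, 50_000, peak_year=2034),
            "65-74": AgeClassCurve(5_900_000, 45_000, peak_year=2036),
            "75-84": AgeClassCurve(3_700_000, 40_000, peak_year=2046),
            ">84": AgeClassCurve(1_100_000, 20_000),
        },
    )


def default_rate_scenario() -> RateScenario:
    """Rate surface loosely calibrated to published national margins.

    Base rates put the 2001 expected volume near 68k with the age profile
    concentrated in 65-74; the 2.2%/yr trend combined with the demographic
    scenario yields roughly +80% by 2023. The 2020 shock of 0.84 emulates
    the elective-surgery suspension with rebound multipliers slightly above
    one in 2021-2023.
    """
    return RateScenario(
        base_rate={
            "<50": 1.5e-4,
            "50-54": 8.3e-4,
            "55-64": 1.93e-3,
            "65-74": 3.86e-3,
            "75-84": 4.6e-3,
            ">84": 1.75e-3,
        },
        female_share={
            "<50": 0.40,
            "50-54": 0.42,
            "55-64": 0.48,
            "65-74": 0.57,
            "75-84": 0.65,
            ">84": 0.71,
        },
        trend=1.022,
        shock_multipliers={2020: 0.84, 2021: 1.07, 2022: 1.05, 2023: 1.03},
        overdispersion_sd=0.03,
        origin_year=2001,
    )


def generate_population(scenario: PopulationScenario) -> pd.DataFrame:
    """Evaluate the scenario's trajectories on its year span.

    Returns a frame indexed by year with one column per age class plus a
    ``pop50`` aggregate (sum of all classes except ``<50``). Deterministic.

    Raises
    ------
    ScenarioInfeasibleError
        If any trajectory is non-positive at any year.
    """
    if scenario.end_year < scenario.start_year:
        raise ValueError("empty year span")
    years = list(scenario.years)
    data = {}
    for cls, curve in scenario.curves.items():
        if not np.isfinite([curve.level, curve.growth]).all():
            raise ValueError(f"non-finite curve parameters for class {cls!r}")
        vals = np.array([curve.value(y, scenario.start_year) for y in years])
        if (vals <= 0).any():
            bad = years[int(np.argmax(vals <= 0))]
            raise ScenarioInfeasibleError(
                f"population for class {cls!r} non-positive at year {bad}"
            )
        data[cls] = vals
    pop = pd.DataFrame(data, index=pd.Index(years, name="year"))
    over50 = [c for c in pop.columns if c != "<50"]
    pop["pop50"] = pop[over50].sum(axis=1)
    return pop


def generate_annual_counts(
    pop: pd.DataFrame,
    rates: RateScenario,
    seed: int,
    start_year: int | None = None,
    end_year: int | None = None,
) -> pd.DataFrame:
    """Draw annual THA counts by year, age class and sex.

    Counts are Poisson with mean
    ``pop * base_rate * trend**(year - origin) * shock * exp(eps)`` where
    ``eps ~ Normal(0, overdispersion_sd**2)`` is drawn once per year
    (shared across classes, as a common log-normal year effect).
    Reproducible: one substream per year derived from ``seed``.

    Returns a long frame with columns year, age_class, sex, count.
    """
    classes = [c for c in pop.columns if c != "pop50"]
    missing = [c for c in classes if c not in rates.base_rate]
    if missing:
        raise KeyError(f"rate scenario missing age classes: {missing}")
    years = pop.index
    if start_year is not None or end_year is not None:
        lo = start_year if start_year is not None else years.min()
        hi = end_year if end_year is not None else years.max()
        years = years[(years >= lo) & (years <= hi)]
    rows = []
    for year in years:
        rng = np.random.default_rng([seed, int(year)])
        t = year - rates.origin_year
        eps = rng.normal(0.0, rates.overdispersion_sd) if rates.overdispersion_sd else 0.0
        shock = rates.shock_multipliers.get(int(year), 1.0)
        for cls in classes:
            mean = (
                pop.at[year, cls]
                * rates.base_rate[cls]
                * rates.trend**t
                * shock
                * np.exp(eps)
            )
            total = rng.poisson(mean) if mean > 0 else 0
            n_f = rng.binomial(total, rates.female_share.get(cls, 0.5)) if total else 0
            rows.append((int(year), cls, "F", int(n_f)))
            rows.append((int(year), cls, "M", int(total - n_f)))
    return pd.DataFrame(rows, columns=["year", "age_class", "sex", "count"])


def counts_to_series(breakdown: pd.DataFrame) -> pd.Series:
    """Aggregate a year/age_class/sex breakdown to the total annual series."""
    s = breakdown.groupby("year")["count"].sum().sort_index()
    s.name = "count"
    return s


def _ages_for_classes(classes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    ages = np.empty(len(classes), dtype=int)
    for cls in np.unique(classes):
        lo, hi = _AGE_RANGES[str(cls)]
        mask = classes == cls
        ages[mask] = rng.integers(lo, hi + 1, mask.sum())
    return ages


def generate_discharge_records(
    breakdown: pd.DataFrame, cfg: SimConfig
) -> pd.DataFrame:
    """Emit one discharge record per counted procedure, plus decoys.

    For every elective THA counted in ``breakdown`` one record is written
    with code 81.51 in the principal (or, for ~20%, a random secondary)
    procedure slot and an osteoarthritis diagnosis. Per year,
    ``round(fracture_fraction * elective)`` fracture-THA records (81.51
    plus an 820.xx diagnosis, to be excluded downstream) and
    ``n_distractor_per_year`` non-THA records are added. Output is
    CSV-writable with the fixed registry column layout and is
    deterministic given ``cfg.seed`` (one substream per year).
    """
    if (breakdown["count"] < 0).any():
        raise ValueError("negative counts")
    frames: list[pd.DataFrame] = []
    for year, per_year in breakdown.groupby("year"):
        rng = np.random.default_rng([cfg.seed, 7919, int(year)])
        per_year = per_year.sort_values(["age_class", "sex"], kind="stable")
        counts = per_year["count"].to_numpy(int)
        k_el = int(counts.sum())
        classes = np.repeat(per_year["age_class"].to_numpy(), counts)
        sexes = np.repeat(per_year["sex"].to_numpy(), counts)
        k_fx = int(round(cfg.fracture_fraction * k_el))
        k_di = cfg.n_distractor_per_year
        k = k_el + k_fx + k_di
        fx_classes = rng.choice(POP_AGE_CLASSES[2:], k_fx)  # fractures skew old
        di_classes = rng.choice(POP_AGE_CLASSES, k_di)
        all_classes = np.concatenate([classes, fx_classes, di_classes])
        df = pd.DataFrame(
            {
                "year": np.full(k, int(year)),
                "age": _ages_for_classes(all_classes, rng),
                "sex": np.concatenate([sexes, rng.choice(SEXES, k_fx + k_di)]),
            }
        )
        for c in RECORD_COLUMNS[4:]:
            df[c] = ""
        df["proc_main"] = ""
        # elective: 81.51 in the principal slot or a random secondary slot
        in_main = rng.random(k_el) < 0.8
        sec_slot = rng.integers(1, 11, k_el)
        proc_main = np.where(in_main, THA_CODE, rng.choice(DISTRACTOR_PROCS, k_el))
        df.loc[: k_el - 1, "proc_main"] = proc_main
        df.loc[: k_el - 1, "diag_main"] = rng.choice(OSTEOARTHRITIS_DIAGS, k_el)
        for i in range(1, 11):
            mask = ~in_main & (sec_slot == i)
            if mask.any():
                df.loc[np.flatnonzero(mask), f"proc_sec_{i}"] = THA_CODE
        # fracture-coded THA: 81.51 plus an 820.xx diagnosis somewhere
        fx_idx = np.arange(k_el, k_el + k_fx)
        df.loc[fx_idx, "proc_main"] = THA_CODE
        fx_in_main = rng.random(k_fx) < 0.7
        fx_slot = rng.integers(1, 6, k_fx)
        fx_diag = rng.choice(FRACTURE_DIAGS, k_fx)
        df.loc[fx_idx, "diag_main"] = np.where(
            fx_in_main, fx_diag, rng.choice(OSTEOARTHRITIS_DIAGS, k_fx)
        )
        for i in range(1, 6):
            mask = ~fx_in_main & (fx_slot == i)
            if mask.any():
                df.loc[fx_idx[mask], f"diag_sec_{i}"] = fx_diag[mask]
        # non-THA distractors; some carry the fracture diagnosis (fixation)
        di_idx = np.arange(k_el + k_fx, k)
        df.loc[di_idx, "proc_main"] = rng.choice(DISTRACTOR_PROCS, k_di)
        df.loc[di_idx, "diag_main"] = np.where(
            rng.random(k_di) < 0.3,
            rng.choice(FRACTURE_DIAGS, k_di),
            rng.choice(OSTEOARTHRITIS_DIAGS, k_di),
        )
        frames.append(df[RECORD_COLUMNS])
    if not frames:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def write_records_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def write_population_csv(pop: pd.DataFrame, path) -> None:
    """Long-format population CSV: year, age_class, population."""
    long = (
        pop.drop(columns=["pop50"])
        .reset_index()
        .melt(id_vars="year", var_name="age_class", value_name="population")
        .sort_values(["year", "age_class"], kind="stable")
    )
    long.to_csv(path, index=False)


def read_population_csv(path) -> pd.DataFrame:
    long = pd.read_csv(path)
    pop = long.pivot(index="year", columns="age_class", values="population")
    pop = pop[[c for c in POP_AGE_CLASSES if c in pop.columns]]
    pop.columns.name = None
    over50 = [c for c in pop.columns if c != "<50"]
    pop["pop50"] = pop[over50].sum(axis=1)
    return pop
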