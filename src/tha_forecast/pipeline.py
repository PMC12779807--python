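"""End-to-end orchestration: simulate -> extract -> fit -> forecast ->
validate -> report.

A :class:`RunConfig` (YAML-serialisable) names the inputs and controls
every stage; :func:`run_pipeline` executes the stages in order, writing
CSV outputs plus a manifest (config hash, seed, package version) so that
identical configuration and seed reproduce identical outputs. When no
record file is configured the synthetic registry defaults are generated
first, which makes the shipped demo configuration self-contained.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .extraction import RejectsLog, build_annual_series, build_demographics_table
from .hpte import HPTEConfig, age_stratified_counts
from .models import TimeIndex
from .synthetic import (
    SimConfig,
    counts_to_series,
    default_population_scenario,
    default_rate_scenario,
    generate_annual_counts,
    generate_discharge_records,
    generate_population,
    read_population_csv,
    write_population_csv,
    write_records_csv,
)
from .uncertainty import compute_rate_ratio, forecast_analytic, forecast_posterior, forecast_simulated
from .validation import (
    fit_model,
    in_sample_metrics,
    out_of_sample_eval,
    rolling_origin,
)

DEFAULT_MODELS = ["LM", "PM", "LogM", "IP", "PLN", "HPTE"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class RunConfig:
    """Full pipeline configuration (round-trips through YAML unchanged)."""

    out_dir: str = "results/run"
    records_csv: str | None = None  # None -> simulate with the defaults
    population_csv: str | None = None
    start_year: int = 2001
    end_year: int = 2023  # last observed year
    horizon_end: int = 2050
    cutoff_year: int = 2019  # last training year
    reference_year: int = 2019  # RR anchor (observed volume)
    models: list[str] = field(default_factory=lambda: list(DEFAULT_MODELS))
    n_sims: int = 10_000
    seed: int = 20250101
    initial_window: int = 10
    rolling_horizon: int = 1
    rolling_step: int = 1
    rolling_models: list[str] | None = None  # default: `models` minus HPTE
    hpte: dict = field(default_factory=dict)  # HPTEConfig overrides
    sim: dict = field(default_factory=dict)  # SimConfig overrides

    def __post_init__(self) -> None:
        if not (self.start_year <= self.cutoff_year <= self.end_year <= self.horizon_end):
            raise ValueError("require start <= cutoff <= end <= horizon_end")
        unknown = [m for m in self.models if m not in DEFAULT_MODELS]
        if unknown:
            raise ValueError(f"unknown models {unknown}")

    def hpte_config(self) -> HPTEConfig:
        return HPTEConfig(**{"seed": self.seed, **self.hpte})

    def sim_config(self) -> SimConfig:
        return SimConfig(**{"seed": self.seed, **self.sim})

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Run every stage; return a name -> path map of the outputs written."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    manifest = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": __version__,
        "stages": [],
    }

    # -- simulate ----------------------------------------------------------
    try:
        if cfg.records_csv is None:
            pop = generate_population(default_population_scenario())
            breakdown = generate_annual_counts(
                pop, default_rate_scenario(), cfg.seed,
                cfg.start_year, cfg.end_year,
            )
            records = generate_discharge_records(breakdown, cfg.sim_config())
            rec_path = out / "records.csv"
            pop_path = out / "population.csv"
            write_records_csv(records, rec_path)
            write_population_csv(pop, pop_path)
            outputs["records"], outputs["population"] = rec_path, pop_path
        else:
            records = pd.read_csv(cfg.records_csv, dtype={"sex": str}, keep_default_na=False)
            if cfg.population_csv is None:
                raise StageError("simulate", "missing-input",
                                 "records_csv given without population_csv")
            pop = read_population_csv(cfg.population_csv)
        manifest["stages"].append("simulate")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("simulate", "generation-failed", str(exc)) from exc

    # -- extract -----------------------------------------------------------
    try:
        rejects = RejectsLog()
        series = build_annual_series(records, (cfg.start_year, cfg.end_year), rejects)
        demo = build_demographics_table(records)
        p = out / "annual_series.csv"
        series.rename("count").to_csv(p)
        outputs["annual_series"] = p
        p = out / "demographics.csv"
        demo.to_csv(p)
        outputs["demographics"] = p
        if len(rejects):
            rejects.write(out / "rejects.log")
            outputs["rejects"] = out / "rejects.log"
        cohort_breakdown = _cohort_breakdown(records)
        manifest["stages"].append("extract")
    except Exception as exc:
        raise StageError("extract", "extraction-failed", str(exc)) from exc

    # -- fit ---------------------------------------------------------------
    train = series.loc[cfg.start_year : cfg.cutoff_year]
    ti = TimeIndex(cfg.start_year)
    counts_by_age = age_stratified_counts(cohort_breakdown)
    fits = {}
    try:
        for m in cfg.models:
            fits[m] = fit_model(m, train, pop, counts_by_age, cfg.hpte_config(), ti)
            fp = out / f"fit_{m}.json"
            fits[m].to_json(fp)
            outputs[f"fit_{m}"] = fp
        manifest["stages"].append("fit")
    except Exception as exc:
        raise StageError("fit", "fit-failed", str(exc)) from exc

    # -- forecast ----------------------------------------------------------
    try:
        years = list(range(cfg.start_year, cfg.horizon_end + 1))
        ref = float(series.loc[cfg.reference_year])
        rr_rows = []
        for m, fit in fits.items():
            if m == "LogM":
                fc = forecast_analytic(fit, years)
            elif m == "HPTE":
                fc = forecast_posterior(fit, pop, years, seed=cfg.seed)
            else:
                fc = forecast_simulated(fit, years, pop["pop50"],
                                        n_sims=cfg.n_sims, seed=cfg.seed)
            fp = out / f"forecast_{m}.csv"
            fc.to_frame(series).assign(config_hash=cfg.config_hash()).to_csv(fp, index=False)
            outputs[f"forecast_{m}"] = fp
            rr = compute_rate_ratio(fc, ref)
            rr["model_id"] = m
            rr_rows.append(rr.reset_index())
        # observed series expressed as RR too (reference-year row is 1.0)
        obs_rr = pd.DataFrame(
            {"year": series.index, "rr": series / ref,
             "lower95": np.nan, "upper95": np.nan, "model_id": "observed"}
        )
        rr_rows.append(obs_rr)
        rr_path = out / "rate_ratios.csv"
        pd.concat(rr_rows).assign(reference_year=cfg.reference_year).to_csv(
            rr_path, index=False
        )
        outputs["rate_ratios"] = rr_path
        manifest["stages"].append("forecast")
    except Exception as exc:
        raise StageError("forecast", "forecast-failed", str(exc)) from exc

    # -- validate ----------------------------------------------------------
    try:
        metrics = in_sample_metrics(fits, train, pop)
        p = out / "metrics_train.csv"
        metrics.to_csv(p)
        outputs["metrics_train"] = p
        if cfg.end_year >= 2023:
            oos = out_of_sample_eval(fits, series, pop)
            for (w0, w1), frame in oos.items():
                p = out / f"metrics_oos_{w0}_{w1}.csv"
                frame.to_csv(p)
                outputs[f"metrics_oos_{w0}_{w1}"] = p
        roll_models = (
            cfg.rolling_models
            if cfg.rolling_models is not None
            else [m for m in cfg.models if m != "HPTE"]
        )
        if roll_models:
            ro = rolling_origin(
                train, pop, roll_models,
                initial_window=cfg.initial_window,
                horizon=cfg.rolling_horizon, step=cfg.rolling_step,
                cutoff_year=cfg.cutoff_year,
                counts_by_age=counts_by_age, hpte_cfg=cfg.hpte_config(),
            )
            p = out / "rolling_folds.csv"
            ro.fold_frame().to_csv(p, index=False)
            outputs["rolling_folds"] = p
            p = out / "rolling_summary.csv"
            ro.summary.to_csv(p)
            outputs["rolling_summary"] = p
        manifest["stages"].append("validate")
    except Exception as exc:
        raise StageError("validate", "validation-failed", str(exc)) from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    outputs["manifest"] = manifest_path
    return outputs


def _cohort_breakdown(records: pd.DataFrame) -> pd.DataFrame:
    """Year/age_class/sex counts of the elective cohort (model strata)."""
    from .extraction import extract_elective

    cohort = extract_elective(records).copy()
    age = cohort["age"].astype(int)
    bins = [-1, 49, 54, 64, 74, 84, 200]
    labels = ["<50", "50-54", "55-64", "65-74", "75-84", ">84"]
    cohort["age_class"] = pd.cut(age, bins=bins, labels=labels).astype(str)
    out = (
        cohort.groupby(["year", "age_class", "sex"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return out


def make_report(out_dir: str | Path, fig_name: str = "report.png") -> Path:
    """Render the observed series, per-model forecast fans and metric tables.

    Reads the CSV outputs of :func:`run_pipeline` from ``out_dir`` and
    writes a multi-panel figure plus a plain-text table summary. Raises
    with the missing file names if the pipeline outputs are incomplete.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    series_path = out / "annual_series.csv"
    if not series_path.exists():
        raise FileNotFoundError(f"missing pipeline outputs: {series_path}")
    series = pd.read_csv(series_path, index_col="year")["count"]
    forecasts = sorted(out.glob("forecast_*.csv"))
    n_panels = max(1, len(forecasts))
    ncol = min(3, n_panels)
    nrow = int(np.ceil(n_panels / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(5 * ncol, 3.5 * nrow), squeeze=False)
    flat_axes = axes.ravel()
    if not forecasts:
        flat_axes[0].plot(series.index, series.values, "k.-")
        flat_axes[0].set_title("observed annual volumes")
    for ax, fpath in zip(flat_axes, forecasts):
        fc = pd.read_csv(fpath)
        model = fc["model_id"].iloc[0]
        ax.fill_between(fc["year"], fc["lower95"], fc["upper95"], alpha=0.3)
        ax.plot(fc["year"], fc["point"], label="forecast")
        ax.plot(series.index, series.values, "k.", ms=3, label="observed")
        ax.set_title(model)
    for ax in flat_axes[n_panels:]:
        ax.axis("off")
    fig.tight_layout()
    fig_path = out / fig_name
    fig.savefig(fig_path, dpi=110)
    plt.close(fig)

    lines = []
    for name in ["metrics_train.csv", "metrics_oos_2020_2021.csv",
                 "metrics_oos_2022_2023.csv", "rolling_summary.csv"]:
        p = out / name
        if p.exists():
            lines.append(f"== {name} ==")
            lines.append(pd.read_csv(p).to_string(index=False))
            lines.append("")
    rr = out / "rate_ratios.csv"
    if rr.exists():
        tab = pd.read_csv(rr)
        ref_year = int(tab["reference_year"].iloc[0])
        sel = tab[tab["year"].isin([ref_year, 2036, tab["year"].max()])]
        lines.append(f"== rate ratios vs {ref_year} ==")
        lines.append(sel.to_string(index=False))
    (out / "report.txt").write_text("\n".join(lines))
    return fig_path
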