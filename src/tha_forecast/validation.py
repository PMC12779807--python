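"""Model-assessment protocol: error metrics, rolling-origin and
out-of-sample validation.

The error battery pairs the usual accuracy metrics (MSE, RMSE, MAE) with
two stability metrics on the squared errors (their sample SD and their
interquartile range) and two normalised ratios (RMSE and MAE divided by a
data scale). The default scale is the mean absolute first difference of
the observed training series - a naive-forecast error scale in the spirit
of MASE - so the ratios read as "error relative to a no-model benchmark";
any positive scale can be passed instead.

Internal validation uses a rolling origin with an expanding training
window: fit on years up to the origin, forecast the next ``horizon``
years, score against the held-out observations, advance the origin. Data
after the configured cutoff (2019 by default, to keep pandemic years out
of training) never enter a training window. The out-of-sample phase
trains every model once on the full pre-cutoff window and scores 2020-2023
predictions in two blocks (2020-2021, 2022-2023).

Conventions, used everywhere: sample SD with the n-1 denominator;
quartiles by linear interpolation between order statistics (type 7).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import hpte as hpte_mod
from . import models as model_mod
from .hpte import HPTEConfig, fit_hpte, posterior_mean_path
from .models import FitError, ModelFit, TimeIndex, mean_function

METRIC_NAMES = ["mse", "rmse", "mae", "sd_se", "iqr_se", "ratio_rmse", "ratio_mae"]


@dataclass(frozen=True)
class MetricsReport:
    """The seven-number error battery."""

    mse: float
    rmse: float
    mae: float
    sd_se: float
    iqr_se: float
    ratio_rmse: float
    ratio_mae: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in METRIC_NAMES}


def naive_scale(series: pd.Series) -> float:
    """Mean absolute first difference of a series (MASE-style scale)."""
    diffs = np.abs(np.diff(np.asarray(series, dtype=float)))
    if len(diffs) == 0:
        raise ValueError("need at least 2 points to compute the naive scale")
    return float(diffs.mean())


def compute_metrics(observed, predicted, scale: float) -> MetricsReport:
    """Error battery for one prediction vector.

    ``sd_se`` uses the n-1 denominator (0.0 for a single error, where a
    sample SD is undefined); ``iqr_se`` is Q3 - Q1 of the squared errors
    with type-7 quartiles.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or len(obs) < 1:
        raise ValueError("observed and predicted must be equal-length 1-d arrays")
    if scale <= 0:
        raise ValueError("scale must be positive")
    e = obs - pred
    se = e**2
    mse = float(se.mean())
    rmse = float(np.sqrt(mse))
    mae = float(np.abs(e).mean())
    sd_se = float(se.std(ddof=1)) if len(se) > 1 else 0.0
    q1, q3 = np.percentile(se, [25.0, 75.0])
    return MetricsReport(
        mse=mse,
        rmse=rmse,
        mae=mae,
        sd_se=sd_se,
        iqr_se=float(q3 - q1),
        ratio_rmse=rmse / scale,
        ratio_mae=mae / scale,
    )


# ---------------------------------------------------------------------------
# A uniform fit/predict surface over the six models, used by the
# validation loops and the pipeline.


def fit_model(
    model_id: str,
    counts: pd.Series,
    pop: pd.DataFrame | None = None,
    counts_by_age: pd.DataFrame | None = None,
    hpte_cfg: HPTEConfig | None = None,
    time_index: TimeIndex | None = None,
) -> ModelFit:
    """Fit any of the six models on a training series.

    ``pop`` is the population frame (needs ``pop50`` for the offset models
    and the age-class columns for HPTE); ``counts_by_age`` is required for
    HPTE only and is truncated to the years of ``counts``.
    """
    pop50 = pop["pop50"] if pop is not None else None
    if model_id == "LM":
        return model_mod.fit_lm(counts, pop50, time_index)
    if model_id == "PM":
        return model_mod.fit_pm(counts, pop50, time_index)
    if model_id == "LogM":
        return model_mod.fit_logm(counts, time_index)
    if model_id == "IP":
        return model_mod.fit_ip(counts, time_index)
    if model_id == "PLN":
        return model_mod.fit_pln(counts, pop50, time_index)
    if model_id == "HPTE":
        if counts_by_age is None:
            raise ValueError("HPTE requires age-stratified counts")
        sub = counts_by_age.loc[counts.index.min() : counts.index.max()]
        return fit_hpte(sub, pop, hpte_cfg, time_index)
    if model_id == "Naive":
        # last-observed-value benchmark, useful as a validation baseline
        return ModelFit(
            "Naive",
            {"value": float(counts.sort_index().iloc[-1])},
            ["value"],
            None,
            (int(counts.index.min()), int(counts.index.max())),
            time_index or TimeIndex(int(counts.index.min())),
        )
    raise ValueError(f"unknown model {model_id!r}")


def point_forecast(fit: ModelFit, years, pop: pd.DataFrame | None = None) -> np.ndarray:
    """Point (expected-count) forecast for any fitted model."""
    if fit.model_id == "HPTE":
        if pop is None:
            raise ValueError("HPTE forecast needs the population frame")
        return posterior_mean_path(fit, pop, years)
    if fit.model_id == "Naive":
        return np.full(len(np.atleast_1d(years)), fit.params["value"])
    pop50 = pop["pop50"] if pop is not None else None
    return mean_function(fit, years, pop50)


@dataclass
class Fold:
    origin_year: int
    train_span: tuple[int, int]
    test_years: list[int]
    metrics: dict[str, MetricsReport] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)


@dataclass
class RollingOriginResult:
    folds: list[Fold]
    summary: pd.DataFrame  # rows models, columns metric battery (mean over folds)

    def fold_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.folds:
            for m, rep in f.metrics.items():
                rows.append(
                    {"origin_year": f.origin_year, "train_start": f.train_span[0],
                     "train_end": f.train_span[1], "model_id": m, **rep.as_dict()}
                )
        return pd.DataFrame(rows)


def rolling_origin(
    counts: pd.Series,
    pop: pd.DataFrame | None,
    model_ids: list[str],
    initial_window: int = 10,
    horizon: int = 1,
    step: int = 1,
    cutoff_year: int = 2019,
    counts_by_age: pd.DataFrame | None = None,
    hpte_cfg: HPTEConfig | None = None,
    scale: float | None = None,
) -> RollingOriginResult:
    """Expanding-window internal validation.

    Only years up to ``cutoff_year`` are used. For each origin the models
    are fitted on the window's years and scored on the next ``horizon``
    observed years; a fit failure is recorded for that model without
    dropping the fold for the others. The summary averages each metric
    over the folds where the model produced a forecast.
    """
    if initial_window < 5:
        raise ValueError("initial_window must be >= 5")
    series = counts.loc[counts.index <= cutoff_year].sort_index()
    years = series.index.to_numpy(int)
    first = int(years.min())
    folds: list[Fold] = []
    origin = first + initial_window - 1
    while origin + horizon <= int(years.max()):
        train = series.loc[:origin]
        test_years = [y for y in range(origin + 1, origin + horizon + 1)]
        fold = Fold(origin, (first, origin), test_years)
        fold_scale = scale if scale is not None else naive_scale(train)
        obs = series.loc[test_years].to_numpy(float)
        for m in model_ids:
            try:
                fit = fit_model(m, train, pop, counts_by_age, hpte_cfg)
                pred = point_forecast(fit, test_years, pop)
                fold.metrics[m] = compute_metrics(obs, pred, fold_scale)
            except (FitError, hpte_mod.ConvergenceError) as exc:
                fold.failures[m] = str(exc)
        folds.append(fold)
        origin += step
    rows = {}
    for m in model_ids:
        reps = [f.metrics[m] for f in folds if m in f.metrics]
        if reps:
            rows[m] = {k: float(np.mean([r.as_dict()[k] for r in reps])) for k in METRIC_NAMES}
    summary = pd.DataFrame.from_dict(rows, orient="index").rename_axis("model_id")
    return RollingOriginResult(folds, summary)


def in_sample_metrics(
    fits: dict[str, ModelFit],
    counts: pd.Series,
    pop: pd.DataFrame | None = None,
    scale: float | None = None,
) -> pd.DataFrame:
    """Goodness-of-fit battery on the training window (one row per model)."""
    scale = scale if scale is not None else naive_scale(counts)
    rows = {}
    for m, fit in fits.items():
        yrs = [y for y in counts.index if fit.train_years[0] <= y <= fit.train_years[1]]
        pred = point_forecast(fit, yrs, pop)
        rows[m] = compute_metrics(counts.loc[yrs].to_numpy(float), pred, scale).as_dict()
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("model_id")


def out_of_sample_eval(
    fits: dict[str, ModelFit],
    observed: pd.Series,
    pop: pd.DataFrame | None = None,
    windows: tuple[tuple[int, int], ...] = ((2020, 2021), (2022, 2023)),
    scale: float | None = None,
) -> dict[tuple[int, int], pd.DataFrame]:
    """Score pre-cutoff fits against post-cutoff observations per window.

    Each window is scored separately (pandemic years versus recovery
    years). Returns one metric frame (rows = models) per window.
    """
    out = {}
    for w0, w1 in windows:
        yrs = list(range(w0, w1 + 1))
        missing = [y for y in yrs if y not in observed.index]
        if missing:
            raise ValueError(f"observed values missing for {missing}")
        obs = observed.loc[yrs].to_numpy(float)
        rows = {}
        for m, fit in fits.items():
            pred = point_forecast(fit, yrs, pop)
            w_scale = scale if scale is not None else naive_scale(observed.loc[: fit.train_years[1]])
            rows[m] = compute_metrics(obs, pred, w_scale).as_dict()
        out[(w0, w1)] = pd.DataFrame.from_dict(rows, orient="index").rename_axis("model_id")
    return out
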