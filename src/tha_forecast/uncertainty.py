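"""Forecasts with 95% prediction intervals, and rate ratios vs a reference.

Each fitted model gets the interval mechanism suited to its likelihood:

* analytic Gaussian prediction intervals for the logarithmic trend
  (classical linear-model theory with the Student-t quantile and the
  leverage of the new time point);
* parametric simulation for the binomial-logit, Poisson, power-law and
  Poisson log-normal models: parameters drawn from the asymptotic normal
  sampling distribution of the MLE, pushed through the mean function, with
  observation noise from the model's own family added on top;
* the posterior predictive distribution for the hierarchical Bayesian
  model, extending the latent random walk over the horizon draw by draw.

Intervals are empirical 2.5/97.5 percentiles (linear interpolation between
order statistics, the "type 7" convention) for the stochastic mechanisms.
Rate ratios divide each year's point and interval bounds by a reference
volume (by convention the last pre-pandemic observed count).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .models import ModelFit, mean_function

_Q = (2.5, 50.0, 97.5)


@dataclass
class Forecast:
    """Per-year point forecast with a 95% prediction interval."""

    model_id: str
    table: pd.DataFrame  # index year; columns point, lower95, upper95
    method: str  # analytic | parametric-simulation | posterior-predictive
    n_sims: int | None = None
    draws: np.ndarray | None = None  # (n_years, n_sims) predictive counts
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.table
        tol = 1e-9 * np.maximum(1.0, np.abs(t["point"]))
        ok = (
            (t["lower95"] >= -tol)
            & (t["lower95"] <= t["point"] + tol)
            & (t["point"] <= t["upper95"] + tol)
        )
        if not ok.all():
            bad = t.index[~ok].tolist()
            raise ValueError(f"interval ordering violated at years {bad}")

    @property
    def years(self) -> np.ndarray:
        return self.table.index.to_numpy(int)

    def to_frame(self, observed: pd.Series | None = None) -> pd.DataFrame:
        """Supplementary-table layout: year, observed, forecast, bounds."""
        out = self.table.copy()
        out.insert(0, "observed", observed.reindex(out.index) if observed is not None else np.nan)
        out["model_id"] = self.model_id
        return out.reset_index()


def forecast_analytic(fit: ModelFit, years) -> Forecast:
    """Analytic Gaussian prediction interval for the logarithmic model."""
    if fit.model_id != "LogM":
        raise ValueError("analytic intervals are defined for the LogM fit")
    years = np.asarray(years, dtype=int)
    t_new = fit.time_index.t(years)
    lnt = np.log(t_new)
    point = fit.params["alpha"] + fit.params["gamma"] * lnt
    n, df = fit.meta["n"], fit.meta["df_resid"]
    lev = 1.0 / n + (lnt - fit.meta["mean_lnt"]) ** 2 / fit.meta["sxx"]
    s = fit.params["sigma"]
    half = stats.t.ppf(0.975, df) * s * np.sqrt(1.0 + lev)
    table = pd.DataFrame(
        {
            "point": point,
            "lower95": np.clip(point - half, 0.0, None),
            "upper95": point + half,
        },
        index=pd.Index(years, name="year"),
    )
    return Forecast("LogM", table, "analytic")


def _draw_params(fit: ModelFit, n_sims: int, rng: np.random.Generator) -> np.ndarray:
    cov = np.asarray(fit.cov, dtype=float)
    k = len(fit.param_names)
    cov = cov[:k, :k]
    # eigenvalue square root: tolerates semi-definite (incl. zero) covariances
    w, V = np.linalg.eigh((cov + cov.T) / 2)
    if w.min() < -1e-8 * max(1.0, abs(w.max())):
        raise ValueError("parameter covariance is not positive semi-definite")
    root = V * np.sqrt(np.clip(w, 0.0, None))
    return fit.theta[None, :] + rng.standard_normal((n_sims, k)) @ root.T


def forecast_simulated(
    fit: ModelFit,
    years,
    pop50: pd.Series | None = None,
    n_sims: int = 10_000,
    seed: int = 0,
    observation_noise: bool = True,
    keep_draws: bool = False,
) -> Forecast:
    """Parametric-simulation prediction intervals for LM, PM, IP and PLN.

    Parameter vectors are drawn from Normal(estimate, covariance); each is
    pushed through the model's mean function over ``years`` and observation
    noise from the model family (binomial, Poisson, log-normal, or
    Poisson over a log-normal mean) is added. The point forecast is the
    mean function at the estimate; bounds are empirical 2.5/97.5
    percentiles across simulations. ``observation_noise=False`` isolates
    the parameter-uncertainty component (used in degenerate-case tests).
    """
    if fit.model_id not in ("LM", "PM", "IP", "PLN"):
        raise ValueError(f"simulation intervals not defined for {fit.model_id}")
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    years = np.asarray(years, dtype=int)
    t = fit.time_index.t(years)
    rng = np.random.default_rng(seed)
    theta = _draw_params(fit, n_sims, rng)  # (S, k)

    if fit.model_id in ("LM", "PM", "PLN"):
        if pop50 is None:
            raise ValueError(f"{fit.model_id} needs a population projection")
        n = pop50.loc[years].to_numpy(float)[None, :]  # (1, Y)

    if fit.model_id == "LM":
        p = special.expit(theta[:, [0]] + theta[:, [1]] * t[None, :])
        sims = rng.binomial(np.broadcast_to(n, p.shape).astype(int), p) if observation_noise else n * p
    elif fit.model_id == "PM":
        lam = n * np.exp(theta[:, [0]] + theta[:, [1]] * t[None, :])
        sims = rng.poisson(lam) if observation_noise else lam
    elif fit.model_id == "PLN":
        sig = np.clip(theta[:, [2]], 0.0, None)
        log_mean = np.log(n) + theta[:, [0]] + theta[:, [1]] * t[None, :]
        if observation_noise:
            eps = rng.standard_normal(log_mean.shape) * sig
            sims = rng.poisson(np.exp(np.clip(log_mean + eps, None, 50.0)))
        else:
            sims = np.exp(log_mean + sig**2 / 2.0)
    else:  # IP
        log_mean = theta[:, [0]] + theta[:, [1]] * np.log(t)[None, :]
        if observation_noise:
            eps = rng.standard_normal(log_mean.shape) * fit.params["sdlog"]
            sims = np.exp(log_mean + eps)
        else:
            sims = np.exp(log_mean)

    sims = np.asarray(sims, dtype=float)
    lo, med, hi = np.percentile(sims, _Q, axis=0)
    point = mean_function(fit, years, pop50)
    table = pd.DataFrame(
        {
            "point": point,
            "lower95": np.minimum(np.clip(lo, 0.0, None), point),
            "upper95": np.maximum(hi, point),
            "median_sim": med,
        },
        index=pd.Index(years, name="year"),
    )
    return Forecast(
        fit.model_id, table, "parametric-simulation", n_sims=n_sims,
        draws=sims.T if keep_draws else None, meta={"seed": seed},
    )


def forecast_posterior(
    fit: ModelFit,
    pop: pd.DataFrame,
    years,
    seed: int = 0,
    observation_noise: bool = True,
    keep_draws: bool = False,
) -> Forecast:
    """Posterior-predictive forecast for the hierarchical model.

    For each retained posterior draw the latent temporal effect is extended
    over the horizon by simulating its random walk (zero drift), Poisson
    counts are drawn for every age stratum from the projected populations,
    and strata are summed. Point = posterior-predictive mean; bounds are
    2.5/97.5 percentiles across draws.
    """
    if fit.model_id != "HPTE" or fit.draws is None:
        raise ValueError("posterior-predictive forecast requires an HPTE fit")
    years = np.asarray(years, dtype=int)
    strata = fit.meta["age_classes"]
    y0, y1 = fit.meta["train_years"]
    if years.max() > pop.index.max():
        raise ValueError(
            f"horizon {years.max()} beyond population projection ({pop.index.max()})"
        )
    rw_order = fit.meta.get("rw_order", 1)
    d = fit.draws
    S = len(d)
    T = y1 - y0 + 1
    mu = d["mu"].to_numpy()
    tau_g = d["tau_gamma"].to_numpy()
    alpha = d[[f"alpha_{c}" for c in strata]].to_numpy()
    gamma_train = d[[f"gamma_{t}" for t in range(1, T + 1)]].to_numpy()
    rng = np.random.default_rng(seed)

    h_max = max(0, int(years.max()) - y1)
    gamma_fut = np.empty((S, h_max))
    prev = gamma_train[:, -1]
    prev2 = gamma_train[:, -2] if T >= 2 else prev
    for h in range(h_max):
        innov = rng.standard_normal(S) * tau_g
        nxt = (prev + innov) if rw_order == 1 else (2 * prev - prev2 + innov)
        gamma_fut[:, h] = nxt
        prev2, prev = prev, nxt

    n = pop.loc[years, strata].to_numpy(float)  # (Y, A)
    sims = np.empty((len(years), S))
    for j, yr in enumerate(years):
        g = gamma_train[:, yr - y0] if yr <= y1 else gamma_fut[:, yr - y1 - 1]
        lam = (n[j][None, :] * np.exp(mu[:, None] + alpha + g[:, None])).sum(axis=1)
        sims[j] = rng.poisson(lam) if observation_noise else lam
    lo, med, hi = np.percentile(sims, _Q, axis=1)
    point = sims.mean(axis=1)
    table = pd.DataFrame(
        {
            "point": point,
            "lower95": np.minimum(lo, point),
            "upper95": np.maximum(hi, point),
            "median_sim": med,
        },
        index=pd.Index(years, name="year"),
    )
    return Forecast(
        "HPTE", table, "posterior-predictive", n_sims=S,
        draws=sims if keep_draws else None, meta={"seed": seed},
    )


def compute_rate_ratio(
    forecast: Forecast, reference_volume: float, method: str = "bounds"
) -> pd.DataFrame:
    """Express a forecast as rate ratios versus a reference-year volume.

    ``method='bounds'`` (default) divides the point and the interval bounds
    by the (constant) reference volume; ``method='draws'`` takes type-7
    percentiles of the per-draw ratio instead, which coincides with the
    default when the reference is constant but is available for
    sensitivity checks. Returns a frame indexed by year with columns
    rr, lower95, upper95.
    """
    if reference_volume <= 0:
        raise ValueError("reference volume must be positive")
    t = forecast.table
    if method == "bounds":
        out = pd.DataFrame(
            {
                "rr": t["point"] / reference_volume,
                "lower95": t["lower95"] / reference_volume,
                "upper95": t["upper95"] / reference_volume,
            }
        )
    elif method == "draws":
        if forecast.draws is None:
            raise ValueError("forecast was built without keep_draws=True")
        ratios = forecast.draws / reference_volume
        lo, hi = np.percentile(ratios, (2.5, 97.5), axis=1)
        out = pd.DataFrame(
            {"rr": t["point"] / reference_volume, "lower95": lo, "upper95": hi},
            index=t.index,
        )
    else:
        raise ValueError(f"unknown rate-ratio method {method!r}")
    out.index.name = "year"
    return out
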