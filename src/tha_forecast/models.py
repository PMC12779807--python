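"""The five likelihood-based trend models for annual procedure volumes.

All models regress the annual elective-THA count on a time covariate
``t = year - origin_year + 1`` (so the first training year has t = 1, as
required by the logarithmic and power forms):

* ``LM``  - binomial-logit rate model: count ~ Binomial(pop50, p_t),
  logit(p_t) = b0 + b1 t. The >=50 resident population is the denominator.
* ``PM``  - Poisson regression with a log-population offset:
  count ~ Poisson(pop50 * exp(b0 + b1 t)).
* ``LogM`` - Gaussian logarithmic trend on raw counts:
  count = alpha + gamma ln t + eps, eps ~ N(0, sigma^2).
* ``IP``  - inverse/power law with multiplicative log-normal error:
  count = a t^b * exp(eps), fitted as OLS of ln count on ln t.
* ``PLN`` - Poisson log-normal: count ~ Poisson(lambda_t),
  ln lambda_t = ln pop50 + b0 + b1 t + eps_t, eps_t ~ N(0, sigma^2);
  the random effect is integrated out by fixed-node Gauss-Hermite
  quadrature and (b0, b1, sigma) estimated by marginal maximum likelihood.

The hierarchical Poisson model with temporal effects lives in
:mod:`tha_forecast.hpte`.

Each fit returns a :class:`ModelFit` holding point estimates, a parameter
covariance (or posterior draws for the Bayesian model), the maximised
log-likelihood and the time index, which downstream interval construction
consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special
from statsmodels.tools.numdiff import approx_fprime, approx_hess

MLE_MODELS = ("LM", "PM", "LogM", "IP", "PLN")
ALL_MODELS = MLE_MODELS + ("HPTE",)

GH_NODES_DEFAULT = 30


class FitError(RuntimeError):
    """Model estimation failed (non-convergence, separation, bad inputs)."""


@dataclass(frozen=True)
class TimeIndex:
    """Maps calendar years to the model time covariate t = year - origin + 1."""

    origin_year: int

    def t(self, years) -> np.ndarray:
        t = np.asarray(years, dtype=float) - self.origin_year + 1.0
        if (t < 1).any():
            raise ValueError(
                f"year before time origin {self.origin_year}: t must be >= 1"
            )
        return t


@dataclass
class ModelFit:
    """A fitted volume model and its uncertainty representation."""

    model_id: str
    params: dict[str, float]
    param_names: list[str]
    cov: np.ndarray | None
    train_years: tuple[int, int]
    time_index: TimeIndex
    loglik: float | None = None
    draws: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cov is not None:
            c = np.asarray(self.cov, dtype=float)
            if not np.allclose(c, c.T, atol=1e-8):
                raise ValueError("covariance not symmetric")
            eig = np.linalg.eigvalsh((c + c.T) / 2)
            if eig.min() < -1e-8 * max(1.0, eig.max()):
                raise ValueError("covariance not positive semi-definite")
        if self.model_id == "HPTE" and (self.draws is None or self.draws.empty):
            raise ValueError("HPTE fit requires posterior draws")

    @property
    def theta(self) -> np.ndarray:
        return np.array([self.params[p] for p in self.param_names], dtype=float)

    def to_json(self, path: str | Path, draws_path: str | Path | None = None) -> None:
        """Serialise to JSON; posterior draws go to a side CSV if present."""
        obj = {
            "model_id": self.model_id,
            "params": self.params,
            "param_names": self.param_names,
            "cov": None if self.cov is None else np.asarray(self.cov).tolist(),
            "train_years": list(self.train_years),
            "origin_year": self.time_index.origin_year,
            "loglik": self.loglik,
            "meta": {k: v for k, v in self.meta.items() if _jsonable(v)},
        }
        if self.draws is not None:
            draws_path = Path(draws_path or Path(path).with_suffix(".draws.csv"))
            self.draws.to_csv(draws_path, index=False)
            obj["draws_csv"] = draws_path.name
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelFit":
        obj = json.loads(Path(path).read_text())
        draws = None
        if obj.get("draws_csv"):
            draws = pd.read_csv(Path(path).parent / obj["draws_csv"])
        return cls(
            model_id=obj["model_id"],
            params=obj["params"],
            param_names=obj["param_names"],
            cov=None if obj["cov"] is None else np.array(obj["cov"]),
            train_years=tuple(obj["train_years"]),
            time_index=TimeIndex(obj["origin_year"]),
            loglik=obj["loglik"],
            draws=draws,
            meta=obj.get("meta", {}),
        )


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def _align(counts: pd.Series, pop50: pd.Series | None):
    counts = counts.sort_index()
    years = counts.index.to_numpy(int)
    y = counts.to_numpy(float)
    if pop50 is None:
        return years, y, None
    missing = [int(yr) for yr in years if yr not in pop50.index]
    if missing:
        raise ValueError(f"population missing for training years {missing}")
    n = pop50.loc[years].to_numpy(float)
    if (y > n).any():
        raise ValueError("counts exceed population denominator")
    return years, y, n


def _design(years: np.ndarray, time_index: TimeIndex) -> np.ndarray:
    return np.column_stack([np.ones_like(years, dtype=float), time_index.t(years)])


def fit_lm(
    counts: pd.Series, pop50: pd.Series, time_index: TimeIndex | None = None
) -> ModelFit:
    """Binomial-logit rate trend (the 'logistic regression' model)."""
    years, y, n = _align(counts, pop50)
    ti = time_index or TimeIndex(int(years.min()))
    X = _design(years, ti)
    try:
        res = sm.GLM(np.column_stack([y, n - y]), X, family=sm.families.Binomial()).fit()
    except Exception as exc:  # pragma: no cover - statsmodels raise paths vary
        raise FitError(f"LM fit failed: {exc}") from exc
    if not res.converged:
        raise FitError(f"LM did not converge: {res.mle_retvals}")
    return ModelFit(
        "LM",
        {"b0": float(res.params[0]), "b1": float(res.params[1])},
        ["b0", "b1"],
        np.asarray(res.cov_params()),
        (int(years.min()), int(years.max())),
        ti,
        loglik=float(res.llf),
        meta={"converged": bool(res.converged)},
    )


def fit_pm(
    counts: pd.Series, pop50: pd.Series, time_index: TimeIndex | None = None
) -> ModelFit:
    """Poisson regression with log-population offset."""
    years, y, n = _align(counts, pop50)
    ti = time_index or TimeIndex(int(years.min()))
    X = _design(years, ti)
    try:
        res = sm.GLM(y, X, family=sm.families.Poisson(), offset=np.log(n)).fit()
    except Exception as exc:  # pragma: no cover
        raise FitError(f"PM fit failed: {exc}") from exc
    if not res.converged:
        raise FitError(f"PM did not converge: {res.mle_retvals}")
    return ModelFit(
        "PM",
        {"b0": float(res.params[0]), "b1": float(res.params[1])},
        ["b0", "b1"],
        np.asarray(res.cov_params()),
        (int(years.min()), int(years.max())),
        ti,
        loglik=float(res.llf),
        meta={"converged": bool(res.converged)},
    )


def fit_logm(counts: pd.Series, time_index: TimeIndex | None = None) -> ModelFit:
    """Gaussian logarithmic trend fitted by ordinary least squares."""
    years, y, _ = _align(counts, None)
    if len(years) < 3:
        raise FitError("LogM needs at least 3 training points")
    ti = time_index or TimeIndex(int(years.min()))
    lnt = np.log(ti.t(years))
    X = np.column_stack([np.ones_like(lnt), lnt])
    res = sm.OLS(y, X).fit()
    sigma2 = float(res.ssr / res.df_resid)
    cov = np.zeros((3, 3))
    cov[:2, :2] = np.asarray(res.cov_params())
    cov[2, 2] = 2 * sigma2**2 / res.df_resid  # asymptotic var of sigma^2-hat
    return ModelFit(
        "LogM",
        {
            "alpha": float(res.params[0]),
            "gamma": float(res.params[1]),
            "sigma": float(np.sqrt(sigma2)),
        },
        ["alpha", "gamma", "sigma"],
        cov,
        (int(years.min()), int(years.max())),
        ti,
        loglik=float(res.llf),
        meta={
            "n": int(len(years)),
            "df_resid": int(res.df_resid),
            "mean_lnt": float(lnt.mean()),
            "sxx": float(((lnt - lnt.mean()) ** 2).sum()),
        },
    )


def fit_ip(counts: pd.Series, time_index: TimeIndex | None = None) -> ModelFit:
    """Power-law trend count = a t^b with log-normal error (log-log OLS)."""
    years, y, _ = _align(counts, None)
    if (y <= 0).any():
        raise FitError(
            "IP requires strictly positive counts; floor zero counts "
            "(e.g. replace with 0.5) before fitting"
        )
    ti = time_index or TimeIndex(int(years.min()))
    lnt = np.log(ti.t(years))
    X = np.column_stack([np.ones_like(lnt), lnt])
    res = sm.OLS(np.log(y), X).fit()
    sdlog = float(np.sqrt(res.ssr / res.df_resid)) if res.df_resid > 0 else 0.0
    return ModelFit(
        "IP",
        {
            "log_a": float(res.params[0]),
            "b": float(res.params[1]),
            "a": float(np.exp(res.params[0])),
            "sdlog": sdlog,
        },
        ["log_a", "b"],
        np.asarray(res.cov_params()),
        (int(years.min()), int(years.max())),
        ti,
        loglik=float(res.llf),
        meta={"df_resid": int(res.df_resid)},
    )


def pln_loglik(
    theta: np.ndarray,
    y: np.ndarray,
    log_n: np.ndarray,
    t: np.ndarray,
    n_nodes: int = GH_NODES_DEFAULT,
) -> float:
    """Marginal PLN log-likelihood via adaptive Gauss-Hermite quadrature.

    ``theta = (b0, b1, sigma)``. For each year the log-normal random effect
    is integrated on ``n_nodes`` Hermite nodes recentred and rescaled at
    the mode of the integrand (found by a few Newton steps). Plain
    fixed-node quadrature is unusable here: at count levels of 1e4-1e5 the
    integrand's width in the standardised effect is ~1/(sigma*sqrt(count)),
    far narrower than the node spacing. Accumulation is via log-sum-exp.
    """
    b0, b1, sigma = theta
    if sigma < 0:
        return -np.inf
    eta = log_n + b0 + b1 * t  # (T,)
    if sigma == 0.0:
        return float((y * eta - np.exp(eta) - special.gammaln(y + 1.0)).sum())
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    # Newton iterations for the mode of h(z) = log Poisson(y; e^{eta+s z}) + log phi(z)
    z = np.zeros_like(eta)
    for _ in range(50):
        th = eta + sigma * z
        grad = sigma * (y - np.exp(th)) - z
        hess = -(sigma**2) * np.exp(th) - 1.0
        step = grad / hess
        z = z - np.clip(step, -2.0, 2.0)
        if np.max(np.abs(step)) < 1e-12:
            break
    th = eta + sigma * z
    s_hat = 1.0 / np.sqrt(sigma**2 * np.exp(th) + 1.0)  # (T,)
    zi = z[:, None] + np.sqrt(2.0) * s_hat[:, None] * nodes[None, :]  # (T, K)
    th_i = eta[:, None] + sigma * zi
    h = (
        y[:, None] * th_i
        - np.exp(th_i)
        - special.gammaln(y + 1.0)[:, None]
        - 0.5 * zi**2
        - 0.5 * np.log(2.0 * np.pi)
    )
    log_int = special.logsumexp(
        h + nodes[None, :] ** 2 + np.log(weights)[None, :], axis=1
    ) + np.log(np.sqrt(2.0) * s_hat)
    return float(log_int.sum())


def fit_pln(
    counts: pd.Series,
    pop50: pd.Series,
    time_index: TimeIndex | None = None,
    n_nodes: int = GH_NODES_DEFAULT,
    sigma_floor: float = 1e-3,
) -> ModelFit:
    """Marginal MLE of the Poisson log-normal trend model.

    Optimises (b0, b1, log sigma) from a Poisson-regression start. A
    solution with sigma below ``sigma_floor`` is flagged degenerate
    (``meta['degenerate_sigma']``): the model has collapsed to plain
    Poisson and the covariance falls back to the Poisson one padded with a
    zero-variance sigma row.
    """
    pm = fit_pm(counts, pop50, time_index)
    years, y, n = _align(counts, pop50)
    ti = pm.time_index
    t = ti.t(years)
    log_n = np.log(n)

    def nll(x):
        return -pln_loglik(np.array([x[0], x[1], np.exp(x[2])]), y, log_n, t, n_nodes)

    x0 = np.array([pm.params["b0"], pm.params["b1"], np.log(0.05)])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
    res2 = optimize.minimize(nll, res.x, method="BFGS",
                             options={"gtol": 1e-8, "maxiter": 500})
    best = res2 if res2.fun <= res.fun else res
    b0, b1, sigma = best.x[0], best.x[1], float(np.exp(best.x[2]))
    ll = -float(best.fun)
    degenerate = sigma < sigma_floor
    if degenerate:
        cov = np.zeros((3, 3))
        cov[:2, :2] = pm.cov
    else:
        H = approx_hess(np.array([b0, b1, sigma]),
                        lambda th: -pln_loglik(th, y, log_n, t, n_nodes))
        try:
            cov = np.linalg.inv((H + H.T) / 2)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv((H + H.T) / 2)
        if np.linalg.eigvalsh((cov + cov.T) / 2).min() < 0:
            cov = np.linalg.pinv((H + H.T) / 2)
            cov = (cov + cov.T) / 2
            w, V = np.linalg.eigh(cov)
            cov = (V * np.clip(w, 0.0, None)) @ V.T
    return ModelFit(
        "PLN",
        {"b0": float(b0), "b1": float(b1), "sigma": float(sigma)},
        ["b0", "b1", "sigma"],
        cov,
        (int(years.min()), int(years.max())),
        ti,
        loglik=ll,
        meta={"degenerate_sigma": bool(degenerate), "n_nodes": int(n_nodes),
              "pm_loglik": pm.loglik},
    )


def mean_function(fit: ModelFit, years, pop50: pd.Series | None = None) -> np.ndarray:
    """Expected annual count under the fitted model at the point estimate.

    Offset models (LM, PM, PLN) need the >=50 population for the requested
    years; the PLN mean includes the log-normal factor exp(sigma^2 / 2).
    """
    years = np.asarray(years, dtype=int)
    t = fit.time_index.t(years)
    p = fit.params
    if fit.model_id in ("LM", "PM", "PLN"):
        if pop50 is None:
            raise ValueError(f"{fit.model_id} forecast requires a population projection")
        missing = [int(yr) for yr in years if yr not in pop50.index]
        if missing:
            raise ValueError(f"population projection missing years {missing}")
        n = pop50.loc[years].to_numpy(float)
    if fit.model_id == "LM":
        return n * special.expit(p["b0"] + p["b1"] * t)
    if fit.model_id == "PM":
        return n * np.exp(p["b0"] + p["b1"] * t)
    if fit.model_id == "PLN":
        return n * np.exp(p["b0"] + p["b1"] * t + p["sigma"] ** 2 / 2.0)
    if fit.model_id == "LogM":
        return p["alpha"] + p["gamma"] * np.log(t)
    if fit.model_id == "IP":
        return p["a"] * t ** p["b"]
    raise ValueError(f"no closed-form mean for model {fit.model_id}")


def loglik_gradient_norm(fit: ModelFit, counts: pd.Series,
                         pop50: pd.Series | None = None) -> float:
    """Max |numerical log-likelihood gradient| at the optimum, on a
    standardised scale (each component times the parameter's SE).

    Diagnostic used by the self-consistency suite: a genuine MLE should
    bring this close to zero.
    """
    years, y, n = _align(counts, pop50 if fit.model_id in ("LM", "PM", "PLN") else None)
    t = fit.time_index.t(years)

    if fit.model_id == "LM":
        def ll(th):
            eta = th[0] + th[1] * t
            pr = special.expit(eta)
            return float((y * np.log(pr) + (n - y) * np.log1p(-pr)).sum())
    elif fit.model_id == "PM":
        def ll(th):
            lam = n * np.exp(th[0] + th[1] * t)
            return float((y * np.log(lam) - lam).sum())
    elif fit.model_id == "PLN":
        log_n = np.log(n)
        nn = fit.meta.get("n_nodes", GH_NODES_DEFAULT)
        if fit.meta.get("degenerate_sigma"):
            # sigma sits on the boundary; check stationarity in (b0, b1) only
            sig = fit.params["sigma"]

            def ll(th):
                return pln_loglik(np.array([th[0], th[1], sig]), y, log_n, t, nn)
        else:

            def ll(th):
                return pln_loglik(th, y, log_n, t, nn)
    elif fit.model_id == "LogM":
        lnt = np.log(t)

        def ll(th):
            r = y - th[0] - th[1] * lnt
            return float(-0.5 * (r**2).sum())  # profile: scale-free score in (alpha, gamma)
    elif fit.model_id == "IP":
        lnt = np.log(t)
        lny = np.log(y)

        def ll(th):
            r = lny - th[0] - th[1] * lnt
            return float(-0.5 * (r**2).sum())
    else:
        raise ValueError(fit.model_id)

    theta = fit.theta
    if fit.model_id == "LogM" or (
        fit.model_id == "PLN" and fit.meta.get("degenerate_sigma")
    ):
        theta = theta[:2]
    grad = approx_fprime(theta, ll, centered=True)
    se = np.sqrt(np.clip(np.diag(np.atleast_2d(fit.cov))[: len(theta)], 1e-30, None))
    return float(np.max(np.abs(grad * se)))
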