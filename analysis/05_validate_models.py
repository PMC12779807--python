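"""Model assessment: training-set error battery, rolling-origin internal
validation, and the two-window out-of-sample evaluation.

Scores every model on (a) the 2001-2019 training window, (b) expanding
rolling-origin folds within 2001-2019, and (c) the held-out pandemic
(2020-2021) and recovery (2022-2023) windows. Writes the three metric
tables under results/validation/.
"""

from pathlib import Path

import pandas as pd

from tha_forecast.hpte import HPTEConfig, age_stratified_counts
from tha_forecast.models import ModelFit
from tha_forecast.synthetic import read_population_csv
from tha_forecast.validation import (
    in_sample_metrics,
    out_of_sample_eval,
    rolling_origin,
)

SEED = 20250101
MODELS = ("LM", "PM", "LogM", "IP", "PLN", "HPTE")
ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    series = pd.read_csv(ROOT / "extraction" / "annual_series.csv",
                         index_col="year")["count"]
    pop = read_population_csv(ROOT / "data" / "population.csv")
    breakdown = pd.read_csv(ROOT / "data" / "true_counts.csv")
    counts_by_age = age_stratified_counts(breakdown)
    train = series.loc[2001:2019]
    fits = {m: ModelFit.from_json(ROOT / "fits" / f"fit_{m}.json") for m in MODELS}
    out = ROOT / "validation"
    out.mkdir(parents=True, exist_ok=True)

    metrics = in_sample_metrics(fits, train, pop)
    metrics.to_csv(out / "metrics_train.csv")
    print("== training-set metrics (2001-2019) ==")
    print(metrics.round(3).to_string())
    print(f"best in-sample RMSE: {metrics['rmse'].idxmin()}")

    oos = out_of_sample_eval(fits, series, pop)
    for (w0, w1), frame in oos.items():
        frame.to_csv(out / f"metrics_oos_{w0}_{w1}.csv")
    comp = pd.DataFrame({
        "mse_2020_2021": oos[(2020, 2021)]["mse"],
        "mse_2022_2023": oos[(2022, 2023)]["mse"],
    })
    print("== out-of-sample MSE by window ==")
    print(comp.round(0).to_string())

    # rolling origin: MLE models each fold; the MCMC model at reduced
    # sampler settings to keep the fold loop tractable
    ro = rolling_origin(
        train, pop, list(MODELS), initial_window=10,
        counts_by_age=counts_by_age,
        hpte_cfg=HPTEConfig(seed=SEED, n_chains=2, n_warmup=1500, n_draws=1000,
                            thin=25, rhat_threshold=1.2),
    )
    ro.fold_frame().to_csv(out / "rolling_folds.csv", index=False)
    ro.summary.to_csv(out / "rolling_summary.csv")
    print("== rolling-origin mean MSE per model ==")
    print(ro.summary["mse"].round(0).to_string())


if __name__ == "__main__":
    main()
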