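"""Elective total-hip-arthroplasty volume extraction and demand forecasting.

Library layout:

- :mod:`tha_forecast.synthetic` - synthetic discharge-registry generator
- :mod:`tha_forecast.extraction` - ICD9-CM cohort extraction and demographics
- :mod:`tha_forecast.models` - the five likelihood-based trend models
- :mod:`tha_forecast.hpte` - hierarchical Poisson model with temporal effects
- :mod:`tha_forecast.uncertainty` - 95% prediction intervals and rate ratios
- :mod:`tha_forecast.validation` - error battery, rolling-origin, out-of-sample
- :mod:`tha_forecast.pipeline` - end-to-end orchestration and reporting
"""

__version__ = "0.1.0"

from importlib import resources as _resources

import pandas as _pd


def load_demographics_cells() -> "_pd.DataFrame":
    """Published national sex x age-class THA cell counts (2001-2023)."""
    with _resources.files("tha_forecast.data").joinpath(
        "italy_tha_demographics_2001_2023.csv"
    ).open() as fh:
        return _pd.read_csv(fh)


def load_volume_anchors() -> "_pd.Series":
    """Published first/last-year national elective THA volumes."""
    with _resources.files("tha_forecast.data").joinpath(
        "italy_tha_volume_anchors.csv"
    ).open() as fh:
        return _pd.read_csv(fh, index_col="year")["count"]
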