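"""Extract the elective-THA cohort from the registry and tabulate it.

Applies the inclusion rule (ICD9-CM procedure 81.51 in any slot) and the
urgency exclusion (any 820.xx femoral-neck-fracture diagnosis), writes the
annual volume series and the sex x age-class demographics table, and
verifies the extraction against the generator's true counts: the recovery
must be exact, with no fracture or distractor leakage.
"""

from pathlib import Path

import pandas as pd

from tha_forecast.extraction import (
    RejectsLog,
    build_annual_series,
    build_demographics_table,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    records = pd.read_csv(ROOT / "data" / "records.csv", keep_default_na=False)
    rejects = RejectsLog()
    series = build_annual_series(records, (2001, 2023), rejects)
    table = build_demographics_table(records)
    out = ROOT / "extraction"
    out.mkdir(parents=True, exist_ok=True)
    series.to_csv(out / "annual_series.csv")
    table.to_csv(out / "demographics.csv")
    if len(rejects):
        rejects.write(out / "rejects.log")

    truth = (
        pd.read_csv(ROOT / "data" / "true_counts.csv")
        .groupby("year")["count"].sum()
    )
    diff = (series - truth).abs().max()
    print(f"extracted {series.sum():,} elective THAs from {len(records):,} records")
    print(f"max |extracted - generated| per year: {diff} (must be 0)")
    share = table.at["65-74", "Total_pct"]
    print(f"modal age class 65-74 holds {share:.1f}% of the cohort")
    assert diff == 0


if __name__ == "__main__":
    main()
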