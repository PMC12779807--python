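"""Render the final report: observed series, six forecast fans, tables.

Collects the outputs of the previous steps into a multi-panel figure and
a plain-text table digest under results/report/.
"""

import shutil
from pathlib import Path

from tha_forecast.pipeline import make_report

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    report_dir = ROOT / "report"
    report_dir.mkdir(parents=True, exist_ok=True)
    # make_report consumes the pipeline CSV layout; stage the step outputs
    shutil.copy(ROOT / "extraction" / "annual_series.csv", report_dir)
    for p in (ROOT / "forecasts").glob("forecast_*.csv"):
        shutil.copy(p, report_dir)
    for p in (ROOT / "validation").glob("metrics_*.csv"):
        shutil.copy(p, report_dir)
    shutil.copy(ROOT / "validation" / "rolling_summary.csv", report_dir)
    fig = make_report(report_dir)
    print(f"figure: {fig}")
    print(f"tables: {report_dir / 'report.txt'}")


if __name__ == "__main__":
    main()
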