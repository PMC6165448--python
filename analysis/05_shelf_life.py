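#!/usr/bin/env python
"""Shelf-life monitoring: storage-day band trends per class.

For each class, scans the generator's band-amplitude series (30
replicates per sampling day) for significant day effects, reports the
direction of change, and fits the quadratic storage-time trend with the
Spearman acceptance rule (|r| > 0.2).  Writes results/shelflife.json
and a trend-table CSV.
"""

import json
from pathlib import Path

import pandas as pd

from hamqa import pipeline, synthetic

OUT = Path(__file__).resolve().parents[1] / "results"

DRIFTED = ["1744", "1170_1154", "1627", "1541", "3100_3020",
           "2950_2920", "2852", "1117", "966"]


def main() -> None:
    all_reports = {}
    trend_rows = []
    for k, name in enumerate(synthetic.CLASS_SPECS):
        series = pipeline.band_amplitude_series(name, n_per_day=30, seed=500 + k)
        report = pipeline.shelflife_report(series, DRIFTED)
        all_reports[name] = report
        for var, fit in report["trends"].items():
            trend_rows.append({"class": name, "variable": var, **fit})
        flagged = [r["variable"] for r in report["scan"] if r["flagged"]]
        ups = [r["variable"] for r in report["scan"] if r["flagged"] and r["direction"] > 0]
        downs = [r["variable"] for r in report["scan"] if r["flagged"] and r["direction"] < 0]
        print(f"{name}: {len(flagged)}/{len(DRIFTED)} bands change with storage; "
              f"down {downs}, up {ups}")
    OUT.mkdir(exist_ok=True)
    pipeline.save_report(all_reports, OUT / "shelflife.json")
    pd.DataFrame(trend_rows).to_csv(OUT / "trend_table.csv", index=False)
    print(f"\nreports -> {OUT / 'shelflife.json'}, {OUT / 'trend_table.csv'}")


if __name__ == "__main__":
    main()
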