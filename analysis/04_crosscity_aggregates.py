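"""Cross-city coverage aggregation: coastal versus inland risk extent.

Two aggregations of per-level coverage-area percentages, averaged over
day and night members of each city group:

1. the published reference table for the eleven major Italian cities
   (2001–2013 summers) shipped with the package — the headline result
   is that the two most dangerous levels cover more of the coastal
   cities (high 11.3 %, very high 6.0 %) than the inland ones
   (8.1 % and 3.3 %);
2. the synthetic scenes' own summaries written by 03_risk_maps.py,
   aggregated with the same machinery.

Writes results/crosscity_reference.csv and results/crosscity_synthetic.csv.
"""

from pathlib import Path

import pandas as pd

from heatrisk.report import aggregate_coverage, load_city_reference_table

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)

    ref = load_city_reference_table()
    members = [(c, p, g) for (c, p), g in ref.groupby(["city", "period"])]
    groups = dict(ref[["city", "group"]].drop_duplicates().values)
    agg = aggregate_coverage(members, groups)
    agg.to_csv(RESULTS / "crosscity_reference.csv", index=False)
    print("published 11-city aggregation (mean coverage-area %, day+night):")
    for row in agg.itertuples():
        print(f"  {row.group:>8} {row.level_name:>10}: "
              f"{row.mean_coverage_area_pct:5.1f}%  (n={row.n_members})")

    members, groups = [], {}
    for path in sorted(RESULTS.glob("summary_*_*.csv")):
        _, city, period = path.stem.rsplit("_", 2)
        members.append((city, period, pd.read_csv(path)))
        groups[city] = "coastal" if "coastal" in city else "inland"
    if members:
        synth = aggregate_coverage(members, groups)
        synth.to_csv(RESULTS / "crosscity_synthetic.csv", index=False)
        print("synthetic-scene aggregation written to crosscity_synthetic.csv")
    else:
        print("no synthetic summaries found (run 03_risk_maps.py first)")


if __name__ == "__main__":
    main()
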