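"""Zonal statistics per risk level and cross-city aggregation.

``summarize`` produces one row per risk level with the mean and SD of
summer LST over the level's pixels, the level's share of the (land)
city area, the share of the city's total and elderly population living
there, and the corresponding population densities per km².

``aggregate_coverage`` averages coverage-area percentages across
(city × period) members of named city groups — the machinery behind
coastal-versus-inland comparisons.  The packaged reference table
(:func:`load_city_reference_table`) carries published per-level summer
risk statistics for eleven major Italian cities (2001–2013), and feeds
that aggregation.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import CategoricalGrid, GeoGrid, write_grid
from .heri import LEVEL_NAMES

__all__ = [
    "summarize",
    "aggregate_coverage",
    "export_map",
    "load_city_reference_table",
]

LEVEL_ORDER = ["very low", "low", "moderate", "high", "very high"]

#: Fixed legend colours for the five risk levels (low→high).
LEVEL_PALETTE = ["#2c7bb6", "#abd9e9", "#ffffbf", "#fdae61", "#d7191c"]


def summarize(levels: CategoricalGrid, lst: GeoGrid,
              pop_total: GeoGrid, pop_elderly: GeoGrid) -> pd.DataFrame:
    """Per-risk-level zonal statistics on aligned 100-m grids.

    Empty levels yield a row of zeros (a level can simply not occur in
    a city).  Percentages are reported unrounded; round at presentation
    time.
    """
    for g in (lst, pop_total, pop_elderly):
        levels.require_aligned(g)
    valid = ~levels.nodata_mask
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("risk-level grid has no valid pixels")
    cell_km2 = (levels.cell_size / 1000.0) ** 2
    tot_all = np.nansum(np.where(valid, pop_total.values, 0.0))
    eld_all = np.nansum(np.where(valid, pop_elderly.values, 0.0))
    rows = []
    for level in range(1, 6):
        sel = (levels.codes == level) & valid
        n = int(sel.sum())
        lst_sel = lst.values[sel & ~lst.nodata_mask]
        tot = float(np.nansum(pop_total.values[sel]))
        eld = float(np.nansum(pop_elderly.values[sel]))
        area_km2 = n * cell_km2
        rows.append({
            "level": level,
            "level_name": LEVEL_NAMES[level],
            "mean_lst": float(lst_sel.mean()) if lst_sel.size else 0.0,
            "sd_lst": float(lst_sel.std(ddof=0)) if lst_sel.size else 0.0,
            "coverage_area_pct": 100.0 * n / n_valid,
            "total_pop_freq_pct": 100.0 * tot / tot_all if tot_all else 0.0,
            "elderly_pop_freq_pct": 100.0 * eld / eld_all if eld_all else 0.0,
            "total_pop_density": tot / area_km2 if n else 0.0,
            "elderly_pop_density": eld / area_km2 if n else 0.0,
            "n_pixels": n,
        })
    return pd.DataFrame(rows)


def aggregate_coverage(summaries: list[tuple[str, str, pd.DataFrame]],
                       groups: dict[str, str]) -> pd.DataFrame:
    """Mean coverage-area % per level across (city, period) group members.

    ``summaries`` holds ``(city, period, summary_frame)`` triples; each
    frame needs ``level_name`` and ``coverage_area_pct`` columns.
    ``groups`` maps city → group label (e.g. coastal / inland).  Every
    (city, period) member contributes with equal weight.
    """
    if not summaries:
        raise ValueError("no summaries to aggregate")
    unknown = sorted({c for c, _, _ in summaries} - set(groups))
    if unknown:
        raise ValueError(f"cities without a group label: {unknown}")
    records = []
    for city, period, df in summaries:
        for _, row in df.iterrows():
            records.append({
                "group": groups[city], "city": city, "period": period,
                "level_name": row["level_name"],
                "coverage_area_pct": float(row["coverage_area_pct"]),
            })
    tidy = pd.DataFrame(records)
    out = (tidy.groupby(["group", "level_name"], as_index=False)
           ["coverage_area_pct"].agg(["mean", "count"])
           .rename(columns={"mean": "mean_coverage_area_pct", "count": "n_members"}))
    out["level_name"] = pd.Categorical(out["level_name"], LEVEL_ORDER, ordered=True)
    return out.sort_values(["group", "level_name"]).reset_index(drop=True)


def load_city_reference_table() -> pd.DataFrame:
    """Published per-level summer heat-risk statistics for eleven Italian
    cities (2001–2013), day and night, with the coastal/inland grouping
    (Rome counted as inland).  Columns: city, group, period, level_name,
    mean_lst, sd_lst, coverage_area_pct, total_pop_freq_pct,
    elderly_pop_freq_pct, total_pop_density, elderly_pop_density.
    """
    with resources.files("heatrisk.data").joinpath(
            "italian_cities_heri_levels.csv").open() as fh:
        return pd.read_csv(fh)


def export_map(levels: CategoricalGrid, png_path, raster_path=None,
               title: str | None = None) -> None:
    """Render the five-level risk map to PNG with a fixed legend.

    Optionally also writes the categorical raster itself.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, ListedColormap
    from matplotlib.patches import Patch

    if levels.nodata_mask.all():
        raise ValueError("cannot render an all-nodata risk grid")
    arr = np.where(levels.nodata_mask, np.nan, levels.codes.astype(float))
    cmap = ListedColormap(LEVEL_PALETTE)
    norm = BoundaryNorm(np.arange(0.5, 6.0), cmap.N)
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(arr, cmap=cmap, norm=norm, interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])
    if title:
        ax.set_title(title)
    handles = [Patch(color=LEVEL_PALETTE[i], label=LEVEL_ORDER[i]) for i in range(5)]
    ax.legend(handles=handles, loc="lower left", fontsize=8, framealpha=0.9)
    fig.savefig(png_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    if raster_path is not None:
        write_grid(levels, raster_path)
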