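"""End-to-end city analysis: scene → hazard → risk index → summaries.

Thin orchestration over the library modules, used by the command-line
interface, the analysis drivers and the tests.  Normalization is per
city and per period (day and night are mapped separately).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import downscale
from .grids import CategoricalGrid, GeoGrid, WATER_CODE, resample_nearest
from .heri import HeriConfig, classify, combine, normalize_layer
from .population import exposure_layer, vulnerability_layer
from .report import summarize
from .synthetic import CityScene

__all__ = ["CityResult", "PeriodResult", "run_city_analysis"]


@dataclass
class PeriodResult:
    """Hazard, index, levels and the zonal summary for one period."""

    hazard: GeoGrid
    heri: GeoGrid
    levels: CategoricalGrid
    summary: pd.DataFrame
    models: downscale.ClassModelSet


@dataclass
class CityResult:
    name: str
    exposure: GeoGrid
    vulnerability: GeoGrid
    periods: dict[str, PeriodResult] = field(default_factory=dict)
    fit_report: pd.DataFrame | None = None


def run_city_analysis(scene: CityScene, model: str = "GAM",
                      periods: tuple[str, ...] = ("day", "night"),
                      config: HeriConfig | None = None,
                      min_valid_months: int = 1,
                      min_samples: int = downscale.MIN_SAMPLES) -> CityResult:
    """Run the full risk mapping for one city scene.

    Fits the chosen model family per land-cover class and period,
    predicts fine LST, builds the 100-m hazard/exposure/vulnerability
    layers, combines them into the risk index and summarizes the five
    levels.  Both model families are always fitted for the report; the
    ``model`` argument selects which one drives the hazard layer.
    """
    config = config or HeriConfig()
    stacks = {"day": scene.lst_day_monthly, "night": scene.lst_night_monthly}
    unknown = set(periods) - set(stacks)
    if unknown:
        raise ValueError(f"unknown periods {sorted(unknown)}")

    lc100 = resample_nearest(scene.land_cover, 100.0)
    water100 = (lc100.codes == WATER_CODE) & ~lc100.nodata_mask

    exposure = exposure_layer(scene.population_total, analysis_mask=water100)
    vulnerability = vulnerability_layer(
        scene.population_total, scene.municipalities, scene.elderly_fractions)
    vulnerability = exposure_layer(vulnerability, analysis_mask=water100)

    result = CityResult(name=scene.name, exposure=exposure,
                        vulnerability=vulnerability)
    fits_for_report: dict[tuple[str, str], downscale.ClassModelSet] = {}
    for period in periods:
        table = downscale.build_training_table(
            stacks[period], scene.ndvi_monthly, scene.land_cover)
        model_sets = {
            kind: downscale.fit_class_models(table, kind, min_samples=min_samples)
            for kind in ("LRM", "GAM")
        }
        for kind, ms in model_sets.items():
            fits_for_report[(period, kind)] = ms
        chosen = model_sets[model.upper()]
        pred = downscale.predict_fine_lst(chosen, scene.ndvi_monthly,
                                          scene.land_cover)
        hazard = downscale.hazard_layer(pred, min_valid_months=min_valid_months)

        mask = hazard.nodata_mask | exposure.nodata_mask | vulnerability.nodata_mask
        hz = _with_mask(hazard, mask)
        ex = _with_mask(exposure, mask)
        vu = _with_mask(vulnerability, mask)
        heri = combine(normalize_layer(hz, config.normalization),
                       normalize_layer(ex, config.normalization),
                       normalize_layer(vu, config.normalization), config)
        levels = classify(heri, config)
        summary = summarize(levels, hz, ex, vu)
        result.periods[period] = PeriodResult(
            hazard=hazard, heri=heri, levels=levels, summary=summary,
            models=chosen)
    result.fit_report = downscale.compile_fit_report(fits_for_report)
    return result


def _with_mask(grid: GeoGrid, mask: np.ndarray) -> GeoGrid:
    out = grid.copy()
    out.nodata_mask = out.nodata_mask | mask
    out.values = np.where(out.nodata_mask, np.nan, out.values)
    return out
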