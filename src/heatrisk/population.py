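"""Exposure and vulnerability layers from the population grid.

Exposure is the 100-m total-population grid itself; vulnerability is
the elderly (aged 65+) population, obtained by multiplying each pixel's
total population by the elderly fraction of the municipality the pixel
belongs to.  Elderly counts stay real-valued — a percentage applied to
a density grid — so municipality sums reproduce the administrative
elderly totals exactly.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .grids import CategoricalGrid, GeoGrid

__all__ = [
    "MissingFractionError",
    "read_elderly_fractions",
    "vulnerability_layer",
    "exposure_layer",
]


class MissingFractionError(KeyError):
    """A municipality present in the grid has no elderly fraction."""


def read_elderly_fractions(path) -> dict[int, float]:
    """Read a ``municipality_id,fraction`` CSV into a mapping."""
    out: dict[int, float] = {}
    with open(Path(path), newline="") as fh:
        for row in csv.DictReader(fh):
            out[int(row["municipality_id"])] = float(row["fraction"])
    return out


def vulnerability_layer(pop_total: GeoGrid, municipalities: CategoricalGrid,
                        fractions: dict[int, float]) -> GeoGrid:
    """Elderly population per pixel: municipal fraction × pixel total."""
    pop_total.require_aligned(municipalities)
    present = np.unique(municipalities.codes[~municipalities.nodata_mask])
    missing = [int(c) for c in present if int(c) not in fractions]
    if missing:
        raise MissingFractionError(
            f"no elderly fraction for municipality code(s) {missing}")
    bad = {m: f for m, f in fractions.items() if not 0.0 <= f <= 1.0}
    if bad:
        raise ValueError(f"elderly fractions outside [0, 1]: {bad}")
    frac = np.zeros(pop_total.shape)
    for code in present:
        frac[municipalities.codes == code] = fractions[int(code)]
    mask = pop_total.nodata_mask | municipalities.nodata_mask
    vals = np.where(mask, np.nan, pop_total.values * frac)
    return GeoGrid(vals, pop_total.cell_size, pop_total.origin, mask)


def exposure_layer(pop_total: GeoGrid,
                   analysis_mask: np.ndarray | None = None) -> GeoGrid:
    """Total population, with the mask harmonised to the analysis mask.

    ``analysis_mask`` (True = excluded) lets the caller impose the
    scene-wide water/validity mask; population mass on the remaining
    pixels is untouched.
    """
    out = pop_total.copy()
    if analysis_mask is not None:
        analysis_mask = np.asarray(analysis_mask, dtype=bool)
        if analysis_mask.shape != out.shape:
            raise ValueError("analysis mask shape does not match the grid")
        out.nodata_mask = out.nodata_mask | analysis_mask
        out.values = np.where(out.nodata_mask, np.nan, out.values)
    return out
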