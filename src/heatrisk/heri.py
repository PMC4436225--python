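"""The risk-triangle core: normalize, combine, classify.

Risk is the interaction of three sides of a triangle — hazard (summer
LST), exposure (total population) and vulnerability (elderly
population).  Each layer is first normalized to [0, 1]; the exposure
and vulnerability sides are then averaged into an "exposed and
vulnerable" layer (each weighted 50 %), which is combined with the
hazard layer (weighted 50 %):

    HERI = 0.5·H + 0.5·(0.5·E + 0.5·V) = 0.5·H + 0.25·E + 0.25·V

The index is finally split into five equal-width risk levels:
very low (≤ 0.2), low (0.2, 0.4], moderate (0.4, 0.6], high (0.6, 0.8]
and very high (> 0.8).

Normalization is min–max by default — ``(x − min)/(max − min)`` is the
only reading of "on the same scale (0 to 1)" that guarantees the full
unit interval — with the plain divide-by-range variant available as a
config switch.  Zero-population pixels are kept (zero exposure is a
valid, riskless state); they normalize to the layer minimum rather
than dropping to nodata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import CategoricalGrid, GeoGrid

__all__ = [
    "HeriConfig",
    "DegenerateLayerError",
    "normalize_layer",
    "combine",
    "classify",
    "LEVEL_NAMES",
]

LEVEL_NAMES = {1: "very low", 2: "low", 3: "moderate", 4: "high", 5: "very high"}


class DegenerateLayerError(ValueError):
    """A layer is constant: no risk gradient is expressible."""


@dataclass(frozen=True)
class HeriConfig:
    """Weights, level bounds and the normalization variant."""

    w_hazard: float = 0.5
    w_exposure_within_ev: float = 0.5
    w_vulnerability_within_ev: float = 0.5
    level_bounds: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)
    level_names: dict[int, str] = field(default_factory=lambda: dict(LEVEL_NAMES))
    normalization: str = "minmax"  # or "range" (literal divide-by-range)

    def __post_init__(self) -> None:
        if abs(self.w_exposure_within_ev + self.w_vulnerability_within_ev - 1) > 1e-9:
            raise ValueError("exposure and vulnerability weights must sum to 1")
        if not 0 <= self.w_hazard <= 1:
            raise ValueError("hazard weight must be in [0, 1]")
        b = self.level_bounds
        if len(b) != 4 or any(y <= x for x, y in zip(b, b[1:])) \
                or b[0] <= 0 or b[-1] >= 1:
            raise ValueError(f"level bounds must be strictly increasing in (0,1): {b}")
        if self.normalization not in {"minmax", "range"}:
            raise ValueError(f"unknown normalization {self.normalization!r}")


def normalize_layer(grid: GeoGrid, method: str = "minmax") -> GeoGrid:
    """Rescale a layer to [0, 1] over its unmasked pixels."""
    vals = grid.unmasked()
    if vals.size < 2:
        raise DegenerateLayerError("fewer than two valid pixels")
    lo, hi = float(vals.min()), float(vals.max())
    rng = hi - lo
    if rng <= 0:
        raise DegenerateLayerError("constant layer: no gradient to normalize")
    if method == "minmax":
        out = (grid.values - lo) / rng
    elif method == "range":
        out = grid.values / rng
    else:
        raise ValueError(f"unknown normalization {method!r}")
    out = np.where(grid.nodata_mask, np.nan, out)
    return GeoGrid(out, grid.cell_size, grid.origin, grid.nodata_mask.copy())


def combine(hazard_n: GeoGrid, exposure_n: GeoGrid, vulnerability_n: GeoGrid,
            config: HeriConfig | None = None) -> GeoGrid:
    """Weighted risk-triangle combination of the three normalized layers."""
    config = config or HeriConfig()
    hazard_n.require_aligned(exposure_n)
    hazard_n.require_aligned(vulnerability_n)
    ev = (config.w_exposure_within_ev * exposure_n.values
          + config.w_vulnerability_within_ev * vulnerability_n.values)
    heri = config.w_hazard * hazard_n.values + (1 - config.w_hazard) * ev
    mask = (hazard_n.nodata_mask | exposure_n.nodata_mask
            | vulnerability_n.nodata_mask)
    heri = np.where(mask, np.nan, heri)
    return GeoGrid(heri, hazard_n.cell_size, hazard_n.origin, mask)


def classify(heri: GeoGrid, config: HeriConfig | None = None) -> CategoricalGrid:
    """Bin the index into the five risk levels (boundaries belong below).

    Level 1 iff x ≤ 0.2, 2 iff 0.2 < x ≤ 0.4, ..., 5 iff x > 0.8.
    """
    config = config or HeriConfig()
    vals = heri.unmasked()
    tol = 1e-9
    if vals.size and (vals.min() < -tol or vals.max() > 1 + tol):
        raise ValueError(
            f"index values outside [0, 1]: range [{vals.min()}, {vals.max()}]")
    x = np.clip(heri.values, 0.0, 1.0)
    # side='left' puts exact boundary values in the lower level; the tiny
    # epsilon keeps a boundary value computed with float jitter there too
    codes = np.searchsorted(np.asarray(config.level_bounds), x - 1e-12,
                            side="left") + 1
    codes = np.where(heri.nodata_mask, 1, codes).astype(int)
    return CategoricalGrid(codes, dict(config.level_names), heri.cell_size,
                           heri.origin, heri.nodata_mask.copy())
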