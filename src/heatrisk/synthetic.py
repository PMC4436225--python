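"""Synthetic city scenes with known ground truth.

Generates the complete input stack the risk analysis consumes —
Globcover-style land cover (300 m), monthly summer NDVI (250 m), coarse
monthly day/night LST (1 km), a 100-m population grid and a municipality
partition with elderly fractions — together with the noise-free fine LST
("truth") that the downscaling stage tries to recover.

The construction mirrors the statistical structure of the real data:

* land cover is laid out in concentric urban→rural rings (built-up core,
  then progressively greener classes); a coastal preset adds a water
  stripe along one edge.  Rings are square annuli whose boundaries sit
  on the 3-km common grid, so each 1-km LST cell is pure in class;
* NDVI is the class mean plus kilometre-scale structure (a radial
  greening gradient and a per-block texture, both constant within each
  1-km block), a small seasonal sinusoid across the summer months, and
  a faint cell-level ripple;
* truth LST at 100 m is a per-class monotone *decreasing* response to
  NDVI (linear, or a saturating tanh curve for the nonlinear regime);
  coarse 1-km LST is the 10×10 block mean of the truth plus i.i.d.
  Gaussian noise — exactly the generative assumption under which
  regression downscaling is well posed;
* night LST is the day truth minus a fixed urban-heat-island offset,
  observed with smaller noise (night-time retrievals are less variable
  because the sunlight/shadow heterogeneity is absent);
* population is an exponential-decay surface from the city centre,
  rounded to whole persons by largest remainder so the city total is
  conserved exactly; municipalities are a Voronoi partition.

Everything is deterministic given ``SceneSpec.seed``.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .grids import (
    CategoricalGrid,
    GeoGrid,
    GLOBCOVER_LABELS,
    MonthlyStack,
    WATER_CODE,
    read_grid,
    resample_nearest,
    temporal_mean,
    write_grid,
)

__all__ = [
    "LinearResponse",
    "SaturatingResponse",
    "SceneSpec",
    "CityScene",
    "generate_scene",
    "default_spec",
    "save_scene",
    "load_scene",
]

SUMMER_MONTHS = [5, 6, 7, 8, 9]


@dataclass(frozen=True)
class LinearResponse:
    """LST = intercept + slope * NDVI, slope <= 0 (°C per NDVI unit)."""

    intercept: float
    slope: float

    def __call__(self, ndvi: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(ndvi, dtype=float)


@dataclass(frozen=True)
class SaturatingResponse:
    """LST = top − drop·tanh(NDVI/scale): monotone decreasing, saturating.

    The curvature is strongest near NDVI ≈ 0 and the response flattens
    for dense vegetation, the kind of nonlinearity a straight line
    cannot capture but a penalized spline can.
    """

    top: float
    drop: float
    scale: float

    def __call__(self, ndvi: np.ndarray) -> np.ndarray:
        return self.top - self.drop * np.tanh(np.asarray(ndvi, dtype=float) / self.scale)


Response = LinearResponse | SaturatingResponse


@dataclass
class SceneSpec:
    """Recipe for one synthetic city.

    ``shape`` is the scene size in 100-m cells and must be a multiple of
    30 in both axes so the 250-m, 300-m and 1-km layers tile the same
    extent exactly.  ``classes`` are laid out as concentric rings from
    the centre outwards, in list order (put the built-up class first).
    """

    name: str = "synthville"
    shape: tuple[int, int] = (300, 300)
    layout: str = "concentric"
    classes: tuple[int, ...] = (190, 14, 20, 50, 130)
    ndvi_class_means: dict[int, float] = field(default_factory=lambda: {
        190: 0.12, 14: 0.28, 20: 0.40, 50: 0.52, 130: 0.46,
    })
    lst_response: dict[int, Response] = field(default_factory=lambda: {
        190: LinearResponse(31.0, -3.5),
        14: LinearResponse(32.0, -10.0),
        20: SaturatingResponse(34.0, 14.0, 0.35),
        50: SaturatingResponse(35.0, 16.0, 0.40),
        130: LinearResponse(30.5, -7.3),
    })
    day_night_offset: float = 13.0
    noise_sd: float = 1.0
    night_noise_sd: float | None = None  # defaults to 0.4 × noise_sd
    ndvi_gradient: float = 0.12          # radial NDVI rise centre→edge
    ndvi_seasonal_amp: float = 0.03
    ndvi_block_sd: float = 0.06          # 1-km block-level NDVI texture
    ndvi_ripple_sd: float = 0.005        # cell-level NDVI texture
    coastal_water_frac: float = 0.0      # fraction of columns flooded (east edge)
    pop_total: int = 350_000
    pop_decay: float = 2_000.0           # e-folding distance, metres
    n_municipalities: int = 5
    elderly_fractions: tuple[float, ...] = (0.18, 0.20, 0.21, 0.22, 0.24)
    months: tuple[int, ...] = tuple(SUMMER_MONTHS)
    seed: int = 0

    def validate(self) -> None:
        rows, cols = self.shape
        if rows % 30 or cols % 30:
            raise ValueError(f"shape must be a multiple of 30 cells, got {self.shape}")
        if not self.classes:
            raise ValueError("at least one land-cover class is required")
        for c in self.classes:
            if c not in self.ndvi_class_means:
                raise ValueError(f"class {c} has no NDVI mean")
            if c not in self.lst_response:
                raise ValueError(f"class {c} has no LST response")
        for c, resp in self.lst_response.items():
            if isinstance(resp, LinearResponse) and resp.slope > 0:
                raise ValueError(f"class {c}: LST-NDVI slope must be <= 0")
        if any(not 0.0 <= f <= 1.0 for f in self.elderly_fractions):
            raise ValueError("elderly fractions must lie in [0, 1]")
        if len(self.elderly_fractions) != self.n_municipalities:
            raise ValueError("need one elderly fraction per municipality")
        if self.pop_total < 0 or self.noise_sd < 0:
            raise ValueError("pop_total and noise_sd must be non-negative")
        if not 0.0 <= self.coastal_water_frac < 1.0:
            raise ValueError("coastal_water_frac must be in [0, 1)")

    @property
    def night_sd(self) -> float:
        return self.noise_sd * 0.4 if self.night_noise_sd is None else self.night_noise_sd


@dataclass
class CityScene:
    """The full input bundle for one city, plus synthetic ground truth."""

    name: str
    land_cover: CategoricalGrid          # 300 m native
    ndvi_monthly: MonthlyStack           # 250 m
    lst_day_monthly: MonthlyStack        # 1 km
    lst_night_monthly: MonthlyStack      # 1 km
    population_total: GeoGrid            # 100 m, persons per cell
    municipalities: CategoricalGrid      # 100 m
    elderly_fractions: dict[int, float]
    truth_lst_day: GeoGrid | None = None   # 100 m, noise-free summer mean
    truth_lst_night: GeoGrid | None = None


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _cell_centres(n: int, cell: float) -> np.ndarray:
    return (np.arange(n) + 0.5) * cell


def _radial_distance(rows: int, cols: int, cell: float) -> np.ndarray:
    """Distance (m) of each cell centre from the scene centre."""
    y = _cell_centres(rows, cell) - rows * cell / 2.0
    x = _cell_centres(cols, cell) - cols * cell / 2.0
    return np.hypot(*np.meshgrid(y, x, indexing="ij"))


def _chebyshev_distance(rows: int, cols: int, cell: float) -> np.ndarray:
    """Chebyshev (square-ring) distance of cell centres from the centre."""
    y = np.abs(_cell_centres(rows, cell) - rows * cell / 2.0)
    x = np.abs(_cell_centres(cols, cell) - cols * cell / 2.0)
    return np.maximum(*np.meshgrid(y, x, indexing="ij"))


def _land_cover(spec: SceneSpec, rng: np.random.Generator) -> CategoricalGrid:
    rows100, cols100 = spec.shape
    extent_y, extent_x = rows100 * 100.0, cols100 * 100.0
    nr, nc = int(extent_y / 300.0), int(extent_x / 300.0)
    k = len(spec.classes)
    if spec.layout == "concentric":
        # square annuli of equal width; with a default-sized scene the
        # ring boundaries land on the 3-km grid, so every 1-km LST cell
        # contains a single land-cover class
        d = _chebyshev_distance(nr, nc, 300.0)
        rmax = min(extent_y, extent_x) / 2.0
        ring = np.minimum((d / (rmax / k)).astype(int), k - 1)
        codes = np.asarray(spec.classes)[ring]
    elif spec.layout == "blobs":
        n_blobs = 4 * k
        sy = rng.uniform(0, extent_y, n_blobs)
        sx = rng.uniform(0, extent_x, n_blobs)
        yy = _cell_centres(nr, 300.0)[:, None]
        xx = _cell_centres(nc, 300.0)[None, :]
        dist = np.stack([np.hypot(yy - y0, xx - x0) for y0, x0 in zip(sy, sx)])
        nearest = np.argmin(dist, axis=0)
        codes = np.asarray(spec.classes)[nearest % k]
    else:
        raise ValueError(f"unknown layout {spec.layout!r}")
    if spec.coastal_water_frac > 0:
        n_water = max(1, int(round(nc * spec.coastal_water_frac)))
        codes[:, nc - n_water:] = WATER_CODE
    labels = {int(c): GLOBCOVER_LABELS.get(int(c), f"C{int(c)}")
              for c in np.unique(codes)}
    return CategoricalGrid(codes.astype(int), labels, 300.0, (0.0, extent_y))


def _seasonal(month: int, amp: float) -> float:
    # NDVI peaks in early summer and declines towards September
    return amp * math.cos(2.0 * math.pi * (month - 5) / 12.0)


def _ndvi_monthly(spec: SceneSpec, lc250: CategoricalGrid,
                  rng: np.random.Generator) -> MonthlyStack:
    nr, nc = lc250.shape
    extent_y = spec.shape[0] * 100.0
    base = np.zeros((nr, nc))
    for c in spec.classes:
        base[lc250.codes == c] = spec.ndvi_class_means[c]
    # kilometre-scale structure is kept block-constant at 1 km so the
    # coarse LST block means remain an exact function of the fine NDVI
    # within each class (no regression attenuation by construction)
    iby = np.floor(_cell_centres(nr, 250.0) / 1000.0).astype(int)
    ibx = np.floor(_cell_centres(nc, 250.0) / 1000.0).astype(int)
    nby, nbx = iby.max() + 1, ibx.max() + 1
    cy = (iby[:, None] + 0.5) / nby - 0.5
    cx = (ibx[None, :] + 0.5) / nbx - 0.5
    radial = spec.ndvi_gradient * 2.0 * np.hypot(cy, cx)
    texture = rng.normal(0.0, spec.ndvi_block_sd, size=(nby, nbx))[
        np.ix_(iby, ibx)] if spec.ndvi_block_sd > 0 else 0.0
    ripple = (rng.normal(0.0, spec.ndvi_ripple_sd, size=(nr, nc))
              if spec.ndvi_ripple_sd > 0 else 0.0)
    water = (lc250.codes == WATER_CODE) & ~lc250.nodata_mask
    grids = []
    for m in spec.months:
        vals = base + radial + texture + ripple + _seasonal(m, spec.ndvi_seasonal_amp)
        vals = np.clip(vals, -0.1, 0.9)
        vals[water] = np.nan
        grids.append(GeoGrid(vals, 250.0, (0.0, extent_y), water.copy()))
    return MonthlyStack(list(spec.months), grids)


def _truth_lst(spec: SceneSpec, lc100: CategoricalGrid,
               ndvi100: GeoGrid) -> GeoGrid:
    vals = np.full(lc100.shape, np.nan)
    for c in spec.classes:
        sel = (lc100.codes == c) & ~ndvi100.nodata_mask
        vals[sel] = spec.lst_response[c](ndvi100.values[sel])
    mask = ~np.isfinite(vals)
    return GeoGrid(vals, 100.0, ndvi100.origin, mask)


def _block_mean(fine: GeoGrid, factor: int) -> GeoGrid:
    """Aggregate a fine grid to coarse cells by the mean of valid cells."""
    nr, nc = fine.shape
    vals = fine.values.reshape(nr // factor, factor, nc // factor, factor)
    mask = fine.nodata_mask.reshape(nr // factor, factor, nc // factor, factor)
    valid = (~mask).sum(axis=(1, 3))
    summed = np.where(mask, 0.0, np.nan_to_num(vals)).sum(axis=(1, 3))
    with np.errstate(invalid="ignore"):
        mean = np.where(valid > 0, summed / np.maximum(valid, 1), np.nan)
    return GeoGrid(mean, fine.cell_size * factor, fine.origin, valid == 0)


def _population(spec: SceneSpec, water100: np.ndarray) -> GeoGrid:
    rows, cols = spec.shape
    extent_y = rows * 100.0
    d = _radial_distance(rows, cols, 100.0)
    weight = np.exp(-d / spec.pop_decay)
    weight[water100] = 0.0
    total_w = weight.sum()
    if spec.pop_total == 0 or total_w == 0:
        vals = np.zeros((rows, cols))
    else:
        ideal = weight / total_w * spec.pop_total
        vals = _largest_remainder(ideal, spec.pop_total)
    return GeoGrid(vals.astype(float), 100.0, (0.0, extent_y), water100.copy())


def _largest_remainder(ideal: np.ndarray, total: int) -> np.ndarray:
    """Round a non-negative array to integers preserving its sum exactly."""
    floors = np.floor(ideal)
    deficit = int(round(total - floors.sum()))
    if deficit > 0:
        remainders = (ideal - floors).ravel()
        take = np.argsort(-remainders, kind="stable")[:deficit]
        flat = floors.ravel()
        flat[take] += 1
        floors = flat.reshape(ideal.shape)
    return floors


def _municipalities(spec: SceneSpec, water100: np.ndarray,
                    rng: np.random.Generator) -> CategoricalGrid:
    rows, cols = spec.shape
    extent_y = rows * 100.0
    # Voronoi partition around random interior seed points: contiguous,
    # irregular regions standing in for municipal boundaries
    sy = rng.uniform(0.1, 0.9, spec.n_municipalities) * rows * 100.0
    sx = rng.uniform(0.1, 0.9, spec.n_municipalities) * cols * 100.0
    yy = _cell_centres(rows, 100.0)[:, None]
    xx = _cell_centres(cols, 100.0)[None, :]
    dist = np.stack([np.hypot(yy - y0, xx - x0) for y0, x0 in zip(sy, sx)])
    codes = (np.argmin(dist, axis=0) + 1).astype(int)
    labels = {i + 1: f"M{i + 1}" for i in range(spec.n_municipalities)}
    return CategoricalGrid(codes, labels, 100.0, (0.0, extent_y))


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

def generate_scene(spec: SceneSpec) -> CityScene:
    """Build a complete deterministic :class:`CityScene` from a spec."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape
    extent_y = rows * 100.0

    land_cover = _land_cover(spec, rng)
    lc250 = resample_nearest(land_cover, 250.0)
    lc100 = resample_nearest(land_cover, 100.0)
    water100 = (lc100.codes == WATER_CODE) & ~lc100.nodata_mask

    ndvi_monthly = _ndvi_monthly(spec, lc250, rng)

    truth_day_months, truth_night_months = [], []
    lst_day, lst_night = [], []
    for month, ndvi in ndvi_monthly:
        ndvi100 = resample_nearest(ndvi, 100.0)
        t_day = _truth_lst(spec, lc100, ndvi100)
        t_night = GeoGrid(t_day.values - spec.day_night_offset, 100.0,
                          t_day.origin, t_day.nodata_mask.copy())
        truth_day_months.append(t_day)
        truth_night_months.append(t_night)
        coarse_day = _block_mean(t_day, 10)
        coarse_night = _block_mean(t_night, 10)
        for coarse, sd in ((coarse_day, spec.noise_sd), (coarse_night, spec.night_sd)):
            if sd > 0:
                noise = rng.normal(0.0, sd, size=coarse.shape)
                coarse.values = np.where(coarse.nodata_mask, np.nan,
                                         coarse.values + noise)
        lst_day.append(coarse_day)
        lst_night.append(coarse_night)

    months = list(spec.months)
    truth_day = temporal_mean(MonthlyStack(months, truth_day_months))
    truth_night = temporal_mean(MonthlyStack(months, truth_night_months))

    population = _population(spec, water100)
    municipalities = _municipalities(spec, water100, rng)
    fractions = {i + 1: float(f) for i, f in enumerate(spec.elderly_fractions)}

    return CityScene(
        name=spec.name,
        land_cover=land_cover,
        ndvi_monthly=ndvi_monthly,
        lst_day_monthly=MonthlyStack(months, lst_day),
        lst_night_monthly=MonthlyStack(months, lst_night),
        population_total=population,
        municipalities=municipalities,
        elderly_fractions=fractions,
        truth_lst_day=truth_day,
        truth_lst_night=truth_night,
    )


def default_spec(preset: str, seed: int = 0, response_family: str = "mixed") -> SceneSpec:
    """A documented, seeded spec for an ``"inland"`` or ``"coastal"`` city.

    The elderly fractions bracket the ≈21 % national share of residents
    aged 65+.  ``response_family`` selects the LST–NDVI truth: ``"mixed"``
    (default; linear and saturating classes), ``"linear"`` (all linear,
    the regime where the linear model is exactly correct) or
    ``"nonlinear"`` (all saturating, where the additive-smooth model
    should win for every class).
    """
    if preset not in {"inland", "coastal"}:
        raise ValueError(f"unknown preset {preset!r}; expected 'inland' or 'coastal'")
    spec = SceneSpec(name=f"{preset}-city", seed=seed)
    if preset == "coastal":
        # a 3-km water stripe along the east edge, aligned to the 1-km
        # block grid so mixed land/water LST cells stay class-pure
        spec = replace(spec, name="coastal-city", coastal_water_frac=0.1,
                       pop_decay=2500.0,
                       elderly_fractions=(0.19, 0.20, 0.22, 0.23, 0.21))
    if response_family == "linear":
        spec = replace(spec, lst_response={
            190: LinearResponse(31.0, -3.5),
            14: LinearResponse(32.0, -10.0),
            20: LinearResponse(33.0, -12.5),
            50: LinearResponse(34.0, -16.0),
            130: LinearResponse(30.5, -7.3),
        })
    elif response_family == "nonlinear":
        spec = replace(spec, lst_response={
            190: SaturatingResponse(31.5, 6.0, 0.20),
            14: SaturatingResponse(33.0, 12.0, 0.30),
            20: SaturatingResponse(34.0, 14.0, 0.35),
            50: SaturatingResponse(35.0, 16.0, 0.40),
            130: SaturatingResponse(31.5, 9.0, 0.45),
        })
    elif response_family != "mixed":
        raise ValueError(f"unknown response_family {response_family!r}")
    return spec


# ---------------------------------------------------------------------------
# scene persistence (the `simulate` CLI writes this layout)
# ---------------------------------------------------------------------------

def save_scene(scene: CityScene, directory) -> Path:
    """Write every layer as GeoTIFF plus a YAML manifest and fractions CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"name": scene.name, "months": list(scene.ndvi_monthly.months)}
    write_grid(scene.land_cover, directory / "land_cover.tif")
    write_grid(scene.population_total, directory / "population_total.tif")
    write_grid(scene.municipalities, directory / "municipalities.tif")
    for stem, stack in (("ndvi", scene.ndvi_monthly),
                        ("lst_day", scene.lst_day_monthly),
                        ("lst_night", scene.lst_night_monthly)):
        for month, grid in stack:
            write_grid(grid, directory / f"{stem}_{month:02d}.tif")
    for stem, grid in (("truth_lst_day", scene.truth_lst_day),
                       ("truth_lst_night", scene.truth_lst_night)):
        if grid is not None:
            write_grid(grid, directory / f"{stem}.tif")
            manifest[stem] = f"{stem}.tif"
    with open(directory / "elderly_fractions.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["municipality_id", "fraction"])
        for mid in sorted(scene.elderly_fractions):
            w.writerow([mid, scene.elderly_fractions[mid]])
    with open(directory / "scene.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    return directory


def load_scene(directory) -> CityScene:
    """Read a scene directory written by :func:`save_scene`."""
    directory = Path(directory)
    with open(directory / "scene.yaml") as fh:
        manifest = yaml.safe_load(fh)
    months = [int(m) for m in manifest["months"]]

    def stack(stem: str) -> MonthlyStack:
        return MonthlyStack(months, [read_grid(directory / f"{stem}_{m:02d}.tif")
                                     for m in months])

    fractions: dict[int, float] = {}
    with open(directory / "elderly_fractions.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            fractions[int(row["municipality_id"])] = float(row["fraction"])

    def maybe(stem: str):
        p = directory / f"{stem}.tif"
        return read_grid(p) if p.exists() else None

    return CityScene(
        name=manifest["name"],
        land_cover=read_grid(directory / "land_cover.tif"),
        ndvi_monthly=stack("ndvi"),
        lst_day_monthly=stack("lst_day"),
        lst_night_monthly=stack("lst_night"),
        population_total=read_grid(directory / "population_total.tif"),
        municipalities=read_grid(directory / "municipalities.tif"),
        elderly_fractions=fractions,
        truth_lst_day=maybe("truth_lst_day"),
        truth_lst_night=maybe("truth_lst_night"),
    )
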