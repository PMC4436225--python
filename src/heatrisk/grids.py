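"""Raster data model and plumbing.

All layers in the analysis — land surface temperature (LST, °C), NDVI,
land cover, population, municipality partitions, risk levels — live on
axis-aligned regular grids in a single projected equal-area coordinate
system, so pixel area is simply ``cell_size**2`` and per-km² densities
are cell-count arithmetic.  The convention throughout is top-left
origin, row-major storage, and an explicit boolean ``nodata_mask``
(True = missing).  Masked cells never contribute to a statistic or a
model fit, and no operation invents values in masked cells.

Two on-disk formats are supported: single-band GeoTIFF (via tifffile,
writing the standard georeference tags) and a plain-text grid dialect
(ESRI ASCII style) used for human-readable fixtures.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "GeoGrid",
    "CategoricalGrid",
    "MonthlyStack",
    "AlignmentError",
    "GridIOError",
    "resample_nearest",
    "temporal_mean",
    "apply_water_mask",
    "read_grid",
    "write_grid",
    "GLOBCOVER_LABELS",
    "WATER_CODE",
]

#: Default Globcover-style land-cover label table.  C190 is artificial /
#: built-up surfaces; C210 is water and is excluded from the analysis.
GLOBCOVER_LABELS: dict[int, str] = {
    11: "C11", 14: "C14", 20: "C20", 50: "C50", 70: "C70", 90: "C90",
    100: "C100", 110: "C110", 120: "C120", 130: "C130", 150: "C150",
    190: "C190", 210: "C210",
}

WATER_CODE = 210

_FLOAT_NODATA = -9999.0
_INT_NODATA = -9999


class AlignmentError(ValueError):
    """Two grids that must share shape, cell size and origin do not."""


class GridIOError(IOError):
    """A raster file could not be read or lacks georeferencing."""


@dataclass
class GeoGrid:
    """A 2-D continuous raster with georeference and missing-data mask.

    Parameters
    ----------
    values
        2-D float array, row-major, row 0 at the top.
    cell_size
        Pixel edge length in metres (> 0).
    origin
        ``(x, y)`` of the top-left corner in projected coordinates.
    nodata_mask
        Boolean array, same shape as ``values``; True marks missing cells.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError("nodata_mask shape does not match values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float]:
        """(width, height) of the grid in metres."""
        return (self.ncols * self.cell_size, self.nrows * self.cell_size)

    def aligned_with(self, other: "GeoGrid | CategoricalGrid") -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.cell_size, other.cell_size, rel_tol=1e-9)
            and math.isclose(self.origin[0], other.origin[0], abs_tol=1e-6)
            and math.isclose(self.origin[1], other.origin[1], abs_tol=1e-6)
        )

    def require_aligned(self, other: "GeoGrid | CategoricalGrid") -> None:
        if not self.aligned_with(other):
            raise AlignmentError(
                f"grids are not aligned: shape {self.shape} vs {other.shape}, "
                f"cell {self.cell_size} vs {other.cell_size}, "
                f"origin {self.origin} vs {other.origin}"
            )

    def unmasked(self) -> np.ndarray:
        """1-D array of the valid cell values."""
        return self.values[~self.nodata_mask]

    def copy(self) -> "GeoGrid":
        return GeoGrid(self.values.copy(), self.cell_size, self.origin,
                       self.nodata_mask.copy())


@dataclass
class CategoricalGrid:
    """Integer-coded raster (land cover, municipality id, risk level)."""

    codes: np.ndarray
    labels: dict[int, str]
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if not np.issubdtype(self.codes.dtype, np.integer):
            raise ValueError("codes must be an integer array")
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D array")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.codes.shape, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.codes.shape:
            raise ValueError("nodata_mask shape does not match codes")
        missing = set(np.unique(self.codes[~self.nodata_mask]).tolist()) - set(self.labels)
        if missing:
            raise ValueError(f"codes without labels: {sorted(missing)}")

    # alignment semantics are identical for both grid kinds
    aligned_with = GeoGrid.aligned_with
    require_aligned = GeoGrid.require_aligned

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    @property
    def nrows(self) -> int:
        return self.codes.shape[0]

    @property
    def ncols(self) -> int:
        return self.codes.shape[1]

    @property
    def extent(self) -> tuple[float, float]:
        return (self.ncols * self.cell_size, self.nrows * self.cell_size)

    @property
    def values(self) -> np.ndarray:
        # lets alignment checks treat both grid kinds uniformly
        return self.codes

    def unmasked_codes(self) -> np.ndarray:
        return self.codes[~self.nodata_mask]

    def copy(self) -> "CategoricalGrid":
        return CategoricalGrid(self.codes.copy(), dict(self.labels),
                               self.cell_size, self.origin, self.nodata_mask.copy())


@dataclass
class MonthlyStack:
    """An ordered set of aligned monthly grids (e.g. May–September, 5..9).

    The multi-year record collapses into one flat list of monthly
    composites; ``months`` must be strictly increasing.
    """

    months: list[int]
    grids: list[GeoGrid]

    def __post_init__(self) -> None:
        if len(self.months) != len(self.grids):
            raise ValueError("months and grids differ in length")
        if any(b <= a for a, b in zip(self.months, self.months[1:])):
            raise ValueError(f"months must be strictly increasing: {self.months}")
        for g in self.grids[1:]:
            self.grids[0].require_aligned(g)

    def __len__(self) -> int:
        return len(self.grids)

    def __iter__(self):
        return iter(zip(self.months, self.grids))

    @property
    def cell_size(self) -> float:
        return self.grids[0].cell_size

    def map(self, fn) -> "MonthlyStack":
        """Apply ``fn`` to every grid, keeping the month axis."""
        return MonthlyStack(list(self.months), [fn(g) for g in self.grids])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _nearest_indices(n_src: int, src_size: float, n_out: int, out_size: float) -> np.ndarray:
    """Index of the source pixel whose centre is nearest each output centre.

    Ties (output centre exactly on a source-pixel boundary) go to the
    top-left candidate for determinism.  Returns -1 where the output
    centre falls outside the source extent (padding).
    """
    centres = (np.arange(n_out) + 0.5) * out_size
    # ceil(x/s) - 1 selects the containing pixel and resolves boundary
    # ties to the lower index; the epsilon guards float jitter in x/s.
    idx = np.ceil(centres / src_size - 1e-9).astype(int) - 1
    idx[idx < 0] = 0  # first output centre is always inside pixel 0
    idx[centres > n_src * src_size + 1e-9 * src_size] = -1
    idx[idx >= n_src] = -1
    return idx


def resample_nearest(src, target_cell_size: float):
    """Nearest-neighbour resample to a new cell size, extent preserved.

    Works for both :class:`GeoGrid` and :class:`CategoricalGrid`.  When
    the extent is not an integer multiple of the target cell size the
    output is padded with nodata on the bottom/right.
    """
    if target_cell_size <= 0:
        raise ValueError(f"target_cell_size must be positive, got {target_cell_size}")
    s = src.cell_size
    t = float(target_cell_size)
    n_out_r = max(1, math.ceil(src.nrows * s / t - 1e-9))
    n_out_c = max(1, math.ceil(src.ncols * s / t - 1e-9))
    ri = _nearest_indices(src.nrows, s, n_out_r, t)
    ci = _nearest_indices(src.ncols, s, n_out_c, t)
    rr, cc = np.meshgrid(ri, ci, indexing="ij")
    inside = (rr >= 0) & (cc >= 0)
    rs, cs = rr.clip(min=0), cc.clip(min=0)
    mask = src.nodata_mask[rs, cs] | ~inside
    if isinstance(src, CategoricalGrid):
        out = src.codes[rs, cs].copy()
        return CategoricalGrid(out, dict(src.labels), t, src.origin, mask)
    out = src.values[rs, cs].astype(float)
    out[mask] = np.nan
    return GeoGrid(out, t, src.origin, mask)


def temporal_mean(stack: MonthlyStack, min_valid_months: int = 1) -> GeoGrid:
    """Per-pixel mean over the unmasked months of a stack.

    A pixel is masked in the output when fewer than ``min_valid_months``
    months carry a valid value there.  The default of 1 keeps every
    pixel seen at least once.
    """
    if len(stack) == 0:
        raise ValueError("cannot average an empty stack")
    if not (1 <= min_valid_months <= len(stack)):
        raise ValueError(
            f"min_valid_months must be in [1, {len(stack)}], got {min_valid_months}"
        )
    vals = np.stack([g.values for g in stack.grids])
    masks = np.stack([g.nodata_mask for g in stack.grids])
    valid = (~masks).sum(axis=0)
    with np.errstate(invalid="ignore"):
        summed = np.where(masks, 0.0, np.nan_to_num(vals)).sum(axis=0)
        mean = np.where(valid > 0, summed / np.maximum(valid, 1), np.nan)
    out_mask = valid < min_valid_months
    mean[out_mask] = np.nan
    g0 = stack.grids[0]
    return GeoGrid(mean, g0.cell_size, g0.origin, out_mask)


def apply_water_mask(grid: GeoGrid, water: CategoricalGrid,
                     water_codes: tuple[int, ...] = (WATER_CODE,)) -> GeoGrid:
    """Mask out pixels whose land-cover code is a water class."""
    grid.require_aligned(water)
    is_water = np.isin(water.codes, water_codes) & ~water.nodata_mask
    out = grid.copy()
    out.nodata_mask = out.nodata_mask | is_water
    out.values = np.where(out.nodata_mask, np.nan, out.values)
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _labels_sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".labels.csv")


def _write_labels(path: Path, labels: dict[int, str]) -> None:
    with open(_labels_sidecar(path), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["code", "label"])
        for code in sorted(labels):
            w.writerow([code, labels[code]])


def _read_labels(path: Path) -> dict[int, str] | None:
    sidecar = _labels_sidecar(path)
    if not sidecar.exists():
        return None
    labels: dict[int, str] = {}
    with open(sidecar, newline="") as fh:
        for row in csv.DictReader(fh):
            labels[int(row["code"])] = row["label"]
    return labels


def read_label_table(path) -> dict[int, str]:
    """Read a ``code,label`` CSV into a label mapping."""
    labels: dict[int, str] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            labels[int(row["code"])] = row["label"]
    return labels


def _write_ascii(grid, path: Path) -> None:
    categorical = isinstance(grid, CategoricalGrid)
    nodata = _INT_NODATA if categorical else _FLOAT_NODATA
    arr = grid.codes.astype(float) if categorical else grid.values.copy()
    arr = np.where(grid.nodata_mask, nodata, arr)
    xll = grid.origin[0]
    yll = grid.origin[1] - grid.nrows * grid.cell_size
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {xll!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"nodata_value {nodata}\n")
        fmt = "%d" if categorical else "%.10g"
        np.savetxt(fh, arr, fmt=fmt)
    if categorical:
        _write_labels(path, grid.labels)


def _read_ascii(path: Path):
    header: dict[str, float] = {}
    rows_needed = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in rows_needed:
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        data = np.loadtxt(fh, ndmin=2)
    missing = {"ncols", "nrows", "cellsize", "xllcorner", "yllcorner"} - set(header)
    if missing:
        raise GridIOError(f"{path}: missing georeference header fields {sorted(missing)}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (nrows, ncols):
        raise GridIOError(f"{path}: data shape {data.shape} != header ({nrows}, {ncols})")
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cell)
    nodata = header.get("nodata_value", _FLOAT_NODATA)
    mask = np.isclose(data, nodata) | ~np.isfinite(data)
    labels = _read_labels(path)
    if labels is not None:
        codes = np.where(mask, _INT_NODATA, data).astype(int)
        return CategoricalGrid(codes, labels, cell, origin, mask)
    vals = np.where(mask, np.nan, data)
    return GeoGrid(vals, cell, origin, mask)


# GeoTIFF tag ids: ModelPixelScale, ModelTiepoint, GDAL nodata
_TAG_SCALE, _TAG_TIEPOINT, _TAG_NODATA = 33550, 33922, 42113


def _write_tiff(grid, path: Path) -> None:
    import tifffile

    categorical = isinstance(grid, CategoricalGrid)
    if categorical:
        arr = np.where(grid.nodata_mask, _INT_NODATA, grid.codes).astype(np.int16)
        nodata = _INT_NODATA
    else:
        arr = np.where(grid.nodata_mask, _FLOAT_NODATA, grid.values).astype(np.float32)
        nodata = _FLOAT_NODATA
    sx = sy = float(grid.cell_size)
    extratags = [
        (_TAG_SCALE, "d", 3, (sx, sy, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.origin[0], grid.origin[1], 0.0)),
        (_TAG_NODATA, "s", 0, str(nodata)),
    ]
    tifffile.imwrite(path, arr, extratags=extratags)
    if categorical:
        _write_labels(path, grid.labels)


def _read_tiff(path: Path):
    import tifffile

    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            data = page.asarray()
            tags = {t.code: t.value for t in page.tags.values()}
    except Exception as exc:  # pragma: no cover - corrupt file diagnostics
        raise GridIOError(f"{path}: cannot read TIFF ({exc})") from exc
    if _TAG_SCALE not in tags or _TAG_TIEPOINT not in tags:
        raise GridIOError(f"{path}: no georeference (missing pixel-scale/tiepoint tags)")
    cell = float(tags[_TAG_SCALE][0])
    tie = tags[_TAG_TIEPOINT]
    origin = (float(tie[3]), float(tie[4]))
    nodata = float(tags.get(_TAG_NODATA, _FLOAT_NODATA))
    data = np.asarray(data)
    mask = np.isclose(data.astype(float), nodata)
    labels = _read_labels(path)
    if labels is not None or np.issubdtype(data.dtype, np.integer):
        if labels is None:
            labels = {int(c): f"C{int(c)}" for c in np.unique(data[~mask])}
        codes = np.where(mask, _INT_NODATA, data).astype(int)
        return CategoricalGrid(codes, labels, cell, origin, mask)
    vals = np.where(mask, np.nan, data.astype(float))
    return GeoGrid(vals, cell, origin, mask)


def write_grid(grid, path, fmt: str | None = None) -> None:
    """Write a grid to GeoTIFF (``.tif``) or text grid (``.asc``/``.txt``).

    Categorical grids get a ``<file>.labels.csv`` sidecar carrying the
    label table so round-trips preserve it.
    """
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "tiff":
        _write_tiff(grid, path)
    elif fmt == "ascii":
        _write_ascii(grid, path)
    else:
        raise GridIOError(f"unknown raster format {fmt!r}")


def read_grid(path, fmt: str | None = None):
    """Read a grid written by :func:`write_grid` (format from extension)."""
    path = Path(path)
    if not path.exists():
        raise GridIOError(f"{path}: no such file")
    fmt = fmt or _infer_format(path)
    if fmt == "tiff":
        return _read_tiff(path)
    if fmt == "ascii":
        return _read_ascii(path)
    raise GridIOError(f"unknown raster format {fmt!r}")


def _infer_format(path: Path) -> str:
    ext = path.suffix.lower()
    if ext in {".tif", ".tiff"}:
        return "tiff"
    if ext in {".asc", ".txt", ".grd"}:
        return "ascii"
    raise GridIOError(f"{path}: cannot infer raster format from extension {ext!r}")
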