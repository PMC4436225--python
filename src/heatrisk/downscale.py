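"""Per-land-cover-class statistical downscaling of coarse LST with NDVI.

The hazard layer is built by regressing coarse (1-km) land surface
temperature on fine (250-m) NDVI separately within each land-cover
class — a nested procedure with a single predictive model per class
that sidesteps the large emissivity variability of urban surfaces.
Two model families are fitted:

``LRM``
    Ordinary least squares ``LST = a + b·NDVI``.  The summer LST–NDVI
    relation is negative, so ``b`` is expected below zero.

``GAM``
    A univariate additive-smooth model ``LST = f(NDVI)`` with ``f`` a
    penalized cubic B-spline (P-spline): equally spaced knots extended
    beyond the data range and a second-difference coefficient penalty,
    so the penalty null space is exactly {constant, linear} and the
    linear model is nested in the smooth at every penalty strength.
    The smoothing parameter is chosen by generalized cross-validation
    on a fixed logarithmic grid.

Fits are scored in-sample with R², the slope (LRM), a significance
p-value and the RMSE in °C.  Predictions applied class-wise to the
fine NDVI stack give monthly fine LST, which is summer-averaged and
delivered on the 100-m analysis grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
from scipy.interpolate import BSpline
import statsmodels.api as sm

from .grids import (
    CategoricalGrid,
    GeoGrid,
    MonthlyStack,
    WATER_CODE,
    resample_nearest,
    temporal_mean,
)

__all__ = [
    "ClassFit",
    "ClassModelSet",
    "FitError",
    "build_training_table",
    "fit_lrm",
    "fit_gam",
    "fit_class_models",
    "predict_fine_lst",
    "hazard_layer",
    "compile_fit_report",
]

#: Minimum paired sample size for a per-class fit; sparser classes fall
#: back to the model pooled over all classes.
MIN_SAMPLES = 30

GLOBAL_CODE = -1  # pseudo-class for the all-classes fallback model


class FitError(ValueError):
    """A model could not be fitted (too few samples or degenerate NDVI)."""


@dataclass
class ClassFit:
    """A fitted per-class LST~NDVI model with its in-sample metrics."""

    class_code: int
    model_kind: str                     # "LRM" | "GAM"
    r2: float
    p_value: float
    rmse: float
    n_obs: int
    slope_coef: float | None = None     # LRM only
    slope_se: float | None = None       # cluster-robust when block ids known
    intercept: float | None = None
    edf: float | None = None            # GAM effective degrees of freedom
    lam: float | None = None            # GAM smoothing parameter
    predict: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.r2 <= 1 + 1e-9):
            raise ValueError(f"r2 out of range: {self.r2}")
        if self.rmse < 0:
            raise ValueError(f"negative rmse: {self.rmse}")


@dataclass
class ClassModelSet:
    """Per-class fits plus the pooled fallback for sparse classes."""

    model_kind: str
    fits: dict[int, ClassFit]
    fallback: ClassFit
    skipped: dict[int, int] = field(default_factory=dict)  # code -> n_obs

    def model_for(self, code: int) -> ClassFit:
        return self.fits.get(code, self.fallback)


# ---------------------------------------------------------------------------
# training table
# ---------------------------------------------------------------------------

def build_training_table(lst_coarse: MonthlyStack, ndvi: MonthlyStack,
                         land_cover: CategoricalGrid,
                         water_codes: tuple[int, ...] = (WATER_CODE,)) -> pd.DataFrame:
    """Pair every valid 250-m NDVI cell with its block-replicated coarse LST.

    Returns a tidy frame with columns ``ndvi``, ``lst``, ``class_code``,
    ``month`` and ``block`` (the id of the coarse cell the LST value came
    from, used for cluster-robust uncertainty).  Water cells and masked
    cells are dropped.
    """
    target = ndvi.cell_size
    lc = land_cover
    if lc.cell_size != target:
        lc = resample_nearest(lc, target)
    g0 = ndvi.grids[0]
    if lc.shape != g0.shape:
        raise ValueError(
            f"land cover ({lc.shape}) and NDVI ({g0.shape}) do not overlap on "
            f"a common {target:g}-m grid")
    if set(lst_coarse.months) != set(ndvi.months):
        raise ValueError("LST and NDVI stacks cover different months")

    # coarse-block id for each fine cell (row-major over the coarse grid)
    coarse0 = lst_coarse.grids[0]
    factor = coarse0.cell_size / target
    iby = np.floor((np.arange(g0.nrows) + 0.5) / factor).astype(int)
    ibx = np.floor((np.arange(g0.ncols) + 0.5) / factor).astype(int)
    block_id = iby[:, None] * coarse0.ncols + ibx[None, :]

    frames = []
    for (month, ndvi_m), (_, lst_m) in zip(ndvi, lst_coarse):
        lst_fine = resample_nearest(lst_m, target)
        if lst_fine.shape != g0.shape:
            raise ValueError("LST extent does not overlap the NDVI grid")
        keep = (~ndvi_m.nodata_mask & ~lst_fine.nodata_mask
                & ~lc.nodata_mask & ~np.isin(lc.codes, water_codes))
        frames.append(pd.DataFrame({
            "ndvi": ndvi_m.values[keep],
            "lst": lst_fine.values[keep],
            "class_code": lc.codes[keep],
            "month": month,
            "block": block_id[keep],
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# linear model
# ---------------------------------------------------------------------------

def fit_lrm(pairs: pd.DataFrame, class_code: int = GLOBAL_CODE,
            min_samples: int = MIN_SAMPLES) -> ClassFit:
    """OLS fit of LST on NDVI with R², slope, p-value and in-sample RMSE.

    When the pairs carry a ``block`` column the slope standard error is
    the cluster-robust one (coarse LST values are replicated across the
    fine cells of their block, so residuals cluster by block).
    """
    n = len(pairs)
    if n < min_samples:
        raise FitError(f"class {class_code}: {n} pairs < min_samples={min_samples}")
    x = pairs["ndvi"].to_numpy(float)
    y = pairs["lst"].to_numpy(float)
    if np.ptp(x) < 1e-12:
        raise FitError(f"class {class_code}: NDVI has zero variance")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    if "block" in pairs:
        groups = pairs["block"].to_numpy()
        if len(np.unique(groups)) > 1:
            res_se = res.get_robustcov_results(cov_type="cluster", groups=groups)
            slope_se = float(np.sqrt(res_se.cov_params()[1, 1]))
        else:
            slope_se = float(res.bse[1])
    else:
        slope_se = float(res.bse[1])
    resid = y - res.fittedvalues
    a, b = float(res.params[0]), float(res.params[1])
    return ClassFit(
        class_code=class_code,
        model_kind="LRM",
        r2=max(0.0, float(res.rsquared)),
        p_value=float(res.pvalues[1]) if np.isfinite(res.pvalues[1]) else 1.0,
        rmse=float(np.sqrt(np.mean(resid ** 2))),
        n_obs=n,
        slope_coef=b,
        slope_se=slope_se,
        intercept=a,
        predict=lambda v, a=a, b=b: a + b * np.asarray(v, float),
    )


# ---------------------------------------------------------------------------
# penalized-spline GAM
# ---------------------------------------------------------------------------

N_INTERIOR_KNOTS = 10
SPLINE_DEGREE = 3
LAMBDA_GRID = np.logspace(-4, 4, 25)


def _pspline_basis(x: np.ndarray, lo: float, hi: float):
    """Cubic B-spline design matrix on equally spaced extended knots."""
    span = hi - lo
    h = span / (N_INTERIOR_KNOTS + 1)
    k = SPLINE_DEGREE
    knots = lo + h * np.arange(-k, N_INTERIOR_KNOTS + 2 + k)
    # roundoff can put the last base knot a ulp inside [lo, hi]
    x = np.clip(x, knots[k], knots[-k - 1])
    dm = BSpline.design_matrix(x, knots, k, extrapolate=False)
    return dm, knots


def _second_difference_penalty(nbasis: int) -> np.ndarray:
    D = np.diff(np.eye(nbasis), n=2, axis=0)
    return D.T @ D


@dataclass
class PenalizedSpline:
    """The fitted smooth: coefficients, knots and the clamped range."""

    knots: np.ndarray
    coef: np.ndarray
    lo: float
    hi: float
    lam: float
    edf: float

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        scalar = x.ndim == 0
        k = SPLINE_DEGREE
        x = np.clip(x, max(self.lo, self.knots[k]),
                    min(self.hi, self.knots[-k - 1])).ravel()
        dm = BSpline.design_matrix(x, self.knots, k, extrapolate=False)
        out = np.asarray(dm @ self.coef).ravel()
        return out[0] if scalar else out


def fit_gam(pairs: pd.DataFrame, class_code: int = GLOBAL_CODE,
            min_samples: int = MIN_SAMPLES) -> ClassFit:
    """Penalized-regression-spline fit of LST on NDVI.

    The smoothing parameter minimizes GCV(λ) = n·RSS / (n − edf)² over a
    fixed log grid; significance is an approximate F-test of the smooth
    against the intercept-only model using the effective degrees of
    freedom from the smoother trace.  Out-of-range predictions are
    clamped to the fitted NDVI endpoints (constant extrapolation).
    """
    n = len(pairs)
    if n < min_samples:
        raise FitError(f"class {class_code}: {n} pairs < min_samples={min_samples}")
    x = pairs["ndvi"].to_numpy(float)
    y = pairs["lst"].to_numpy(float)
    lo, hi = float(x.min()), float(x.max())
    if hi - lo < 1e-12:
        raise FitError(f"class {class_code}: NDVI has zero variance")

    B, knots = _pspline_basis(x, lo, hi)
    nbasis = B.shape[1]
    BtB = (B.T @ B).toarray()
    Bty = np.asarray(B.T @ y).ravel()
    P = _second_difference_penalty(nbasis)

    best = None
    for lam in LAMBDA_GRID:
        A = BtB + lam * P
        try:
            c, lower = scipy.linalg.cho_factor(A)
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate basis
            continue
        beta = scipy.linalg.cho_solve((c, lower), Bty)
        edf = float(np.trace(scipy.linalg.cho_solve((c, lower), BtB)))
        fitted = np.asarray(B @ beta).ravel()
        rss = float(np.sum((y - fitted) ** 2))
        denom = max(n - edf, 1e-8)
        gcv = n * rss / denom ** 2
        if best is None or gcv < best[0]:
            best = (gcv, lam, beta, edf, rss)
    if best is None:
        raise FitError(f"class {class_code}: spline system is singular")
    _, lam, beta, edf, rss = best

    smooth = PenalizedSpline(knots=knots, coef=beta, lo=lo, hi=hi, lam=lam, edf=edf)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if tss == 0 else max(0.0, 1.0 - rss / tss)
    # F-test of the smooth against the intercept-only model
    df1 = max(edf - 1.0, 1e-6)
    df2 = max(n - edf, 1.0)
    if rss > 0:
        f_stat = max((tss - rss), 0.0) / df1 / (rss / df2)
        p_value = float(scipy.stats.f.sf(f_stat, df1, df2))
    else:
        p_value = 0.0
    return ClassFit(
        class_code=class_code,
        model_kind="GAM",
        r2=r2,
        p_value=p_value,
        rmse=float(np.sqrt(rss / n)),
        n_obs=n,
        edf=edf,
        lam=float(lam),
        predict=smooth,
    )


# ---------------------------------------------------------------------------
# per-class fitting with fallback
# ---------------------------------------------------------------------------

def fit_class_models(table: pd.DataFrame, model_kind: str = "LRM",
                     min_samples: int = MIN_SAMPLES) -> ClassModelSet:
    """Fit one model per land-cover class, plus the pooled fallback.

    Classes with fewer than ``min_samples`` pairs (or degenerate NDVI)
    are skipped and inherit the all-classes global model.
    """
    fitter = {"LRM": fit_lrm, "GAM": fit_gam}.get(model_kind.upper())
    if fitter is None:
        raise ValueError(f"unknown model kind {model_kind!r}")
    fallback = fitter(table, class_code=GLOBAL_CODE, min_samples=min_samples)
    fits: dict[int, ClassFit] = {}
    skipped: dict[int, int] = {}
    for code, sub in table.groupby("class_code"):
        try:
            fits[int(code)] = fitter(sub, class_code=int(code), min_samples=min_samples)
        except FitError:
            skipped[int(code)] = len(sub)
    return ClassModelSet(model_kind=model_kind.upper(), fits=fits,
                         fallback=fallback, skipped=skipped)


# ---------------------------------------------------------------------------
# prediction and the hazard layer
# ---------------------------------------------------------------------------

def predict_fine_lst(models: ClassModelSet, ndvi: MonthlyStack,
                     land_cover: CategoricalGrid,
                     water_codes: tuple[int, ...] = (WATER_CODE,)) -> MonthlyStack:
    """Apply each pixel's class model to its NDVI, month by month."""
    lc = land_cover
    if lc.cell_size != ndvi.cell_size:
        lc = resample_nearest(lc, ndvi.cell_size)
    g0 = ndvi.grids[0]
    if lc.shape != g0.shape:
        raise ValueError("land cover and NDVI are not on a common grid")
    is_water = np.isin(lc.codes, water_codes) & ~lc.nodata_mask
    out_grids = []
    for month, ndvi_m in ndvi:
        vals = np.full(g0.shape, np.nan)
        mask = ndvi_m.nodata_mask | lc.nodata_mask | is_water
        for code in np.unique(lc.codes[~mask]):
            fit = models.model_for(int(code))
            if fit.predict is None:
                raise ValueError(f"class {code} has no usable model")
            sel = (lc.codes == code) & ~mask
            vals[sel] = fit.predict(ndvi_m.values[sel])
        out_grids.append(GeoGrid(vals, ndvi.cell_size, g0.origin, mask))
    return MonthlyStack(list(ndvi.months), out_grids)


def hazard_layer(pred: MonthlyStack, min_valid_months: int = 1,
                 target_cell_size: float = 100.0) -> GeoGrid:
    """Summer-mean the monthly predictions and deliver them at 100 m."""
    return resample_nearest(temporal_mean(pred, min_valid_months), target_cell_size)


# ---------------------------------------------------------------------------
# fit report
# ---------------------------------------------------------------------------

def compile_fit_report(fits: dict[tuple[str, str], ClassModelSet],
                       weighted: bool = False) -> pd.DataFrame:
    """Tabulate per-class metrics with an averages row per model/period.

    ``fits`` maps ``(period, model_kind)`` — e.g. ``("day", "LRM")`` — to
    a fitted model set.  The averages row is the unweighted arithmetic
    mean of the per-class metric columns (``weighted=True`` switches to
    an ``n_obs``-weighted mean).
    """
    if not fits:
        raise ValueError("no fits to report")
    rows = []
    for (period, kind), modelset in fits.items():
        per_class = [modelset.fits[c] for c in sorted(modelset.fits)]
        for f in per_class:
            rows.append({
                "class": f"C{f.class_code}", "period": period, "model": f.model_kind,
                "r2": f.r2, "slope": f.slope_coef, "p_value": f.p_value,
                "rmse": f.rmse, "n_obs": f.n_obs,
            })
        if per_class:
            w = (np.array([f.n_obs for f in per_class], float)
                 if weighted else np.ones(len(per_class)))
            w = w / w.sum()

            def avg(vals):
                vals = [v for v in vals]
                if all(v is None for v in vals):
                    return None
                arr = np.array([np.nan if v is None else v for v in vals], float)
                return float(np.nansum(arr * w) / np.sum(w[~np.isnan(arr)]))

            rows.append({
                "class": "Average", "period": period, "model": kind.upper(),
                "r2": avg([f.r2 for f in per_class]),
                "slope": avg([f.slope_coef for f in per_class]),
                "p_value": avg([f.p_value for f in per_class]),
                "rmse": avg([f.rmse for f in per_class]),
                "n_obs": int(sum(f.n_obs for f in per_class)),
            })
    return pd.DataFrame(rows)
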