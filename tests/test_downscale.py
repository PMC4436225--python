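"""Downscaling engine: training table, LRM/GAM fits, prediction, report."""

import subprocess
import sys
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import heatrisk as hr
from heatrisk import downscale
from heatrisk.downscale import (
    FitError,
    build_training_table,
    compile_fit_report,
    fit_class_models,
    fit_gam,
    fit_lrm,
    hazard_layer,
    predict_fine_lst,
)
from heatrisk.grids import GeoGrid, MonthlyStack, resample_nearest
from conftest import make_cat, make_grid


def _pairs(x, y, block=None):
    df = pd.DataFrame({"ndvi": x, "lst": y})
    if block is not None:
        df["block"] = block
    return df


def _stack(grids, months=None):
    months = months or list(range(5, 5 + len(grids)))
    return MonthlyStack(months, grids)


class TestTrainingTable:
    def test_one_coarse_pixel_replicates_to_16_pairs(self):
        lst = _stack([make_grid([[25.0]], cell_size=1000.0)], [5])
        ndvi = _stack([make_grid(np.linspace(0, 1, 16).reshape(4, 4),
                                 cell_size=250.0)], [5])
        lc = make_cat(np.full((4, 4), 190), cell_size=250.0)
        tab = build_training_table(lst, ndvi, lc)
        assert len(tab) == 16
        assert (tab.lst == 25.0).all()
        assert (tab.class_code == 190).all()
        assert tab.block.nunique() == 1

    def test_absent_class_has_zero_rows(self, inland_day_table):
        assert (inland_day_table.class_code == 110).sum() == 0

    def test_two_months_double_the_rows(self):
        lstg = make_grid([[25.0]], cell_size=1000.0)
        ndvig = make_grid(np.linspace(0, 1, 16).reshape(4, 4), cell_size=250.0)
        lc = make_cat(np.full((4, 4), 190), cell_size=250.0)
        one = build_training_table(_stack([lstg], [5]), _stack([ndvig], [5]), lc)
        two = build_training_table(_stack([lstg, lstg], [5, 6]),
                                   _stack([ndvig, ndvig], [5, 6]), lc)
        assert len(two) == 2 * len(one)

    def test_water_cells_dropped(self):
        lst = _stack([make_grid([[25.0]], cell_size=1000.0)], [5])
        ndvi = _stack([make_grid(np.linspace(0, 1, 16).reshape(4, 4),
                                 cell_size=250.0)], [5])
        codes = np.full((4, 4), 190)
        codes[0, :] = 210
        tab = build_training_table(lst, ndvi, make_cat(codes, cell_size=250.0))
        assert len(tab) == 12

    def test_disjoint_extents_rejected(self):
        lst = _stack([make_grid([[25.0]], cell_size=1000.0)], [5])
        ndvi = _stack([make_grid(np.zeros((8, 8)), cell_size=250.0)], [5])
        lc = make_cat(np.full((8, 8), 190), cell_size=250.0)
        with pytest.raises(ValueError):
            build_training_table(lst, ndvi, lc)


class TestLinearFit:
    def test_exact_line_recovered(self):
        x = np.linspace(0.0, 0.8, 50)
        fit = fit_lrm(_pairs(x, 30.0 - 10.0 * x))
        assert fit.r2 == pytest.approx(1.0)
        assert fit.rmse == pytest.approx(0.0, abs=1e-10)
        assert fit.slope_coef == pytest.approx(-10.0)
        assert fit.intercept == pytest.approx(30.0)
        assert fit.p_value < 1e-10

    def test_constant_lst_gives_zero_slope_and_r2(self):
        x = np.linspace(0.0, 0.8, 40)
        fit = fit_lrm(_pairs(x, np.full_like(x, 22.0)))
        assert fit.slope_coef == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == pytest.approx(0.0, abs=1e-12)

    def test_too_few_samples_skipped(self):
        with pytest.raises(FitError):
            fit_lrm(_pairs(np.arange(5.0), np.arange(5.0)))

    def test_degenerate_ndvi_rejected(self):
        x = np.full(40, 0.3)
        with pytest.raises(FitError):
            fit_lrm(_pairs(x, np.random.default_rng(0).normal(size=40)))

    def test_scene_slope_recovery_within_3_cluster_se(self, linear_noisy_scene):
        scene, spec = linear_noisy_scene
        tab = build_training_table(scene.lst_day_monthly, scene.ndvi_monthly,
                                   scene.land_cover)
        models = fit_class_models(tab, "LRM")
        for code, fit in models.fits.items():
            truth = spec.lst_response[code].slope
            z = abs(fit.slope_coef - truth) / fit.slope_se
            assert z < 3.0, f"class {code}: slope {fit.slope_coef} vs {truth}, z={z}"

    def test_all_scene_slopes_negative(self, inland_fits):
        for period in ("day", "night"):
            for fit in inland_fits[(period, "LRM")].fits.values():
                assert fit.slope_coef < 0


class TestGamFit:
    def test_linear_truth_matches_lrm_predictions(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0.0, 0.8, 400)
        y = 30.0 - 10.0 * x
        lrm, gam = fit_lrm(_pairs(x, y)), fit_gam(_pairs(x, y))
        grid = np.linspace(x.min(), x.max(), 101)
        assert np.max(np.abs(gam.predict(grid) - lrm.predict(grid))) < 1e-6

    def test_nonlinear_truth_beats_lrm(self, nonlinear_scene):
        tab = build_training_table(nonlinear_scene.lst_day_monthly,
                                   nonlinear_scene.ndvi_monthly,
                                   nonlinear_scene.land_cover)
        lrm = fit_class_models(tab, "LRM")
        gam = fit_class_models(tab, "GAM")
        for code in lrm.fits:
            assert gam.fits[code].rmse < lrm.fits[code].rmse

    def test_gam_never_worse_than_lrm_in_sample(self, inland_fits):
        for period in ("day", "night"):
            lrm, gam = inland_fits[(period, "LRM")], inland_fits[(period, "GAM")]
            for code in lrm.fits:
                assert gam.fits[code].rmse <= lrm.fits[code].rmse + 1e-8

    def test_too_few_samples_skipped(self):
        with pytest.raises(FitError):
            fit_gam(_pairs(np.arange(10.0), np.arange(10.0)))

    def test_significance_detects_strong_smooth(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0.0, 0.8, 500)
        y = 30.0 - 12.0 * np.tanh(x / 0.3) + rng.normal(0, 0.5, 500)
        fit = fit_gam(_pairs(x, y))
        assert fit.p_value < 1e-6
        assert 2.0 < fit.edf < 14.0

    def test_agrees_with_mgcv_reference(self, tmp_path, inland_day_table):
        """Cross-check the P-spline fit against R mgcv on one class."""
        sub = inland_day_table[inland_day_table.class_code == 20]
        csv = tmp_path / "pairs.csv"
        sub[["ndvi", "lst"]].to_csv(csv, index=False)
        script = (
            f'suppressMessages(library(mgcv));'
            f'd<-read.csv("{csv}");'
            f'm<-gam(lst~s(ndvi),data=d);'
            f'cat(sqrt(mean(residuals(m)^2)))'
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        mgcv_rmse = float(out.stdout.strip().split()[-1])
        ours = fit_gam(sub).rmse
        assert ours == pytest.approx(mgcv_rmse, rel=0.05)


class TestPrediction:
    def test_linear_prediction_arithmetic(self):
        x = np.linspace(0.0, 0.8, 50)
        models = fit_class_models(
            _pairs(x, 30.0 - 10.0 * x).assign(class_code=190), "LRM")
        ndvi = _stack([make_grid([[0.5]], cell_size=250.0)], [5])
        lc = make_cat([[190]], cell_size=250.0)
        pred = predict_fine_lst(models, ndvi, lc)
        assert pred.grids[0].values[0, 0] == pytest.approx(25.0)

    def test_masked_ndvi_gives_masked_prediction(self):
        x = np.linspace(0.0, 0.8, 50)
        models = fit_class_models(
            _pairs(x, 30.0 - 10.0 * x).assign(class_code=190), "LRM")
        g = make_grid([[0.5, np.nan]], cell_size=250.0,
                      mask=np.array([[False, True]]))
        pred = predict_fine_lst(models, _stack([g], [5]),
                                make_cat([[190, 190]], cell_size=250.0))
        assert not pred.grids[0].nodata_mask[0, 0]
        assert pred.grids[0].nodata_mask[0, 1]

    def test_zero_noise_linear_scene_recovers_truth(self, linear_zero_noise_scene):
        scene, _ = linear_zero_noise_scene
        tab = build_training_table(scene.lst_day_monthly, scene.ndvi_monthly,
                                   scene.land_cover)
        models = fit_class_models(tab, "LRM")
        pred = predict_fine_lst(models, scene.ndvi_monthly, scene.land_cover)
        hz = hazard_layer(pred)
        truth = scene.truth_lst_day
        sel = ~hz.nodata_mask & ~truth.nodata_mask
        rmse = np.sqrt(np.mean((hz.values[sel] - truth.values[sel]) ** 2))
        assert rmse < 0.1

    def test_night_fits_more_accurate_than_day(self, inland_fits):
        for kind in ("LRM", "GAM"):
            day, night = inland_fits[("day", kind)], inland_fits[("night", kind)]
            for code in day.fits:
                assert night.fits[code].rmse < day.fits[code].rmse

    def test_sparse_class_falls_back_to_global_model(self, inland_day_table):
        # keep class 190 below the sample threshold
        thin = pd.concat([
            inland_day_table[inland_day_table.class_code != 190],
            inland_day_table[inland_day_table.class_code == 190].head(10),
        ])
        models = fit_class_models(thin, "LRM")
        assert 190 not in models.fits
        assert 190 in models.skipped
        assert models.model_for(190) is models.fallback


class TestHazardLayer:
    def test_identical_months_replicate_to_100m(self):
        g = make_grid([[20.0, 24.0]], cell_size=250.0)
        hz = hazard_layer(_stack([g] * 5))
        assert hz.cell_size == 100.0
        assert hz.values[0, 0] == 20.0
        assert np.isin(hz.values, [20.0, 24.0]).all()

    def test_mixed_months_mean_then_replicate(self):
        grids = [make_grid([[v]], cell_size=250.0) for v in (20.0, 22.0, 27.0)]
        hz = hazard_layer(_stack(grids))
        assert np.allclose(hz.values, 23.0)
        assert hz.shape == (3, 3)

    def test_fully_masked_month_ignored(self):
        ok = make_grid([[20.0]], cell_size=250.0)
        bad = make_grid([[np.nan]], cell_size=250.0,
                        mask=np.array([[True]]))
        hz = hazard_layer(_stack([ok, bad, ok]))
        assert np.allclose(hz.values, 20.0)
        assert not hz.nodata_mask.any()


class TestFitReport:
    def test_single_class_average_equals_class(self):
        x = np.linspace(0.0, 0.8, 60)
        ms = fit_class_models(_pairs(x, 30 - 10 * x).assign(class_code=14), "LRM")
        rep = compile_fit_report({("day", "LRM"): ms})
        avg = rep[rep["class"] == "Average"].iloc[0]
        cls = rep[rep["class"] == "C14"].iloc[0]
        assert avg.r2 == cls.r2 and avg.rmse == cls.rmse

    def test_two_class_rmse_average(self):
        rng = np.random.default_rng(6)
        x = np.linspace(0.0, 0.8, 200)
        frames = []
        for code, sd in ((14, 1.0), (20, 2.0)):
            y = 30 - 10 * x + rng.normal(0, sd, x.size)
            frames.append(_pairs(x, y).assign(class_code=code))
        ms = fit_class_models(pd.concat(frames), "LRM")
        rep = compile_fit_report({("day", "LRM"): ms})
        avg = rep[rep["class"] == "Average"].iloc[0]
        per = rep[rep["class"] != "Average"]
        assert avg.rmse == pytest.approx(per.rmse.mean())

    def test_full_run_row_count(self, inland_fits):
        rep = compile_fit_report(inland_fits)
        k = len(inland_fits[("day", "LRM")].fits)
        assert len(rep) == 4 * (k + 1)
        assert set(rep.period) == {"day", "night"}
        assert set(rep.model) == {"LRM", "GAM"}

    def test_weighted_average_option(self, inland_fits):
        unw = compile_fit_report(inland_fits, weighted=False)
        wgt = compile_fit_report(inland_fits, weighted=True)
        a = unw[(unw["class"] == "Average") & (unw.period == "day")
                & (unw.model == "LRM")].iloc[0].rmse
        b = wgt[(wgt["class"] == "Average") & (wgt.period == "day")
                & (wgt.model == "LRM")].iloc[0].rmse
        assert a != b
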