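"""Shared fixtures: synthetic scenes and fitted models, built once."""

from dataclasses import replace

import numpy as np
import pytest

import heatrisk as hr
from heatrisk import downscale
from heatrisk.grids import CategoricalGrid, GeoGrid


@pytest.fixture(scope="session")
def inland_scene():
    """Default inland city, mixed linear/saturating truth, seed 1."""
    return hr.generate_scene(hr.default_spec("inland", seed=1))


@pytest.fixture(scope="session")
def coastal_scene():
    return hr.generate_scene(hr.default_spec("coastal", seed=2))


@pytest.fixture(scope="session")
def linear_zero_noise_scene():
    """All-linear truth with every noise source off: exact recovery regime."""
    spec = replace(hr.default_spec("inland", seed=3, response_family="linear"),
                   noise_sd=0.0, night_noise_sd=0.0, ndvi_ripple_sd=0.0)
    return hr.generate_scene(spec), spec


@pytest.fixture(scope="session")
def linear_noisy_scene():
    """All-linear truth with the default observation noise."""
    spec = hr.default_spec("inland", seed=4, response_family="linear")
    return hr.generate_scene(spec), spec


@pytest.fixture(scope="session")
def nonlinear_scene():
    return hr.generate_scene(hr.default_spec("inland", seed=1,
                                             response_family="nonlinear"))


@pytest.fixture(scope="session")
def inland_day_table(inland_scene):
    return downscale.build_training_table(
        inland_scene.lst_day_monthly, inland_scene.ndvi_monthly,
        inland_scene.land_cover)


@pytest.fixture(scope="session")
def inland_fits(inland_scene, inland_day_table):
    night = downscale.build_training_table(
        inland_scene.lst_night_monthly, inland_scene.ndvi_monthly,
        inland_scene.land_cover)
    return {
        ("day", "LRM"): downscale.fit_class_models(inland_day_table, "LRM"),
        ("day", "GAM"): downscale.fit_class_models(inland_day_table, "GAM"),
        ("night", "LRM"): downscale.fit_class_models(night, "LRM"),
        ("night", "GAM"): downscale.fit_class_models(night, "GAM"),
    }


@pytest.fixture(scope="session")
def inland_result(inland_scene):
    """Full pipeline output on the default inland preset."""
    return hr.run_city_analysis(inland_scene, model="GAM")


def make_grid(values, cell_size=100.0, mask=None):
    return GeoGrid(np.asarray(values, dtype=float), cell_size,
                   (0.0, np.shape(values)[0] * cell_size), mask)


def make_cat(codes, labels=None, cell_size=100.0, mask=None):
    codes = np.asarray(codes, dtype=int)
    if labels is None:
        labels = {int(c): f"C{int(c)}" for c in np.unique(codes)}
    return CategoricalGrid(codes, labels, cell_size,
                           (0.0, codes.shape[0] * cell_size), mask)
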