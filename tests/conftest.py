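"""Shared fixtures: tiny scenes with hand-set bands, and one generated year."""

from __future__ import annotations

from datetime import date as Date

import numpy as np
import pytest

from ecoqi.raster import Grid, Raster, Scene, Sensor
from ecoqi.synthetic import LandscapeSpec, generate_series


def as_raster(value, grid: Grid) -> Raster:
    """Scalar or array -> Raster on the grid, fully valid."""
    data = np.broadcast_to(np.asarray(value, dtype=np.float64), grid.shape).copy()
    return Raster(data, np.ones(grid.shape, dtype=bool), grid)


def make_scene(
    blue=0.05,
    green=0.1,
    red=0.1,
    nir=0.4,
    swir1=0.15,
    swir2=0.1,
    thermal_radiance=9.0,
    brightness_temp=300.0,
    emissivity=0.98,
    water_vapor=1.0,
    sensor=Sensor.OLI_TIRS,
    grid: Grid | None = None,
    date=Date(2018, 6, 15),
    valid_mask=None,
) -> Scene:
    """Scene with uniform (or array) bands on a small grid."""
    grid = grid or Grid(4, 4)
    return Scene(
        acquisition_date=date,
        sensor=sensor,
        blue=as_raster(blue, grid),
        green=as_raster(green, grid),
        red=as_raster(red, grid),
        nir=as_raster(nir, grid),
        swir1=as_raster(swir1, grid),
        swir2=as_raster(swir2, grid),
        thermal_radiance=as_raster(thermal_radiance, grid),
        brightness_temp=as_raster(brightness_temp, grid),
        emissivity=as_raster(emissivity, grid),
        water_vapor=water_vapor,
        valid_mask=valid_mask,
    )


@pytest.fixture(scope="session")
def small_year():
    """One generated 48x48, 12-date synthetic year (shared, read-only)."""
    spec = LandscapeSpec(rows=48, cols=48, seed=7)
    scenes, lucc, truth = generate_series(spec)
    return spec, scenes, lucc, truth
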