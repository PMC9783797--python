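"""Indicator math: NDVI, NDBSI, tasseled-cap wetness, single-channel LST."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecoqi.errors import ConfigurationError
from ecoqi.indicators import (
    AtmosphericFunctions,
    C2_UM_K,
    atmospheric_functions,
    compute_indicator_stack,
    compute_lst,
    compute_ndbsi,
    compute_ndvi,
    compute_wet,
    get_sensor_constants,
)
from ecoqi.raster import Sensor

from conftest import make_scene


class TestNdvi:
    @pytest.mark.parametrize(
        "nir,red,expected",
        [(0.5, 0.1, 2 / 3), (0.3, 0.3, 0.0), (0.4, 0.0, 1.0)],
    )
    def test_point_values(self, nir, red, expected):
        result = compute_ndvi(make_scene(nir=nir, red=red))
        assert result.data[result.mask] == pytest.approx(expected)

    def test_zero_denominator_masks_cell(self):
        result = compute_ndvi(make_scene(nir=0.0, red=0.0))
        assert not result.mask.any()

    @given(nir=st.floats(0, 1), red=st.floats(0, 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounded_on_unit_reflectance(self, nir, red):
        result = compute_ndvi(make_scene(nir=nir, red=red))
        if result.mask.any():
            assert np.all(np.abs(result.valid_values()) <= 1 + 1e-12)


class TestNdbsi:
    def test_uniform_reflectance_is_half_ibi(self):
        # all bands 0.25: SI = 0 and IBI = 0, so NDBSI = IBI/2 = 0
        result = compute_ndbsi(make_scene(blue=0.25, green=0.25, red=0.25, nir=0.25, swir1=0.25))
        assert result.valid_values() == pytest.approx(0.0, abs=1e-12)

    def test_bright_bare_soil_positive(self):
        result = compute_ndbsi(make_scene(red=0.4, swir1=0.4, nir=0.1, green=0.1, blue=0.05))
        assert np.all(result.valid_values() > 0)

    def test_dense_vegetation_negative(self):
        result = compute_ndbsi(make_scene(nir=0.5, red=0.05, green=0.1, swir1=0.1, blue=0.03))
        assert np.all(result.valid_values() < 0)

    def test_matches_hand_evaluation(self):
        # independent scalar evaluation of SI and IBI at one band combination
        red, green, nir, swir1 = 0.3, 0.15, 0.35, 0.4
        si = ((red + swir1) - (nir + green)) / ((red + swir1) + (nir + green))
        a = 2 * swir1 / (swir1 + nir)
        b = nir / (nir + red) + green / (green + swir1)
        expected = (si + (a - b) / (a + b)) / 2
        result = compute_ndbsi(make_scene(red=red, green=green, nir=nir, swir1=swir1, blue=0.1))
        assert result.valid_values() == pytest.approx(expected, abs=1e-12)

    @given(
        red=st.floats(0.01, 1), green=st.floats(0.01, 1), blue=st.floats(0.01, 1),
        nir=st.floats(0.01, 1), swir1=st.floats(0.01, 1),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounded_on_unit_reflectance(self, red, green, blue, nir, swir1):
        result = compute_ndbsi(make_scene(red=red, green=green, blue=blue, nir=nir, swir1=swir1))
        if result.mask.any():
            assert np.all(np.abs(result.valid_values()) <= 1 + 1e-12)


class TestWet:
    def test_all_zero_bands_give_zero(self):
        scene = make_scene(blue=0, green=0, red=0, nir=0, swir1=0, swir2=0)
        assert compute_wet(scene).valid_values() == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "sensor,expected",
        [(Sensor.TM, -0.5883), (Sensor.OLI_TIRS, -0.1502)],
    )
    def test_unit_reflectance_equals_coefficient_sum(self, sensor, expected):
        scene = make_scene(blue=1, green=1, red=1, nir=1, swir1=1, swir2=1, sensor=sensor)
        assert compute_wet(scene).valid_values() == pytest.approx(expected, abs=1e-10)

    def test_linearity_in_the_scene(self):
        bands = dict(blue=0.04, green=0.08, red=0.12, nir=0.36, swir1=0.2, swir2=0.16)
        full = compute_wet(make_scene(**bands)).valid_values()
        half = compute_wet(make_scene(**{k: v / 2 for k, v in bands.items()})).valid_values()
        assert half == pytest.approx(full / 2, abs=1e-12)


class TestAtmosphericFunctions:
    @pytest.mark.parametrize(
        "sensor,expected",
        [
            (Sensor.OLI_TIRS, (0.00918, 1.36072, -0.27514)),
            (Sensor.TM, (-0.05457, 1.52631, -0.32136)),
        ],
    )
    def test_zero_water_vapor_selects_constant_column(self, sensor, expected):
        af = atmospheric_functions(0.0, sensor)
        assert (af.phi1, af.phi2, af.phi3) == pytest.approx(expected, abs=1e-12)

    def test_unit_water_vapor_sums_first_row(self):
        af = atmospheric_functions(1.0, Sensor.OLI_TIRS)
        assert af.phi1 == pytest.approx(0.04019 - 0.38333 + 0.00918, abs=1e-12)

    def test_raster_water_vapor_broadcasts(self):
        w = np.array([[0.0, 1.0]])
        af = atmospheric_functions(w, Sensor.OLI_TIRS)
        assert af.phi1.shape == (1, 2)
        assert af.phi1[0, 0] == pytest.approx(0.00918)

    def test_nonfinite_water_vapor_rejected(self):
        with pytest.raises(ConfigurationError):
            atmospheric_functions(np.nan, Sensor.TM)


class TestLst:
    def test_identity_at_unit_emissivity_and_trivial_phis(self):
        # eps = 1, phi = (1, 0, 0) collapses the retrieval to Lst = Ti
        scene = make_scene(emissivity=1.0, brightness_temp=287.5, thermal_radiance=9.5)
        af = AtmosphericFunctions(1.0, 0.0, 0.0)
        result = compute_lst(scene, af=af)
        assert result.valid_values() == pytest.approx(287.5, abs=1e-9)

    def test_matches_scalar_hand_computation(self):
        # oracle: plain arithmetic with b = 1324 K, evaluated by hand
        ti, li, eps, b = 300.0, 9.5, 0.98, 1324.0
        phi = (0.9, 0.5, -0.3)
        gamma = ti**2 / (b * li)
        delta = ti - ti**2 / b
        expected = gamma * ((1 / eps) * (phi[0] * li + phi[1]) + phi[2]) + delta
        constants = replace(
            get_sensor_constants(Sensor.OLI_TIRS), thermal_wavelength_um=C2_UM_K / b
        )
        scene = make_scene(brightness_temp=ti, thermal_radiance=li, emissivity=eps)
        result = compute_lst(scene, af=AtmosphericFunctions(*phi), constants=constants)
        assert result.valid_values() == pytest.approx(expected, abs=1e-9)

    def test_monotone_in_phi2(self):
        scene = make_scene()
        low = compute_lst(scene, af=AtmosphericFunctions(0.9, 0.5, -0.3)).valid_values()
        high = compute_lst(scene, af=AtmosphericFunctions(0.9, 1.0, -0.3)).valid_values()
        assert np.all(high > low)

    def test_nonpositive_inputs_masked(self):
        ti = np.full((4, 4), 300.0)
        ti[0, 0] = -1.0
        result = compute_lst(make_scene(brightness_temp=ti))
        assert not result.mask[0, 0]
        assert result.mask[1:].all()

    def test_celsius_option_shifts_by_273_15(self):
        scene = make_scene(emissivity=1.0, brightness_temp=300.0)
        af = AtmosphericFunctions(1.0, 0.0, 0.0)
        kelvin = compute_lst(scene, af=af).valid_values()
        celsius = compute_lst(scene, af=af, celsius=True).valid_values()
        assert celsius == pytest.approx(kelvin - 273.15)


class TestIndicatorStack:
    def test_composition_equals_individual_operations(self):
        scene = make_scene()
        stack = compute_indicator_stack(scene)
        assert np.array_equal(stack.ndvi.data, compute_ndvi(scene).data)
        assert np.array_equal(stack.ndbsi.data, compute_ndbsi(scene).data)
        assert np.array_equal(stack.wet.data, compute_wet(scene).data)
        assert np.array_equal(stack.lst.data, compute_lst(scene).data)

    def test_thermal_hole_invalidates_stack_region(self):
        ti = np.full((4, 4), 300.0)
        ti[2, 2] = -5.0
        stack = compute_indicator_stack(make_scene(brightness_temp=ti))
        assert not stack.valid_mask[2, 2]
        assert stack.valid_mask.sum() == 15

    def test_deterministic_across_dates(self):
        from datetime import date as Date

        a = compute_indicator_stack(make_scene(date=Date(2018, 1, 1)))
        b = compute_indicator_stack(make_scene(date=Date(2019, 7, 1)))
        for name in ("ndvi", "ndbsi", "wet", "lst"):
            assert np.array_equal(a.indicator(name).data, b.indicator(name).data)

    def test_permutation_equivariance(self):
        # purely per-pixel: permuting input pixels permutes outputs identically
        rng = np.random.default_rng(0)
        nir = rng.uniform(0.2, 0.8, (4, 4))
        stack = compute_indicator_stack(make_scene(nir=nir))
        flipped = compute_indicator_stack(make_scene(nir=nir[::-1]))
        assert np.array_equal(stack.ndvi.data[::-1], flipped.ndvi.data)
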