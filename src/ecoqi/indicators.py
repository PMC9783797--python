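"""The four ecological indicators: greenness, dryness, wetness, heat.

Greenness is NDVI; dryness (NDBSI) averages a bare-soil index and the
built-up index IBI; wetness is the tasseled-cap moisture component with
sensor-specific coefficients; heat is land surface temperature retrieved by
the single-channel algorithm from thermal radiance, brightness temperature,
surface emissivity and the three water-vapor-dependent atmospheric functions.

All computations are per-pixel.  Reflectances are clipped to [0, 1] before
index math (with the clipped-cell count logged) and any zero denominator
masks the cell instead of producing infinities, so downstream min/max
fitting only ever sees finite values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError
from .raster import IndicatorStack, Raster, Scene, Sensor

__all__ = [
    "SensorConstants",
    "AtmosphericFunctions",
    "SENSOR_CONSTANTS",
    "compute_ndvi",
    "compute_ndbsi",
    "compute_wet",
    "atmospheric_functions",
    "compute_lst",
    "compute_indicator_stack",
]

logger = logging.getLogger(__name__)

C2_UM_K = 14387.685
"""Second radiation constant c2 in um*K."""


@dataclass(frozen=True)
class SensorConstants:
    """Per-sensor constants for the wetness and LST computations.

    ``wet_coefficients`` are the tasseled-cap moisture loadings in band
    order (blue, green, red, nir, swir1, swir2).  ``af_matrix`` maps
    (w^2, w, 1) to the atmospheric functions (phi1, phi2, phi3).
    ``thermal_wavelength_um`` is the effective wavelength of the thermal
    band; ``b_gamma`` = c2 / lambda is the Planck-linearisation constant.
    """

    name: Sensor
    thermal_wavelength_um: float
    wet_coefficients: tuple[float, float, float, float, float, float]
    af_matrix: tuple[tuple[float, float, float], ...]

    @property
    def b_gamma(self) -> float:
        return C2_UM_K / self.thermal_wavelength_um


SENSOR_CONSTANTS: dict[Sensor, SensorConstants] = {
    Sensor.TM: SensorConstants(
        name=Sensor.TM,
        thermal_wavelength_um=11.457,  # TM band 6
        # blue, green, red, nir, swir1, swir2
        wet_coefficients=(0.3102, 0.1594, 0.2021, 0.0315, -0.6806, -0.6109),
        af_matrix=(
            (0.06982, -0.51041, -0.05457),
            (-0.03366, -1.20026, 1.52631),
            (1.04896, 0.06297, -0.32136),
        ),
    ),
    Sensor.OLI_TIRS: SensorConstants(
        name=Sensor.OLI_TIRS,
        thermal_wavelength_um=10.904,  # Landsat 8 band 10
        wet_coefficients=(0.3283, 0.3407, 0.1973, 0.1511, -0.7117, -0.4559),
        af_matrix=(
            (0.04019, -0.38333, 0.00918),
            (0.02916, -1.50294, 1.36072),
            (1.01523, 0.20324, -0.27514),
        ),
    ),
}


def get_sensor_constants(sensor: Sensor | str, overrides: dict | None = None) -> SensorConstants:
    sensor = Sensor.parse(sensor)
    try:
        constants = SENSOR_CONSTANTS[sensor]
    except KeyError:  # pragma: no cover - enum is closed
        raise ConfigurationError(f"no constants registered for sensor {sensor}")
    if overrides:
        constants = replace(constants, **overrides)
    return constants


@dataclass
class AtmosphericFunctions:
    """Atmospheric functions (phi1, phi2, phi3), scalar or per-pixel."""

    phi1: float | np.ndarray
    phi2: float | np.ndarray
    phi3: float | np.ndarray


def _clipped_band(raster: Raster, name: str) -> np.ndarray:
    data = raster.data
    bad = raster.mask & ((data < 0.0) | (data > 1.0))
    n_bad = int(bad.sum())
    if n_bad:
        logger.info("clipped %d %s reflectance values to [0, 1]", n_bad, name)
        data = np.clip(data, 0.0, 1.0)
    return data


def _safe_ratio(num: np.ndarray, den: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise num/den; zero denominators drop out of the mask."""
    ok = mask & (den != 0.0)
    out = np.zeros_like(num, dtype=np.float64)
    np.divide(num, den, out=out, where=ok)
    return out, ok


def compute_ndvi(scene: Scene) -> Raster:
    """Greenness: (nir - red) / (nir + red); zero-sum cells are masked."""
    nir = _clipped_band(scene.nir, "nir")
    red = _clipped_band(scene.red, "red")
    value, ok = _safe_ratio(nir - red, nir + red, scene.valid_mask)
    return Raster(value, ok, scene.grid)


def compute_ndbsi(scene: Scene) -> Raster:
    """Dryness: mean of the bare-soil index SI and the built-up index IBI.

    SI = [(red + swir1) - (nir + green)] / [(red + swir1) + (nir + green)]
    IBI contrasts 2*swir1/(swir1+nir) against nir/(nir+red) + green/(green+swir1).
    Any zero denominator (outer or inner) masks the cell.
    """
    red = _clipped_band(scene.red, "red")
    green = _clipped_band(scene.green, "green")
    nir = _clipped_band(scene.nir, "nir")
    swir1 = _clipped_band(scene.swir1, "swir1")

    si, ok = _safe_ratio((red + swir1) - (nir + green), (red + swir1) + (nir + green), scene.valid_mask)

    a, ok = _safe_ratio(2.0 * swir1, swir1 + nir, ok)
    b1, ok = _safe_ratio(nir, nir + red, ok)
    b2, ok = _safe_ratio(green, green + swir1, ok)
    ibi, ok = _safe_ratio(a - (b1 + b2), a + (b1 + b2), ok)

    return Raster((si + ibi) / 2.0, ok, scene.grid)


def compute_wet(scene: Scene, constants: SensorConstants | None = None) -> Raster:
    """Wetness: tasseled-cap moisture, sensor-matched linear band combination."""
    constants = constants or get_sensor_constants(scene.sensor)
    coeffs = constants.wet_coefficients
    bands = ("blue", "green", "red", "nir", "swir1", "swir2")
    value = np.zeros(scene.grid.shape, dtype=np.float64)
    for c, name in zip(coeffs, bands):
        value += c * _clipped_band(getattr(scene, name), name)
    return Raster(value, scene.valid_mask.copy(), scene.grid)


def atmospheric_functions(
    w: float | np.ndarray, sensor: Sensor | str, constants: SensorConstants | None = None
) -> AtmosphericFunctions:
    """(phi1, phi2, phi3) = M_sensor @ (w^2, w, 1) for water vapor w in g cm-2."""
    constants = constants or get_sensor_constants(sensor)
    m = np.asarray(constants.af_matrix, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    if not np.all(np.isfinite(w)):
        raise ConfigurationError("water vapor content must be finite")
    shape = (3,) + (1,) * w.ndim
    phi = (
        m[:, 0].reshape(shape) * w**2
        + m[:, 1].reshape(shape) * w
        + m[:, 2].reshape(shape)
    )
    if w.ndim == 0:
        return AtmosphericFunctions(float(phi[0]), float(phi[1]), float(phi[2]))
    return AtmosphericFunctions(phi[0], phi[1], phi[2])


def compute_lst(
    scene: Scene,
    af: AtmosphericFunctions | None = None,
    constants: SensorConstants | None = None,
    celsius: bool = False,
) -> Raster:
    """Heat: single-channel land surface temperature.

    Lst = gamma * [(1/eps) * (phi1 * Li + phi2) + phi3] + delta with
    gamma = Ti^2 / (b * Li), delta = Ti - Ti^2 / b and b = c2 / lambda.
    With eps = 1 and (phi1, phi2, phi3) = (1, 0, 0) this reduces exactly to
    Lst = Ti.  Cells with nonpositive Li, Ti or emissivity are masked.
    """
    constants = constants or get_sensor_constants(scene.sensor)
    if af is None:
        af = atmospheric_functions(scene.water_vapor_value(), scene.sensor, constants)

    li = scene.thermal_radiance.data
    ti = scene.brightness_temp.data
    eps = scene.emissivity.data
    ok = scene.valid_mask & (li > 0) & (ti > 0) & (eps > 0) & (eps <= 1)
    n_dropped = int((scene.valid_mask & ~ok).sum())
    if n_dropped:
        logger.info("masked %d cells with nonpositive radiance/temperature/emissivity", n_dropped)

    b = constants.b_gamma
    with np.errstate(divide="ignore", invalid="ignore"):
        gamma = ti**2 / (b * li)
        delta = ti - ti**2 / b
        lst = gamma * ((1.0 / eps) * (af.phi1 * li + af.phi2) + af.phi3) + delta
    lst = np.where(ok, lst, np.nan)
    if celsius:
        lst = lst - 273.15
    return Raster(np.nan_to_num(lst, nan=0.0), ok, scene.grid)


def compute_indicator_stack(
    scene: Scene, constants: SensorConstants | None = None, celsius: bool = False
) -> IndicatorStack:
    """All four indicators for one scene, on one shared valid mask."""
    constants = constants or get_sensor_constants(scene.sensor)
    return IndicatorStack(
        acquisition_date=scene.acquisition_date,
        ndvi=compute_ndvi(scene),
        ndbsi=compute_ndbsi(scene),
        wet=compute_wet(scene, constants),
        lst=compute_lst(scene, constants=constants, celsius=celsius),
        valid_mask=scene.valid_mask,
        scene_id=scene.scene_id,
    )
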