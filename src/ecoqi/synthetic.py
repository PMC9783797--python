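"""Synthetic landscape generator.

Builds multiband scene time series with known, class-dependent phenology so
that every pipeline stage — indicator math, normalization, PC1 aggregation,
compositing, and all model comparisons — can run without any downloads.

The generator is *index-first*: each land-cover class carries monthly target
trajectories for greenness (NDVI), wetness (tasseled-cap moisture) and land
surface temperature, and reflectance/thermal bands are back-solved so the
computed indicators hit those targets (before noise).  NDVI and Wet are hit
exactly at zero noise; the dryness index NDBSI is nonlinear in five bands
and is therefore emergent rather than targeted — the truth table records its
realized noiseless value.  Thermal bands are solved so that the
single-channel retrieval reproduces the class LST target exactly at zero
noise.

The default conditions emulate a central-China agricultural mosaic: a
winter-wheat plain (green November-May, bare stubble in high summer and
October) interleaved with summer-corn fields (green June-September),
deciduous forest (leafy May-October), urban land, water and bare soil.
Clouds are random rectangles plus pixel pepper noise — enough to exercise
mask logic, which is all the downstream method ever sees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date

import numpy as np
import pandas as pd

from .baselines import EIInputs, HabitatQualityInputs, LandStressInputs, PollutionLoadInputs, WaterDensityInputs
from .errors import ContractError
from .indicators import atmospheric_functions, compute_indicator_stack, get_sensor_constants
from .raster import Grid, Raster, Scene, Sensor

__all__ = [
    "ClassPhenology",
    "LandscapeSpec",
    "TruthTable",
    "generate_series",
    "generate_ei_inputs",
    "DEFAULT_PHENOLOGY",
]

#: Monthly regional LST baseline (kelvin), January..December.
LST_SEASONAL_BASE = (275.0, 277.0, 283.0, 290.0, 296.0, 301.0, 304.0, 303.0, 297.0, 290.0, 282.0, 276.0)

#: Monthly column water vapor (g cm-2), January..December.
WATER_VAPOR_MONTHLY = (0.6, 0.7, 0.9, 1.2, 1.6, 2.2, 2.6, 2.5, 1.9, 1.3, 0.9, 0.7)

SURFACE_EMISSIVITY = 0.97


@dataclass(frozen=True)
class ClassPhenology:
    """Monthly indicator targets and band-inversion parameters for one class."""

    ndvi: tuple[float, ...]  # 12 monthly means, in [-1, 1]
    wet: tuple[float, ...]  # 12 monthly means
    lst_offset: float  # kelvin relative to the seasonal baseline
    brightness: float  # nir + red total used to invert NDVI into bands
    lucc_code: int

    def __post_init__(self) -> None:
        if len(self.ndvi) != 12 or len(self.wet) != 12:
            raise ContractError("phenology curves must have 12 monthly values")
        if not all(-1.0 <= v <= 1.0 for v in self.ndvi):
            raise ContractError("NDVI targets must lie in [-1, 1]")


_flat = lambda v: (v,) * 12

DEFAULT_PHENOLOGY: dict[str, ClassPhenology] = {
    "forest": ClassPhenology(
        ndvi=(0.30, 0.32, 0.40, 0.55, 0.70, 0.80, 0.85, 0.83, 0.75, 0.60, 0.42, 0.32),
        wet=(0.00, 0.00, 0.02, 0.04, 0.06, 0.08, 0.09, 0.08, 0.06, 0.04, 0.02, 0.00),
        lst_offset=-3.0,
        brightness=0.45,
        lucc_code=21,
    ),
    "cropland_winter_wheat": ClassPhenology(
        # sown in October, peak in April, harvested by June
        ndvi=(0.55, 0.65, 0.75, 0.80, 0.70, 0.30, 0.18, 0.15, 0.15, 0.25, 0.40, 0.50),
        wet=(0.03, 0.04, 0.05, 0.06, 0.04, -0.02, -0.04, -0.04, -0.03, 0.00, 0.02, 0.03),
        lst_offset=-1.0,
        brightness=0.50,
        lucc_code=12,
    ),
    "cropland_summer_corn": ClassPhenology(
        # sown in April-May, peak in July, harvested in September
        ndvi=(0.12, 0.12, 0.12, 0.15, 0.25, 0.55, 0.80, 0.78, 0.50, 0.18, 0.12, 0.12),
        wet=(-0.04, -0.04, -0.03, -0.02, 0.00, 0.04, 0.07, 0.06, 0.02, -0.03, -0.04, -0.04),
        lst_offset=0.0,
        brightness=0.50,
        lucc_code=12,
    ),
    "urban": ClassPhenology(
        ndvi=_flat(0.08), wet=_flat(-0.16), lst_offset=7.0, brightness=0.40, lucc_code=51
    ),
    "water": ClassPhenology(
        ndvi=_flat(-0.05), wet=_flat(0.05), lst_offset=-5.0, brightness=0.12, lucc_code=42
    ),
    "bare": ClassPhenology(
        ndvi=_flat(0.15), wet=_flat(-0.10), lst_offset=3.0, brightness=0.55, lucc_code=65
    ),
}

DEFAULT_FRACTIONS = {
    "cropland_winter_wheat": 0.35,
    "cropland_summer_corn": 0.20,
    "forest": 0.20,
    "urban": 0.10,
    "water": 0.05,
    "bare": 0.10,
}


def _default_dates() -> tuple[Date, ...]:
    return tuple(Date(2018, m, 15) for m in range(1, 13))


@dataclass
class LandscapeSpec:
    """Everything the generator needs: grid, classes, dates, noise, clouds, seed."""

    rows: int = 64
    cols: int = 64
    dates: tuple[Date, ...] = field(default_factory=_default_dates)
    sensor: Sensor = Sensor.OLI_TIRS
    phenology: dict[str, ClassPhenology] = field(default_factory=lambda: dict(DEFAULT_PHENOLOGY))
    class_fractions: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FRACTIONS))
    noise_std: float = 0.01  # reflectance units
    thermal_noise_std: float = 0.3  # kelvin, on brightness temperature
    cloud_fraction: float = 0.15  # per-date expected invalid fraction
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise ContractError(f"class fractions must sum to 1, got {total}")
        unknown = set(self.class_fractions) - set(self.phenology)
        if unknown:
            raise ContractError(f"classes without phenology curves: {sorted(unknown)}")


@dataclass
class TruthTable:
    """Generator ground truth.

    ``indicators`` holds the realized noiseless class-mean indicator values
    per date; ``quality_ordering`` is the intended annual ordering of land
    classes (best first) implied by the phenology curves, computed with an
    equal-weight proxy on min-max-normalized indicators.  Water is excluded
    from the ordering: its extreme wetness makes its rank sensitive to the
    aggregation weights, so it is not a stable ordering truth.
    """

    indicators: pd.DataFrame
    quality_ordering: list[str]
    class_fractions: dict[str, float]
    class_map: np.ndarray  # object array of class names


def _build_class_map(spec: LandscapeSpec, rng: np.random.Generator) -> np.ndarray:
    """Patchy class map: largest class as matrix, others as random rectangles."""
    classes = sorted(spec.class_fractions, key=spec.class_fractions.get, reverse=True)
    base = classes[0]
    cmap = np.full((spec.rows, spec.cols), base, dtype=object)
    n_total = spec.rows * spec.cols
    for cls in classes[1:]:
        target = int(round(spec.class_fractions[cls] * n_total))
        placed = 0
        guard = 0
        while placed < target and guard < 10_000:
            guard += 1
            remaining = target - placed
            side = max(1, int(np.sqrt(remaining * rng.uniform(0.2, 1.0))))
            h = min(side, spec.rows)
            w = min(max(1, remaining // max(h, 1)), spec.cols, side * 2)
            r0 = int(rng.integers(0, spec.rows - h + 1))
            c0 = int(rng.integers(0, spec.cols - w + 1))
            block = cmap[r0 : r0 + h, c0 : c0 + w]
            takeable = block == base
            n_take = min(int(takeable.sum()), remaining)
            if n_take == 0:
                continue
            rr, cc = np.nonzero(takeable)
            for i in range(n_take):
                block[rr[i], cc[i]] = cls
            placed += n_take
    return cmap


def _cloud_mask(spec: LandscapeSpec, rng: np.random.Generator) -> np.ndarray:
    """True = clear.  One random rectangle (~half the budget) plus pepper."""
    clear = np.ones((spec.rows, spec.cols), dtype=bool)
    f = spec.cloud_fraction
    if f <= 0:
        return clear
    rect_area = f / 2.0 * spec.rows * spec.cols
    h = max(1, int(np.sqrt(rect_area * rng.uniform(0.5, 2.0))))
    h = min(h, spec.rows)
    w = min(max(1, int(rect_area / h)), spec.cols)
    r0 = int(rng.integers(0, spec.rows - h + 1))
    c0 = int(rng.integers(0, spec.cols - w + 1))
    clear[r0 : r0 + h, c0 : c0 + w] = False
    # pepper on the remaining clear cells so the expected total hits f
    still_clear = clear.sum()
    deficit = f * spec.rows * spec.cols - (spec.rows * spec.cols - still_clear)
    if deficit > 0 and still_clear > 0:
        p = min(1.0, deficit / still_clear)
        pepper = rng.random((spec.rows, spec.cols)) < p
        clear &= ~pepper
    return clear


def _neutral_radiance(emissivity: float, w: float, sensor: Sensor) -> float:
    """Thermal radiance at which the single-channel retrieval is the identity.

    The retrieval reads Lst = k Ti^2 + Ti with k = (A/Li - 1)/b and
    A = (1/eps)(phi1 Li + phi2) + phi3.  Choosing Li so that A(Li) = Li
    makes k vanish and Lst == Ti exactly, which lets the generator set the
    brightness temperature to the class LST target directly: the retrieval
    stays monotone and noise on Ti propagates one-to-one into LST.
    """
    constants = get_sensor_constants(sensor)
    af = atmospheric_functions(w, sensor, constants)
    denom = 1.0 - af.phi1 / emissivity
    numer = af.phi2 / emissivity + af.phi3
    if denom <= 0 or numer <= 0:
        raise ContractError(
            f"no identity radiance for sensor {sensor} at w={w}; LST target infeasible"
        )
    return float(numer / denom)


def _invert_bands(
    spec: LandscapeSpec, ndvi_t: np.ndarray, wet_t: np.ndarray, brightness: np.ndarray
) -> dict[str, np.ndarray]:
    """Back-solve reflectance bands from NDVI and Wet targets (noiseless)."""
    constants = get_sensor_constants(spec.sensor)
    c_blue, c_green, c_red, c_nir, c_s1, c_s2 = constants.wet_coefficients
    nir = brightness * (1.0 + ndvi_t) / 2.0
    red = brightness * (1.0 - ndvi_t) / 2.0
    green = 0.9 * red + 0.02
    blue = 0.7 * red + 0.01
    vis = c_blue * blue + c_green * green + c_red * red + c_nir * nir
    swir = (vis - wet_t) / (-(c_s1 + c_s2))  # swir1 = swir2 = swir
    return {"blue": blue, "green": green, "red": red, "nir": nir, "swir1": swir.copy(), "swir2": swir.copy()}


def generate_series(spec: LandscapeSpec) -> tuple[list[Scene], Raster, TruthTable]:
    """Generate the scene time series, the matching LUCC raster and the truth.

    Deterministic for a fixed spec (seed included): running twice yields
    bit-identical scenes.
    """
    rng = np.random.default_rng(spec.seed)
    grid = Grid(spec.rows, spec.cols)
    class_map = _build_class_map(spec, rng)
    classes = sorted(spec.class_fractions)
    masks = {cls: class_map == cls for cls in classes}

    lucc_codes = np.zeros(grid.shape, dtype=np.float64)
    for cls in classes:
        lucc_codes[masks[cls]] = spec.phenology[cls].lucc_code
    lucc = Raster(lucc_codes, np.ones(grid.shape, dtype=bool), grid)

    scenes: list[Scene] = []
    truth_rows: list[dict] = []
    for d in spec.dates:
        m = d.month - 1
        ndvi_t = np.zeros(grid.shape)
        wet_t = np.zeros(grid.shape)
        lst_t = np.zeros(grid.shape)
        brightness = np.zeros(grid.shape)
        for cls in classes:
            ph = spec.phenology[cls]
            sel = masks[cls]
            ndvi_t[sel] = ph.ndvi[m]
            wet_t[sel] = ph.wet[m]
            lst_t[sel] = LST_SEASONAL_BASE[m] + ph.lst_offset
            brightness[sel] = ph.brightness

        bands = _invert_bands(spec, ndvi_t, wet_t, brightness)
        w = WATER_VAPOR_MONTHLY[m]
        radiance = _neutral_radiance(SURFACE_EMISSIVITY, w, spec.sensor) * np.ones(grid.shape)
        ti = lst_t.copy()

        clean_scene = _assemble_scene(spec, grid, d, bands, radiance, ti, w, np.ones(grid.shape, bool))
        clean_stack = compute_indicator_stack(clean_scene)
        for cls in classes:
            sel = masks[cls]
            truth_rows.append(
                {
                    "date": d.isoformat(),
                    "class": cls,
                    "ndvi": float(clean_stack.ndvi.data[sel].mean()),
                    "ndbsi": float(clean_stack.ndbsi.data[sel].mean()),
                    "wet": float(clean_stack.wet.data[sel].mean()),
                    "lst": float(clean_stack.lst.data[sel].mean()),
                    "ndvi_target": float(spec.phenology[cls].ndvi[m]),
                    "wet_target": float(spec.phenology[cls].wet[m]),
                    "lst_target": float(LST_SEASONAL_BASE[m] + spec.phenology[cls].lst_offset),
                }
            )

        noisy = {
            name: np.clip(arr + rng.normal(0.0, spec.noise_std, grid.shape), 0.0, 1.0)
            for name, arr in bands.items()
        }
        ti_noisy = ti + rng.normal(0.0, spec.thermal_noise_std, grid.shape)
        clear = _cloud_mask(spec, rng)
        scenes.append(
            _assemble_scene(spec, grid, d, noisy, radiance, ti_noisy, w, clear, scene_id=f"synthetic-{d.isoformat()}")
        )

    truth = TruthTable(
        indicators=pd.DataFrame(truth_rows),
        quality_ordering=_intended_ordering(pd.DataFrame(truth_rows)),
        class_fractions={cls: float(masks[cls].mean()) for cls in classes},
        class_map=class_map,
    )
    return scenes, lucc, truth


def _assemble_scene(spec, grid, d, bands, radiance, ti, w, clear, scene_id="") -> Scene:
    def _r(arr):
        return Raster(np.asarray(arr, dtype=np.float64), np.ones(grid.shape, bool), grid)

    return Scene(
        acquisition_date=d,
        sensor=spec.sensor,
        blue=_r(bands["blue"]),
        green=_r(bands["green"]),
        red=_r(bands["red"]),
        nir=_r(bands["nir"]),
        swir1=_r(bands["swir1"]),
        swir2=_r(bands["swir2"]),
        thermal_radiance=_r(radiance * np.ones(grid.shape)),
        brightness_temp=_r(ti),
        emissivity=_r(SURFACE_EMISSIVITY * np.ones(grid.shape)),
        water_vapor=float(w),
        valid_mask=clear,
        scene_id=scene_id,
    )


def _intended_ordering(truth: pd.DataFrame) -> list[str]:
    """Annual quality ordering implied by the curves (equal-weight proxy).

    Each indicator is min-max normalized over all (class, date) rows; the
    proxy averages ndvi* + wet* + (1 - ndbsi*) + (1 - lst*) over the year.
    Water is excluded (see :class:`TruthTable`).
    """
    df = truth[truth["class"] != "water"].copy()
    proxy = np.zeros(len(df))
    for name, sign in (("ndvi", +1), ("wet", +1), ("ndbsi", -1), ("lst", -1)):
        values = df[name].to_numpy(dtype=float)
        lo, hi = values.min(), values.max()
        norm = (values - lo) / (hi - lo) if hi > lo else np.zeros_like(values)
        proxy += norm if sign > 0 else (1.0 - norm)
    df["proxy"] = proxy / 4.0
    annual = df.groupby("class")["proxy"].mean().sort_values(ascending=False)
    return list(annual.index)


def write_series(spec: LandscapeSpec, out_dir) -> "Path":
    """Generate a series and persist it: GeoTIFF bands, manifest CSV, LUCC, truth.

    Returns the manifest path; everything a file-based pipeline run needs.
    """
    from pathlib import Path

    from .raster import MANIFEST_BAND_COLUMNS, ManifestRecord, SceneManifest, write_raster

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenes, lucc, truth = generate_series(spec)
    records = []
    for scene in scenes:
        stem = scene.scene_id or f"scene-{scene.acquisition_date.isoformat()}"
        paths = {}
        for band in MANIFEST_BAND_COLUMNS:
            p = out / f"{stem}_{band}.tif"
            write_raster(getattr(scene, band), p)
            paths[band] = p.name
        qa = out / f"{stem}_qa.tif"
        write_raster(
            Raster(scene.valid_mask.astype(float), np.ones(scene.grid.shape, bool), scene.grid), qa
        )
        records.append(
            ManifestRecord(
                scene_id=stem,
                date=scene.acquisition_date,
                sensor=scene.sensor,
                band_paths=paths,
                water_vapor=str(scene.water_vapor),
                qa_mask=qa.name,
            )
        )
    write_raster(lucc, out / "lucc.tif")
    truth.indicators.to_csv(out / "truth.csv", index=False)
    (out / "truth_ordering.txt").write_text("\n".join(truth.quality_ordering) + "\n")
    manifest_path = out / "manifest.csv"
    SceneManifest(records).write_csv(manifest_path)
    return manifest_path


def generate_ei_inputs(seed: int = 0) -> EIInputs:
    """Plausible EI component fixture for one administrative unit.

    Areas are drawn so components sum to the total area; coefficients are
    order-of-magnitude realistic stand-ins (the specification's true
    normalization coefficients are configuration inputs, not constants).
    """
    rng = np.random.default_rng(seed)
    total = 10_000.0  # km^2
    shares = rng.dirichlet(np.array([5.0, 2.0, 1.0, 6.0, 2.0, 0.5]))
    areas = shares * total
    hq = HabitatQualityInputs(
        abio=float(rng.uniform(400, 600)),
        a_forest=float(areas[0]),
        a_grass=float(areas[1]),
        a_water=float(areas[2]),
        a_farmland=float(areas[3]),
        a_construction=float(areas[4]),
        a_unused=float(areas[5]),
        total_area=total,
    )
    wd = WaterDensityInputs(
        a_riv=float(rng.uniform(50, 100)),
        s_riv=float(rng.uniform(500, 2000)),
        a_lak=float(rng.uniform(50, 100)),
        s_lak=float(rng.uniform(100, 600)),
        a_res=float(rng.uniform(0.005, 0.02)),
        s_res=float(rng.uniform(1e5, 5e5)),
        area=total,
    )
    ls = LandStressInputs(
        a_reo=float(rng.uniform(100, 300)),
        s_severe=float(rng.uniform(50, 200)),
        s_moderate=float(rng.uniform(100, 400)),
        s_construction=float(areas[4]),
        s_other=float(rng.uniform(50, 200)),
        area=total,
    )
    pollutants = ("cod", "nh3", "so2", "yfc", "nox", "sol")
    pl = PollutionLoadInputs(
        coefficients={k: float(rng.uniform(1, 5)) for k in pollutants},
        emissions={k: float(rng.uniform(1e3, 2e4)) for k in pollutants},
        precipitation=float(rng.uniform(600, 1000)),
    )
    return EIInputs(
        hq=hq,
        ndvi=float(rng.uniform(40, 80)),
        wd=wd,
        ls=ls,
        pl=pl,
        el=0.0,
        unit="synthetic-unit",
        year=2018,
    )
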