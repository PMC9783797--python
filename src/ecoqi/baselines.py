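"""Baseline eco-environment quality models: EI and EQI.

EI is the Chinese national ecological index (HJ 192-2015 style): a weighted
sum of biological abundance (BA), vegetation cover (NDVI), water density
(WD), land stress (LS) and pollution load (PL) on a 0-100 scale, plus a
restrictive environmental-limitation adjustment (EL):

    EI = 0.35 BA + 0.25 NDVI + 0.15 WD + 0.15 (100 - LS)
         + 0.10 (100 - PL) + EL

EQI is the land-use-based index: an area-weighted mean of expert quality
weights per secondary land-use (LUCC) class,
EQI_t = sum_i LUA_i * LUC_i / SA.

The normalization coefficients of the EI sub-indices (Abio, Aveg, Ariv,
Areo, A_COD, ...) come from the assessment specification and are
configuration inputs here; they have no defaults.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ContractError
from .raster import Raster

__all__ = [
    "EILevel",
    "EIWeights",
    "HabitatQualityInputs",
    "WaterDensityInputs",
    "LandStressInputs",
    "PollutionLoadInputs",
    "EIInputs",
    "EIResult",
    "compute_ei",
    "classify_ei",
    "EQIWeightTable",
    "DEFAULT_LUCC_WEIGHTS",
    "compute_eqi",
]

# Indicator weights of the EI weighted sum (national specification values).
EI_WEIGHTS = {"ba": 0.35, "ndvi": 0.25, "wd": 0.15, "ls": 0.15, "pl": 0.10}
EIWeights = EI_WEIGHTS  # alias


class EILevel(str, enum.Enum):
    EXCELLENT = "Excellent"
    GOOD = "Good"
    MEDIUM = "Medium"
    INFERIOR = "Inferior"
    POOR = "Poor"


def classify_ei(ei_value: float) -> EILevel:
    """Five-level classification on the 0-100 EI scale.

    Excellent >= 75 > Good >= 55 > Medium >= 35 > Inferior >= 20 > Poor.
    Lower bounds are closed, upper bounds open.
    """
    if not np.isfinite(ei_value):
        raise ContractError(f"EI value must be finite, got {ei_value}")
    if ei_value >= 75:
        return EILevel.EXCELLENT
    if ei_value >= 55:
        return EILevel.GOOD
    if ei_value >= 35:
        return EILevel.MEDIUM
    if ei_value >= 20:
        return EILevel.INFERIOR
    return EILevel.POOR


@dataclass(frozen=True)
class HabitatQualityInputs:
    """Habitat quality from land-class areas.

    HQ = Abio * (0.35 forest + 0.21 grass + 0.28 water + 0.11 farmland
                 + 0.04 construction + 0.01 unused) / A
    """

    abio: float
    a_forest: float
    a_grass: float
    a_water: float
    a_farmland: float
    a_construction: float
    a_unused: float
    total_area: float

    def value(self) -> float:
        areas = (
            self.a_forest, self.a_grass, self.a_water,
            self.a_farmland, self.a_construction, self.a_unused,
        )
        if any(a < 0 for a in areas) or self.total_area <= 0:
            raise ContractError("habitat areas must be nonnegative and total area positive")
        if sum(areas) > self.total_area * (1 + 1e-9):
            raise ContractError("component areas exceed total area")
        weighted = (
            0.35 * self.a_forest + 0.21 * self.a_grass + 0.28 * self.a_water
            + 0.11 * self.a_farmland + 0.04 * self.a_construction + 0.01 * self.a_unused
        )
        return self.abio * weighted / self.total_area


@dataclass(frozen=True)
class WaterDensityInputs:
    """WD = (Ariv * Sriv + Alak * Slak + Ares * Sres) / (3 S):

    river length, water-surface area and water-resource volume, each with
    its own normalization coefficient, averaged over the region area S.
    """

    a_riv: float
    s_riv: float
    a_lak: float
    s_lak: float
    a_res: float
    s_res: float
    area: float

    def value(self) -> float:
        if self.area <= 0:
            raise ContractError("region area must be positive for WD")
        return (self.a_riv * self.s_riv + self.a_lak * self.s_lak + self.a_res * self.s_res) / (
            3.0 * self.area
        )


@dataclass(frozen=True)
class LandStressInputs:
    """LS = Areo * (0.4 severe + 0.2 moderate + 0.2 construction + 0.2 other) / S."""

    a_reo: float
    s_severe: float
    s_moderate: float
    s_construction: float
    s_other: float
    area: float

    def value(self) -> float:
        if self.area <= 0:
            raise ContractError("region area must be positive for LS")
        return (
            self.a_reo
            * (0.4 * self.s_severe + 0.2 * self.s_moderate + 0.2 * self.s_construction + 0.2 * self.s_other)
            / self.area
        )


@dataclass(frozen=True)
class PollutionLoadInputs:
    """Precipitation-normalized emission load.

    PL = (0.2 A_COD E_COD + 0.2 A_NH3 E_NH3 + 0.2 A_SO2 E_SO2
          + 0.1 A_YFC E_YFC + 0.2 A_NOX E_NOX + 0.1 A_SOL E_SOL) / P
    """

    coefficients: Mapping[str, float]  # A_* per pollutant
    emissions: Mapping[str, float]  # E_* per pollutant
    precipitation: float

    _WEIGHTS = {"cod": 0.2, "nh3": 0.2, "so2": 0.2, "yfc": 0.1, "nox": 0.2, "sol": 0.1}

    def value(self) -> float:
        if self.precipitation <= 0:
            raise ContractError("annual precipitation must be positive for PL")
        missing = [k for k in self._WEIGHTS if k not in self.coefficients or k not in self.emissions]
        if missing:
            raise ContractError(f"pollution load missing pollutant entries: {missing}")
        return sum(
            w * self.coefficients[k] * self.emissions[k] / self.precipitation
            for k, w in self._WEIGHTS.items()
        )


@dataclass
class EIInputs:
    """Sub-index inputs for one administrative unit and year.

    Each sub-index may be supplied either precomputed (0-100 scale) or as a
    raw-component block.  Biological abundance uses BA = (BI + HQ)/2 when a
    biodiversity index BI is available, else the habitat-quality-only path
    BA = HQ.
    """

    bi: float | None = None
    hq: HabitatQualityInputs | float | None = None
    ndvi: float | None = None
    wd: WaterDensityInputs | float | None = None
    ls: LandStressInputs | float | None = None
    pl: PollutionLoadInputs | float | None = None
    el: float = 0.0
    unit: str = ""
    year: int | None = None


@dataclass(frozen=True)
class EIResult:
    ba: float
    ndvi: float
    wd: float
    ls: float
    pl: float
    el: float
    ei: float
    level: EILevel

    @property
    def ei_unit_scale(self) -> float:
        """EI / 100, for comparison against indices on a [0, 1] scale."""
        return self.ei / 100.0


def _resolve(value, name: str) -> float:
    if value is None:
        raise ContractError(f"missing EI sub-index input: {name}")
    if isinstance(value, (int, float)):
        return float(value)
    return float(value.value())


def compute_ei(inputs: EIInputs) -> EIResult:
    """Weighted EI sum with the restrictive adjustment added last."""
    hq = _resolve(inputs.hq, "hq (habitat quality)")
    ba = (float(inputs.bi) + hq) / 2.0 if inputs.bi is not None else hq
    ndvi = _resolve(inputs.ndvi, "ndvi (vegetation cover)")
    wd = _resolve(inputs.wd, "wd (water density)")
    ls = _resolve(inputs.ls, "ls (land stress)")
    pl = _resolve(inputs.pl, "pl (pollution load)")
    ei = (
        EI_WEIGHTS["ba"] * ba
        + EI_WEIGHTS["ndvi"] * ndvi
        + EI_WEIGHTS["wd"] * wd
        + EI_WEIGHTS["ls"] * (100.0 - ls)
        + EI_WEIGHTS["pl"] * (100.0 - pl)
        + inputs.el
    )
    return EIResult(ba, ndvi, wd, ls, pl, inputs.el, ei, classify_ei(ei))


# ---------------------------------------------------------------------------
# EQI

#: Secondary LUCC code -> eco-environment quality weight.
DEFAULT_LUCC_WEIGHTS: dict[int, float] = {
    # cultivated land
    11: 0.30,  # paddy field
    12: 0.25,  # dry land
    # forest
    21: 0.95,  # woodland
    22: 0.65,  # shrub forest
    23: 0.45,  # sparse woodland
    24: 0.40,  # other woodland
    # grassland
    31: 0.75,  # high coverage
    32: 0.45,  # medium coverage
    33: 0.20,  # low coverage
    # water
    41: 0.55,  # rivers and canals
    42: 0.75,  # lake
    43: 0.55,  # reservoir pond
    44: 0.90,  # permanent glacial snow
    45: 0.45,  # tidal flat
    46: 0.55,  # beach
    # construction land
    51: 0.20,  # urban
    52: 0.20,  # rural settlement
    53: 0.20,  # other construction
    # unused land
    61: 0.01,  # sand
    62: 0.01,  # gobi
    63: 0.05,  # saline-alkali soil
    64: 0.65,  # marshland
    65: 0.05,  # bare land
    66: 0.01,  # bare rock / gravel
}


@dataclass(frozen=True)
class EQIWeightTable:
    """LUCC secondary code -> quality weight in [0, 1]."""

    weights: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_LUCC_WEIGHTS))

    def __post_init__(self) -> None:
        for code, w in self.weights.items():
            if not 0.0 <= w <= 1.0:
                raise ContractError(f"weight for code {code} outside [0, 1]: {w}")

    def __getitem__(self, code: int) -> float:
        return self.weights[int(code)]


def compute_eqi(
    lucc: "Raster | pd.DataFrame",
    weights: EQIWeightTable | None = None,
    return_raster: bool = False,
) -> "float | tuple[float, Raster]":
    """Area-weighted quality: EQI = sum_i LUA_i * LUC_i / SA.

    ``lucc`` is either a code raster (equal-area cells; masked cells are
    excluded from numerator and total area alike) or a code/area table with
    columns ``code`` and ``area``.  Unknown codes raise, listing them.
    """
    weights = weights or EQIWeightTable()

    if isinstance(lucc, pd.DataFrame):
        codes = lucc["code"].astype(int).to_numpy()
        areas = lucc["area"].to_numpy(dtype=float)
        if np.any(areas < 0):
            raise ContractError("areas must be nonnegative")
        unknown = sorted(set(codes) - set(int(k) for k in weights.weights))
        if unknown:
            raise ContractError(f"unknown LUCC codes: {unknown}")
        total = areas.sum()
        if total <= 0:
            raise ContractError("total area is zero")
        value = float(sum(a * weights[c] for c, a in zip(codes, areas)) / total)
        if return_raster:
            raise ContractError("return_raster requires a code raster input")
        return value

    codes = np.round(lucc.data).astype(int)
    valid = lucc.mask
    if not valid.any():
        raise ContractError("LUCC raster has no valid cells (zero area)")
    unknown = sorted(set(codes[valid].ravel().tolist()) - set(int(k) for k in weights.weights))
    if unknown:
        raise ContractError(f"unknown LUCC codes: {unknown}")
    # weighted sum over per-code area fractions (exact for uniform regions)
    n_valid = int(valid.sum())
    weight_map = np.zeros(codes.shape, dtype=np.float64)
    value = 0.0
    for code, w in weights.weights.items():
        sel = codes == int(code)
        weight_map[sel] = w
        n_code = int((sel & valid).sum())
        if n_code:
            value += w * (n_code / n_valid)
    value = float(value)
    if return_raster:
        return value, Raster(weight_map, valid.copy(), lucc.grid)
    return value
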