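"""Core raster data model and GeoTIFF input/output.

The whole library works on one rigid contract: every raster in a computation
shares a single grid (shape + affine geotransform + CRS tag), and validity is
tracked with an explicit boolean mask rather than sentinel values.  No
operation ever resamples implicitly; grid mismatches raise
:class:`~ecoqi.errors.GridAlignmentError`.

GeoTIFF files are written through :mod:`tifffile` with the standard
georeferencing tags (ModelPixelScale, ModelTiepoint, GDAL_NODATA) so that the
output is readable by GDAL-based stacks.  The CRS is carried as a string in
the ImageDescription JSON.
"""

from __future__ import annotations

import csv
import enum
import json
from dataclasses import dataclass, field
from datetime import date as Date
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import tifffile

from .errors import ContractError, GridAlignmentError, RasterIOError

__all__ = [
    "Grid",
    "Raster",
    "Sensor",
    "Scene",
    "IndicatorStack",
    "SceneManifest",
    "ManifestRecord",
    "read_raster",
    "write_raster",
    "read_scene",
    "INDICATOR_NAMES",
]

INDICATOR_NAMES = ("ndvi", "ndbsi", "wet", "lst")

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class Grid:
    """Raster grid: shape plus an affine north-up geotransform.

    ``transform`` is ``(x0, dx, y0, dy)`` with ``(x0, y0)`` the outer corner
    of the top-left cell; ``dy`` is negative for north-up rasters.
    """

    rows: int
    cols: int
    transform: tuple[float, float, float, float] = (0.0, 30.0, 0.0, -30.0)
    crs: str = "EPSG:32649"

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    def cell_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        x0, dx, y0, dy = self.transform
        return (x0 + (np.asarray(col) + 0.5) * dx, y0 + (np.asarray(row) + 0.5) * dy)

    def world_to_cell(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Nearest-cell (row, col) indices for world coordinates."""
        x0, dx, y0, dy = self.transform
        col = np.floor((np.asarray(x, dtype=float) - x0) / dx).astype(int)
        row = np.floor((np.asarray(y, dtype=float) - y0) / dy).astype(int)
        return row, col

    def contains(self, row, col) -> np.ndarray:
        r = np.asarray(row)
        c = np.asarray(col)
        return (r >= 0) & (r < self.rows) & (c >= 0) & (c < self.cols)


def _require_same_grid(a: Grid, b: Grid, what: str) -> None:
    if a != b:
        raise GridAlignmentError(
            f"grid mismatch for {what}: {a.shape}/{a.transform} vs {b.shape}/{b.transform}"
        )


@dataclass
class Raster:
    """A single-band raster: float data, validity mask, grid.

    ``mask`` is True on valid cells.  Data under an invalid cell is
    unspecified (may be NaN); data on valid cells must be finite.
    """

    data: np.ndarray
    mask: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.shape != self.grid.shape or self.mask.shape != self.grid.shape:
            raise GridAlignmentError(
                f"raster data {self.data.shape} / mask {self.mask.shape} "
                f"do not match grid {self.grid.shape}"
            )

    @classmethod
    def full(cls, grid: Grid, value: float = 0.0, valid: bool = True) -> "Raster":
        return cls(
            np.full(grid.shape, value, dtype=np.float64),
            np.full(grid.shape, valid, dtype=bool),
            grid,
        )

    @classmethod
    def from_array(cls, data, grid: Grid | None = None) -> "Raster":
        """Wrap an array; NaNs become masked cells."""
        data = np.asarray(data, dtype=np.float64)
        if grid is None:
            grid = Grid(*data.shape)
        return cls(data, np.isfinite(data), grid)

    def valid_values(self) -> np.ndarray:
        return self.data[self.mask]

    def with_mask(self, mask: np.ndarray) -> "Raster":
        return Raster(self.data, self.mask & np.asarray(mask, dtype=bool), self.grid)

    def filled(self, fill: float = np.nan) -> np.ndarray:
        out = self.data.copy()
        out[~self.mask] = fill
        return out

    def same_grid(self, other: "Raster | Grid", what: str = "raster") -> None:
        grid = other.grid if isinstance(other, Raster) else other
        _require_same_grid(self.grid, grid, what)


class Sensor(enum.Enum):
    """Landsat sensor family the band math is parameterised for."""

    TM = "TM"
    OLI_TIRS = "OLI_TIRS"

    @classmethod
    def parse(cls, value: "str | Sensor") -> "Sensor":
        if isinstance(value, cls):
            return value
        try:
            return cls[str(value).upper().replace("/", "_").replace("-", "_")]
        except KeyError:
            raise ContractError(f"unknown sensor tag {value!r}; expected TM or OLI_TIRS")


REFLECTANCE_BANDS = ("blue", "green", "red", "nir", "swir1", "swir2")
THERMAL_FIELDS = ("thermal_radiance", "brightness_temp", "emissivity")


@dataclass
class Scene:
    """One dated, masked multiband acquisition.

    Reflectance bands are unitless (nominally 0-1); ``thermal_radiance`` is
    at-sensor radiance (W m-2 sr-1 um-1), ``brightness_temp`` kelvin,
    ``emissivity`` in (0, 1], ``water_vapor`` g cm-2 (scalar or raster).
    """

    acquisition_date: Date
    sensor: Sensor
    blue: Raster
    green: Raster
    red: Raster
    nir: Raster
    swir1: Raster
    swir2: Raster
    thermal_radiance: Raster
    brightness_temp: Raster
    emissivity: Raster
    water_vapor: float | Raster
    valid_mask: np.ndarray = None  # type: ignore[assignment]
    scene_id: str = ""

    def __post_init__(self) -> None:
        grid = self.grid
        for name in (*REFLECTANCE_BANDS, *THERMAL_FIELDS):
            band: Raster = getattr(self, name)
            _require_same_grid(band.grid, grid, f"band {name!r}")
        if isinstance(self.water_vapor, Raster):
            _require_same_grid(self.water_vapor.grid, grid, "band 'water_vapor'")
        conj = np.ones(grid.shape, dtype=bool)
        for name in (*REFLECTANCE_BANDS, *THERMAL_FIELDS):
            conj &= getattr(self, name).mask
        if isinstance(self.water_vapor, Raster):
            conj &= self.water_vapor.mask
        if self.valid_mask is None:
            self.valid_mask = conj
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool) & conj

    @property
    def grid(self) -> Grid:
        return self.blue.grid

    def bands(self) -> dict[str, Raster]:
        return {name: getattr(self, name) for name in REFLECTANCE_BANDS}

    def water_vapor_value(self) -> float | np.ndarray:
        if isinstance(self.water_vapor, Raster):
            return self.water_vapor.data
        return float(self.water_vapor)


@dataclass
class IndicatorStack:
    """Co-registered greenness/dryness/wetness/heat rasters for one date."""

    acquisition_date: Date
    ndvi: Raster
    ndbsi: Raster
    wet: Raster
    lst: Raster
    valid_mask: np.ndarray = None  # type: ignore[assignment]
    scene_id: str = ""

    def __post_init__(self) -> None:
        grid = self.grid
        for name in INDICATOR_NAMES:
            _require_same_grid(getattr(self, name).grid, grid, f"indicator {name!r}")
        conj = np.ones(grid.shape, dtype=bool)
        for name in INDICATOR_NAMES:
            conj &= getattr(self, name).mask
        if self.valid_mask is None:
            self.valid_mask = conj
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool) & conj

    @property
    def grid(self) -> Grid:
        return self.ndvi.grid

    def indicator(self, name: str) -> Raster:
        if name not in INDICATOR_NAMES:
            raise ContractError(f"unknown indicator {name!r}")
        return getattr(self, name)

    def as_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(n_valid, 4) matrix of indicator values plus the flat valid index."""
        flat = self.valid_mask.ravel()
        cols = [getattr(self, n).data.ravel()[flat] for n in INDICATOR_NAMES]
        return np.column_stack(cols), np.flatnonzero(flat)

    def replace_indicators(self, **rasters: Raster) -> "IndicatorStack":
        kwargs = {n: rasters.get(n, getattr(self, n)) for n in INDICATOR_NAMES}
        return IndicatorStack(
            acquisition_date=self.acquisition_date,
            scene_id=self.scene_id,
            valid_mask=None,
            **kwargs,
        )


# ---------------------------------------------------------------------------
# GeoTIFF I/O


def write_raster(raster: Raster, path, nodata_value: float = DEFAULT_NODATA) -> Path:
    """Write a single-band GeoTIFF; masked cells get ``nodata_value``.

    Valid cells must be finite (NaN is only permitted under the mask) and
    must not collide with the nodata sentinel.
    """
    path = Path(path)
    valid = raster.valid_values()
    if valid.size and not np.all(np.isfinite(valid)):
        raise ContractError("NaN/inf present in the valid region; mask those cells instead")
    if valid.size and np.any(valid == nodata_value):
        raise ContractError(f"valid data collides with nodata value {nodata_value}")
    data = raster.data.astype(np.float64).copy()
    data[~raster.mask] = nodata_value
    x0, dx, y0, dy = raster.grid.transform
    description = json.dumps({"crs": raster.grid.crs})
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (abs(dx), abs(dy), 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata_value)),
    ]
    try:
        tifffile.imwrite(path, data, description=description, extratags=extratags)
    except OSError as exc:  # unwritable path, disk full, ...
        raise RasterIOError(f"cannot write raster to {path}: {exc}") from exc
    return path


def read_raster(path) -> Raster:
    """Read a single-band GeoTIFF written by :func:`write_raster` (or similar)."""
    path = Path(path)
    if not path.exists():
        raise RasterIOError(f"raster file not found: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            data = page.asarray().astype(np.float64)
            tags = page.tags
            nodata = np.nan
            if _TAG_GDAL_NODATA in tags:
                nodata = float(str(tags[_TAG_GDAL_NODATA].value).strip("\x00 "))
            scale = tags[_TAG_MODEL_PIXEL_SCALE].value if _TAG_MODEL_PIXEL_SCALE in tags else (30.0, 30.0, 0.0)
            tie = tags[_TAG_MODEL_TIEPOINT].value if _TAG_MODEL_TIEPOINT in tags else (0, 0, 0, 0.0, 0.0, 0.0)
            crs = ""
            desc = page.description or ""
            if desc:
                try:
                    crs = json.loads(desc).get("crs", "")
                except (ValueError, AttributeError):
                    crs = ""
    except (tifffile.TiffFileError, KeyError, IndexError) as exc:
        raise RasterIOError(f"cannot read raster {path}: {exc}") from exc
    if data.ndim != 2:
        raise RasterIOError(f"{path} is not single-band (shape {data.shape})")
    mask = np.isfinite(data)
    if np.isfinite(nodata):
        mask &= data != nodata
    grid = Grid(
        rows=data.shape[0],
        cols=data.shape[1],
        transform=(float(tie[3]), float(scale[0]), float(tie[4]), -float(scale[1])),
        crs=crs or Grid.__dataclass_fields__["crs"].default,
    )
    return Raster(data, mask, grid)


# ---------------------------------------------------------------------------
# Scene manifest

MANIFEST_BAND_COLUMNS = (
    "blue",
    "green",
    "red",
    "nir",
    "swir1",
    "swir2",
    "thermal_radiance",
    "brightness_temp",
    "emissivity",
)


@dataclass(frozen=True)
class ManifestRecord:
    scene_id: str
    date: Date
    sensor: Sensor
    band_paths: Mapping[str, str]
    water_vapor: str  # scalar literal or raster path
    qa_mask: str | None = None


@dataclass
class SceneManifest:
    """Ordered scene records, read from / written to a plain CSV.

    Columns: ``scene_id, date, sensor`` then one path column per band,
    ``water_vapor`` (a number or a raster path) and optional ``qa_mask``.
    """

    records: list[ManifestRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.scene_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ContractError(f"duplicate scene identifiers in manifest: {dupes}")

    def __iter__(self) -> Iterator[ManifestRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def read_csv(cls, path) -> "SceneManifest":
        path = Path(path)
        if not path.exists():
            raise RasterIOError(f"manifest not found: {path}")
        records = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                records.append(
                    ManifestRecord(
                        scene_id=row["scene_id"],
                        date=Date.fromisoformat(row["date"]),
                        sensor=Sensor.parse(row["sensor"]),
                        band_paths={b: row[b] for b in MANIFEST_BAND_COLUMNS},
                        water_vapor=row["water_vapor"],
                        qa_mask=row.get("qa_mask") or None,
                    )
                )
        return cls(records)

    def write_csv(self, path) -> Path:
        path = Path(path)
        cols = ["scene_id", "date", "sensor", *MANIFEST_BAND_COLUMNS, "water_vapor", "qa_mask"]
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=cols)
            writer.writeheader()
            for r in self.records:
                row = {
                    "scene_id": r.scene_id,
                    "date": r.date.isoformat(),
                    "sensor": r.sensor.value,
                    "water_vapor": r.water_vapor,
                    "qa_mask": r.qa_mask or "",
                }
                row.update(r.band_paths)
                writer.writerow(row)
        return path


def read_scene(record: ManifestRecord, base_dir=None) -> Scene:
    """Load one manifest record into a :class:`Scene`.

    The scene ``valid_mask`` is the conjunction of all per-band masks and the
    QA mask if one is supplied.  A grid mismatch raises
    :class:`GridAlignmentError` naming the offending band.
    """
    base = Path(base_dir) if base_dir is not None else Path(".")

    def _load(rel: str) -> Raster:
        p = Path(rel)
        return read_raster(p if p.is_absolute() else base / p)

    bands: dict[str, Raster] = {}
    ref_grid: Grid | None = None
    for name in MANIFEST_BAND_COLUMNS:
        r = _load(record.band_paths[name])
        if ref_grid is None:
            ref_grid = r.grid
        else:
            _require_same_grid(r.grid, ref_grid, f"band {name!r}")
        bands[name] = r

    wv: float | Raster
    try:
        wv = float(record.water_vapor)
    except ValueError:
        wv = _load(record.water_vapor)
        _require_same_grid(wv.grid, ref_grid, "band 'water_vapor'")

    qa = None
    if record.qa_mask:
        qa_raster = _load(record.qa_mask)
        _require_same_grid(qa_raster.grid, ref_grid, "band 'qa_mask'")
        qa = qa_raster.mask & (qa_raster.data != 0)

    return Scene(
        acquisition_date=record.date,
        sensor=record.sensor,
        water_vapor=wv,
        valid_mask=qa,
        scene_id=record.scene_id,
        **bands,
    )
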