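"""Model-comparison analytics: deviation tables, profiles, sample statistics.

These are the desk-scale evaluation tools used to compare index models
against one another: elementwise absolute deviation statistics between two
aligned index series, value profiles sampled along a polyline (nearest-cell
rule), and descriptive statistics of a raster at a set of sample points.

Standard deviations use the population convention (divide by n), matching
typical raster-statistics tools; the convention is recorded on the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError
from .raster import Raster

__all__ = [
    "DeviationStats",
    "SampleStats",
    "deviation_stats",
    "extract_profile",
    "sample_stats",
]


@dataclass(frozen=True)
class DeviationStats:
    """Extrema and mean of |a - b| over two aligned series."""

    max: float
    min: float
    mean: float
    n: int


def deviation_stats(series_a, series_b) -> DeviationStats:
    """Absolute elementwise deviations between two equal-length series.

    Symmetric in its arguments; identical series give (0, 0, 0).
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise ContractError(f"series length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ContractError("empty series")
    d = np.abs(a - b)
    return DeviationStats(float(d.max()), float(d.min()), float(d.mean()), int(d.size))


def extract_profile(raster: Raster, polyline, spacing: float) -> pd.DataFrame:
    """Sample a raster along a polyline at fixed spacing, nearest-cell rule.

    ``polyline`` is a sequence of (x, y) world coordinates in the raster
    CRS.  Returns a DataFrame with columns distance, x, y, row, col, value;
    masked or out-of-bounds samples carry value NaN.  Raises if no sample
    point falls inside the raster.
    """
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ContractError("polyline must be >= 2 points of (x, y)")
    if spacing <= 0:
        raise ContractError("spacing must be positive")

    seg_vec = np.diff(pts, axis=0)
    seg_len = np.hypot(seg_vec[:, 0], seg_vec[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = float(cum[-1])
    if total == 0:
        raise ContractError("polyline has zero length")

    distances = np.arange(0.0, total + spacing / 2, spacing)
    distances = distances[distances <= total]
    seg_idx = np.clip(np.searchsorted(cum, distances, side="right") - 1, 0, len(seg_len) - 1)
    frac = np.where(seg_len[seg_idx] > 0, (distances - cum[seg_idx]) / np.where(seg_len[seg_idx] > 0, seg_len[seg_idx], 1.0), 0.0)
    xs = pts[seg_idx, 0] + frac * seg_vec[seg_idx, 0]
    ys = pts[seg_idx, 1] + frac * seg_vec[seg_idx, 1]

    rows, cols = raster.grid.world_to_cell(xs, ys)
    inside = raster.grid.contains(rows, cols)
    if not inside.any():
        raise ContractError("polyline does not intersect the raster (empty profile)")

    values = np.full(distances.shape, np.nan)
    ok = inside.copy()
    ok[inside] &= raster.mask[rows[inside], cols[inside]]
    values[ok] = raster.data[rows[ok], cols[ok]]

    return pd.DataFrame(
        {
            "distance": distances,
            "x": xs,
            "y": ys,
            "row": np.where(inside, rows, -1),
            "col": np.where(inside, cols, -1),
            "value": values,
        }
    )


@dataclass(frozen=True)
class SampleStats:
    """Descriptive statistics of raster values at sample points."""

    max: float
    min: float
    mean: float
    std: float  # population convention (ddof=0)
    variance: float
    n: int
    n_excluded: int  # points outside bounds or on masked cells
    convention: str = "population"


def sample_stats(raster: Raster, points) -> SampleStats:
    """Read the raster at each (x, y) point (nearest cell) and summarize.

    Points outside the raster bounds or on masked cells are excluded and
    counted.  Raises if every point is excluded.
    """
    if isinstance(points, pd.DataFrame):
        pts = points[["x", "y"]].to_numpy(dtype=float)
    else:
        pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] == 0:
        raise ContractError("points must be a nonempty (n, 2) array of (x, y)")

    rows, cols = raster.grid.world_to_cell(pts[:, 0], pts[:, 1])
    inside = raster.grid.contains(rows, cols)
    ok = inside.copy()
    ok[inside] &= raster.mask[rows[inside], cols[inside]]
    if not ok.any():
        raise ContractError("all sample points are masked or out of bounds")

    values = raster.data[rows[ok], cols[ok]]
    return SampleStats(
        max=float(values.max()),
        min=float(values.min()),
        mean=float(values.mean()),
        std=float(values.std(ddof=0)),
        variance=float(values.var(ddof=0)),
        n=int(values.size),
        n_excluded=int((~ok).sum()),
    )
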