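"""Multi-temporal mean compositing of single-phase index rasters.

A composite collapses the per-date index rasters of a period (year, season
or month) into one per-pixel arithmetic mean over the dates where the pixel
is valid, together with an integer raster of contributing-observation
counts.  Pixels valid on no member date are masked with n_obs = 0.  Seasons
follow the meteorological convention (MAM/JJA/SON/DJF) with December
assigned to the following year's winter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date
from typing import Iterable, Sequence

import numpy as np

from .errors import ContractError, GridAlignmentError
from .raster import Grid, Raster

__all__ = [
    "CompositeIndex",
    "PeriodSpec",
    "multi_temporal_mean",
    "seasonal_partition",
    "season_of",
]

_SEASON_OF_MONTH = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}


def season_of(d: Date, convention: str = "meteorological") -> tuple[int, str]:
    """(year, season) of a date; December rolls into next year's winter."""
    if convention != "meteorological":
        raise ContractError(f"unknown season convention {convention!r}")
    season = _SEASON_OF_MONTH[d.month]
    year = d.year + 1 if d.month == 12 else d.year
    return year, season


def seasonal_partition(
    dates: Iterable[Date], convention: str = "meteorological"
) -> dict[Date, tuple[int, str]]:
    """Assign each date to exactly one (year, season)."""
    return {d: season_of(d, convention) for d in dates}


@dataclass(frozen=True)
class PeriodSpec:
    """Select the dates belonging to one compositing period.

    kind "year" with key 2018, "season" with key (2018, "spring"), or
    "month" with key (2018, 4).  kind "all" keeps every date.
    """

    kind: str
    key: object = None

    def label(self) -> str:
        if self.kind == "all":
            return "all"
        if self.kind == "year":
            return str(self.key)
        y, part = self.key  # type: ignore[misc]
        return f"{y}-{part}"

    def member(self, d: Date) -> bool:
        if self.kind == "all":
            return True
        if self.kind == "year":
            return d.year == self.key
        if self.kind == "season":
            return season_of(d) == tuple(self.key)  # type: ignore[arg-type]
        if self.kind == "month":
            y, m = self.key  # type: ignore[misc]
            return d.year == y and d.month == m
        raise ContractError(f"unknown period kind {self.kind!r}")


@dataclass
class CompositeIndex:
    """Per-pixel mean index over a period, with valid-observation counts."""

    period: str
    mean_index: Raster
    n_obs: np.ndarray
    member_dates: list[Date] = field(default_factory=list)

    @property
    def grid(self) -> Grid:
        return self.mean_index.grid


def _dedupe_same_date(phases: Sequence[tuple[Date, Raster]]) -> list[tuple[Date, Raster]]:
    """Average duplicate observations of the same date into one phase.

    Overlapping acquisitions of one day would otherwise double-weight the
    overlap in the temporal mean.
    """
    by_date: dict[Date, list[Raster]] = {}
    for d, r in phases:
        by_date.setdefault(d, []).append(r)
    out = []
    for d in sorted(by_date):
        group = by_date[d]
        if len(group) == 1:
            out.append((d, group[0]))
            continue
        grid = group[0].grid
        total = np.zeros(grid.shape)
        count = np.zeros(grid.shape, dtype=int)
        for r in group:
            r.same_grid(grid, "duplicate-date phase")
            total += np.where(r.mask, r.data, 0.0)
            count += r.mask
        mask = count > 0
        with np.errstate(invalid="ignore"):
            mean = np.divide(total, count, out=np.zeros_like(total), where=mask)
        out.append((d, Raster(mean, mask, grid)))
    return out


def multi_temporal_mean(
    phases: Sequence[tuple[Date, Raster]],
    period_spec: PeriodSpec = PeriodSpec("all"),
    min_obs: int = 1,
) -> CompositeIndex:
    """Per-pixel arithmetic mean over the period's dates where the pixel is valid."""
    if not phases:
        raise ContractError("no phases supplied")
    selected = [(d, r) for d, r in phases if period_spec.member(d)]
    if not selected:
        raise ContractError(f"no phases fall in period {period_spec.label()!r}")
    selected = _dedupe_same_date(selected)
    grid = selected[0][1].grid
    total = np.zeros(grid.shape)
    count = np.zeros(grid.shape, dtype=int)
    for d, r in selected:
        try:
            r.same_grid(grid)
        except GridAlignmentError as exc:
            raise GridAlignmentError(f"phase {d.isoformat()}: {exc}") from exc
        total += np.where(r.mask, r.data, 0.0)
        count += r.mask
    mask = count >= max(1, min_obs)
    mean = np.divide(total, count, out=np.zeros_like(total), where=count > 0)
    return CompositeIndex(
        period=period_spec.label(),
        mean_index=Raster(mean, mask, grid),
        n_obs=count,
        member_dates=[d for d, _ in selected],
    )
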