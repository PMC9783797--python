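"""Dimensionless (min-max) transforms for the indicator time series.

Two scopes exist:

* ``full_sequence`` — extrema are taken jointly over all pixels of all dates,
  giving one strictly increasing affine map per indicator.  Values from any
  two scenes stay comparable, which is what makes a multi-temporal composite
  meaningful.
* ``static_per_scene`` — extrema per single date, the convention of the
  classic single-scene RSEI.  Order is preserved within a date but can invert
  across dates, since each date gets its own map.

The transform is x* = c + (x - min) / (max - min) * d, with shift c and
scale d (defaults 0 and 1).  Fitting is streaming: extrema are accumulated
scene by scene, so the result is independent of visit order and no more than
one stack needs to be resident.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ContractError, FittingError
from .raster import INDICATOR_NAMES, IndicatorStack, Raster

__all__ = [
    "NormalizationParams",
    "fit_full_sequence",
    "fit_static",
    "apply_normalization",
    "normalize_stack",
    "params_from_anchors",
    "save_params",
    "load_params",
]


@dataclass(frozen=True)
class NormalizationParams:
    """Fitted min-max map for one indicator."""

    indicator: str
    scope: str  # "full_sequence" | "static_per_scene"
    min: float
    max: float
    c: float = 0.0
    d: float = 1.0

    def __post_init__(self) -> None:
        if self.max < self.min:
            raise ContractError(f"max < min for {self.indicator}: {self.max} < {self.min}")
        if self.d <= 0:
            raise ContractError(f"scale d must be positive, got {self.d}")

    @property
    def degenerate(self) -> bool:
        return self.max == self.min


def _fit(stacks: Sequence[IndicatorStack], scope: str, c: float, d: float) -> dict[str, NormalizationParams]:
    lo = {name: np.inf for name in INDICATOR_NAMES}
    hi = {name: -np.inf for name in INDICATOR_NAMES}
    for stack in stacks:
        for name in INDICATOR_NAMES:
            values = stack.indicator(name).data[stack.valid_mask]
            if values.size:
                lo[name] = min(lo[name], float(values.min()))
                hi[name] = max(hi[name], float(values.max()))
    params = {}
    for name in INDICATOR_NAMES:
        if not np.isfinite(lo[name]):
            raise FittingError(f"indicator {name!r} has zero valid cells; cannot fit extrema")
        params[name] = NormalizationParams(name, scope, lo[name], hi[name], c, d)
    return params


def fit_full_sequence(
    stacks: Iterable[IndicatorStack], c: float = 0.0, d: float = 1.0
) -> dict[str, NormalizationParams]:
    """Joint extrema over all valid cells of all dates, per indicator."""
    return _fit(list(stacks), "full_sequence", c, d)


def fit_static(stack: IndicatorStack, c: float = 0.0, d: float = 1.0) -> dict[str, NormalizationParams]:
    """Per-scene extrema: the static convention of the single-scene RSEI."""
    return _fit([stack], "static_per_scene", c, d)


def apply_normalization(raster: Raster, params: NormalizationParams) -> Raster:
    """x* = c + (x - min)/(max - min) * d, clipped to [c, c + d].

    Clipping only matters when the params were fitted on a different scene
    set than the raster.  The degenerate max == min case maps every valid
    cell to c.
    """
    if params.degenerate:
        data = np.full(raster.data.shape, params.c, dtype=np.float64)
    else:
        scaled = (raster.data - params.min) / (params.max - params.min)
        data = params.c + np.clip(scaled, 0.0, 1.0) * params.d
    return Raster(data, raster.mask.copy(), raster.grid)


def normalize_stack(stack: IndicatorStack, params: dict[str, NormalizationParams]) -> IndicatorStack:
    """Apply per-indicator params to all four indicators of one stack."""
    missing = [n for n in INDICATOR_NAMES if n not in params]
    if missing:
        raise ContractError(f"missing normalization params for {missing}")
    return stack.replace_indicators(
        **{n: apply_normalization(stack.indicator(n), params[n]) for n in INDICATOR_NAMES}
    )


def params_from_anchors(
    pair_a: tuple[float, float],
    pair_b: tuple[float, float],
    indicator: str = "index",
    scope: str = "full_sequence",
    c: float = 0.0,
    d: float = 1.0,
) -> NormalizationParams:
    """Recover min/max from two known (original, transformed) pairs.

    Solves x* = c + (x - min)/(max - min) * d for min and max given two
    observations of the map.  Useful for reconstructing a published
    normalization from tabulated values.
    """
    (xa, ya), (xb, yb) = pair_a, pair_b
    if xa == xb or ya == yb:
        raise ContractError("anchor pairs must differ in both coordinates")
    slope = (yb - ya) / (xb - xa)  # = d / (max - min)
    if slope <= 0:
        raise ContractError("anchor pairs imply a non-increasing map")
    span = d / slope
    lo = xa - (ya - c) / d * span
    return NormalizationParams(indicator, scope, lo, lo + span, c, d)


def save_params(params: dict[str, NormalizationParams], path) -> Path:
    path = Path(path)
    path.write_text(json.dumps({k: asdict(v) for k, v in params.items()}, indent=2))
    return path


def load_params(path) -> dict[str, NormalizationParams]:
    raw = json.loads(Path(path).read_text())
    return {k: NormalizationParams(**v) for k, v in raw.items()}
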