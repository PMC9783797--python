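"""PC1 aggregation of the four indicators, with deterministic sign choice.

The single-phase index is the projection of the (normalized) indicator
vector onto the first principal component of their covariance matrix.  An
eigenvector is only defined up to sign, which is exactly the classic
instability of PCA-based ecological indices: the same scene can come out
"high is good" or "high is bad" depending on the solver.  The fix is a
convention: greenness (NDVI) always contributes positively, so whenever the
NDVI loading of the first eigenvector is negative the whole vector is
negated.  After that the index is unique and batch computation is safe.

The classic single-scene RSEI is provided as a baseline: static per-scene
normalization, PC1, sign stabilization, then a min-max rescale to [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import ContractError, DegenerateModelError, FittingError
from .indicators import compute_indicator_stack
from .normalization import fit_static, normalize_stack
from .raster import INDICATOR_NAMES, IndicatorStack, Raster, Scene

__all__ = [
    "PC1Model",
    "fit_pc1",
    "stabilize_sign",
    "aggregate_single_phase",
    "single_phase_index",
    "rsei_single_scene",
    "save_model",
    "load_model",
]

DEFAULT_SAMPLE_LIMIT = 2_000_000


@dataclass(frozen=True)
class PC1Model:
    """First principal component of the indicator covariance matrix.

    ``eigenvalues`` are sorted descending and nonnegative; ``eigenvector``
    is l1, unit length.  ``sign_stabilized`` records whether the NDVI-loading
    convention has been applied; aggregation refuses unstabilized models.
    """

    indicator_order: tuple[str, ...]
    eigenvalues: tuple[float, ...]
    eigenvector: tuple[float, ...]
    mean: tuple[float, ...]
    n_samples: int
    seed: int | None = None
    sign_stabilized: bool = False

    @property
    def ndvi_index(self) -> int:
        return self.indicator_order.index("ndvi")

    @property
    def v_ndvi(self) -> float:
        return self.eigenvector[self.ndvi_index]

    @property
    def variance_explained(self) -> float:
        total = sum(self.eigenvalues)
        return self.eigenvalues[0] / total if total > 0 else 0.0


def fit_pc1(
    stack: IndicatorStack,
    sample_limit: int = DEFAULT_SAMPLE_LIMIT,
    seed: int | None = 0,
) -> PC1Model:
    """Eigen-decompose the covariance of the four indicators over valid cells.

    When the stack holds more than ``sample_limit`` valid cells, a uniform
    random subsample (drawn with ``seed``) estimates the covariance; the
    seed is recorded in the model so the fit is reproducible.
    """
    matrix, _ = stack.as_matrix()
    if matrix.shape[0] < 2:
        raise FittingError(f"need at least 2 valid cells to fit PCA, got {matrix.shape[0]}")
    if sample_limit and matrix.shape[0] > sample_limit:
        rng = np.random.default_rng(seed)
        idx = rng.choice(matrix.shape[0], size=sample_limit, replace=False)
        matrix = matrix[np.sort(idx)]
    mean = matrix.mean(axis=0)
    centered = matrix - mean
    cov = centered.T @ centered / (matrix.shape[0] - 1)
    eigenvalues, eigenvectors = np.linalg.eigh(cov)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = np.clip(eigenvalues[order], 0.0, None)  # clip tiny negative round-off
    eigenvectors = eigenvectors[:, order]
    if eigenvalues[0] <= 0:
        raise DegenerateModelError("all sampled cells are identical; covariance has rank 0")
    return PC1Model(
        indicator_order=INDICATOR_NAMES,
        eigenvalues=tuple(float(v) for v in eigenvalues),
        eigenvector=tuple(float(v) for v in eigenvectors[:, 0]),
        mean=tuple(float(v) for v in mean),
        n_samples=int(matrix.shape[0]),
        seed=seed,
    )


def stabilize_sign(model: PC1Model) -> PC1Model:
    """Enforce a positive NDVI loading; idempotent.

    A zero NDVI loading leaves the orientation undefined and raises.
    """
    if model.v_ndvi == 0.0:
        raise ContractError("NDVI loading of PC1 is exactly zero; orientation is undefined")
    if model.v_ndvi < 0.0:
        model = replace(model, eigenvector=tuple(-v for v in model.eigenvector))
    return replace(model, sign_stabilized=True)


def aggregate_single_phase(stack: IndicatorStack, model: PC1Model) -> Raster:
    """Per-cell dot product of the stabilized l1 with the indicator vector.

    The raw projection v . x is used (equivalently: the centered projection
    plus the projected mean), so the score is exactly the sign-convention
    linear combination of the normalized indicators.
    """
    if not model.sign_stabilized:
        raise ContractError("model must be sign-stabilized before aggregation")
    if tuple(model.indicator_order) != INDICATOR_NAMES:
        raise ContractError(f"unexpected indicator order {model.indicator_order}")
    v = np.asarray(model.eigenvector)
    data = np.zeros(stack.grid.shape, dtype=np.float64)
    for weight, name in zip(v, model.indicator_order):
        data += weight * stack.indicator(name).data
    data = np.where(stack.valid_mask, data, 0.0)
    return Raster(data, stack.valid_mask.copy(), stack.grid)


def single_phase_index(
    stack: IndicatorStack, sample_limit: int = DEFAULT_SAMPLE_LIMIT, seed: int | None = 0
) -> tuple[Raster, PC1Model]:
    """Fit, stabilize and project in one step (normalized stack in)."""
    model = stabilize_sign(fit_pc1(stack, sample_limit=sample_limit, seed=seed))
    return aggregate_single_phase(stack, model), model


def rescale_unit(raster: Raster) -> Raster:
    """Min-max rescale of the valid cells to [0, 1]."""
    values = raster.valid_values()
    if values.size == 0:
        raise FittingError("no valid cells to rescale")
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        data = np.zeros_like(raster.data)
    else:
        data = (raster.data - lo) / (hi - lo)
    return Raster(np.where(raster.mask, data, 0.0), raster.mask.copy(), raster.grid)


def rsei_single_scene(
    scene: Scene, sample_limit: int = DEFAULT_SAMPLE_LIMIT, seed: int | None = 0
) -> Raster:
    """Classic single-scene remote-sensing ecological index, sign-repaired.

    indicators -> static per-scene min-max -> PC1 -> positive-NDVI sign ->
    projection -> rescale to [0, 1].
    """
    stack = compute_indicator_stack(scene)
    normalized = normalize_stack(stack, fit_static(stack))
    score, _ = single_phase_index(normalized, sample_limit=sample_limit, seed=seed)
    return rescale_unit(score)


def save_model(model: PC1Model, path) -> Path:
    path = Path(path)
    payload = {
        "indicator_order": list(model.indicator_order),
        "eigenvalues": list(model.eigenvalues),
        "eigenvector": list(model.eigenvector),
        "mean": list(model.mean),
        "n_samples": model.n_samples,
        "seed": model.seed,
        "sign_stabilized": model.sign_stabilized,
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def load_model(path) -> PC1Model:
    raw = json.loads(Path(path).read_text())
    return PC1Model(
        indicator_order=tuple(raw["indicator_order"]),
        eigenvalues=tuple(raw["eigenvalues"]),
        eigenvector=tuple(raw["eigenvector"]),
        mean=tuple(raw["mean"]),
        n_samples=raw["n_samples"],
        seed=raw["seed"],
        sign_stabilized=raw["sign_stabilized"],
    )
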