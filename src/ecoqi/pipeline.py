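"""End-to-end composite-index pipeline.

Stage order: per-scene indicators -> full-sequence min-max normalization
(one affine map per indicator over all dates jointly) -> per-phase PC1
aggregation with the positive-NDVI sign convention -> one full-sequence
min-max rescale of the phase scores over all phases (keeping cross-date
comparability) -> multi-temporal mean per pixel.

Every intermediate parameter set (normalization extrema, PC1 models) is
persisted to JSON next to the output rasters, together with a provenance
sidecar holding the config and its hash, so a run is exactly repeatable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date as Date
from pathlib import Path
from typing import Sequence

import numpy as np

from .aggregation import PC1Model, aggregate_single_phase, fit_pc1, save_model, stabilize_sign
from .composite import CompositeIndex, PeriodSpec, multi_temporal_mean, season_of
from .config import PipelineConfig
from .errors import EcoqiError
from .indicators import compute_indicator_stack, get_sensor_constants
from .normalization import NormalizationParams, fit_full_sequence, normalize_stack, save_params
from .raster import IndicatorStack, Raster, Scene, SceneManifest, Sensor, read_scene, write_raster

__all__ = ["PipelineResult", "run_pipeline", "compute_phase_scores", "composite_index_for_scenes"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Artifacts of one composite-index run."""

    composites: dict[str, CompositeIndex]
    phase_scores: list[tuple[Date, Raster]]
    norm_params: dict[str, NormalizationParams]
    models: dict[str, PC1Model]
    score_extrema: tuple[float, float]
    out_dir: Path | None = None
    provenance: dict = field(default_factory=dict)


def _sensor_overrides(config: PipelineConfig, sensor: Sensor) -> dict:
    block = config.tm_overrides if sensor is Sensor.TM else config.oli_overrides
    data = block.model_dump(exclude_none=True)
    return data


def compute_phase_scores(
    stacks: Sequence[IndicatorStack],
    c: float = 0.0,
    d: float = 1.0,
    pca_scope: str = "per_date",
    seed: int = 0,
    sample_limit: int = 2_000_000,
) -> tuple[list[tuple[Date, Raster]], dict[str, NormalizationParams], dict[str, PC1Model], tuple[float, float]]:
    """Normalized, sign-stabilized, rescaled single-phase scores for all stacks.

    With ``pca_scope='per_date'`` each date gets its own PC1 fit; with
    ``'global'`` one model is fitted on all dates' cells pooled.  The final
    rescale uses one min-max over all phase scores jointly, so phases stay
    comparable.
    """
    if not stacks:
        raise EcoqiError("no indicator stacks supplied")
    params = fit_full_sequence(stacks, c=c, d=d)
    normalized = [normalize_stack(s, params) for s in stacks]

    models: dict[str, PC1Model] = {}
    raw_scores: list[tuple[Date, Raster]] = []
    if pca_scope == "global":
        pooled = np.concatenate([s.as_matrix()[0] for s in normalized], axis=0)
        model = stabilize_sign(_fit_from_matrix(pooled, seed, sample_limit))
        models["global"] = model
        for s in normalized:
            raw_scores.append((s.acquisition_date, aggregate_single_phase(s, model)))
    else:
        for s in normalized:
            model = stabilize_sign(fit_pc1(s, sample_limit=sample_limit, seed=seed))
            models[s.acquisition_date.isoformat()] = model
            raw_scores.append((s.acquisition_date, aggregate_single_phase(s, model)))

    lo = min(float(r.valid_values().min()) for _, r in raw_scores if r.mask.any())
    hi = max(float(r.valid_values().max()) for _, r in raw_scores if r.mask.any())
    span = hi - lo
    scores = []
    for date, r in raw_scores:
        if span > 0:
            data = (r.data - lo) / span
        else:
            data = np.zeros_like(r.data)
        scores.append((date, Raster(np.where(r.mask, data, 0.0), r.mask.copy(), r.grid)))
    return scores, params, models, (lo, hi)


def _fit_from_matrix(matrix: np.ndarray, seed: int, sample_limit: int) -> PC1Model:
    """PC1 fit on an already-pooled (n, 4) matrix (global-scope path)."""
    from .errors import FittingError
    from .raster import INDICATOR_NAMES

    if matrix.shape[0] < 2:
        raise FittingError("need at least 2 pooled cells for a global PCA fit")
    if matrix.shape[0] > sample_limit:
        rng = np.random.default_rng(seed)
        idx = rng.choice(matrix.shape[0], size=sample_limit, replace=False)
        matrix = matrix[np.sort(idx)]
    mean = matrix.mean(axis=0)
    centered = matrix - mean
    cov = centered.T @ centered / (matrix.shape[0] - 1)
    eigenvalues, eigenvectors = np.linalg.eigh(cov)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = np.clip(eigenvalues[order], 0.0, None)
    from .errors import DegenerateModelError

    if eigenvalues[0] <= 0:
        raise DegenerateModelError("pooled cells are identical; covariance has rank 0")
    return PC1Model(
        indicator_order=INDICATOR_NAMES,
        eigenvalues=tuple(float(v) for v in eigenvalues),
        eigenvector=tuple(float(v) for v in eigenvectors[:, order][:, 0]),
        mean=tuple(float(v) for v in mean),
        n_samples=int(matrix.shape[0]),
        seed=seed,
    )


def _periods_present(dates: Sequence[Date], kind: str) -> list[PeriodSpec]:
    if kind == "all":
        return [PeriodSpec("all")]
    if kind == "year":
        return [PeriodSpec("year", y) for y in sorted({d.year for d in dates})]
    if kind == "season":
        return [PeriodSpec("season", key) for key in sorted({season_of(d) for d in dates})]
    return [PeriodSpec("month", key) for key in sorted({(d.year, d.month) for d in dates})]


def composite_index_for_scenes(
    scenes: Sequence[Scene],
    c: float = 0.0,
    d: float = 1.0,
    pca_scope: str = "per_date",
    seed: int = 0,
    sample_limit: int = 2_000_000,
    period: str = "all",
    min_obs: int = 1,
) -> PipelineResult:
    """Library-level pipeline entry: scenes in, composites + params out."""
    stacks = [compute_indicator_stack(s) for s in scenes]
    scores, params, models, extrema = compute_phase_scores(
        stacks, c=c, d=d, pca_scope=pca_scope, seed=seed, sample_limit=sample_limit
    )
    composites = {}
    for spec in _periods_present([s.acquisition_date for s in scenes], period):
        composites[spec.label()] = multi_temporal_mean(scores, spec, min_obs=min_obs)
    return PipelineResult(composites, scores, params, models, extrema)


def run_pipeline(config: PipelineConfig, base_dir=None) -> PipelineResult:
    """Run the full pipeline from a manifest per the config; persist artifacts.

    Any stage failure is re-raised annotated with the stage name and scene
    id.  Rerunning with an identical config and seed yields bit-identical
    rasters.
    """
    manifest_path = Path(config.manifest)
    base = Path(base_dir) if base_dir is not None else manifest_path.parent
    manifest = SceneManifest.read_csv(manifest_path)

    scenes = []
    for record in manifest:
        try:
            scenes.append(read_scene(record, base_dir=base))
        except EcoqiError as exc:
            raise type(exc)(f"stage read_scene, scene {record.scene_id!r}: {exc}") from exc

    stacks = []
    for scene in scenes:
        try:
            overrides = _sensor_overrides(config, scene.sensor)
            constants = get_sensor_constants(scene.sensor, overrides or None)
            stacks.append(compute_indicator_stack(scene, constants, celsius=config.celsius))
        except EcoqiError as exc:
            raise type(exc)(f"stage indicators, scene {scene.scene_id!r}: {exc}") from exc

    try:
        scores, params, models, extrema = compute_phase_scores(
            stacks,
            c=config.c,
            d=config.d,
            pca_scope=config.pca_scope,
            seed=config.seed,
            sample_limit=config.sample_limit,
        )
    except EcoqiError as exc:
        raise type(exc)(f"stage normalization/aggregation: {exc}") from exc

    composites = {}
    for spec in _periods_present([s.acquisition_date for s in stacks], config.period):
        try:
            composites[spec.label()] = multi_temporal_mean(scores, spec, min_obs=config.min_obs)
        except EcoqiError as exc:
            raise type(exc)(f"stage composite, period {spec.label()!r}: {exc}") from exc

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_params(params, out_dir / "normalization_params.json")
    for key, model in models.items():
        save_model(model, out_dir / f"pc1_model_{key}.json")
    for label, comp in composites.items():
        write_raster(comp.mean_index, out_dir / f"composite_{label}.tif")
        write_raster(
            Raster(comp.n_obs.astype(float), np.ones_like(comp.n_obs, dtype=bool), comp.grid),
            out_dir / f"composite_{label}_nobs.tif",
        )
        (out_dir / f"composite_{label}_dates.json").write_text(
            json.dumps([d.isoformat() for d in comp.member_dates])
        )
    provenance = {
        "config": config.model_dump(),
        "config_hash": config.config_hash(),
        "n_scenes": len(scenes),
        "score_extrema": list(extrema),
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    logger.info("pipeline run complete: %d scenes -> %d composites in %s", len(scenes), len(composites), out_dir)
    return PipelineResult(composites, scores, params, models, extrema, out_dir, provenance)
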