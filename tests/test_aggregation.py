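"""PC1 aggregation: eigen-oracle, sign stabilization, RSEI baseline."""

from dataclasses import replace
from datetime import date as Date

import numpy as np
import pytest

from ecoqi.aggregation import (
    aggregate_single_phase,
    fit_pc1,
    load_model,
    rsei_single_scene,
    save_model,
    single_phase_index,
    stabilize_sign,
)
from ecoqi.errors import ContractError, DegenerateModelError
from ecoqi.raster import Grid, IndicatorStack, Raster

from conftest import make_scene


def brute_force_eigenvalues(cov: np.ndarray) -> np.ndarray:
    """Independent eigen-solution via the characteristic polynomial (sympy)."""
    import sympy as sp

    poly = sp.Matrix(cov).charpoly()
    roots = np.roots([float(c) for c in poly.all_coeffs()])
    return np.sort(roots.real)[::-1]


def stack_from_matrix(matrix: np.ndarray, date=Date(2018, 6, 1)) -> IndicatorStack:
    """IndicatorStack whose four indicator planes hold the matrix columns."""
    n = matrix.shape[0]
    grid = Grid(n, 1)
    rasters = {}
    for i, name in enumerate(("ndvi", "ndbsi", "wet", "lst")):
        rasters[name] = Raster(matrix[:, i].reshape(n, 1), np.ones((n, 1), bool), grid)
    return IndicatorStack(acquisition_date=date, **rasters)


@pytest.fixture
def random_stack():
    rng = np.random.default_rng(11)
    base = rng.normal(size=200)
    matrix = np.column_stack(
        [
            base + rng.normal(0, 0.3, 200),
            -0.8 * base + rng.normal(0, 0.4, 200),
            0.5 * base + rng.normal(0, 0.5, 200),
            -0.3 * base + rng.normal(0, 0.6, 200),
        ]
    )
    return stack_from_matrix(matrix), matrix


class TestFitPc1:
    def test_eigenvalues_match_characteristic_polynomial_oracle(self, random_stack):
        stack, matrix = random_stack
        model = fit_pc1(stack, seed=0)
        cov = np.cov(matrix.T, ddof=1)
        expected = brute_force_eigenvalues(cov)
        assert np.allclose(model.eigenvalues, expected, atol=1e-10)

    def test_known_solution_for_correlated_pair(self):
        # two perfectly correlated columns + two constant columns:
        # l1 is (+-1/sqrt2, +-1/sqrt2, 0, 0) and only one eigenvalue is nonzero
        t = np.linspace(-1, 1, 50)
        matrix = np.column_stack([t, t, np.zeros_like(t), np.zeros_like(t)])
        model = fit_pc1(stack_from_matrix(matrix), seed=0)
        v = np.abs(np.asarray(model.eigenvector))
        assert v[:2] == pytest.approx([1 / np.sqrt(2)] * 2, abs=1e-10)
        assert v[2:] == pytest.approx([0, 0], abs=1e-10)
        assert model.eigenvalues[1] == pytest.approx(0.0, abs=1e-10)

    def test_unit_length_and_descending_nonnegative_eigenvalues(self, random_stack):
        model = fit_pc1(random_stack[0], seed=0)
        assert np.linalg.norm(model.eigenvector) == pytest.approx(1.0, abs=1e-12)
        ev = np.asarray(model.eigenvalues)
        assert np.all(ev >= 0) and np.all(np.diff(ev) <= 1e-12)

    def test_rayleigh_identity(self, random_stack):
        # lambda1 equals the variance of the data projected onto l1
        stack, matrix = random_stack
        model = fit_pc1(stack, seed=0)
        projected = (matrix - matrix.mean(axis=0)) @ np.asarray(model.eigenvector)
        assert model.eigenvalues[0] == pytest.approx(projected.var(ddof=1), abs=1e-8)

    def test_pc1_pc2_projections_uncorrelated(self, random_stack):
        stack, matrix = random_stack
        model = fit_pc1(stack, seed=0)
        centered = matrix - matrix.mean(axis=0)
        cov = np.cov(matrix.T, ddof=1)
        eigvals, eigvecs = np.linalg.eigh(cov)
        l2 = eigvecs[:, np.argsort(eigvals)[::-1][1]]
        r = np.corrcoef(centered @ np.asarray(model.eigenvector), centered @ l2)[0, 1]
        assert abs(r) < 1e-6
        assert 0 < model.variance_explained <= 1

    def test_subsampling_is_seed_deterministic(self, random_stack):
        stack, _ = random_stack
        a = fit_pc1(stack, sample_limit=50, seed=42)
        b = fit_pc1(stack, sample_limit=50, seed=42)
        assert a == b
        assert a.n_samples == 50

    def test_rank_zero_data_raises(self):
        matrix = np.ones((20, 4))
        with pytest.raises(DegenerateModelError):
            fit_pc1(stack_from_matrix(matrix), seed=0)


class TestSignStabilization:
    def test_negative_ndvi_loading_flips_whole_vector(self):
        model = fit_pc1(stack_from_matrix(np.random.default_rng(1).normal(size=(50, 4))), seed=0)
        forced = replace(model, eigenvector=(-0.6, 0.5, -0.5, 0.37))
        out = stabilize_sign(forced)
        assert out.eigenvector == (0.6, -0.5, 0.5, -0.37)
        assert out.sign_stabilized

    def test_positive_ndvi_loading_unchanged_and_idempotent(self):
        model = fit_pc1(stack_from_matrix(np.random.default_rng(2).normal(size=(50, 4))), seed=0)
        forced = replace(model, eigenvector=(0.6, 0.5, -0.5, -0.37))
        once = stabilize_sign(forced)
        assert once.eigenvector == forced.eigenvector
        assert stabilize_sign(once) == once

    def test_zero_ndvi_loading_is_unstabilizable(self):
        model = fit_pc1(stack_from_matrix(np.random.default_rng(3).normal(size=(50, 4))), seed=0)
        with pytest.raises(ContractError, match="zero"):
            stabilize_sign(replace(model, eigenvector=(0.0, 1.0, 0.0, 0.0)))


class TestAggregation:
    def test_pure_ndvi_model_projects_ndvi(self, random_stack):
        stack, matrix = random_stack
        model = fit_pc1(stack, seed=0)
        model = replace(model, eigenvector=(1.0, 0.0, 0.0, 0.0), sign_stabilized=True)
        out = aggregate_single_phase(stack, model)
        assert np.allclose(out.data, stack.ndvi.data)

    def test_adversarial_eigenvector_negation_is_invisible(self, random_stack):
        # THE instability fix: whatever orientation the solver returns,
        # the stabilized projection is identical
        stack, _ = random_stack
        model = fit_pc1(stack, seed=0)
        flipped = replace(model, eigenvector=tuple(-v for v in model.eigenvector))
        a = aggregate_single_phase(stack, stabilize_sign(model))
        b = aggregate_single_phase(stack, stabilize_sign(flipped))
        assert np.array_equal(a.data, b.data)

    def test_unstabilized_model_rejected(self, random_stack):
        stack, _ = random_stack
        with pytest.raises(ContractError, match="stabilized"):
            aggregate_single_phase(stack, fit_pc1(stack, seed=0))

    def test_uniform_stack_would_be_degenerate_but_near_uniform_is_uniformish(self):
        rng = np.random.default_rng(5)
        matrix = 0.5 + rng.normal(0, 1e-9, size=(30, 4))
        score, _ = single_phase_index(stack_from_matrix(matrix), seed=0)
        assert np.ptp(score.data) < 1e-7

    def test_model_json_round_trip(self, tmp_path, random_stack):
        model = stabilize_sign(fit_pc1(random_stack[0], seed=0))
        save_model(model, tmp_path / "m.json")
        assert load_model(tmp_path / "m.json") == model


class TestRseiBaseline:
    @pytest.fixture
    def structured_scene(self):
        # left half vegetated (high nir, moist), right half bare (bright, dry, hot)
        grid = Grid(8, 8)
        half = np.zeros(grid.shape, bool)
        half[:, :4] = True
        rng = np.random.default_rng(9)

        def band(veg, bare, jitter=0.01):
            return np.where(half, veg, bare) + rng.normal(0, jitter, grid.shape)

        return make_scene(
            grid=grid,
            nir=band(0.55, 0.25),
            red=band(0.06, 0.35),
            green=band(0.1, 0.25),
            blue=band(0.04, 0.15),
            swir1=band(0.1, 0.45),
            swir2=band(0.08, 0.4),
            brightness_temp=band(295.0, 305.0, jitter=0.2),
        ), half

    def test_output_spans_unit_interval(self, structured_scene):
        scene, _ = structured_scene
        out = rsei_single_scene(scene, seed=0)
        assert out.valid_values().min() == pytest.approx(0.0, abs=1e-12)
        assert out.valid_values().max() == pytest.approx(1.0, abs=1e-12)

    def test_vegetated_cells_score_above_bare_cells(self, structured_scene):
        scene, veg_mask = structured_scene
        out = rsei_single_scene(scene, seed=0)
        assert out.data[veg_mask].mean() > out.data[~veg_mask].mean()

    def test_rerun_is_bit_identical(self, structured_scene):
        scene, _ = structured_scene
        a = rsei_single_scene(scene, seed=0)
        b = rsei_single_scene(scene, seed=0)
        assert np.array_equal(a.data, b.data) and np.array_equal(a.mask, b.mask)
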