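import numpy as np
import pandas as pd
import pytest

from littersim import (
    GridSpec,
    LMCModel,
    Structure,
    cokrige,
    decompose_lmc,
    etype_mean,
    run_cosimulation,
    turning_bands_unconditional,
)
from littersim.cosimulation import CokrigingSystem
from littersim.exceptions import InvalidModelError, SingularSystemError

from .oracles import dense_gaussian_cosimulation


def _samples_df(xy, values):
    return pd.DataFrame(
        {
            "x": xy[:, 0],
            "y": xy[:, 1],
            "butts_per_m2": values[:, 0],
            "sharp_per_m2": values[:, 1],
        }
    )


class TestDecomposeLMC:
    def test_identity_sill(self):
        m = LMCModel((Structure("nugget", np.eye(2)),))
        (A,) = decompose_lmc(m)
        np.testing.assert_allclose(A @ A.T, np.eye(2), atol=1e-12)

    def test_reference_spherical_sill_reconstructs(self, beach_model):
        factors = decompose_lmc(beach_model)
        for A, s in zip(factors, beach_model.structures):
            np.testing.assert_allclose(A @ A.T, s.sill, atol=1e-10)

    def test_rank_one_sill_single_factor(self):
        m = LMCModel((Structure("nugget", [[1.0, 1.0], [1.0, 1.0]]),))
        (A,) = decompose_lmc(m)
        norms = np.linalg.norm(A, axis=0)
        assert (norms > 1e-8).sum() == 1
        np.testing.assert_allclose(A @ A.T, [[1.0, 1.0], [1.0, 1.0]], atol=1e-12)

    def test_materially_indefinite_rejected(self):
        m = LMCModel((Structure("nugget", [[1.0, 1.5], [1.5, 1.0]]),))
        with pytest.raises(InvalidModelError):
            decompose_lmc(m)


class TestTurningBands:
    def test_variance_and_long_range_decorrelation(self, beach_model):
        pts = np.array([[0.0, 0.0], [0.0, 200.0]])
        R = 2500
        acc = np.zeros((R, 2, 2))
        for r in range(R):
            acc[r] = turning_bands_unconditional(beach_model, pts, n_lines=300,
                                                 rng=r)
        var = acc.reshape(R, 4).var(axis=0)
        np.testing.assert_allclose(var, 1.0, atol=3 * np.sqrt(2 / R) + 0.02)
        cross_site = np.mean(acc[:, 0, 0] * acc[:, 1, 0])
        assert abs(cross_site) < 3 / np.sqrt(R) + 0.02

    def test_cross_correlation_at_zero_lag(self, beach_model):
        R = 2500
        z = np.array(
            [
                turning_bands_unconditional(beach_model, [[5.0, 5.0]],
                                            n_lines=300, rng=10_000 + r)[0]
                for r in range(R)
            ]
        )
        c = np.mean(z[:, 0] * z[:, 1])
        assert c == pytest.approx(0.79, abs=3 / np.sqrt(R) + 0.02)

    def test_matches_dense_factorization_oracle(self, beach_model, rng):
        # scaled-range model so structure is visible on a small grid
        model = LMCModel(
            (
                Structure("nugget", [[0.075, 0.02], [0.02, 0.115]]),
                Structure("spherical", [[0.925, 0.77], [0.77, 0.885]],
                          a_max=8.0, a_min=3.0),
            )
        )
        grid = GridSpec(nx=7, ny=7)
        pts = grid.node_coords()
        R = 600
        tb = np.array(
            [
                turning_bands_unconditional(model, pts, n_lines=300, rng=r)
                for r in range(R)
            ]
        )
        oracle = dense_gaussian_cosimulation(model, pts, R, rng)
        def cov_of(stack):
            flat = stack.transpose(0, 2, 1).reshape(R, -1)
            return flat.T @ flat / R

        diff = np.abs(cov_of(tb) - cov_of(oracle))
        # both are MC estimates: allow 3 x combined standard error
        assert diff.max() < 3 * np.sqrt(2 / R) * 2

    def test_deterministic_under_seed(self, beach_model):
        pts = np.array([[0.0, 0.0], [3.0, 40.0]])
        a = turning_bands_unconditional(beach_model, pts, n_lines=200, rng=5)
        b = turning_bands_unconditional(beach_model, pts, n_lines=200, rng=5)
        np.testing.assert_array_equal(a, b)


class TestCokriging:
    def test_exact_interpolation_at_data(self, beach_model, rng):
        xy = rng.uniform(0, 40, size=(15, 2))
        scores = rng.standard_normal((15, 2))
        est, var = cokrige(xy, scores, beach_model, xy)
        np.testing.assert_allclose(est, scores, atol=1e-8)
        np.testing.assert_allclose(var, 0.0, atol=1e-8)

    def test_single_datum_closed_form(self):
        m = LMCModel((Structure("spherical", np.eye(2), a_max=84.0, a_min=84.0),))
        est, var = cokrige(
            np.array([[0.0, 0.0]]),
            np.array([[2.0, 0.0]]),
            m,
            np.array([[0.0, 42.0], [0.0, 500.0]]),
        )
        assert est[0, 0] == pytest.approx(0.3125 * 2.0)
        assert est[1, 0] == pytest.approx(0.0, abs=1e-12)  # beyond range -> mean
        assert var[0, 0] == pytest.approx(1.0 - 0.3125**2)

    def test_duplicate_locations_named(self, beach_model):
        xy = np.array([[1.0, 1.0], [1.0, 1.0], [5.0, 5.0]])
        with pytest.raises(SingularSystemError) as exc:
            CokrigingSystem(xy, beach_model)
        assert exc.value.duplicates

    def test_ordinary_mode_translation_equivariance(self, beach_model, rng):
        # unbiasedness constraints: own-variable weights sum to 1, cross
        # weights to 0, so shifting one variable shifts only its estimates
        xy = rng.uniform(0, 30, size=(25, 2))
        scores = rng.standard_normal((25, 2))
        targets = np.array([[10.0, 10.0], [500.0, 500.0]])
        est, _ = cokrige(xy, scores, beach_model, targets, mode="ordinary")
        shifted = scores.copy()
        shifted[:, 0] += 5.0
        est2, _ = cokrige(xy, shifted, beach_model, targets, mode="ordinary")
        np.testing.assert_allclose(est2[:, 0], est[:, 0] + 5.0, atol=1e-8)
        np.testing.assert_allclose(est2[:, 1], est[:, 1], atol=1e-8)


class TestRunCosimulation:
    def test_conditioning_exactness(self, small_truth):
        from littersim import draw_survey

        samples = draw_survey(small_truth, n=40, seed=3)
        stack = run_cosimulation(samples, small_truth.model, small_truth.grid,
                                 n_real=5, seed=11, n_lines=300)
        node = small_truth.grid.node_index(samples[["x", "y"]].to_numpy())
        for v, col in enumerate(stack.var_names):
            data = samples[col].to_numpy()
            sim = stack.values[:, node, v]
            assert np.max(np.abs(sim - data[None, :])) < 1e-5

    def test_fully_conditioned_grid_reproduces_data(self, rng):
        grid = GridSpec(nx=5, ny=5)
        m = LMCModel(
            (
                Structure("nugget", 0.1 * np.eye(2)),
                Structure("spherical", 0.9 * np.eye(2), a_max=6.0, a_min=6.0),
            )
        )
        vals = rng.lognormal(0.5, 0.7, size=(grid.n_nodes, 2))
        samples = _samples_df(grid.node_coords(), vals)
        stack = run_cosimulation(samples, m, grid, n_real=1, seed=2, n_lines=200)
        np.testing.assert_allclose(stack.values[0], vals, rtol=1e-5, atol=1e-6)

    def test_determinism_and_exchangeability(self, small_truth):
        from littersim import draw_survey

        samples = draw_survey(small_truth, n=25, seed=4)
        kw = dict(n_real=4, seed=9, n_lines=200)
        s1 = run_cosimulation(samples, small_truth.model, small_truth.grid, **kw)
        s2 = run_cosimulation(samples, small_truth.model, small_truth.grid, **kw)
        np.testing.assert_array_equal(s1.values, s2.values)
        # realization order does not affect the E-type map
        perm = np.random.default_rng(0).permutation(s1.n_real)
        np.testing.assert_allclose(s1.values[perm].mean(axis=0), s1.etype_mean())

    def test_etype_examples_and_cokriging_consistency(self, small_truth):
        from littersim import draw_survey
        from littersim.transforms import normal_scores
        from scipy.stats import spearmanr

        samples = draw_survey(small_truth, n=30, seed=5)
        stack = run_cosimulation(samples, small_truth.model, small_truth.grid,
                                 n_real=200, seed=13, n_lines=200)
        # trivial identities
        two = stack.values[:2].copy()
        two[0] = 1.0
        two[1] = 3.0
        assert np.allclose(two.mean(axis=0), 2.0)
        # E-type mean tracks the cokriging estimate (monotone back-transform)
        node = small_truth.grid.node_index(samples[["x", "y"]].to_numpy())
        scores = np.column_stack(
            [normal_scores(samples[c].to_numpy(), tie_seed=1)[0]
             for c in stack.var_names]
        )
        est, _ = cokrige(small_truth.grid.node_coords()[node], scores,
                         small_truth.model, small_truth.grid.node_coords())
        rho = spearmanr(etype_mean(stack)[:, 0], est[:, 0]).statistic
        assert rho > 0.95
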