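import numpy as np
import pytest

from littersim import (
    GridSpec,
    LMCModel,
    Structure,
    beach_litter_lmc,
    check_psd,
    evaluate_model,
    experimental_variogram,
    fit_lmc,
    grid_variogram_set,
    pool_variograms,
    turning_bands_unconditional,
    variogram_set,
)
from littersim.exceptions import FittingError, InvalidModelError
from littersim.variography import ExperimentalVariogram, azimuth_direction

from .oracles import brute_variogram


class TestExperimentalVariogram:
    def test_collinear_direct_hand_example(self):
        xy = np.array([[0.0, 0.0], [0.0, 1.0], [0.0, 2.0]])
        vg = experimental_variogram(xy, [1.0, 2.0, 4.0], azimuth=0.0,
                                    lag_centres=[1.0, 2.0])
        np.testing.assert_allclose(vg.gamma, [1.25, 4.5])
        np.testing.assert_array_equal(vg.counts, [2, 1])

    def test_collinear_cross_hand_example(self):
        xy = np.array([[0.0, 0.0], [0.0, 1.0], [0.0, 2.0]])
        vg = experimental_variogram(xy, [1.0, 2.0, 4.0], [2.0, 3.0, 5.0],
                                    azimuth=0.0, lag_centres=[1.0])
        assert vg.gamma[0] == pytest.approx(1.25)

    def test_constant_field_is_zero(self, rng):
        xy = rng.uniform(0, 20, size=(40, 2))
        vg = experimental_variogram(xy, np.full(40, 3.3), azimuth=0.0,
                                    lag_centres=np.arange(1.0, 10.0), ang_tol=90.0)
        assert np.allclose(vg.gamma[vg.counts > 0], 0.0)

    def test_pair_exchange_symmetry(self, rng):
        xy = rng.uniform(0, 30, size=(60, 2))
        za, zb = rng.standard_normal(60), rng.standard_normal(60)
        kw = dict(azimuth=30.0, lag_centres=np.arange(2.0, 20.0, 2.0), ang_tol=40.0)
        vab = experimental_variogram(xy, za, zb, **kw)
        vba = experimental_variogram(xy, zb, za, **kw)
        np.testing.assert_allclose(
            np.nan_to_num(vab.gamma), np.nan_to_num(vba.gamma), atol=1e-12
        )

    def test_matches_brute_force_oracle(self, rng):
        xy = rng.uniform(0, 15, size=(35, 2))
        za, zb = rng.standard_normal(35), rng.standard_normal(35)
        lags = np.arange(1.0, 9.0)
        vg = experimental_variogram(xy, za, zb, azimuth=70.0, lag_centres=lags,
                                    ang_tol=25.0)
        g, n = brute_variogram(xy, za, zb, 70.0, lags, 0.5, 25.0)
        np.testing.assert_array_equal(vg.counts, n)
        np.testing.assert_allclose(np.nan_to_num(vg.gamma), np.nan_to_num(g),
                                   atol=1e-12)

    def test_empty_variogram_warns(self):
        xy = np.array([[0.0, 0.0], [100.0, 0.0]])
        with pytest.warns(UserWarning, match="no pairs"):
            vg = experimental_variogram(xy, [1.0, 2.0], azimuth=0.0,
                                        lag_centres=[1.0, 2.0])
        assert vg.is_empty
        assert np.all(np.isnan(vg.gamma))

    def test_grid_fast_path_equals_scattered(self, rng):
        grid = GridSpec(nx=9, ny=11)
        z = rng.standard_normal((grid.n_nodes, 2))
        lags = np.arange(1.0, 7.0)
        for az in (0.0, 90.0):
            fast = grid_variogram_set(grid, z, azimuths=(az,), lag_centres=lags)
            slow = variogram_set(grid.node_coords(), z, azimuths=(az,),
                                 lag_centres=lags)
            for f, s in zip(fast, slow):
                np.testing.assert_array_equal(f.counts, s.counts)
                np.testing.assert_allclose(np.nan_to_num(f.gamma),
                                           np.nan_to_num(s.gamma), atol=1e-10)


class TestModelEvaluation:
    def test_zero_lag_is_zero_matrix(self, beach_model):
        np.testing.assert_array_equal(
            evaluate_model(beach_model, [0.0, 0.0]), np.zeros((2, 2))
        )

    def test_half_range_spherical_value(self):
        m = LMCModel((Structure("spherical", [[1.0, 0.0], [0.0, 1.0]],
                                a_max=84.0, a_min=84.0),))
        g = evaluate_model(m, [0.0, 42.0])
        assert g[0, 0] == pytest.approx(0.6875)

    def test_beyond_range_reaches_total_sill(self, beach_model):
        for lag in ([0.0, 200.0], [200.0, 0.0], [150.0, 150.0]):
            np.testing.assert_allclose(
                evaluate_model(beach_model, lag),
                [[1.0, 0.79], [0.79, 1.0]],
                atol=1e-12,
            )

    def test_anisotropic_ranges_along_axes(self, beach_model):
        # along-shore the spherical structure saturates at 84 m, cross-shore at 27 m
        g_along = evaluate_model(beach_model, [0.0, 83.0])
        g_across = evaluate_model(beach_model, [27.5, 0.0])
        assert g_along[0, 0] < 1.0
        assert g_across[0, 0] == pytest.approx(1.0)

    def test_increment_variance_nonnegative(self, beach_model, rng):
        # for any zero-sum-per-variable weights, -sum l_i l_j gamma(h_ij) >= 0
        for _ in range(20):
            pts = rng.uniform(0, 60, size=(6, 2))
            lam = rng.standard_normal((6, 2))
            lam -= lam.mean(axis=0)
            g = beach_model.semivariance(
                (pts[:, None, :] - pts[None, :, :]).reshape(-1, 2)
            ).reshape(6, 6, 2, 2)
            q = -np.einsum("ia,jb,ijab->", lam, lam, g)
            assert q >= -1e-9


class TestPSD:
    def test_reference_model_passes(self, beach_model):
        report = check_psd(beach_model)
        assert report.passed
        assert all(e.min() >= 0 for e in report.eigenvalues)

    def test_indefinite_sill_fails(self):
        m = LMCModel((Structure("nugget", [[1.0, 1.5], [1.5, 1.0]]),))
        report = check_psd(m)
        assert not report.passed
        np.testing.assert_allclose(report.eigenvalues[0], [-0.5, 2.5])

    def test_zero_matrix_passes(self):
        m = LMCModel((Structure("nugget", np.zeros((2, 2))),))
        assert check_psd(m).passed

    def test_negative_range_rejected(self):
        with pytest.raises(InvalidModelError):
            Structure("spherical", np.eye(2), a_max=-5.0, a_min=3.0)


class TestFitLMC:
    @staticmethod
    def _pseudo_data(model, azimuths=(0.0, 90.0), max_lag=100.0):
        vgs = []
        for az in azimuths:
            u = azimuth_direction(az)
            lags = np.arange(1.0, max_lag + 0.5)
            G = model.semivariance(np.outer(lags, u))
            for a, b in ((0, 0), (0, 1), (1, 1)):
                vgs.append(
                    ExperimentalVariogram(a, b, az, lags, G[:, a, b],
                                          np.full(lags.size, 100), 0.5, 0.0)
                )
        return vgs

    def test_exact_curves_recovered(self, beach_model):
        model, info = fit_lmc(self._pseudo_data(beach_model))
        assert info.ranges[0] == pytest.approx(84.0, rel=0.01)
        assert info.ranges[1] == pytest.approx(27.0, rel=0.01)
        for fitted, ref in zip(model.structures, beach_model.structures):
            np.testing.assert_allclose(fitted.sill, ref.sill, atol=0.01)
        assert check_psd(model).passed

    def test_white_noise_gives_nugget_covariance(self, rng):
        n = 400
        xy = rng.uniform(0, 40, size=(n, 2))
        L = np.linalg.cholesky([[1.0, 0.3], [0.3, 1.0]])
        z = rng.standard_normal((n, 2)) @ L.T
        vgs = variogram_set(xy, z, azimuths=(0.0,), ang_tol=90.0,
                            lag_centres=np.arange(2.0, 20.0, 2.0))
        model, _ = fit_lmc(vgs, structures=("nugget",))
        np.testing.assert_allclose(model.structures[0].sill, np.cov(z.T), atol=0.25)

    def test_range_recovery_from_simulation(self, rng):
        # moderate ranges relative to the domain keep ergodic fluctuation low
        truth = LMCModel(
            (
                Structure("nugget", [[0.1, 0.05], [0.05, 0.1]]),
                Structure("spherical", [[0.9, 0.7], [0.7, 0.9]],
                          a_max=12.0, a_min=5.0),
            )
        )
        grid = GridSpec(nx=40, ny=40)
        sets = [
            grid_variogram_set(
                grid,
                turning_bands_unconditional(truth, grid.node_coords(),
                                            n_lines=400, rng=100 + r),
                azimuths=(0.0, 90.0),
                lag_centres=np.arange(1.0, 21.0),
            )
            for r in range(4)
        ]
        model, info = fit_lmc(pool_variograms(sets))
        assert info.ranges[0] == pytest.approx(12.0, rel=0.3)
        assert info.ranges[1] == pytest.approx(5.0, rel=0.3)
        assert check_psd(model).passed

    def test_missing_cross_variogram_rejected(self, beach_model):
        vgs = [v for v in self._pseudo_data(beach_model) if v.var_a == v.var_b]
        with pytest.raises(FittingError, match="cross"):
            fit_lmc(vgs)
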