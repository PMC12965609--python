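"""Semivariograms, ordinary kriging, CV model selection, surface correction."""

import numpy as np
import pytest
from shapely.geometry import box
from scipy.spatial.distance import pdist, squareform

from pixelyield.kriging import (
    ResidualField,
    VariogramModel,
    compute_residuals,
    correct_yield_surface,
    empirical_semivariogram,
    fit_variogram,
    fit_variogram_to_field,
    krige_residual_surface,
    ordinary_kriging,
    select_variogram_cv,
)
from pixelyield.regions import VillageMap


def _field(n=30, seed=0, values=None):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, 1000, (n, 2))
    vals = rng.normal(size=n) if values is None else values
    return ResidualField(pts, vals)


class TestResiduals:
    def _villages(self, yields):
        n = len(yields)
        return VillageMap(
            np.array([f"v{i}" for i in range(n)], dtype=object),
            np.array(["B0"] * n, dtype=object),
            [box(i * 10, 0, i * 10 + 5, 5) for i in range(n)],
            np.array(yields, dtype=float),
        )

    def test_subtraction(self):
        vm = self._villages([40.0, 50.0])
        f = compute_residuals(vm, np.array([42.0, 47.0]))
        np.testing.assert_allclose(f.values, [-2.0, 3.0])

    def test_perfect_predictions_zero_field(self):
        vm = self._villages([40.0, 50.0, 45.0])
        f = compute_residuals(vm, vm.observed_yield.copy())
        np.testing.assert_array_equal(f.values, 0.0)

    def test_mean_linearity(self):
        rng = np.random.default_rng(1)
        y = rng.normal(40, 3, 10)
        yhat = rng.normal(40, 3, 10)
        f = compute_residuals(self._villages(y), yhat)
        assert f.values.mean() == pytest.approx(y.mean() - yhat.mean())

    def test_unmatched_ids_rejected(self):
        import pandas as pd

        vm = self._villages([40.0, 50.0])
        preds = pd.DataFrame({"village_id": ["v0"], "mean": [41.0]})
        with pytest.raises(ValueError, match="missing"):
            compute_residuals(vm, preds)


class TestEmpiricalSemivariogram:
    def test_constant_residuals_give_zero(self):
        f = _field(values=np.full(30, 2.5))
        _, gamma, counts = empirical_semivariogram(f)
        np.testing.assert_allclose(gamma[counts > 0], 0.0)

    def test_two_points_hand_value(self):
        f = ResidualField(np.array([[0.0, 0.0], [30.0, 40.0]]), np.array([0.0, 2.0]))
        lags, gamma, counts = empirical_semivariogram(f, n_lags=5, max_dist=60.0)
        k = np.flatnonzero(counts)[0]
        assert gamma[k] == pytest.approx(2.0)  # (0-2)^2 / (2*1)
        assert counts.sum() == 1

    def test_full_distance_counts_all_pairs(self):
        f = _field(n=10, seed=2)
        d = pdist(f.points)
        _, _, counts = empirical_semivariogram(f, n_lags=8, max_dist=d.max())
        assert counts.sum() == 45  # n(n-1)/2

    def test_coincident_points_rejected(self):
        f = ResidualField(np.zeros((3, 2)), np.arange(3.0))
        with pytest.raises(ValueError, match="coincident"):
            empirical_semivariogram(f)


class TestFitVariogram:
    def test_recovers_exact_spherical_curve(self):
        lags = np.linspace(20, 800, 15)
        truth = VariogramModel("spherical", 0.3, 2.0, 500.0)
        gamma = truth(lags)
        model = fit_variogram(lags, gamma, np.full(15, 50.0), "spherical")
        assert model.sill == pytest.approx(2.0, rel=0.01)
        assert model.range_ == pytest.approx(500.0, rel=0.01)
        assert model.nugget == pytest.approx(0.3, abs=0.01)

    def test_flat_semivariogram_becomes_pure_nugget(self):
        lags = np.linspace(20, 800, 12)
        model = fit_variogram(lags, np.full(12, 1.7), np.full(12, 30.0), "exponential")
        # the fitted curve is flat at the nugget level: no spatial structure
        assert model(np.array([20.0]))[0] == pytest.approx(1.7, rel=0.05)
        assert model(np.array([500.0]))[0] == pytest.approx(1.7, rel=0.05)

    def test_scaling_residuals_scales_sill_quadratically(self):
        f = _field(n=60, seed=3)
        m1 = fit_variogram_to_field(f, "exponential")
        f2 = ResidualField(f.points, 3.0 * f.values)
        m2 = fit_variogram_to_field(f2, "exponential")
        total1 = m1.nugget + m1.sill
        total2 = m2.nugget + m2.sill
        assert total2 == pytest.approx(9.0 * total1, rel=0.05)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="three"):
            fit_variogram(np.array([1.0, 2.0]), np.array([0.5, 0.6]),
                          np.array([4, 4]), "spherical")


class TestOrdinaryKriging:
    def test_exact_at_data_points_with_zero_nugget(self):
        f = _field(n=12, seed=5)
        model = VariogramModel("exponential", 0.0, 1.0, 300.0)
        preds = ordinary_kriging(f.points, f.values, model, f.points)
        np.testing.assert_allclose(preds, f.values, atol=1e-8)

    def test_nugget_smooths_at_data_points(self):
        f = _field(n=12, seed=5)
        model = VariogramModel("exponential", 0.5, 1.0, 300.0)
        preds = ordinary_kriging(f.points, f.values, model, f.points)
        assert np.abs(preds - f.values).max() > 1e-3

    def test_equidistant_pair_gets_half_weights(self):
        pts = np.array([[0.0, 0.0], [100.0, 0.0], [50.0, 2000.0]])
        vals = np.array([4.0, 8.0, 6.0])
        model = VariogramModel("linear", 0.0, 0.01)
        pred, wsum = ordinary_kriging(
            pts, vals, model, np.array([[50.0, 0.0]]), return_weights=True
        )
        assert wsum[0] == pytest.approx(1.0, abs=1e-10)
        assert pred[0] == pytest.approx(0.5 * 4.0 + 0.5 * 8.0, abs=1e-6)

    def test_matches_dense_solver_oracle(self):
        # independent oracle: assemble and solve the augmented gamma system
        # with a plain dense solve at every probe location
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 500, (8, 2))
        vals = rng.normal(40, 4, 8)
        model = VariogramModel("linear", 0.2, 0.003)
        probes = np.column_stack(
            [np.repeat(np.linspace(50, 450, 5), 5), np.tile(np.linspace(50, 450, 5), 5)]
        )
        preds = ordinary_kriging(pts, vals, model, probes)
        n = len(pts)
        G = model(squareform(pdist(pts)))
        A = np.zeros((n + 1, n + 1))
        A[:n, :n] = G
        A[n, :n] = A[:n, n] = 1.0
        for j, p0 in enumerate(probes):
            rhs = np.append(model(np.linalg.norm(pts - p0, axis=1), at_zero="limit"), 1.0)
            sol = np.linalg.solve(A, rhs)
            assert preds[j] == pytest.approx(sol[:n] @ vals, abs=1e-6)

    def test_weight_sums_are_one_everywhere(self):
        f = _field(n=40, seed=8)
        model = VariogramModel("spherical", 0.1, 1.5, 400.0)
        targets = np.random.default_rng(9).uniform(0, 1000, (500, 2))
        _, wsum = ordinary_kriging(f.points, f.values, model, targets, return_weights=True)
        assert np.abs(wsum - 1.0).max() < 1e-8

    def test_duplicate_points_rejected(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [10.0, 10.0]])
        with pytest.raises(np.linalg.LinAlgError):
            ordinary_kriging(pts, np.arange(3.0),
                             VariogramModel("linear", 0.0, 1.0), np.zeros((1, 2)))

    def test_moving_neighbourhood_close_to_global(self):
        f = _field(n=50, seed=10)
        model = VariogramModel("exponential", 0.0, 1.0, 400.0)
        targets = np.random.default_rng(11).uniform(0, 1000, (20, 2))
        global_ = ordinary_kriging(f.points, f.values, model, targets)
        local = ordinary_kriging(f.points, f.values, model, targets,
                                 max_global=10, n_neighbors=50)
        np.testing.assert_allclose(local, global_, atol=1e-8)


class TestSelectVariogramCV:
    def test_deterministic_on_duplicate_field(self):
        f = _field(n=40, seed=12)
        a = select_variogram_cv(f)[0]
        b = select_variogram_cv(ResidualField(f.points.copy(), f.values.copy()))[0]
        assert a == b

    def test_white_noise_still_selects_one_type(self):
        f = _field(n=50, seed=13)  # i.i.d. residuals, no spatial structure
        selected, rmses, _ = select_variogram_cv(f)
        assert selected in ("linear", "spherical", "gaussian", "exponential")
        finite = [v for v in rmses.values() if np.isfinite(v)]
        # all candidates hover near the residual standard deviation
        assert max(finite) / min(finite) < 1.3

    def test_needs_ten_points(self):
        with pytest.raises(ValueError, match="10"):
            select_variogram_cv(_field(n=5, seed=1))


class TestCorrection:
    def test_zero_residual_surface_is_identity(self):
        pred = np.random.default_rng(0).normal(40, 3, (6, 6))
        np.testing.assert_array_equal(
            correct_yield_surface(pred, np.zeros((6, 6))), pred
        )

    def test_constant_residual_shifts_village_means(self, small_scene):
        from pixelyield.recurrent import aggregate_to_admin

        pred = np.full(small_scene.shape, 40.0)
        corrected = correct_yield_surface(pred, np.full(small_scene.shape, 1.5))
        agg0 = aggregate_to_admin(pred, small_scene.villages, small_scene.resolution,
                                  small_scene.origin, small_scene.crop_mask)
        agg1 = aggregate_to_admin(corrected, small_scene.villages, small_scene.resolution,
                                  small_scene.origin, small_scene.crop_mask)
        ok = np.isfinite(agg0["mean"])
        np.testing.assert_allclose(agg1["mean"][ok] - agg0["mean"][ok], 1.5)

    def test_nodata_propagates_and_floor_clips(self):
        pred = np.array([[1.0, np.nan]])
        resid = np.array([[-3.0, 1.0]])
        out = correct_yield_surface(pred, resid)
        assert out[0, 0] == -2.0 and np.isnan(out[0, 1])
        floored = correct_yield_surface(pred, resid, floor_at_zero=True)
        assert floored[0, 0] == 0.0

    def test_misaligned_grids_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            correct_yield_surface(np.zeros((3, 3)), np.zeros((4, 4)))


def test_krige_residual_surface_audit(small_scene):
    rng = np.random.default_rng(14)
    f = ResidualField(small_scene.villages.centroids, rng.normal(0, 1, 12))
    model = VariogramModel("exponential", 0.0, 1.0, 800.0)
    raster, audit = krige_residual_surface(
        f, model, small_scene.shape, small_scene.resolution, small_scene.origin
    )
    assert audit["max_weight_sum_error"] < 1e-8
    assert raster.shape == small_scene.shape
    assert np.isfinite(raster).all()
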