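"""Error metrics, Friedman/Nemenyi rank comparison, Moran's I."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from pixelyield.metrics import (
    friedman_test,
    knn_weights,
    morans_i,
    nemenyi_cd,
    regression_metrics,
    validation_report,
)


class TestRegressionMetrics:
    def test_perfect_predictions(self):
        y = np.array([40.0, 45.0, 50.0])
        rep = regression_metrics(y, y)
        assert rep.r2 == 1.0 and rep.rmse == 0.0 and rep.mae == 0.0 and rep.mape == 0.0

    def test_hand_computed_two_points(self):
        rep = regression_metrics(np.array([10.0, 20.0]), np.array([9.0, 22.0]))
        assert rep.mae == pytest.approx(1.5)
        assert rep.mape == pytest.approx(10.0)
        assert rep.rmse == pytest.approx(np.sqrt(5.0 / 2.0))

    def test_adjusted_r2_formula(self):
        # R^2 = 0.9, n = 11, p = 1 -> 1 - (10/9)(0.1) = 0.8889
        rng = np.random.default_rng(0)
        y = rng.normal(size=11)
        # construct predictions achieving the target R^2 exactly
        ss_tot = np.sum((y - y.mean()) ** 2)
        err = y - y.mean()
        err = err / np.sqrt(np.sum(err ** 2)) * np.sqrt(0.1 * ss_tot)
        rep = regression_metrics(y, y - err, p=1)
        assert rep.r2 == pytest.approx(0.9)
        assert rep.adj_r2 == pytest.approx(1 - (10 / 9) * 0.1)

    def test_zero_observations_excluded_from_mape(self):
        rep = regression_metrics(np.array([0.0, 10.0]), np.array([1.0, 11.0]))
        assert rep.mape == pytest.approx(10.0)
        assert rep.mape_excluded == 1

    @given(
        st.lists(st.floats(-100, 100), min_size=3, max_size=30),
        st.integers(0, 2 ** 32 - 1),
    )
    @settings(max_examples=60, deadline=None)
    def test_rmse_dominates_mae(self, obs, seed):
        y = np.asarray(obs)
        yhat = y + np.random.default_rng(seed).normal(size=len(y))
        rep = regression_metrics(y, yhat)
        assert rep.rmse >= rep.mae - 1e-12


class TestPrintedBlockTables:
    """The published block-level wheat/mustard validation columns reproduce."""

    @pytest.mark.parametrize(
        "column,rmse,mae",
        [("weight_based", 3.33, 2.74), ("lstm_kriging", 1.79, 1.44)],
    )
    def test_wheat_summaries(self, wheat_blocks, column, rmse, mae):
        rep = regression_metrics(
            wheat_blocks["actual"].values, wheat_blocks[column].values
        )
        # within one unit of the last printed digit (mixed rounding in print)
        assert abs(rep.rmse - rmse) <= 0.01
        assert abs(rep.mae - mae) <= 0.01

    @pytest.mark.parametrize(
        "column,rmse", [("gru_kriging", 1.81), ("lstm_kriging", 2.12)]
    )
    def test_mustard_summaries(self, mustard_blocks, column, rmse):
        rep = regression_metrics(
            mustard_blocks["actual"].values, mustard_blocks[column].values
        )
        assert abs(rep.rmse - rmse) <= 0.01


class TestFriedman:
    def test_consistent_rankings_reach_maximum(self):
        # identical orderings in all 3 blocks of 3 treatments: chi2 = N(k-1)
        scores = np.array([[1.0, 2.0, 3.0]] * 3)
        test = friedman_test(scores)
        assert test.statistic == pytest.approx(3 * 2)

    def test_fully_tied_matrix_gives_zero(self):
        test = friedman_test(np.full((4, 3), 7.0))
        assert test.statistic == pytest.approx(0.0)
        assert test.p_value == pytest.approx(1.0)

    def test_matches_rank_sum_oracle_on_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            scores = rng.normal(size=(5, 4))
            test = friedman_test(scores)
            # brute-force: explicit rank sums straight from the definition
            n, k = scores.shape
            ranks = np.array([rankdata(row) for row in scores])
            rbar = ranks.sum(axis=0) / n
            stat = 12 * n / (k * (k + 1)) * (np.sum(rbar ** 2) - k * (k + 1) ** 2 / 4)
            assert test.statistic == pytest.approx(stat, rel=1e-12)

    def test_invariant_to_monotone_transformations(self):
        rng = np.random.default_rng(2)
        scores = rng.uniform(1, 5, size=(6, 4))
        a = friedman_test(scores).statistic
        b = friedman_test(np.exp(scores)).statistic
        assert a == pytest.approx(b)

    def test_direction_flag_flips_ranks(self):
        scores = np.array([[1.0, 2.0], [1.0, 3.0], [2.0, 5.0]])
        low = friedman_test(scores, lower_is_better=True)
        high = friedman_test(scores, lower_is_better=False)
        np.testing.assert_array_equal(low.ranks, 3 - high.ranks)


class TestNemenyi:
    def test_published_critical_difference(self):
        assert nemenyi_cd(7, 6, 0.05) == pytest.approx(3.6772, abs=5e-5)

    def test_cd_decreases_with_more_blocks(self):
        cds = [nemenyi_cd(5, n, 0.05) for n in (2, 5, 10, 50)]
        assert all(a > b for a, b in zip(cds, cds[1:]))

    def test_two_treatments_single_block(self):
        assert nemenyi_cd(2, 1, 0.05) == pytest.approx(1.959964 * 1.0, rel=1e-6)

    def test_out_of_table_rejected(self):
        with pytest.raises(ValueError):
            nemenyi_cd(25, 5)
        with pytest.raises(ValueError):
            nemenyi_cd(5, 5, alpha=0.01)


class TestMoransI:
    def _grid_points(self, n_side=8):
        xs, ys = np.meshgrid(np.arange(n_side), np.arange(n_side))
        return np.column_stack([xs.ravel(), ys.ravel()]).astype(float)

    def test_weights_have_no_self_neighbours(self):
        w = knn_weights(self._grid_points(), k=8)
        assert (w.rows != w.cols).all()

    def test_permutation_mean_matches_expectation(self):
        pts = self._grid_points()
        w = knn_weights(pts, k=8)
        rng = np.random.default_rng(3)
        z = rng.normal(size=len(pts))

        def stat(zv):
            zc = zv - zv.mean()
            num = np.sum(w.weights * zc[w.rows] * zc[w.cols])
            return w.n / w.s0 * num / np.sum(zc ** 2)

        perm_mean = np.mean([stat(rng.permutation(z)) for _ in range(4000)])
        assert perm_mean == pytest.approx(-1 / (len(pts) - 1), abs=0.01)

    def test_smooth_gradient_is_strongly_clustered(self):
        pts = self._grid_points(10)
        values = pts[:, 0] + pts[:, 1]  # smooth spatial gradient
        w = knn_weights(pts, k=8)
        i, _, p = morans_i(values, w, n_permutations=999, seed=0)
        assert i > 0.3
        assert p == pytest.approx(1 / 1000)

    def test_iid_noise_is_usually_insignificant(self):
        pts = self._grid_points(8)
        w = knn_weights(pts, k=8)
        insignificant = 0
        for seed in range(20):
            z = np.random.default_rng(seed).normal(size=len(pts))
            i, _, p = morans_i(z, w, n_permutations=199, seed=seed)
            insignificant += p > 0.05
        assert insignificant >= 18  # >= 90% of seeds

    def test_affine_invariance(self):
        pts = self._grid_points(6)
        w = knn_weights(pts, k=8)
        z = np.random.default_rng(5).normal(size=len(pts))
        i1, _, _ = morans_i(z, w, n_permutations=99, seed=1)
        i2, _, _ = morans_i(5.0 * z + 20.0, w, n_permutations=99, seed=1)
        assert i1 == pytest.approx(i2, rel=1e-12)

    def test_constant_field_rejected(self):
        w = knn_weights(self._grid_points(4), k=3)
        with pytest.raises(ValueError, match="constant"):
            morans_i(np.ones(16), w)


class TestValidationReport:
    def test_identical_tables_give_zero_errors(self):
        obs = pd.DataFrame({"village_id": ["a", "b", "c"], "mean": [40.0, 42.0, 44.0]})
        rep = validation_report(obs, {"m": obs.copy()})
        row = rep.iloc[0]
        assert row.RMSE == 0.0 and row.MAE == 0.0 and row.MAPE == 0.0
        assert row.R2 == 1.0

    def test_block_level_omits_r2(self, wheat_blocks):
        obs_v = pd.DataFrame({"village_id": ["a", "b", "c"], "mean": [40.0, 42.0, 44.0]})
        obs_b = wheat_blocks.rename(columns={"block": "block_id", "actual": "mean"})
        preds_b = {
            "weight": obs_b[["block_id"]].assign(mean=wheat_blocks["weight_based"].values)
        }
        rep = validation_report(obs_v, {"m": obs_v.copy()}, obs_b, preds_b)
        block_row = rep[rep.level == "block"].iloc[0]
        assert np.isnan(block_row.get("R2", np.nan))
        assert block_row.RMSE == pytest.approx(3.329, abs=1e-3)
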