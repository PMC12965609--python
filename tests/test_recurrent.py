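"""Two-branch recurrent downscaler: architecture, gradients, training."""

import numpy as np
import pytest

from pixelyield.dataset import SampleSet
from pixelyield.recurrent import (
    FeatureCube,
    RecurrentDownscaler,
    RecurrentSpec,
    TrainConfig,
    aggregate_to_admin,
    build_recurrent_model,
    count_trainable_parameters,
    predict_pixel_yield,
    train_model,
)


class TestParameterCounts:
    def test_reference_lstm_total(self):
        assert count_trainable_parameters(RecurrentSpec(cell="LSTM")) == 25_889

    def test_reference_gru_total(self):
        assert count_trainable_parameters(RecurrentSpec(cell="GRU")) == 23_553

    def test_minimal_lstm_cell(self):
        # one input, one unit: 4 * (1*1 + 1*1 + 1) = 12 plus the head
        spec = RecurrentSpec(cell="LSTM", t1=1, f1=1, t2=1, f2=1, rnn_units=1,
                             branch_dense=1, head=(1,))
        cell_only = 4 * (1 + 1 + 1)
        dense = 2 * 1          # per branch dense (1+1)*1
        head = (2 * 1 + 1 + 1) * 1 + (1 + 1) * 1  # merged 3 -> 1, out 1 -> 1
        assert count_trainable_parameters(spec) == 2 * (cell_only + dense) + head

    @pytest.mark.parametrize("cell", ["LSTM", "GRU"])
    def test_closed_form_matches_instantiated_weights(self, cell):
        spec = RecurrentSpec(cell=cell, t1=2, f1=4, t2=3, f2=5, f3=2,
                             rnn_units=7, branch_dense=6, head=(9, 5))
        model = build_recurrent_model(spec, seed=0)
        assert model.n_parameters() == count_trainable_parameters(spec)

    def test_merged_width(self):
        assert RecurrentSpec().merged_width == 16 + 16 + 1


class TestForward:
    def test_output_nonnegative_for_random_probes(self):
        spec = RecurrentSpec(cell="GRU", rnn_units=8, head=(8, 4, 4))
        model = RecurrentDownscaler(spec, seed=0)
        rng = np.random.default_rng(1)
        yhat, _ = model.forward(
            rng.normal(0, 5, (2000, 3, 7)), rng.normal(0, 5, (2000, 5, 6)),
            rng.normal(0, 5, (2000, 1)),
        )
        assert (yhat >= 0).all()

    def test_zero_weights_output_softplus_of_zero(self):
        model = RecurrentDownscaler(RecurrentSpec(cell="LSTM", rnn_units=4,
                                                  head=(4,)), seed=0)
        for arr in model.parameters().values():
            arr[...] = 0.0
        yhat, _ = model.forward(np.ones((3, 3, 7)), np.ones((3, 5, 6)), np.ones((3, 1)))
        np.testing.assert_allclose(yhat, np.log(2.0))

    def test_constant_inputs_give_constant_raster(self):
        spec = RecurrentSpec(cell="GRU", rnn_units=4, head=(4,))
        model = RecurrentDownscaler(spec, seed=3)
        n = 25
        cube = FeatureCube(
            np.ones((n, 3, 7)), np.ones((n, 5, 6)), np.ones((n, 1)),
            shape=(5, 5), resolution=10.0, origin=(0.0, 50.0),
        )
        mask = np.ones((5, 5), bool)
        mask[0, 0] = False
        out = predict_pixel_yield(model, cube, mask)
        assert np.isnan(out[0, 0])  # masked pixel is nodata
        vals = out[mask]
        np.testing.assert_allclose(vals, vals[0])


@pytest.mark.parametrize("cell", ["LSTM", "GRU"])
def test_backward_matches_finite_differences(cell):
    spec = RecurrentSpec(cell=cell, t1=2, f1=3, t2=3, f2=2, f3=1,
                         rnn_units=4, branch_dense=3, head=(5, 4), dropout=0.0)
    model = RecurrentDownscaler(spec, seed=0)
    rng = np.random.default_rng(1)
    n = 4
    Xb = rng.standard_normal((n, 2, 3))
    Xw = rng.standard_normal((n, 3, 2))
    Xs = rng.standard_normal((n, 1))
    y = rng.standard_normal(n) + 2.0

    yhat, cache = model.forward(Xb, Xw, Xs)
    grads = model.backward(2.0 * (yhat - y) / n, cache)

    def loss():
        return np.mean((model.forward(Xb, Xw, Xs)[0] - y) ** 2)

    check_rng = np.random.default_rng(2)
    for name, p in model.parameters().items():
        flat_idx = check_rng.choice(p.size, size=min(5, p.size), replace=False)
        for fi in flat_idx:
            idx = np.unravel_index(fi, p.shape)
            orig = p[idx]
            p[idx] = orig + 1e-6
            lp = loss()
            p[idx] = orig - 1e-6
            lm = loss()
            p[idx] = orig
            num = (lp - lm) / 2e-6
            assert grads[name][idx] == pytest.approx(num, abs=1e-5, rel=1e-4), name


def _toy_samples(n, seed, prefix="v"):
    rng = np.random.default_rng(seed)
    bands = rng.normal(size=(n, 3, 7))
    weather = rng.normal(size=(n, 5, 6))
    static = np.ones((n, 1))
    y = 40.0 + 2.0 * bands[:, :, 0].mean(axis=1) + weather[:, :, 0].mean(axis=1)
    return SampleSet(
        np.array([f"{prefix}{i}" for i in range(n)], dtype=object),
        bands, weather, np.empty((n, 0)), static, y,
        np.full(n, "train", dtype=object), "band-weather",
    )


class TestTraining:
    def test_memorizes_small_noiseless_fixture(self):
        train = _toy_samples(20, seed=0)
        val = _toy_samples(8, seed=1, prefix="w")
        spec = RecurrentSpec(cell="GRU", dropout=0.0)
        model = build_recurrent_model(spec, seed=0)
        cfg = TrainConfig(learning_rate=0.01, max_epochs=500, patience=0, seed=0)
        model, hist = train_model(model, train, val, cfg)
        assert hist["loss"].min() < 1e-2

    def test_identical_seeds_reproduce_val_mae(self):
        train = _toy_samples(24, seed=3)
        val = _toy_samples(8, seed=4, prefix="w")
        results = []
        for _ in range(2):
            model = build_recurrent_model(RecurrentSpec(cell="LSTM"), seed=5)
            _, hist = train_model(model, train, val,
                                  TrainConfig(max_epochs=30, patience=10, seed=5))
            results.append(hist["val_mae"].values)
        np.testing.assert_array_equal(results[0], results[1])

    def test_early_stopping_halts_within_patience(self):
        train = _toy_samples(24, seed=6)
        val = _toy_samples(8, seed=7, prefix="w")
        model = build_recurrent_model(RecurrentSpec(cell="GRU"), seed=6)
        cfg = TrainConfig(max_epochs=400, patience=15, seed=6)
        _, hist = train_model(model, train, val, cfg)
        stopped, best = hist.attrs["stopped_epoch"], hist.attrs["best_epoch"]
        if stopped < 399:
            assert stopped - best == 15  # halted right when patience ran out

    def test_overlapping_splits_rejected(self):
        train = _toy_samples(10, seed=8)
        with pytest.raises(ValueError, match="overlap"):
            train_model(build_recurrent_model(RecurrentSpec(), 0), train, train)

    def test_standardization_stats_are_stored_and_applied(self):
        train = _toy_samples(24, seed=9)
        val = _toy_samples(8, seed=10, prefix="w")
        model = build_recurrent_model(RecurrentSpec(cell="GRU"), seed=9)
        model, _ = train_model(model, train, val, TrainConfig(max_epochs=5, patience=1, seed=9))
        assert model.norm is not None
        assert model.norm["bands_mean"].shape == (3, 7)
        # predict() must apply the stored statistics: shifting inputs changes output
        a = model.predict(train.bands, train.weather, train.static)
        b = model.predict(train.bands + 1.0, train.weather, train.static)
        assert not np.allclose(a, b)


def test_pixel_aggregation_round_trip(small_scene):
    """Village means of the pixel raster equal the zonal aggregation output."""
    rng = np.random.default_rng(0)
    raster = rng.normal(40, 3, small_scene.shape)
    agg = aggregate_to_admin(
        raster, small_scene.villages, small_scene.resolution,
        small_scene.origin, small_scene.crop_mask,
    )
    for i, v in enumerate(small_scene.villages.village_id):
        sel = (small_scene.village_labels == i) & small_scene.crop_mask
        if sel.any():
            assert agg["mean"].iloc[i] == pytest.approx(raster[sel].mean())


def test_cube_layout_mismatch_rejected(small_scene):
    model = build_recurrent_model(RecurrentSpec(cell="GRU", f1=5), seed=0)
    cube = FeatureCube.from_stack(small_scene.covariates)
    with pytest.raises(ValueError, match="layout"):
        predict_pixel_yield(model, cube, small_scene.crop_mask)
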