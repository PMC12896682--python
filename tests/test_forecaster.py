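"""DSW embedding, statistical feature space, RevIN, channel fusion, and
the training loop's early-stopping/determinism contracts."""

import numpy as np
import pandas as pd
import pytest

from peanutstore import forecaster as fc
from peanutstore import preprocess as prep
from peanutstore.nn import Tensor


class TestDSWEmbedding:
    def test_grid_shape(self):
        X = np.random.default_rng(0).normal(size=(16, 8))
        grid = fc.dsw_embed(X, fc.DSWConfig(L_seg=4, d_model=32))
        assert grid.shape == (4, 8, 32)

    def test_zero_weights_give_zero_grid(self):
        emb = fc.DSWEmbedding(16, 8, fc.DSWConfig(L_seg=4, d_model=32),
                              np.random.default_rng(0))
        emb.proj.weight.data[:] = 0.0
        emb.pos.data[:] = 0.0
        grid = emb.grid(np.ones((16, 8)))
        assert np.allclose(grid.numpy(), 0.0)

    def test_segments_partition_every_raw_point(self):
        member = fc.segment_membership(16, 4)
        assert len(member) == 16
        assert np.array_equal(np.bincount(member), [4, 4, 4, 4])
        # each raw point lands in exactly one segment and order is preserved
        assert np.all(np.diff(member) >= 0)

    def test_segmentation_is_lossless_before_projection(self):
        X = np.arange(16 * 8, dtype=float).reshape(16, 8)
        segs = X.reshape(4, 4, 8).transpose(0, 2, 1)  # (seg, var, L_seg)
        rebuilt = segs.transpose(0, 2, 1).reshape(16, 8)
        assert np.array_equal(rebuilt, X)

    def test_indivisible_window_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            fc.DSWEmbedding(16, 8, fc.DSWConfig(L_seg=5),
                            np.random.default_rng(0))


class TestStatFeatureSpace:
    def test_median_is_robust_to_outlier(self):
        table = pd.DataFrame({
            "day": [1, 1, 1], "condition_id": [1, 2, 3],
            "fatty_acid": [1.0, 2.0, 100.0]})
        space = fc.build_stat_space(table, features=["fatty_acid"])
        assert space.median[0, 0] == 2.0

    def test_constant_table_gives_zero_std(self):
        table = pd.DataFrame({
            "day": [1, 1, 2, 2], "condition_id": [1, 2, 1, 2],
            "fatty_acid": [5.0] * 4})
        space = fc.build_stat_space(table, features=["fatty_acid"])
        assert np.allclose(space.std, 0.0)

    def test_full_table_has_one_row_per_day(self, default_table):
        space = fc.build_stat_space(default_table)
        assert space.median.shape[0] == 210
        assert space.std.shape == space.median.shape
        assert np.all(space.std >= 0)

    def test_rows_clamped_outside_training_span(self, default_table):
        space = fc.build_stat_space(
            default_table[default_table["day"] <= 100])
        med, _ = space.rows_for(np.array([150]), L=4)
        assert np.allclose(med[0], space.median[-1])  # frozen at the edge


class TestRevIN:
    def test_identity_configuration(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(1, 101, 1))
        x = x - np.median(x)  # median 0
        x = x / x.std()       # unit variance
        revin = fc.RevIN(1)
        xhat = revin.normalize(x).numpy()
        assert np.allclose(xhat, x, atol=1e-6)

    def test_constant_series_maps_to_beta(self):
        revin = fc.RevIN(2)
        revin.beta.data[:] = [0.5, -0.5]
        out = revin.normalize(np.full((1, 10, 2), 7.0)).numpy()
        assert np.all(np.isfinite(out))
        assert np.allclose(out[..., 0], 0.5) and np.allclose(out[..., 1], -0.5)

    def test_round_trip_identity(self, rng):
        revin = fc.RevIN(4)
        revin.lam.data[:] = rng.uniform(0.5, 2.0, 4)
        revin.beta.data[:] = rng.normal(size=4)
        x = rng.normal(size=(3, 16, 4)) * 10 + 5
        back = revin.denormalize(revin.normalize(x)).numpy()
        assert np.allclose(back, x, atol=1e-6)

    def test_degenerate_affine_returns_cached_median(self):
        revin = fc.RevIN(1)
        revin.lam.data[:] = 0.0
        x = np.arange(9.0).reshape(1, 9, 1)
        out = revin.denormalize(revin.normalize(x)).numpy()
        assert np.allclose(out, np.median(x))

    def test_denormalize_requires_cached_stats(self):
        with pytest.raises(RuntimeError, match="cached"):
            fc.RevIN(1).denormalize(np.zeros((1, 4, 1)))


class TestChannelFusion:
    def test_mean_kernel_averages_channels(self):
        stack = np.stack([np.full((4, 3), v) for v in (1.0, 2.0, 6.0)])
        fused = fc.fuse_channels(stack, weights=[1 / 3] * 3)
        assert np.allclose(fused, 3.0)

    def test_zero_input_zero_output(self):
        assert np.allclose(fc.fuse_channels(np.zeros((3, 5, 2))), 0.0)

    def test_spatial_shape_preserved(self):
        fused = fc.fuse_channels(np.random.default_rng(0).normal(size=(3, 7, 9)))
        assert fused.shape == (7, 9)

    def test_channel_count_mismatch_rejected(self):
        fusion = fc.ChannelFusion(3)
        with pytest.raises(ValueError, match="channels"):
            fusion([Tensor(np.zeros((2, 2)))] * 2)

    def test_averaging_commutes_with_linear_maps(self, rng):
        stack = rng.normal(size=(3, 6, 4))
        A = rng.normal(size=(4, 4))
        left = fc.fuse_channels(stack @ A, weights=[1 / 3] * 3)
        right = fc.fuse_channels(stack, weights=[1 / 3] * 3) @ A
        assert np.allclose(left, right, atol=1e-12)


@pytest.fixture(scope="module")
def small_datasets(noiseless_table):
    split = prep.chronological_split(210)
    datasets, scaler = prep.window_dataset(noiseless_table, split, L=16,
                                           horizon=4)
    datasets = {k: {**v, "y": v["y"][..., :6]} for k, v in datasets.items()}
    space = fc.build_stat_space(prep.split_table(noiseless_table, split)["train"])
    return datasets, space, scaler


class TestTraining:
    def test_same_seed_same_final_metric(self, small_datasets):
        datasets, space, _ = small_datasets
        cfg = fc.TrainConfig(epochs=2, seed=2021)
        vals = []
        for _ in range(2):
            model = fc.DSCSformer(horizon=4, D_in=8, seed=2021)
            hist = fc.train_forecaster(model, datasets["train"],
                                       datasets["val"], space, cfg)
            vals.append(hist["val_loss"])
        assert vals[0] == vals[1]  # bit-identical

    def test_patience_arithmetic(self, small_datasets):
        """lr=0 freezes the model, so val never improves after epoch 1."""
        datasets, space, _ = small_datasets
        model = fc.DSCSformer(horizon=4, D_in=8, seed=0,
                              cfg=fc.DSWConfig(dropout=0.0))
        cfg = fc.TrainConfig(epochs=50, patience=10, lr=0.0, seed=0)
        hist = fc.train_forecaster(model, datasets["train"], datasets["val"],
                                   space, cfg)
        assert hist["stopped_epoch"] == 11

    def test_empty_val_disables_early_stopping(self, small_datasets):
        datasets, space, _ = small_datasets
        model = fc.DSCSformer(horizon=4, D_in=8, seed=0)
        with pytest.warns(UserWarning, match="early stopping"):
            hist = fc.train_forecaster(model, datasets["train"], None, space,
                                       fc.TrainConfig(epochs=1))
        assert hist["best_val"] is None

    def test_lstm_baseline_trains_and_is_deterministic(self, small_datasets):
        datasets, space, _ = small_datasets
        runs = []
        for _ in range(2):
            model = fc.LSTMForecaster(horizon=4, D_in=8, seed=2021)
            hist = fc.train_forecaster(model, datasets["train"],
                                       datasets["val"], None,
                                       fc.TrainConfig(epochs=2, seed=2021))
            runs.append(hist["val_loss"])
        assert runs[0] == runs[1]


class TestForecast:
    def test_output_shape_40_by_6(self, small_datasets):
        _, space, scaler = small_datasets
        model = fc.DSCSformer(horizon=40, D_in=8, seed=0)
        window = np.random.default_rng(0).normal(size=(16, 8))
        med, std = space.rows_for(np.array([100]), 16)
        out = fc.forecast(model, window, scaler, med[0], std[0])
        assert out.shape == (40, 6)

    def test_inverse_transforms_undo_forward(self, small_datasets):
        _, _, scaler = small_datasets
        raw = np.random.default_rng(1).normal(size=(5, 6)) * 4 + 50
        std = (raw - scaler.mean[:6]) / scaler.std[:6]
        assert np.allclose(std * scaler.std[:6] + scaler.mean[:6], raw,
                           atol=1e-10)

    def test_wrong_window_shape_rejected(self, small_datasets):
        _, space, scaler = small_datasets
        model = fc.DSCSformer(horizon=4, D_in=8, seed=0)
        with pytest.raises(ValueError, match="window shape"):
            fc.forecast(model, np.zeros((8, 8)), scaler)


def test_checkpoint_round_trip(tmp_path, small_datasets):
    datasets, space, _ = small_datasets
    model = fc.DSCSformer(horizon=4, D_in=8, seed=5)
    fc.save_model(model, tmp_path / "ckpt.npz")
    clone = fc.load_model(tmp_path / "ckpt.npz")
    pred1 = fc.predict_standardized(model, datasets["test"], space)
    pred2 = fc.predict_standardized(clone, datasets["test"], space)
    assert np.array_equal(pred1, pred2)


def test_ablation_table_structure(small_datasets):
    datasets, space, _ = small_datasets
    cfg = fc.TrainConfig(epochs=1, seed=0)
    table = fc.ablation_suite(datasets, space, horizon=4, train_cfg=cfg)
    assert len(table) == 4
    assert {"MSE", "MAE"} <= set(table.columns)
    gap = table.loc["+DSW", "MSE"] - table.loc["full", "MSE"]
    assert table.loc["+DSW", "MSE_gap_vs_full"] == pytest.approx(gap)
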