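"""The neural map model: splits, training behavior, application, serialization."""

import numpy as np
import pytest

from embedmap.core import Embedding, normalize_embedding
from embedmap.netmap import (
    NeuralMapModel,
    NeuralMapResults,
    TrainConfig,
    apply_map,
    split_data,
)


class TestSplitData:
    def test_exact_fractions(self):
        tr, te, va = split_data(100, TrainConfig(seed=0))
        assert (len(tr), len(te), len(va)) == (70, 15, 15)

    def test_rounding_within_one(self):
        tr, te, va = split_data(101, TrainConfig(seed=0))
        assert len(tr) + len(te) + len(va) == 101
        assert abs(len(tr) - 70.7) <= 1
        assert abs(len(te) - 15.15) <= 1
        assert abs(len(va) - 15.15) <= 1

    def test_disjoint_exhaustive_reproducible(self):
        a = split_data(53, TrainConfig(seed=7))
        b = split_data(53, TrainConfig(seed=7))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)
        union = np.sort(np.concatenate(a))
        np.testing.assert_array_equal(union, np.arange(53))

    def test_too_small(self):
        with pytest.raises(ValueError):
            split_data(5, TrainConfig())


class TestTrainConfig:
    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(train_frac=0.8, test_frac=0.15, val_frac=0.15)
        with pytest.raises(ValueError):
            TrainConfig(max_epochs=0)


def _linear_problem(n=1500, p=10, d=3, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, p))
    w = rng.normal(size=(p, d))
    y = x @ w * 0.1 + 0.5
    return x, y


class TestTraining:
    def test_realizable_linear_target(self):
        x, y = _linear_problem()
        res = NeuralMapModel(x, y, "forward", TrainConfig(seed=0)).fit()
        assert res.diagnostics["r2_test_min"] >= 0.999

    def test_permuted_targets_near_zero(self):
        x, y = _linear_problem()
        y_shuf = y[np.random.default_rng(1).permutation(len(y))]
        # weak fixed L2 so the net overfits and validation stays above baseline
        with pytest.warns(UserWarning, match="baseline"):
            res = NeuralMapModel(
                x, y_shuf, "forward", TrainConfig(seed=0, max_epochs=150, alpha=1e-4)
            ).fit()
        assert res.diagnostics["r2_test_mean"] < 0.2

    def test_single_feature_inverse_realizable(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(size=(300, 3))
        target = coords[:, [0]] * 4.0 + 1.0  # one feature equal to a coordinate
        res = NeuralMapModel(coords, target, "inverse", TrainConfig(seed=0)).fit()
        assert res.diagnostics["r2_test_min"] >= 0.999

    def test_diagnostics_bounds_and_sizes(self):
        x, y = _linear_problem(n=200)
        res = NeuralMapModel(x, y, "forward", TrainConfig(seed=3, max_epochs=50)).fit()
        d = res.diagnostics
        for split in ("train", "test", "val"):
            assert 0.0 <= d[f"r2_{split}_min"] <= 1.0
        assert sum(d["split_sizes"]) == 200
        assert d["epochs_run"] <= 50

    def test_roundtrip_beats_mean_baseline(self, toy_maps):
        ds = toy_maps["dataset"]
        fwd, inv = toy_maps["forward"], toy_maps["inverse"]
        x = ds.matrix.values
        recon = inv.predict(fwd.predict(x))
        mse_model = float(np.mean((recon - x) ** 2))
        mse_baseline = float(np.mean((x.mean(axis=0) - x) ** 2))
        assert mse_model < mse_baseline


class TestApplyMap:
    def test_memorization_of_training_rows(self, toy_maps):
        ds, e, fwd = toy_maps["dataset"], toy_maps["embedding"], toy_maps["forward"]
        pred = fwd.predict(ds.matrix.values)
        resid = np.abs(pred - e.coords).mean()
        assert resid < 0.1  # fitted embedding recovered within training residual

    def test_chunk_independence_bit_identical(self, toy_maps):
        fwd = toy_maps["forward"]
        x = toy_maps["dataset"].matrix.values
        full = apply_map(fwd, x)
        tiny = apply_map(fwd, x, chunk_size=1)
        big = apply_map(fwd, x, chunk_size=10_000)
        np.testing.assert_array_equal(tiny, full)
        np.testing.assert_array_equal(big, full)

    def test_duplicate_row_identical_output(self, toy_maps):
        fwd = toy_maps["forward"]
        x = toy_maps["dataset"].matrix.values
        dup = np.vstack([x[:5], x[3:4]])
        out = fwd.predict(dup)
        np.testing.assert_array_equal(out[5], out[3])
        # and pure-function behavior on repeated calls
        np.testing.assert_array_equal(fwd.predict(x[:7]), fwd.predict(x[:7]))

    def test_dimension_mismatch(self, toy_maps):
        with pytest.raises(ValueError, match="columns"):
            toy_maps["forward"].predict(np.ones((2, 3)))

    def test_non_finite_rejected(self, toy_maps):
        x = toy_maps["dataset"].matrix.values[:2].copy()
        x[0, 0] = np.inf
        with pytest.raises(ValueError, match="finite"):
            toy_maps["forward"].predict(x)


class TestSerialization:
    def test_save_load_roundtrip(self, toy_maps, tmp_path):
        fwd = toy_maps["forward"]
        x = toy_maps["dataset"].matrix.values[:50]
        path = tmp_path / "map.npz"
        fwd.save(path)
        back = NeuralMapResults.load(path)
        assert back.direction == "forward"
        assert back.config.hidden == fwd.config.hidden
        np.testing.assert_array_equal(back.predict(x), fwd.predict(x))
        assert back.diagnostics["epochs_run"] == fwd.diagnostics["epochs_run"]

    def test_inverse_carries_feature_axis(self, toy_maps, tmp_path):
        inv = toy_maps["inverse"]
        path = tmp_path / "inv.npz"
        inv.save(path)
        back = NeuralMapResults.load(path)
        np.testing.assert_array_equal(
            back.feature_axis, toy_maps["dataset"].matrix.feature_axis
        )


def test_from_matrices_requires_normalized_embedding(small_msi):
    e = Embedding(coords=np.random.default_rng(0).normal(size=(small_msi.matrix.n, 3)),
                  method="tsne")
    with pytest.raises(ValueError, match="normalized"):
        NeuralMapModel.from_matrices(small_msi.matrix, e)
    NeuralMapModel.from_matrices(small_msi.matrix, normalize_embedding(e))


def test_summary_mentions_key_fields(toy_maps):
    s = toy_maps["forward"].summary()
    assert "forward" in s and "r2" in s and "epochs" in s
    s_inv = toy_maps["inverse"].summary()
    assert "reconstruction" in s_inv
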