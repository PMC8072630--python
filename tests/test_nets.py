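"""Network architectures, training contracts, the autoencoder mask
invariant, grid search, and model persistence."""

import numpy as np
import pytest

from metskip import nets
from metskip.errors import DataError, SchemaMismatchError
from metskip.nets import (
    ConvNetSpec,
    DenseNetSpec,
    SCASpec,
    build_connectivity_mask,
    build_network,
    classify,
    encode,
    grid_search,
    load_model,
    predict,
    save_model,
    train_classifier,
    train_sca,
)


def separable_data(n=120, seed=0):
    """Two features; the first behaves like exon-14 coverage: positive for
    the WT class, zero for the skipped class."""
    rng = np.random.default_rng(seed)
    X = np.zeros((n, 2))
    y = np.array(["WT", "delta14"] * (n // 2))
    wt = y == "WT"
    X[wt, 0] = rng.uniform(0.5, 1.0, wt.sum())
    X[~wt, 0] = 0.0
    X[:, 1] = rng.uniform(0, 1, n)
    return X, y


class TestArchitectures:
    def test_dense_parameter_count_formula(self):
        spec = DenseNetSpec(input_dim=486)
        net = build_network(spec, np.random.default_rng(0))
        dims = [486, 256, 256, 128, 128, 1]
        expected = sum(a * b + b for a, b in zip(dims, dims[1:]))
        assert net.n_params() == expected

    def test_conv_output_plumbing(self):
        spec = ConvNetSpec(input_dim=100, kernel_size=10)
        net = build_network(spec, np.random.default_rng(0))
        out = net.forward(np.random.default_rng(1).random((5, 100)))
        assert out.shape == (5, 1)
        assert np.all((out > 0) & (out < 1))

    def test_kernel_larger_than_input_rejected(self):
        with pytest.raises(DataError):
            ConvNetSpec(input_dim=50, kernel_size=100)


class TestTrainClassifier:
    def test_separable_toy_reaches_perfect_validation_accuracy(self):
        X, y = separable_data()
        tm = train_classifier(DenseNetSpec(input_dim=2), X, y, epochs=20, seed=1)
        scores = predict(tm, X)
        acc = np.mean((scores > 0.5) == (y == "delta14"))
        assert acc == 1.0

    def test_same_seed_same_final_loss(self):
        X, y = separable_data()
        a = train_classifier(DenseNetSpec(input_dim=2), X, y, epochs=5, seed=3)
        b = train_classifier(DenseNetSpec(input_dim=2), X, y, epochs=5, seed=3)
        assert abs(a.training_log["train_loss"][-1] - b.training_log["train_loss"][-1]) < 1e-6

    def test_shuffled_labels_give_chance_accuracy_held_out(self):
        X, _ = separable_data(n=300, seed=2)
        rng = np.random.default_rng(7)
        y = rng.permutation(np.array(["WT", "delta14"] * 150))
        tm = train_classifier(DenseNetSpec(input_dim=2), X[:200], y[:200], epochs=10, seed=4)
        acc = np.mean((predict(tm, X[200:]) > 0.5) == (y[200:] == "delta14"))
        assert 0.25 <= acc <= 0.75  # permutation null: chance-level held-out accuracy

    def test_single_class_labels_rejected(self):
        X = np.random.default_rng(0).random((10, 2))
        with pytest.raises(DataError, match="single class"):
            train_classifier(DenseNetSpec(input_dim=2), X, ["WT"] * 10)

    def test_dimension_mismatch_rejected(self):
        X, y = separable_data()
        with pytest.raises(DataError):
            train_classifier(DenseNetSpec(input_dim=5), X, y)

    def test_training_loss_decreases_on_average(self):
        X, y = separable_data(n=200, seed=5)
        firsts, lasts = [], []
        for seed in range(5):
            tm = train_classifier(
                DenseNetSpec(input_dim=2), X, y, epochs=15, seed=seed, val_fraction=0.0
            )
            firsts.append(tm.training_log["train_loss"][0])
            lasts.append(tm.training_log["train_loss"][-1])
        assert np.mean(lasts) <= np.mean(firsts)


class TestPredictClassify:
    def test_untrained_zero_input_scores_half(self):
        # zero input through zero biases: sigmoid(0) = 0.5
        net = build_network(DenseNetSpec(input_dim=4), np.random.default_rng(0))
        tm = nets.TrainedModel(DenseNetSpec(input_dim=4), net, "", {}, 0)
        assert predict(tm, np.zeros((1, 4)))[0] == pytest.approx(0.5)

    def test_exact_threshold_calls_negative_class(self):
        net = build_network(DenseNetSpec(input_dim=4), np.random.default_rng(0))
        tm = nets.TrainedModel(DenseNetSpec(input_dim=4), net, "", {}, 0)
        assert classify(tm, np.zeros((1, 4)), threshold=0.5)[0] == "WT"

    def test_schema_hash_mismatch_rejected(self):
        X, y = separable_data()
        tm = train_classifier(
            DenseNetSpec(input_dim=2), X, y, epochs=2, seed=0, feature_schema_hash="abc"
        )
        with pytest.raises(SchemaMismatchError):
            predict(tm, X, schema_hash="def")


class TestSCA:
    @pytest.fixture()
    def toy_sca(self):
        # 6 features over 3 latent exons: two features each
        mask = np.kron(np.eye(3), np.ones((2, 1)))
        spec = SCASpec(input_dim=6, latent_dim=3, mask=mask, latent_ordinals=(13, 14, 15))
        rng = np.random.default_rng(0)
        X = np.abs(rng.normal(size=(40, 6)))
        return spec, X

    def test_masked_weights_zero_before_and_after_training(self, toy_sca):
        spec, X = toy_sca
        net = nets.build_sca_network(spec, np.random.default_rng(1))
        assert np.all(net.layers[0].W.value[spec.mask == 0] == 0)
        tm = train_sca(spec, X, epochs=10, seed=1)
        assert nets.masked_weights_are_zero(tm)

    def test_trainable_encoder_weights_equal_mask_ones(self, toy_sca):
        spec, X = toy_sca
        tm = train_sca(spec, X, epochs=2, seed=0)
        assert nets.n_trainable_encoder_weights(tm) == int(spec.mask.sum())

    def test_duplicate_samples_encode_identically(self, toy_sca):
        spec, X = toy_sca
        tm = train_sca(spec, X, epochs=5, seed=2)
        Z = encode(tm, np.vstack([X[0], X[0]]))
        assert np.array_equal(Z[0], Z[1])

    def test_uncovered_feature_reported_as_offender(self):
        with pytest.raises(DataError, match="offenders"):
            build_connectivity_mask([(13,), ()], (13, 14))

    def test_junction_feature_connects_to_both_flanks(self):
        mask = build_connectivity_mask([(13,), (13, 15), (15,)], (13, 14, 15))
        assert mask.tolist() == [[1, 0, 0], [1, 0, 1], [0, 0, 1]]

    def test_mask_column_sums_match_exon_block_lengths(self, met_model):
        from metskip import featurization as fz

        scope = (13, 14, 15)
        attrib = fz.feature_exon_attribution("coverage", met_model, scope)
        mask = build_connectivity_mask(attrib, scope)
        assert mask.sum(axis=0).tolist() == [len(met_model.exon(o)) for o in scope]


class TestGridSearch:
    def test_single_config_grid_returns_it(self):
        X, y = separable_data()
        df = grid_search("dense", {"dropout": [0.1]}, X, y, seed=0, epochs=3)
        assert len(df) == 1 and df.loc[0, "dropout"] == 0.1

    def test_kernel_sweep_produces_one_row_per_kernel(self):
        rng = np.random.default_rng(0)
        n, d = 60, 220
        y = np.array(["WT", "delta14"] * (n // 2))
        X = rng.random((n, d)) + 0.5 * (y == "delta14")[:, None]
        df = grid_search(
            "conv", {"kernel_size": list(nets.CNN_KERNEL_SIZES)}, X, y, seed=0, epochs=2
        )
        assert sorted(df["kernel_size"]) == sorted(nets.CNN_KERNEL_SIZES)
        assert df["val_loss"].is_monotonic_increasing

    def test_identical_configs_identical_scores(self):
        X, y = separable_data()
        df = grid_search("dense", {"dropout": [0.1, 0.1]}, X, y, seed=0, epochs=3)
        assert df["val_loss"].nunique() == 1

    def test_empty_grid_rejected(self):
        X, y = separable_data()
        with pytest.raises(DataError):
            grid_search("dense", {}, X, y)


class TestPersistence:
    def test_classifier_bundle_round_trip(self, tmp_path):
        X, y = separable_data()
        tm = train_classifier(
            DenseNetSpec(input_dim=2), X, y, epochs=3, seed=0, feature_schema_hash="h1"
        )
        path = tmp_path / "model.npz"
        save_model(tm, path)
        back = load_model(path)
        assert back.feature_schema_hash == "h1"
        assert np.array_equal(predict(back, X), predict(tm, X))

    def test_sca_bundle_round_trip(self, tmp_path):
        mask = np.kron(np.eye(2), np.ones((3, 1)))
        spec = SCASpec(input_dim=6, latent_dim=2, mask=mask, latent_ordinals=(1, 2))
        X = np.abs(np.random.default_rng(0).normal(size=(20, 6)))
        tm = train_sca(spec, X, epochs=3, seed=1)
        path = tmp_path / "sca.npz"
        save_model(tm, path)
        back = load_model(path)
        assert np.array_equal(encode(back, X), encode(tm, X))
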