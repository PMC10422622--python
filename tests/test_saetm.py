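"""Stacked autoencoder: algebra, training, structural loss, classifier."""

import numpy as np
import pytest

from mudring_ecg import saetm


def finite_diff(f, arr, eps=1e-6):
    """Central finite differences of scalar f w.r.t. every entry of arr."""
    g = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = arr[idx]
        arr[idx] = orig + eps
        fp = f()
        arr[idx] = orig - eps
        fm = f()
        arr[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
    return g


class TestSigmoid:
    def test_midpoint(self):
        assert saetm.sigmoid(0.0) == 0.5

    def test_symmetry(self):
        z = np.linspace(-20, 20, 41)
        np.testing.assert_allclose(saetm.sigmoid(z) + saetm.sigmoid(-z), 1.0,
                                   atol=1e-12)

    def test_saturation_without_overflow(self):
        assert saetm.sigmoid(50.0) > 1 - 1e-9
        assert np.isfinite(saetm.sigmoid(1e3))
        assert np.isfinite(saetm.sigmoid(-1e3))


class TestEncodeDecode:
    def test_zero_weights_give_half(self):
        layer = saetm.AutoencoderLayer(W=np.zeros((3, 4)), b=np.zeros(3),
                                       c=np.zeros(4))
        np.testing.assert_array_equal(saetm.encode(np.ones(4), layer),
                                      np.full(3, 0.5))
        np.testing.assert_array_equal(saetm.decode(np.ones(3), layer),
                                      np.full(4, 0.5))

    def test_hand_evaluated_1x1_layer(self):
        layer = saetm.AutoencoderLayer(W=np.array([[2.0]]), b=np.array([-1.0]),
                                       c=np.array([0.0]))
        h = saetm.encode(np.array([1.0]), layer)
        assert h[0] == pytest.approx(0.73106, abs=1e-5)
        xp = saetm.decode(h, layer)
        # sigma(2*sigma(1)) = sigma(1.4621172) = 0.8118563
        assert xp[0] == pytest.approx(0.8118563, abs=1e-6)

    def test_dimension_mismatch(self):
        layer = saetm.AutoencoderLayer(W=np.zeros((3, 4)), b=np.zeros(3),
                                       c=np.zeros(4))
        with pytest.raises(ValueError):
            saetm.encode(np.ones(5), layer)
        with pytest.raises(ValueError):
            saetm.decode(np.ones(4), layer)


class TestReconstructionError:
    def test_hand_value(self):
        assert saetm.reconstruction_error(np.array([[1.0, 0.0]]),
                                          np.array([[0.5, 0.5]])) == 0.5

    def test_zero_on_identical(self):
        X = np.random.default_rng(0).random((5, 3))
        assert saetm.reconstruction_error(X, X) == 0.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            saetm.reconstruction_error(np.zeros((2, 2)), np.zeros((2, 3)))


class TestGradients:
    """Analytic gradients vs central finite differences on a 3x4x2 toy net."""

    def test_autoencoder_gradients(self, rng):
        layer = saetm._init_layer(3, 4, rng, "sigmoid")
        X = rng.random((6, 3))

        def loss():
            return saetm.reconstruction_error(
                X, saetm.decode(saetm.encode(X, layer), layer))

        _, dW, db, dc = saetm.ae_gradients(layer, X)
        for analytic, arr in ((dW, layer.W), (db, layer.b), (dc, layer.c)):
            numeric = finite_diff(loss, arr)
            scale = max(np.abs(numeric).max(), 1e-8)
            assert np.abs(analytic - numeric).max() / scale < 1e-5

    def test_supervised_gradients(self, rng):
        stack = saetm.SAEStack(layers=[saetm._init_layer(3, 4, rng, "sigmoid")])
        stack.beta = rng.normal(size=(2, 4))
        stack.alpha = rng.normal(size=2)
        X = rng.random((8, 3))
        y = rng.integers(0, 2, 8)

        def loss():
            return saetm.supervised_loss_and_gradients(stack, X, y)[0]

        _, dbeta, dalpha, layer_grads = saetm.supervised_loss_and_gradients(
            stack, X, y)
        checks = [(dbeta, stack.beta), (dalpha, stack.alpha),
                  (layer_grads[0][0], stack.layers[0].W),
                  (layer_grads[0][1], stack.layers[0].b)]
        for analytic, arr in checks:
            numeric = finite_diff(loss, arr)
            scale = max(np.abs(numeric).max(), 1e-8)
            assert np.abs(analytic - numeric).max() / scale < 1e-5


class TestTrainAutoencoder:
    def test_loss_decreases_on_repeated_pattern(self, rng):
        X = np.tile(rng.random(8), (50, 1))
        layer = saetm.train_autoencoder(X, 2, saetm.TrainConfig(epochs=20, seed=0))
        assert layer.training_errors[-1] < layer.training_errors[0]

    def test_deterministic_given_seed(self, rng):
        X = rng.random((30, 6))
        a = saetm.train_autoencoder(X, 3, saetm.TrainConfig(epochs=5, seed=7))
        b = saetm.train_autoencoder(X, 3, saetm.TrainConfig(epochs=5, seed=7))
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.b, b.b)

    def test_rank1_beats_mean_baseline(self, rng):
        u = rng.random(40)
        v = rng.random(6)
        X = 0.2 + 0.6 * np.outer(u, v) / np.outer(u, v).max()
        layer = saetm.train_autoencoder(
            X, 1, saetm.TrainConfig(epochs=200, learning_rate=0.05, seed=1))
        recon = saetm.decode(saetm.encode(X, layer), layer)
        err = saetm.reconstruction_error(X, recon) / len(X)
        baseline = saetm.reconstruction_error(
            X, np.tile(X.mean(axis=0), (len(X), 1))) / len(X)
        assert err < 0.25 * baseline

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            saetm.train_autoencoder(np.array([[np.nan, 1.0]]), 1,
                                    saetm.TrainConfig())


class TestPretrainStack:
    def test_single_layer_equals_train_autoencoder(self, rng):
        X = rng.random((20, 5))
        cfg = saetm.TrainConfig(epochs=5, seed=3)
        stack = saetm.pretrain_stack(X, [4], cfg)
        solo = saetm.train_autoencoder(X, 4, cfg)
        np.testing.assert_array_equal(stack.layers[0].W, solo.W)

    def test_greedy_freezes_earlier_layers(self, rng):
        X = rng.random((30, 6))
        cfg = saetm.TrainConfig(epochs=5, seed=4)
        stack = saetm.pretrain_stack(X, [5, 3], cfg)
        # retrain only the first layer with the same rng stream prefix
        rng2 = np.random.default_rng(cfg.seed)
        first_alone = saetm.train_autoencoder(X, 5, cfg, rng=rng2)
        np.testing.assert_array_equal(stack.layers[0].W, first_alone.W)
        np.testing.assert_array_equal(stack.layers[0].b, first_alone.b)

    def test_each_layer_loss_decreases(self, rng):
        X = rng.random((40, 8))
        stack = saetm.pretrain_stack(X, [6, 4], saetm.TrainConfig(epochs=15, seed=5))
        for layer in stack.layers:
            assert layer.training_errors[-1] <= layer.training_errors[0]


class TestDeepRepresentation:
    def test_empty_stack_is_identity(self, rng):
        x = rng.random(5)
        np.testing.assert_array_equal(
            saetm.deep_representation(x, saetm.SAEStack(layers=[])), x)

    def test_single_layer_equals_encode(self, rng):
        layer = saetm._init_layer(5, 3, rng, "sigmoid")
        x = rng.random(5)
        np.testing.assert_array_equal(
            saetm.deep_representation(x, saetm.SAEStack(layers=[layer])),
            saetm.encode(x, layer))

    def test_output_in_unit_interval(self, rng):
        stack = saetm.SAEStack(layers=[saetm._init_layer(6, 4, rng, "sigmoid"),
                                       saetm._init_layer(4, 2, rng, "sigmoid")])
        h = saetm.deep_representation(rng.random((10, 6)), stack)
        assert np.all((h > 0) & (h < 1))


class TestSLF:
    def test_perfect_and_anti_correlation_give_zero(self, rng):
        D = rng.normal(size=(50, 4))
        assert saetm.slf(D, D) == pytest.approx(0.0, abs=1e-12)
        assert saetm.slf(D, -D) == pytest.approx(0.0, abs=1e-12)

    def test_independent_matrices_near_one(self):
        vals = [saetm.slf(np.random.default_rng(s).normal(size=(100, 10)),
                          np.random.default_rng(10_000 + s).normal(size=(100, 10)))
                for s in range(20)]
        assert np.mean(vals) == pytest.approx(1.0, abs=0.1)

    def test_bounds_and_degenerate_cases(self, rng):
        for s in range(10):
            r2 = np.random.default_rng(s)
            v = saetm.slf(r2.normal(size=(20, 3)),
                          r2.normal(size=(20, 3)) + 0.5 * r2.normal(size=(20, 3)))
            assert 0.0 <= v <= 1.0
        D = rng.normal(size=(10, 2))
        assert saetm.slf(D, np.zeros_like(D)) == 1.0  # constant Dz -> rho = 0
        with pytest.raises(ValueError):
            saetm.slf(np.zeros_like(D), D)
        with pytest.raises(ValueError):
            saetm.slf(D, D[:5])


class TestSelectArchitecture:
    def test_single_candidate_returned(self, rng):
        X = rng.random((30, 6))
        assert saetm.select_architecture(
            X, [[3]], saetm.TrainConfig(epochs=3, seed=0)) == [3]

    def test_argmin_contract(self, rng):
        # an untrained 1-neuron stack vs a roomy one on structured data
        u = rng.normal(size=(200, 2))
        X = u @ rng.normal(size=(2, 12)) + 0.05 * rng.normal(size=(200, 12))
        cfg = saetm.TrainConfig(epochs=10, seed=1)
        Xs = saetm._minmax_scale(X)[0]
        slfs = {}
        for sizes in ([2], [16]):
            stack = saetm.pretrain_stack(Xs, sizes, cfg)
            slfs[tuple(sizes)] = saetm.slf(Xs, saetm.reconstruct(Xs, stack))
        choice = saetm.select_architecture(X, [[2], [16]], cfg)
        assert slfs[tuple(choice)] == min(slfs.values())

    def test_structured_beats_shuffled_control(self, rng):
        u = rng.normal(size=(500, 2))
        X = u @ rng.normal(size=(2, 20)) + 0.05 * rng.normal(size=(500, 20))
        cfg = saetm.TrainConfig(epochs=10, seed=2)
        Xs = saetm._minmax_scale(X)[0]
        for sizes in ([2], [16]):
            stack = saetm.pretrain_stack(Xs, sizes, cfg)
            recon = saetm.reconstruct(Xs, stack)
            control = recon[rng.permutation(len(recon))]
            assert saetm.slf(Xs, recon) < saetm.slf(Xs, control)


class TestClassifier:
    @pytest.fixture()
    def clusters(self, rng):
        n = 50
        X = np.vstack([rng.normal(0.0, 0.3, size=(n, 4)),
                       rng.normal(3.0, 0.3, size=(n, 4))])
        y = np.array(["a"] * n + ["b"] * n)
        return X, y

    def test_separable_clusters_learned(self, clusters):
        X, y = clusters
        errs = []
        for seed in range(5):
            cfg = saetm.TrainConfig(epochs=50, seed=seed, dropout=0.0)
            stack = saetm.fit_classifier(X, y, [8], cfg)
            pred = saetm.predict(stack, X)
            errs.append(100.0 * np.mean(pred != y))
        assert np.median(errs) < 10.0

    def test_finetuning_reduces_cross_entropy(self, clusters):
        X, y = clusters
        stack = saetm.fit_classifier(X, y, [8],
                                     saetm.TrainConfig(epochs=30, seed=0,
                                                       dropout=0.0))
        assert stack.finetune_losses[-1] < stack.finetune_losses[0]

    def test_proba_rows_sum_to_one(self, clusters):
        X, y = clusters
        stack = saetm.fit_classifier(X, y, [6], saetm.TrainConfig(epochs=5, seed=0))
        P = saetm.predict_proba(stack, X)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((P >= 0) & (P <= 1))

    def test_predict_consistent_with_proba_and_batching(self, clusters):
        X, y = clusters
        stack = saetm.fit_classifier(X, y, [6], saetm.TrainConfig(epochs=5, seed=0))
        P = saetm.predict_proba(stack, X)
        labels = saetm.predict(stack, X)
        np.testing.assert_array_equal(
            labels, np.array(stack.classes)[P.argmax(axis=1)])
        single = np.array([saetm.predict(stack, X[i])[0] for i in range(5)])
        np.testing.assert_array_equal(single, labels[:5])

    def test_deterministic_given_seed(self, clusters):
        X, y = clusters
        cfg = saetm.TrainConfig(epochs=5, seed=9)
        a = saetm.fit_classifier(X, y, [6], cfg)
        b = saetm.fit_classifier(X, y, [6], cfg)
        np.testing.assert_array_equal(saetm.predict(a, X), saetm.predict(b, X))

    def test_label_outside_class_set_rejected(self, clusters):
        X, y = clusters
        with pytest.raises(ValueError):
            saetm.fit_classifier(X, y, [4], saetm.TrainConfig(epochs=1),
                                 classes=["a", "c"])

    def test_serialization_roundtrip(self, clusters, tmp_path):
        X, y = clusters
        stack = saetm.fit_classifier(X, y, [5], saetm.TrainConfig(epochs=3, seed=0))
        p = tmp_path / "model.json"
        saetm.save_stack(stack, p)
        back = saetm.load_stack(p)
        np.testing.assert_allclose(saetm.predict_proba(back, X),
                                   saetm.predict_proba(stack, X), atol=1e-12)
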