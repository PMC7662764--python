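"""Classifier architecture, training and evaluation."""

import numpy as np
import pytest

from tennisgcn.model import (
    EvalResult,
    ModelConfig,
    TrainConfig,
    build_model,
    count_parameters,
    evaluate,
    forward,
    load_model,
    save_model,
    train,
)
from tennisgcn.features import feature_matrix
from tennisgcn.skeleton_io import MotionSample
from tennisgcn.stgraph import CANONICAL_NODE_NAMES, build_graph
from tennisgcn.synth import samples_to_array


def closed_form_count(kernels, kt, c_in, n_classes, n_feats):
    """Independent hand count: conv + bias + BN affine per layer, then the
    1x1 map and the fusion layer."""
    total = 0
    prev = c_in
    for k in kernels:
        total += k * prev * kt + k + 2 * k
        prev = k
    total += kernels[-1] * kernels[-1] + kernels[-1]
    total += n_classes * (kernels[-1] + n_feats) + n_classes
    return total


@pytest.fixture(scope="module")
def arrays(clean_dataset):
    X = samples_to_array(clean_dataset.samples)
    y = clean_dataset.labels
    F = feature_matrix(clean_dataset.samples).astype(np.float32)
    F = (F - F.mean(0)) / np.maximum(F.std(0), 1e-8)
    return X, y, F


class TestArchitecture:
    def test_first_layer_width(self, graph):
        m = build_model(ModelConfig(input_channels=2), graph)
        assert m.params["W0"].shape == (32, 2, 3)
        m6 = build_model(ModelConfig(input_channels=6), graph)
        assert m6.params["W0"].shape == (32, 6, 3)

    @pytest.mark.parametrize("c_in,n_feats", [(2, 50), (6, 50), (2, 0)])
    def test_parameter_count_matches_closed_form(self, graph, c_in, n_feats):
        cfg = ModelConfig(
            input_channels=c_in,
            use_active_features=n_feats > 0,
            n_feature_inputs=n_feats,
        )
        m = build_model(cfg, graph)
        actual = sum(p.size for p in m.params.values())
        assert actual == count_parameters(cfg)
        assert actual == closed_form_count((32, 64, 64), 3, c_in, 3, n_feats)

    def test_disabling_features_shrinks_fusion(self, graph):
        with_f = ModelConfig(use_active_features=True, n_feature_inputs=50)
        without = ModelConfig(use_active_features=False, n_feature_inputs=50)
        assert count_parameters(with_f) - count_parameters(without) == 3 * 50

    def test_even_temporal_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            ModelConfig(temporal_kernel=4)


class TestForward:
    def test_probabilities_normalized(self, graph, rng):
        m = build_model(ModelConfig(n_feature_inputs=50), graph, seed=0)
        s = MotionSample(
            data=rng.normal(size=(2, 19, 14)),
            node_names=CANONICAL_NODE_NAMES,
            channel_names=("x", "z"),
        )
        p = forward(m, s, rng.normal(size=50))
        assert p.shape == (3,)
        assert np.all(p >= 0)
        assert p.sum() == pytest.approx(1.0, abs=1e-6)

    def test_zero_final_layer_uniform(self, graph, rng):
        m = build_model(ModelConfig(), graph, seed=0)
        m.params["Wf"][:] = 0
        m.params["bf"][:] = 0
        s = MotionSample(
            data=rng.normal(size=(2, 19, 14)),
            node_names=CANONICAL_NODE_NAMES,
            channel_names=("x", "z"),
        )
        np.testing.assert_allclose(forward(m, s, rng.normal(size=50)), 1 / 3, atol=1e-7)

    def test_deterministic_given_parameters(self, graph, rng):
        m = build_model(ModelConfig(), graph, seed=5)
        X = rng.normal(size=(4, 2, 19, 14)).astype(np.float32)
        F = rng.normal(size=(4, 50)).astype(np.float32)
        np.testing.assert_array_equal(m.predict_proba(X, F), m.predict_proba(X, F))

    def test_node_permutation_invariance(self, rng):
        """Permuting graph nodes and data rows consistently leaves the
        pooled prediction unchanged (graph conv equivariance + pooling)."""
        names = list(CANONICAL_NODE_NAMES)
        from tennisgcn.stgraph import CANONICAL_EDGES

        g = build_graph(names, CANONICAL_EDGES)
        perm = list(rng.permutation(19))
        pnames = [names[i] for i in perm]
        gp = build_graph(pnames, CANONICAL_EDGES)
        cfg = ModelConfig(use_active_features=False, n_feature_inputs=0)
        m = build_model(cfg, g, seed=3)
        mp = build_model(cfg, gp, seed=3)  # same seed -> same weights
        X = rng.normal(size=(2, 2, 19, 14)).astype(np.float32)
        Xp = X[:, :, perm, :]
        np.testing.assert_allclose(mp.predict_proba(Xp), m.predict_proba(X), atol=1e-5)


class TestTraining:
    def test_separable_data_reaches_full_accuracy(self, graph, arrays):
        X, y, F = arrays
        m = build_model(ModelConfig(), graph, seed=1)
        res = train(m, X, y, F, TrainConfig(learning_rate=0.02, batch_size=16,
                                            max_epochs=200, seed=1))
        assert res.epochs_run <= 200
        assert evaluate(m, X, y, F).accuracy == 1.0

    def test_seeded_runs_bit_identical(self, graph, arrays):
        X, y, F = arrays
        cfg = TrainConfig(learning_rate=0.02, max_epochs=8, seed=9)
        r1 = train(build_model(ModelConfig(), graph, seed=2), X, y, F, cfg)
        r2 = train(build_model(ModelConfig(), graph, seed=2), X, y, F, cfg)
        assert r1.loss_trajectory == r2.loss_trajectory

    def test_zero_learning_rate_stops_at_patience_floor(self, graph, arrays):
        X, y, F = arrays
        m = build_model(ModelConfig(), graph, seed=0)
        before = {k: v.copy() for k, v in m.params.items()}
        # tol large enough that batch-shuffle jitter in the epoch loss
        # cannot register as improvement
        cfg = TrainConfig(learning_rate=0.0, patience=4, max_epochs=100, tol=1e-2, seed=0)
        res = train(m, X, y, F, cfg)
        for k in before:
            np.testing.assert_array_equal(m.params[k], before[k])
        # loss never improves, so training stops after patience+1 epochs
        assert res.epochs_run == cfg.patience + 1

    def test_missing_class_rejected(self, graph, arrays):
        X, y, F = arrays
        keep = y != 2
        m = build_model(ModelConfig(), graph, seed=0)
        with pytest.raises(ValueError, match="no_shot"):
            train(m, X[keep], y[keep], F[keep], TrainConfig(max_epochs=1))

    def test_loss_decreases_on_separable_data(self, graph, arrays):
        X, y, F = arrays
        m = build_model(ModelConfig(), graph, seed=4)
        res = train(m, X, y, F, TrainConfig(learning_rate=0.02, max_epochs=30, seed=4))
        assert res.loss_trajectory[-1] < res.loss_trajectory[0]


class TestEvaluate:
    def _constant_model(self, graph, cls):
        m = build_model(ModelConfig(use_active_features=False, n_feature_inputs=0), graph, seed=0)
        m.params["Wf"][:] = 0
        m.params["bf"][:] = 0
        m.params["bf"][cls] = 10.0
        return m

    def test_perfect_and_degenerate_predictions(self, graph, rng):
        X = rng.normal(size=(30, 2, 19, 14)).astype(np.float32)
        y = np.repeat([0, 1, 2], 10)
        m = self._constant_model(graph, 2)  # predicts no_shot always
        ev = evaluate(m, X, y)
        assert ev.accuracy == pytest.approx(1 / 3)
        assert ev.confusion[:, 2].sum() == 30
        assert ev.tp_rates[2] == 1.0 and ev.tp_rates[0] == 0.0

    def test_confusion_matrix_arithmetic(self, graph, rng):
        X = rng.normal(size=(25, 2, 19, 14)).astype(np.float32)
        y = rng.integers(0, 3, size=25)
        while len(np.unique(y)) < 3:
            y = rng.integers(0, 3, size=25)
        m = build_model(ModelConfig(use_active_features=False, n_feature_inputs=0), graph, seed=8)
        ev = evaluate(m, X, y)
        pred = m.predict(X)
        manual = np.zeros((3, 3), dtype=int)
        for t, p in zip(y, pred):
            manual[t, p] += 1
        np.testing.assert_array_equal(ev.confusion, manual)
        assert ev.accuracy == pytest.approx(np.trace(manual) / 25)
        rows = manual.sum(axis=1)
        for c in range(3):
            if rows[c]:
                assert ev.tp_rates[c] == pytest.approx(manual[c, c] / rows[c])

    def test_bad_labels_rejected(self, graph, rng):
        X = rng.normal(size=(3, 2, 19, 14)).astype(np.float32)
        m = build_model(ModelConfig(use_active_features=False, n_feature_inputs=0), graph)
        with pytest.raises(ValueError, match="labels"):
            evaluate(m, X, np.array([0, 1, 7]))


def test_refresh_bn_stats_aligns_eval_with_training(graph, arrays):
    """After the precise-BN pass, evaluation-mode accuracy on the training
    data matches the near-perfect fit that train-mode batches achieved."""
    X, y, F = arrays
    m = build_model(ModelConfig(), graph, seed=11)
    train(m, X, y, F, TrainConfig(learning_rate=0.05, batch_size=16, max_epochs=60, seed=11))
    m.refresh_bn_stats(X, F)
    assert evaluate(m, X, y, F).accuracy >= 0.99


def test_save_load_roundtrip(graph, rng, tmp_path):
    m = build_model(ModelConfig(), graph, seed=6)
    X = rng.normal(size=(3, 2, 19, 14)).astype(np.float32)
    F = rng.normal(size=(3, 50)).astype(np.float32)
    p0 = m.predict_proba(X, F)
    path = tmp_path / "model.npz"
    save_model(m, path)
    back = load_model(path, graph)
    np.testing.assert_array_equal(back.predict_proba(X, F), p0)
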