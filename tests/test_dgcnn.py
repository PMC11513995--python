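"""Graph regressor: split protocol, forward-pass properties, training contract."""

import numpy as np
import pytest

from metagraph import autodiff as ad
from metagraph.dgcnn import (
    ModelConfig,
    TrainedRegressor,
    _Batch,
    _Prepared,
    _fit,
    evaluate,
    forward,
    init_params,
    null_model_mae,
    split_data,
    train,
)
from metagraph.graphs import SampleGraph


def tiny_graph(seed=0, n_nodes=7, sample_id="G"):
    rng = np.random.default_rng(seed)
    feats = np.zeros((n_nodes, 2), dtype=np.int64)
    feats[n_nodes // 2 :, 0] = 1
    feats[-1, 1] = 1
    edges, weights = [], []
    for j in range(1, n_nodes):
        edges.append([rng.integers(0, j), j])
        weights.append(float(rng.integers(1, 40)))
    return SampleGraph(
        sample_id=sample_id,
        node_names=[f"n{i}" for i in range(n_nodes)],
        node_features=feats,
        edges=np.array(edges),
        weights=np.array(weights),
        label=float(rng.normal(100, 30)),
    )


SMALL_CONFIG = ModelConfig(
    attention_widths=(2, 4, 4, 4, 6), conv_width=6, dense_widths=(6, 3, 1), epochs=2
)


class TestSplit:
    def test_floor_convention(self):
        train_ids, test_ids = split_data(list(range(20)))
        assert (len(train_ids), len(test_ids)) == (17, 3)
        train_ids, test_ids = split_data(list(range(184)))
        assert (len(train_ids), len(test_ids)) == (156, 28)

    def test_deterministic_partition(self):
        a = split_data(list(range(50)), 0.85, 40)
        b = split_data(list(range(50)), 0.85, 40)
        assert a == b
        assert set(a[0]) | set(a[1]) == set(range(50))
        assert not set(a[0]) & set(a[1])

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            split_data([1])


class TestForward:
    def test_scalar_output_and_determinism(self):
        params = init_params(SMALL_CONFIG, np.random.default_rng(0))
        batch = _Batch([_Prepared(tiny_graph(1))])
        out1 = forward(params, batch, SMALL_CONFIG)
        out2 = forward(params, batch, SMALL_CONFIG)
        assert out1.data.shape == (1,)
        assert out1.data[0] == out2.data[0]

    def test_permutation_invariance(self):
        """Relabelling nodes leaves the prediction unchanged (message passing
        plus max readout are order-free)."""
        params = init_params(SMALL_CONFIG, np.random.default_rng(3))
        rng = np.random.default_rng(5)
        for trial in range(5):
            g = tiny_graph(seed=trial, n_nodes=9)
            perm = rng.permutation(g.n_nodes)
            inv = np.argsort(perm)
            permuted = SampleGraph(
                sample_id=g.sample_id,
                node_names=[g.node_names[i] for i in perm],
                node_features=g.node_features[perm],
                edges=inv[g.edges],
                weights=g.weights,
                label=g.label,
            )
            a = forward(params, _Batch([_Prepared(g)]), SMALL_CONFIG).data[0]
            b = forward(params, _Batch([_Prepared(permuted)]), SMALL_CONFIG).data[0]
            assert b == pytest.approx(a, rel=1e-5)

    def test_zero_node_graph_rejected(self):
        g = SampleGraph(
            sample_id="empty",
            node_names=[],
            node_features=np.zeros((0, 2)),
            edges=np.zeros((0, 2)),
            weights=np.zeros(0),
            label=0.0,
        )
        with pytest.raises(ValueError, match="no nodes"):
            _Prepared(g)

    def test_batching_matches_single_graph_forward(self):
        params = init_params(SMALL_CONFIG, np.random.default_rng(2))
        graphs = [tiny_graph(seed=s) for s in range(4)]
        together = forward(
            params, _Batch([_Prepared(g) for g in graphs]), SMALL_CONFIG
        ).data
        separate = [
            forward(params, _Batch([_Prepared(g)]), SMALL_CONFIG).data[0] for g in graphs
        ]
        np.testing.assert_allclose(together, separate, rtol=1e-10)

    def test_end_to_end_gradients_match_finite_differences(self):
        from test_autodiff import numeric_grad

        params = init_params(SMALL_CONFIG, np.random.default_rng(7))
        batch = _Batch([_Prepared(tiny_graph(s)) for s in range(2)])
        target = np.array([0.3, -0.2])

        loss = ad.mean_abs_error(forward(params, batch, SMALL_CONFIG), target)
        loss.backward()
        for name in ("gat0_w", "gat2_a_src", "gcn_w", "post_b", "dense2_w"):
            t = params[name]

            def f():
                return float(ad.mean_abs_error(forward(params, batch, SMALL_CONFIG), target).data)

            num = numeric_grad(f, t.data)
            np.testing.assert_allclose(t.grad, num, rtol=1e-4, atol=1e-8, err_msg=name)


@pytest.fixture(scope="module")
def graphs():
    return [tiny_graph(seed=s, sample_id=f"G{s}") for s in range(30)]


class TestTrainingContract:
    def test_epochs_zero_predicts_training_mean(self, graphs):
        labels = np.array([g.label for g in graphs])
        prepared = [_Prepared(g) for g in graphs]
        cfg = ModelConfig(epochs=0)
        model = _fit(prepared, labels, cfg, seed=0)
        preds = model.predict(graphs)
        # zero output bias + standardised targets: predictions sit at the
        # training mean up to the small pre-activation leakage of random init
        np.testing.assert_allclose(preds, labels.mean(), rtol=0.05)
        mae = np.mean(np.abs(preds - labels))
        assert mae == pytest.approx(null_model_mae(labels, labels), rel=0.1)

    def test_training_reduces_loss_history(self, graphs):
        labels = np.array([g.label for g in graphs])
        cfg = ModelConfig(
            attention_widths=(2, 8, 8, 8, 16), conv_width=16, dense_widths=(16, 8, 1), epochs=30
        )
        model = _fit([_Prepared(g) for g in graphs], labels, cfg, seed=1)
        assert len(model.history) == 30
        assert model.history[-1] < model.history[0]

    def test_train_protocol_report_fields(self, graphs):
        cfg = ModelConfig(
            attention_widths=(2, 4, 4, 4, 6), conv_width=6, dense_widths=(6, 3, 1), epochs=2
        )
        model, report = train(graphs, cfg)
        assert report.train_mae >= 0 and report.test_mae >= 0
        assert report.cv_sd_mae >= 0
        assert report.rmse >= 0
        # final model predicts deterministically
        np.testing.assert_array_equal(model.predict(graphs[:3]), model.predict(graphs[:3]))

    def test_too_few_graphs_for_cv(self):
        with pytest.raises(ValueError):
            train([tiny_graph(s) for s in range(6)], SMALL_CONFIG)

    def test_checkpoint_round_trip(self, graphs, tmp_path):
        labels = np.array([g.label for g in graphs])
        model = _fit([_Prepared(g) for g in graphs], labels, SMALL_CONFIG, seed=4)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = TrainedRegressor.load(path)
        np.testing.assert_array_equal(loaded.predict(graphs), model.predict(graphs))
        assert loaded.config == model.config


class TestEvaluate:
    def _model_with_fixed_preds(self, preds):
        class Stub:
            def predict(self, graphs):
                return np.asarray(preds[: len(graphs)])

        return Stub()

    def test_perfect_predictions(self):
        graphs = [tiny_graph(seed=s) for s in range(4)]
        truths = np.array([g.label for g in graphs])
        m = evaluate(self._model_with_fixed_preds(truths), graphs)
        assert (m.mae, m.rmse) == (0.0, 0.0)
        assert m.pearson_r == pytest.approx(1.0)

    def test_constant_offset(self):
        graphs = [tiny_graph(seed=s) for s in range(4)]
        truths = np.array([g.label for g in graphs])
        m = evaluate(self._model_with_fixed_preds(truths + 5.0), graphs)
        assert m.mae == pytest.approx(5.0)
        assert m.rmse == pytest.approx(5.0)
        assert m.pearson_r == pytest.approx(1.0)

    def test_four_point_hand_oracle(self):
        # preds (1,2,3,4) vs truths (2,2,5,3): residuals (-1,0,-2,1)
        graphs = [tiny_graph(seed=s) for s in range(4)]
        for g, t in zip(graphs, [2.0, 2.0, 5.0, 3.0]):
            g.label = t
        m = evaluate(self._model_with_fixed_preds(np.array([1.0, 2.0, 3.0, 4.0])), graphs)
        assert m.mae == pytest.approx(1.0)
        assert m.rmse == pytest.approx(np.sqrt(6 / 4))
        x, y = np.array([1, 2, 3, 4.0]), np.array([2, 2, 5, 3.0])
        r_manual = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert m.pearson_r == pytest.approx(r_manual)

    def test_rmse_at_least_mae(self):
        rng = np.random.default_rng(11)
        graphs = [tiny_graph(seed=s) for s in range(10)]
        preds = np.array([g.label for g in graphs]) + rng.normal(0, 20, 10)
        m = evaluate(self._model_with_fixed_preds(preds), graphs)
        assert m.rmse >= m.mae

    def test_zero_variance_truth_flags_r(self):
        graphs = [tiny_graph(seed=s) for s in range(3)]
        for g in graphs:
            g.label = 7.0
        m = evaluate(self._model_with_fixed_preds(np.array([1.0, 2.0, 3.0])), graphs)
        assert np.isnan(m.pearson_r)
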