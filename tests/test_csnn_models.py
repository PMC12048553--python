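"""Neighbourhood models: aggregation, heads, loss masking, training."""

import numpy as np
import pytest

from csnn.csnn_models import (CSNNModel, ModelConfig, TrainConfig, batch_loss,
                              confidence_filter, gradient_check, train)
from csnn.dataset_builder import NeighbourhoodGraph
from csnn.laf_inference import ABSTAIN


def toy_graph(n_edges=2, node_dim=4, edge_dim=7, target_dim=3, label_cls=0,
              n_classes=6, mode="single", seed=0, label=None):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_edges + 1, node_dim))
    e = rng.standard_normal((n_edges, edge_dim))
    if label is None and mode == "single":
        label = np.zeros(n_classes)
        label[label_cls] = 1.0
    return NeighbourhoodGraph(
        query_id="q",
        node_ids=["q"] + [f"n{i}" for i in range(n_edges)],
        node_features=x,
        edge_src=np.arange(1, n_edges + 1),
        edge_features=e,
        similarities=np.full(n_edges, 0.5),
        laf_vector=(np.ones(n_classes) / n_classes if mode == "single"
                    else np.ones(edge_dim) / 7),
        mode=mode,
        receptor_id="R0" if mode == "single" else None,
        target_embedding=(rng.standard_normal(target_dim)
                          if mode == "single" else None),
        label=label,
    )


def zeroed(model):
    for k in model.params:
        model.params[k][:] = 0.0
    return model


class TestDimensions:
    def test_single_receptor_skip_width_582(self):
        cfg = ModelConfig.nn_single()
        assert cfg.skip_dim == 256 + 320 + 6 == 582
        assert cfg.out_dim == 6

    def test_multi_receptor_widths(self):
        cfg = ModelConfig.nn_multi()
        assert cfg.edge_dim == 128 * 7 == 896
        assert cfg.skip_dim == 64 + 896 == 960
        assert cfg.out_dim == 896


class TestAggregation:
    def test_zero_edges_reduces_to_query_features(self):
        # eps=0, zero weights: r = ReLU(W2 ReLU(W1 x)) with W=0 -> 0;
        # instead check the pre-MLP sum via a 1-layer identity surrogate
        cfg = ModelConfig(mode="single", node_dim=4, target_dim=3,
                          gnn_hidden=4, gnn_out=4, head_hidden=4)
        model = CSNNModel(cfg, seed=0)
        g = toy_graph(n_edges=0, node_dim=4, target_dim=3)
        cache = model._forward(g)
        assert cache["s"] == pytest.approx(g.node_features[0])

    def test_eps_scales_query_contribution(self):
        cfg = ModelConfig(mode="single", node_dim=4, target_dim=3,
                          gnn_hidden=4, gnn_out=4, head_hidden=4, eps_gin=1.0)
        model = CSNNModel(cfg, seed=0)
        g = toy_graph(n_edges=0, node_dim=4, target_dim=3)
        assert model._forward(g)["s"] == pytest.approx(2 * g.node_features[0])

    def test_duplicate_edges_sum_not_mean(self):
        cfg = ModelConfig(mode="single", node_dim=4, target_dim=3,
                          gnn_hidden=4, gnn_out=4, head_hidden=4)
        model = CSNNModel(cfg, seed=1)
        g1 = toy_graph(n_edges=1, node_dim=4, target_dim=3, seed=5)
        # duplicate the single edge (same neighbour features)
        g2 = NeighbourhoodGraph(
            query_id=g1.query_id,
            node_ids=g1.node_ids + [g1.node_ids[1]],
            node_features=np.vstack([g1.node_features, g1.node_features[1]]),
            edge_src=np.array([1, 2]),
            edge_features=np.vstack([g1.edge_features, g1.edge_features]),
            similarities=np.concatenate([g1.similarities, g1.similarities]),
            laf_vector=g1.laf_vector, mode="single",
            receptor_id=g1.receptor_id,
            target_embedding=g1.target_embedding, label=g1.label)
        s1 = model._forward(g1)["s"]
        s2 = model._forward(g2)["s"]
        x0 = g1.node_features[0]
        assert s2 - x0 == pytest.approx(2 * (s1 - x0))

    def test_edge_permutation_bit_exact(self, single_graphs):
        cfg = ModelConfig(mode="single", node_dim=24, target_dim=12,
                          gnn_hidden=16, gnn_out=16, head_hidden=16)
        model = CSNNModel(cfg, seed=2)
        g = next(g for g in single_graphs if g.n_edges >= 3)
        z_ref = model.logits(g)
        rng = np.random.default_rng(0)
        for _ in range(5):
            perm = rng.permutation(g.n_edges)
            shuffled = NeighbourhoodGraph(
                query_id=g.query_id,
                node_ids=[g.node_ids[0]] + [g.node_ids[1 + k] for k in perm],
                node_features=np.vstack([g.node_features[:1],
                                         g.node_features[1 + perm]]),
                edge_src=np.arange(1, g.n_edges + 1),
                edge_features=g.edge_features[perm],
                similarities=g.similarities[perm],
                laf_vector=g.laf_vector, mode=g.mode,
                receptor_id=g.receptor_id,
                target_embedding=g.target_embedding, label=g.label)
            assert (model.logits(shuffled) == z_ref).all()


class TestHeads:
    def test_probabilities_sum_to_one(self, single_graphs):
        cfg = ModelConfig(mode="single", node_dim=24, target_dim=12,
                          gnn_hidden=8, gnn_out=8, head_hidden=8)
        model = CSNNModel(cfg, seed=3)
        g = next(g for g in single_graphs if g.n_edges)
        pred = model.predict(g)
        assert pred.probabilities.sum() == pytest.approx(1.0, abs=1e-6)

    def test_zero_weights_uniform_single(self):
        cfg = ModelConfig(mode="single", node_dim=4, target_dim=3,
                          gnn_hidden=4, gnn_out=4, head_hidden=4)
        model = zeroed(CSNNModel(cfg, seed=0))
        pred = model.predict(toy_graph(n_edges=2, node_dim=4, target_dim=3))
        assert pred.probabilities == pytest.approx(np.full(6, 1 / 6))
        assert pred.confidence == pytest.approx(1 / 6)

    def test_zero_weights_uniform_multi(self):
        cfg = ModelConfig.nn_multi(n_receptors=4, node_dim=4, gnn_hidden=4,
                                   gnn_out=4, head_hidden=4)
        model = zeroed(CSNNModel(cfg, seed=0))
        g = toy_graph(n_edges=2, node_dim=4, edge_dim=4 * 7, mode="multi",
                      label=np.array([0, 6, 6, 1]))
        pred = model.predict(g)
        assert pred.probabilities.shape == (4, 7)
        assert pred.probabilities == pytest.approx(np.full((4, 7), 1 / 7))

    def test_multi_rows_sum_to_one(self, multi_graphs, small_space):
        R = small_space.spec.n_receptors
        cfg = ModelConfig.nn_multi(n_receptors=R, node_dim=24, gnn_hidden=8,
                                   gnn_out=8, head_hidden=8)
        model = CSNNModel(cfg, seed=4)
        g = next(g for g in multi_graphs if g.n_edges)
        pred = model.predict(g)
        assert pred.probabilities.sum(axis=1) == pytest.approx(np.ones(R))

    def test_ood_graph_abstains(self):
        cfg = ModelConfig(mode="single", node_dim=4, target_dim=3,
                          gnn_hidden=4, gnn_out=4, head_hidden=4)
        model = CSNNModel(cfg, seed=0)
        assert model.predict(toy_graph(n_edges=0, node_dim=4,
                                       target_dim=3)) is ABSTAIN


class TestLoss:
    def test_uniform_logits_loss_ln6(self):
        cfg = ModelConfig(mode="single", node_dim=4, target_dim=3,
                          gnn_hidden=4, gnn_out=4, head_hidden=4)
        model = zeroed(CSNNModel(cfg, seed=0))
        loss = batch_loss(model, [toy_graph(node_dim=4, target_dim=3)])
        assert loss == pytest.approx(np.log(6), abs=1e-12)

    def test_confident_correct_prediction_low_loss(self):
        cfg = ModelConfig(mode="single", node_dim=4, target_dim=3,
                          gnn_hidden=4, gnn_out=4, head_hidden=4)
        model = zeroed(CSNNModel(cfg, seed=0))
        model.params["c3"][:] = np.array([50.0, 0, 0, 0, 0, 0])
        loss = batch_loss(model, [toy_graph(node_dim=4, target_dim=3,
                                            label_cls=0)])
        assert loss < 1e-12

    def test_fully_masked_record_never_changes_loss(self):
        cfg = ModelConfig.nn_multi(n_receptors=4, node_dim=4, gnn_hidden=4,
                                   gnn_out=4, head_hidden=4)
        model = CSNNModel(cfg, seed=5)
        labelled = toy_graph(n_edges=2, node_dim=4, edge_dim=28, mode="multi",
                             label=np.array([0, 2, 6, 6]), seed=1)
        masked = toy_graph(n_edges=2, node_dim=4, edge_dim=28, mode="multi",
                           label=np.array([6, 6, 6, 6]), seed=2)
        base = batch_loss(model, [labelled])
        augmented = batch_loss(model, [labelled, masked, masked])
        assert abs(base - augmented) < 1e-12

    def test_all_masked_batch_is_an_error(self):
        cfg = ModelConfig.nn_multi(n_receptors=4, node_dim=4, gnn_hidden=4,
                                   gnn_out=4, head_hidden=4)
        model = CSNNModel(cfg, seed=0)
        masked = toy_graph(n_edges=1, node_dim=4, edge_dim=28, mode="multi",
                           label=np.array([6, 6, 6, 6]))
        with pytest.raises(ValueError, match="no labelled"):
            batch_loss(model, [masked])

    def test_masked_positions_do_not_receive_gradient(self):
        cfg = ModelConfig.nn_multi(n_receptors=4, node_dim=4, gnn_hidden=4,
                                   gnn_out=4, head_hidden=4)
        model = CSNNModel(cfg, seed=6)
        g = toy_graph(n_edges=1, node_dim=4, edge_dim=28, mode="multi",
                      label=np.array([1, 6, 6, 6]))
        _, grads = model.loss_and_grads([g])
        dc3 = grads["c3"].reshape(4, 7)
        assert (dc3[1:] == 0).all()
        assert (dc3[0] != 0).any()


class TestGradients:
    def test_analytic_matches_finite_difference_single(self):
        cfg = ModelConfig(mode="single", node_dim=5, target_dim=3,
                          gnn_hidden=6, gnn_out=4, head_hidden=5)
        model = CSNNModel(cfg, seed=7)
        graphs = [toy_graph(n_edges=2, node_dim=5, target_dim=3, seed=1),
                  toy_graph(n_edges=0, node_dim=5, target_dim=3, seed=2,
                            label_cls=3)]
        assert gradient_check(model, graphs, n_samples=6, seed=0) < 1e-4

    def test_analytic_matches_finite_difference_multi(self):
        cfg = ModelConfig.nn_multi(n_receptors=3, n_classes=6, node_dim=5,
                                   gnn_hidden=6, gnn_out=4, head_hidden=5)
        model = CSNNModel(cfg, seed=8)
        g = toy_graph(n_edges=2, node_dim=5, edge_dim=21, mode="multi",
                      label=np.array([0, 6, 4]), seed=3)
        assert gradient_check(model, [g], n_samples=6, seed=0) < 1e-4


@pytest.fixture(scope="module")
def trained(single_graphs):
    cfg = ModelConfig(mode="single", node_dim=24, target_dim=12,
                      gnn_hidden=24, gnn_out=24, head_hidden=32)
    tc = TrainConfig(learning_rate=1e-3, epochs=8, seed=0, n_repeats=2)
    return train(single_graphs, cfg, tc)


class TestTraining:
    def test_loss_decreases(self, trained):
        assert trained.loss_history[-1] < trained.loss_history[0]

    def test_repeat_table_and_summary(self, trained):
        assert len(trained.repeat_metrics) == 2
        assert "final_train_loss" in trained.summary

    def test_deterministic_rerun(self, single_graphs):
        cfg = ModelConfig(mode="single", node_dim=24, target_dim=12,
                          gnn_hidden=8, gnn_out=8, head_hidden=8)
        tc = TrainConfig(learning_rate=1e-3, epochs=3, seed=9, n_repeats=1)
        a = train(single_graphs, cfg, tc)
        b = train(single_graphs, cfg, tc)
        assert a.loss_history == b.loss_history
        for k in a.model.params:
            assert (a.model.params[k] == b.model.params[k]).all()

    def test_save_load_round_trip(self, trained, tmp_path, single_graphs):
        trained.model.save(tmp_path / "m")
        back = CSNNModel.load(tmp_path / "m")
        g = next(g for g in single_graphs if g.n_edges)
        assert (back.logits(g) == trained.model.logits(g)).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)


class TestConfidenceFilter:
    def make_preds(self, confidences):
        from csnn.csnn_models import PredictionWithConfidence
        return [PredictionWithConfidence(probabilities=np.full(6, 1 / 6),
                                         predicted_class=0, confidence=c)
                for c in confidences]

    def test_threshold_zero_keeps_all(self):
        preds = self.make_preds([0.2, 0.9])
        kept, frac = confidence_filter(preds, 0.0)
        assert len(kept) == 2 and frac == 1.0

    def test_threshold_one_keeps_none(self):
        kept, frac = confidence_filter(self.make_preds([0.9, 1.0]), 1.0)
        assert kept == [] and frac == 0.0

    def test_abstain_never_passes(self):
        kept, _ = confidence_filter([ABSTAIN] + self.make_preds([0.9]), 0.5)
        assert len(kept) == 1

    def test_filtered_accuracy_not_worse(self, single_graphs):
        """Confident predictions of a trained model are at least as accurate
        as the unfiltered set (high-homophily synthetic space)."""
        cfg = ModelConfig(mode="single", node_dim=24, target_dim=12,
                          gnn_hidden=24, gnn_out=24, head_hidden=32)
        tc = TrainConfig(learning_rate=1e-3, epochs=10, seed=1, n_repeats=1)
        model = train(single_graphs, cfg, tc).model
        scored = []
        for g in single_graphs:
            pred = model.predict(g)
            if pred is ABSTAIN:
                continue
            scored.append((pred.confidence,
                           pred.predicted_class == int(np.argmax(g.label))))
        overall = np.mean([ok for _, ok in scored])
        confident = [ok for c, ok in scored if c > 0.8]
        assert confident, "no confident predictions after training"
        assert np.mean(confident) >= overall
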