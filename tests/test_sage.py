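"""GraphSAGE: sampling, aggregation, layer updates, loss and training."""

import numpy as np
import pytest

from pairsage.dtp import DTPIndex
from pairsage.sage import (
    FullDTPSampler,
    RestrictedSampler,
    SageConfig,
    SageModel,
    aggregate_mean,
    cross_entropy,
    layer_update,
    sample_neighborhood,
    train as sage_train,
)


class TestSampling:
    def test_tree_shape_and_edge_validity(self, small_index):
        sampler = FullDTPSampler(small_index)
        layers = sample_neighborhood(sampler, u=0, fanouts=(2, 1), seed=0)
        assert layers[0].shape == (1,)
        assert layers[1].shape == (1, 2)
        assert layers[2].shape == (1, 2, 1)
        for parent, child in zip(layers[0].ravel(), layers[1].reshape(-1, 2)):
            for c in child:
                assert small_index.adjacency(int(parent), int(c)) == 1
        for parent, child in zip(layers[1].ravel(), layers[2].reshape(-1, 1)):
            assert small_index.adjacency(int(parent), int(child[0])) == 1

    def test_without_replacement_when_degree_sufficient(self, small_index):
        # degree = 3 + 4 - 2 = 5; fanout 5 must produce 5 distinct neighbors
        sampler = FullDTPSampler(small_index)
        rng = np.random.default_rng(0)
        for _ in range(10):
            sample = sampler.sample_batch(np.array([7]), 5, rng)[0]
            assert len(set(sample.tolist())) == 5
            assert set(sample.tolist()) == set(small_index.neighbors(7).tolist())

    def test_with_replacement_fills_fanout_when_degree_small(self):
        index = DTPIndex(["D0", "D1"], ["T0"])  # degree 1
        sampler = FullDTPSampler(index)
        rng = np.random.default_rng(0)
        sample = sampler.sample_batch(np.array([0]), 4, rng)[0]
        assert sample.shape == (4,)
        assert set(sample.tolist()) == {1}

    def test_isolated_node_filled_with_self(self):
        index = DTPIndex(["D0"], ["T0"])
        sampler = FullDTPSampler(index)
        rng = np.random.default_rng(0)
        assert (sampler.sample_batch(np.array([0]), 3, rng) == 0).all()

    def test_same_seed_identical_tree(self, small_index):
        sampler = FullDTPSampler(small_index)
        t1 = sample_neighborhood(sampler, 3, (3, 2), seed=11)
        t2 = sample_neighborhood(sampler, 3, (3, 2), seed=11)
        assert all((a == b).all() for a, b in zip(t1, t2))

    def test_full_sampler_matches_explicit_neighbor_sets(self):
        index = DTPIndex([f"D{i}" for i in range(4)], [f"T{j}" for j in range(5)])
        sampler = FullDTPSampler(index)
        rng = np.random.default_rng(2)
        nodes = np.arange(index.n_pairs)
        out = sampler.sample_batch(nodes, index.degree, rng)
        for u, row in zip(nodes, out):
            assert set(row.tolist()) == set(index.neighbors(int(u)).tolist())

    def test_restricted_sampler_only_returns_subset_nodes(self, small_index):
        subset = np.array([0, 1, 4, 11])
        sampler = RestrictedSampler(small_index, subset)
        rng = np.random.default_rng(0)
        out = sampler.sample_batch(subset, 3, rng)
        for u, row in zip(subset, out):
            nbrs = set(row.tolist()) - {int(u)}
            for v in nbrs:
                assert v in set(subset.tolist())
                assert small_index.adjacency(int(u), v) == 1


class TestElementaryOps:
    def test_mean_aggregator_examples(self):
        assert (aggregate_mean([(1, 3), (3, 5)]) == [2, 4]).all()
        assert (aggregate_mean([(7.0, -1.0)]) == [7.0, -1.0]).all()

    def test_mean_matches_summation_oracle(self):
        rng = np.random.default_rng(0)
        vecs = rng.normal(size=(50, 8))
        oracle = sum(vecs[i] for i in range(50)) / 50
        assert np.allclose(aggregate_mean(list(vecs)), oracle, atol=1e-12)

    def test_mean_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_mean([])

    def test_layer_update_identity_case(self):
        W = np.hstack([np.eye(2), np.zeros((2, 2))])
        out = layer_update([1.0, 2.0], [5.0, 6.0], W)
        assert (out == [1.0, 2.0]).all()

    def test_layer_update_zero_inputs_relu(self):
        W = np.ones((3, 4))
        assert (layer_update([0, 0], [0, 0], W) == 0).all()

    def test_layer_update_matches_matmul_oracle(self):
        rng = np.random.default_rng(1)
        h_self, h_nbr = rng.normal(size=4), rng.normal(size=4)
        W = rng.normal(size=(3, 8))
        oracle = np.maximum(W @ np.concatenate([h_self, h_nbr]), 0.0)
        assert np.allclose(layer_update(h_self, h_nbr, W), oracle, atol=1e-10)

    def test_layer_update_dim_mismatch_rejected(self):
        with pytest.raises(ValueError):
            layer_update([1.0], [1.0], np.ones((2, 3)))

    def test_cross_entropy_closed_forms(self):
        assert cross_entropy([1], [1 - 1e-9]) == pytest.approx(0.0, abs=1e-6)
        assert cross_entropy([1, 0], [0.5, 0.5]) == pytest.approx(np.log(2), abs=1e-12)

    def test_cross_entropy_matches_scalar_loop(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, size=40)
        p = rng.uniform(0.01, 0.99, size=40)
        loop = -sum(
            yi * np.log(pi) + (1 - yi) * np.log(1 - pi) for yi, pi in zip(y, p)
        ) / 40
        assert cross_entropy(y, p) == pytest.approx(loop, abs=1e-12)

    def test_cross_entropy_monotone_toward_truth(self):
        base = cross_entropy([1, 0], [0.6, 0.4])
        assert cross_entropy([1, 0], [0.7, 0.4]) < base
        assert cross_entropy([1, 0], [0.6, 0.3]) < base

    def test_cross_entropy_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy([1, 0], [0.5])


def recursive_forward(index, feats, params, u, k, nonlinearity="relu"):
    """Naive per-node recursive evaluation of the aggregate + update
    recursion with full neighborhoods (the batched-path oracle)."""
    if k == 0:
        return feats[u]
    nbrs = index.neighbors(u)
    m = np.mean(
        [recursive_forward(index, feats, params, int(v), k - 1) for v in nbrs], axis=0
    )
    h_self = recursive_forward(index, feats, params, u, k - 1)
    z = params.W[k - 1] @ np.concatenate([h_self, m])
    return np.maximum(z, 0.0)


class TestForwardEquivalence:
    def test_batched_forward_equals_recursive_oracle(self):
        """With fanouts equal to the full degree, the minibatch tree
        evaluation must reproduce a naive recursive forward pass."""
        index = DTPIndex([f"D{i}" for i in range(3)], [f"T{j}" for j in range(4)])
        deg = index.degree
        cfg = SageConfig(
            fanouts=(deg, deg), hidden_dim=7, epochs=0, seed=3, dtype="float64"
        )
        rng = np.random.default_rng(0)
        F = rng.normal(size=(index.n_pairs, 5))
        model = SageModel(cfg, in_dim=5)
        sampler = FullDTPSampler(index)
        hK, _ = model.forward_nodes(
            np.arange(index.n_pairs), lambda ids: F[ids], sampler,
            np.random.default_rng(1),
        )
        for u in range(index.n_pairs):
            oracle = recursive_forward(index, F, model.params, u, 2)
            assert np.allclose(hK[u], oracle, atol=1e-8)

    def test_mean_path_permutation_invariant(self):
        index = DTPIndex([f"D{i}" for i in range(3)], [f"T{j}" for j in range(4)])
        deg = index.degree
        cfg = SageConfig(fanouts=(deg, deg), hidden_dim=6, epochs=0, seed=0, dtype="float64")
        rng = np.random.default_rng(4)
        F = rng.normal(size=(index.n_pairs, 4))
        model = SageModel(cfg, in_dim=4)
        sampler = FullDTPSampler(index)
        # different sampling rngs permute neighbor order; the full-fanout
        # mean aggregation must not care
        a, _ = model.forward_nodes(np.arange(12), lambda i: F[i], sampler, np.random.default_rng(1))
        b, _ = model.forward_nodes(np.arange(12), lambda i: F[i], sampler, np.random.default_rng(2))
        assert np.allclose(a, b, atol=1e-10)


class TestTraining:
    def _toy_problem(self, seed=0, n_drugs=8, n_targets=10, dim=8):
        rng = np.random.default_rng(seed)
        index = DTPIndex(
            [f"D{i}" for i in range(n_drugs)], [f"T{j}" for j in range(n_targets)]
        )
        F = rng.normal(size=(index.n_pairs, dim))
        labels = (F[:, 0] > 0).astype(float)  # separable by first coordinate
        return index, F, labels

    def test_loss_decreases_on_planted_synthetic(self, tiny_synth):
        """Training loss decreases over the first epochs for most seeds on
        the planted-cluster dataset (cluster one-hot + noise features)."""
        from pairsage.dtp import DTPFeatures, DTPLabels, sample_balanced
        from pairsage.embedding import EmbeddingMatrix

        ds = tiny_synth
        index = DTPIndex(ds.drug_ids, ds.target_ids)
        labels = DTPLabels.from_edges(index, ds.interactions)
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            fd = EmbeddingMatrix(
                list(ds.drug_ids),
                np.eye(2)[ds.drug_clusters] + 0.1 * rng.normal(size=(len(ds.drug_ids), 2)),
            )
            ft = EmbeddingMatrix(
                list(ds.target_ids),
                np.eye(2)[ds.target_clusters] + 0.1 * rng.normal(size=(len(ds.target_ids), 2)),
            )
            feats = DTPFeatures(fd, ft, index)
            sample = sample_balanced(labels, index, seed=seed)
            cfg = SageConfig(fanouts=(8, 4), hidden_dim=16, epochs=5, batch_size=64, seed=seed)
            _, history = sage_train(
                index, feats.matrix_for, sample.node_ids, sample.labels, cfg
            )
            if all(b < a for a, b in zip(history[:-1], history[1:])):
                wins += 1
        assert wins >= 4

    def test_epochs_zero_returns_initialized_model(self):
        index, F, labels = self._toy_problem()
        cfg = SageConfig(fanouts=(4, 2), hidden_dim=8, epochs=0, seed=0)
        model, history = sage_train(
            index, lambda ids: F[ids], np.arange(20), labels[:20], cfg
        )
        assert history == []
        init = SageModel(cfg, in_dim=8)
        assert all((a == b).all() for a, b in zip(model.params.W, init.params.W))
        refined = model.refine(np.arange(5), lambda ids: F[ids], FullDTPSampler(index))
        assert refined.vectors.shape == (5, 8)

    def test_separable_labels_reach_high_training_auroc(self):
        from sklearn.metrics import roc_auc_score

        index, F, labels = self._toy_problem(seed=1)
        cfg = SageConfig(
            fanouts=(8, 4), hidden_dim=16, epochs=40, batch_size=40,
            learning_rate=0.005, seed=1,
        )
        nodes = np.arange(index.n_pairs)
        model, _ = sage_train(index, lambda ids: F[ids], nodes, labels, cfg)
        scores = model.predict_scores(nodes, lambda ids: F[ids], FullDTPSampler(index))
        assert roc_auc_score(labels, scores) >= 0.95

    def test_seeded_training_reproducible(self):
        index, F, labels = self._toy_problem(seed=2)
        cfg = SageConfig(fanouts=(4, 2), hidden_dim=8, epochs=3, batch_size=32, seed=7)
        nodes = np.arange(index.n_pairs)
        m1, h1 = sage_train(index, lambda ids: F[ids], nodes, labels, cfg)
        m2, h2 = sage_train(index, lambda ids: F[ids], nodes, labels, cfg)
        assert h1 == h2
        assert all((a == b).all() for a, b in zip(m1.params.W, m2.params.W))

    @pytest.mark.parametrize("aggregator", ["pooling", "lstm"])
    def test_alternative_aggregators_train(self, aggregator):
        index, F, labels = self._toy_problem(seed=3, n_drugs=5, n_targets=6)
        cfg = SageConfig(
            fanouts=(4, 2), hidden_dim=8, epochs=3, batch_size=30,
            aggregator=aggregator, seed=0,
        )
        nodes = np.arange(index.n_pairs)
        model, history = sage_train(index, lambda ids: F[ids], nodes, labels, cfg)
        assert len(history) == 3
        assert np.isfinite(history).all()
        assert history[-1] < history[0]

    def test_fanout_budget_warning(self):
        with pytest.warns(UserWarning, match="exceeds 500"):
            SageConfig(fanouts=(100, 10))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SageConfig(aggregator="median")
        with pytest.raises(ValueError):
            SageConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            SageConfig(fanouts=(0, 5))
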