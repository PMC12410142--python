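import numpy as np
import pytest
from scipy import sparse

from spotguide import (
    SyntheticConfig,
    TrainConfig,
    ValidationError,
    build_knn_graph,
    contrastive_loss,
    contrastive_loss_corrupt,
    corrupt_features,
    decode,
    discriminator,
    encode,
    finetune,
    gcn_layer,
    generate_synthetic_st,
    pretrain,
    readout,
    reconstruction_loss,
    total_loss,
)
from spotguide.graph import SpotGraph, normalize_adjacency
from spotguide.model import (
    ModelParams,
    _pretrain_arrays,
    _pretrain_forward_backward,
    init_params,
    readout_all,
)


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def make_graph(adjacency: np.ndarray) -> SpotGraph:
    a = sparse.csr_matrix(adjacency.astype(float))
    neighbors = [np.flatnonzero(adjacency[i]) for i in range(adjacency.shape[0])]
    return SpotGraph(a, normalize_adjacency(a), neighbors, k=1)


class TestGcnLayer:
    def test_isolated_node_identity(self):
        s = normalize_adjacency(np.zeros((1, 1)))
        h = np.array([[1.0, -2.0, 3.0]])
        out = gcn_layer(h, s, np.eye(3), np.zeros(3), use_activation=False)
        np.testing.assert_allclose(out, h)

    def test_two_connected_nodes_average(self):
        s = normalize_adjacency(np.array([[0.0, 1], [1, 0]]))
        out = gcn_layer(np.eye(2), s, np.eye(2), np.zeros(2), use_activation=False)
        np.testing.assert_allclose(out, np.full((2, 2), 0.5))

    def test_matches_dense_oracle(self, rng):
        n, d_in, d_out = 8, 5, 4
        a = (rng.random((n, n)) < 0.4).astype(float)
        a = np.triu(a, 1)
        a = a + a.T
        h = rng.normal(size=(n, d_in))
        w = rng.normal(size=(d_in, d_out))
        b = rng.normal(size=d_out)
        s_dense = a + np.eye(n)
        d_half = np.diag(1 / np.sqrt(s_dense.sum(axis=1)))
        expect = np.maximum(d_half @ s_dense @ d_half @ h @ w + b, 0)
        out = gcn_layer(h, normalize_adjacency(a), w, b, use_activation=True)
        np.testing.assert_allclose(out, expect, atol=1e-10)

    def test_dimension_mismatch_raises(self):
        s = normalize_adjacency(np.zeros((1, 1)))
        with pytest.raises(ValidationError):
            gcn_layer(np.ones((1, 3)), s, np.eye(2), np.zeros(2))


class TestEncodeDecode:
    def test_encode_composes_two_layers(self, rng):
        graph = make_graph(np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]]))
        cfg = TrainConfig(hidden_dim=4, embed_dim=2, seed=3)
        params = init_params(5, 2, cfg)
        x = rng.normal(size=(3, 5))
        h = gcn_layer(x, graph.norm_adjacency, *params.encoder[0], use_activation=True)
        expect = gcn_layer(h, graph.norm_adjacency, *params.encoder[1], use_activation=False)
        np.testing.assert_allclose(encode(x, graph, params), expect)

    def test_decode_mirrors_dims(self, rng):
        graph = make_graph(np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]]))
        cfg = TrainConfig(hidden_dim=4, embed_dim=2, seed=3)
        params = init_params(5, 2, cfg)
        z = encode(rng.normal(size=(3, 5)), graph, params)
        assert decode(z, graph, params).shape == (3, 5)

    def test_zero_weights_broadcast_biases(self):
        graph = make_graph(np.array([[0, 1], [1, 0]]))
        cfg = TrainConfig(hidden_dim=3, embed_dim=2, seed=0)
        params = init_params(4, 2, cfg)
        for w, b in params.encoder:
            w[:] = 0
        params.encoder[0][1][:] = -1.0  # ReLU kills it
        params.encoder[1][1][:] = 5.0
        z = encode(np.ones((2, 4)), graph, params)
        np.testing.assert_allclose(z, 5.0)

    def test_permutation_equivariance(self, rng):
        coords = rng.normal(size=(12, 2))
        x = rng.normal(size=(12, 6))
        cfg = TrainConfig(hidden_dim=4, embed_dim=3, seed=1)
        params = init_params(6, 2, cfg)
        perm = rng.permutation(12)
        z = encode(x, build_knn_graph(coords, 3), params)
        z_perm = encode(x[perm], build_knn_graph(coords[perm], 3), params)
        np.testing.assert_allclose(z_perm, z[perm], atol=1e-10)


class TestLosses:
    def test_reconstruction_identity_and_single_entry(self, rng):
        x = rng.normal(size=(4, 3))
        assert reconstruction_loss(x, x) == 0.0
        y = x.copy()
        y[2, 1] += 0.7
        assert np.isclose(reconstruction_loss(x, y), 0.49)

    def test_reconstruction_matches_elementwise_oracle(self, rng):
        x, y = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        expect = sum((x[i, j] - y[i, j]) ** 2 for i in range(4) for j in range(3))
        np.testing.assert_allclose(reconstruction_loss(x, y), expect, atol=1e-12)

    def test_uniform_half_scores_give_ln2(self, rng):
        cfg = TrainConfig(hidden_dim=4, embed_dim=3, seed=0)
        params = init_params(5, 2, cfg)
        params.discriminator[:] = 0.0  # every score is sigmoid(0) = 0.5
        z = rng.normal(size=(6, 3))
        zc = rng.normal(size=(6, 3))
        g = rng.random((6, 3))
        assert np.isclose(contrastive_loss(z, zc, g, params), np.log(2), atol=1e-12)
        assert np.isclose(contrastive_loss_corrupt(z, zc, g, params), np.log(2), atol=1e-12)

    def test_perfect_discrimination_limit(self):
        cfg = TrainConfig(hidden_dim=4, embed_dim=2, seed=0)
        params = init_params(5, 2, cfg)
        params.discriminator[:] = np.eye(2) * 50
        z = np.tile([1.0, 1.0], (3, 1))
        zc = -z
        g = np.tile([1.0, 1.0], (3, 1))
        assert contrastive_loss(z, zc, g, params) < 1e-6

    def test_direct_summation_oracle(self, rng):
        cfg = TrainConfig(hidden_dim=4, embed_dim=3, seed=2)
        params = init_params(5, 2, cfg)
        z, zc = rng.normal(size=(3, 3)), rng.normal(size=(3, 3))
        g = rng.random((3, 3))
        m = params.discriminator
        expect = -sum(
            np.log(sigmoid(z[i] @ m @ g[i])) + np.log(1 - sigmoid(zc[i] @ m @ g[i]))
            for i in range(3)
        ) / 6
        np.testing.assert_allclose(contrastive_loss(z, zc, g, params), expect, atol=1e-12)

    def test_total_loss_arithmetic(self):
        cfg = TrainConfig(lambda1=10, lambda2=1)
        assert total_loss(0.5, 0.2, 0.3, cfg) == pytest.approx(5.5)
        assert total_loss(0.5, 0.2, 0.3, TrainConfig(lambda1=0, lambda2=0)) == 0.0
        assert total_loss(0.5, 0.2, 0.3, TrainConfig(lambda1=1, lambda2=0)) == 0.5


class TestCorruptionAndReadout:
    def test_corruption_preserves_row_multiset(self, rng):
        x = rng.normal(size=(9, 4))
        xc = corrupt_features(x, 5)
        np.testing.assert_allclose(
            np.sort(x, axis=0), np.sort(xc, axis=0)
        )

    def test_corruption_deterministic_and_single_row(self, rng):
        x = rng.normal(size=(7, 3))
        np.testing.assert_array_equal(corrupt_features(x, 1), corrupt_features(x, 1))
        one = rng.normal(size=(1, 3))
        np.testing.assert_array_equal(corrupt_features(one, 0), one)

    def test_readout_closed_cases(self):
        assert np.allclose(readout(np.zeros((3, 4)), [0, 2]), 0.5)
        v = np.array([[0.3, -1.2]])
        np.testing.assert_allclose(readout(v, [0]), sigmoid(v[0]))
        z = np.array([[2.0, -2.0], [0.0, 0.0]])
        np.testing.assert_allclose(readout(z, [0, 1]), sigmoid([1.0, -1.0]), atol=1e-4)

    def test_readout_empty_neighbors_raises(self):
        with pytest.raises(ValidationError):
            readout(np.zeros((2, 2)), [])

    def test_readout_all_matches_per_spot(self, tiny_graph, rng):
        z = rng.normal(size=(tiny_graph.n_spots, 5))
        all_g = readout_all(z, tiny_graph)
        for i in [0, 17, 53]:
            np.testing.assert_allclose(all_g[i], readout(z, tiny_graph.neighbor_lists[i]))


class TestDiscriminator:
    def _params(self, d=2):
        return init_params(4, 2, TrainConfig(hidden_dim=3, embed_dim=d, seed=0))

    def test_zero_embedding_scores_half(self, rng):
        params = self._params(3)
        assert discriminator(np.zeros(3), rng.normal(size=3), params) == pytest.approx(0.5)

    def test_identity_bilinear_hand_value(self):
        params = self._params(2)
        params.discriminator[:] = np.eye(2)
        out = discriminator([1.0, 1.0], [1.0, 1.0], params)
        assert out == pytest.approx(sigmoid(2.0), abs=1e-4)

    def test_monotone_in_bilinear_form(self):
        params = self._params(2)
        params.discriminator[:] = np.eye(2)
        scores = [discriminator([t, 0.0], [1.0, 0.0], params) for t in (-1, 0, 1, 3)]
        assert scores == sorted(scores)


class TestPretrainGradients:
    def test_analytic_gradients_match_finite_differences(self, rng):
        dataset, _ = generate_synthetic_st(
            SyntheticConfig(grid_rows=4, grid_cols=4, n_domains=2, n_genes=7,
                            markers_per_domain=1, seed=2)
        )
        graph = build_knn_graph(dataset.coords, k=2)
        from spotguide import preprocess

        x, _ = preprocess(dataset)
        cfg = TrainConfig(hidden_dim=5, embed_dim=3, seed=1)
        params = init_params(x.shape[1], 2, cfg)
        xc = corrupt_features(x, 7)
        s, p = graph.norm_adjacency, graph.neighbor_mean_operator()
        _, grads = _pretrain_forward_backward(x, xc, s, p, params, cfg)
        arrays = _pretrain_arrays(params)
        eps = 1e-6
        for a, ga in zip(arrays, grads):
            for _ in range(4):
                ix = tuple(rng.integers(0, dim) for dim in a.shape)
                orig = a[ix]
                a[ix] = orig + eps
                lp, _ = _pretrain_forward_backward(x, xc, s, p, params, cfg)
                a[ix] = orig - eps
                lm, _ = _pretrain_forward_backward(x, xc, s, p, params, cfg)
                a[ix] = orig
                numeric = (lp["total"] - lm["total"]) / (2 * eps)
                denom = max(1e-6, abs(numeric) + abs(ga[ix]))
                assert abs(numeric - ga[ix]) / denom < 1e-4


class TestTraining:
    def test_pretrain_zero_epochs_is_noop(self, tiny_X, tiny_graph, small_train_config):
        import dataclasses

        cfg = dataclasses.replace(small_train_config, pretrain_epochs=0)
        init = init_params(tiny_X.shape[1], 3, cfg)
        out, log = pretrain(tiny_X, tiny_graph, cfg, params=init)
        assert log.empty
        for (w0, _), (w1, _) in zip(init.encoder, out.encoder):
            np.testing.assert_array_equal(w0, w1)

    def test_pretrain_decreases_loss_and_is_deterministic(
        self, tiny_X, tiny_graph, small_train_config
    ):
        _, log1 = pretrain(tiny_X, tiny_graph, small_train_config, n_clusters=3)
        _, log2 = pretrain(tiny_X, tiny_graph, small_train_config, n_clusters=3)
        assert log1["total"].iloc[-1] < log1["total"].iloc[0]
        np.testing.assert_allclose(log1["total"], log2["total"], atol=1e-6)

    def test_finetune_stops_at_first_epoch_over_threshold(
        self, tiny_fixture, tiny_X, tiny_graph, small_train_config
    ):
        dataset, _ = tiny_fixture
        classes = sorted(set(dataset.truth_labels))
        idx = list(range(0, dataset.n_spots, 3))
        y = [classes.index(dataset.truth_labels[i]) for i in idx]
        params, _ = pretrain(tiny_X, tiny_graph, small_train_config, n_clusters=3)
        tuned, log = finetune(params, tiny_X, tiny_graph, idx, y, small_train_config)
        over = log["accuracy"] > small_train_config.early_stop_accuracy
        if over.any():
            # trace ends at the first epoch that crossed the bar
            assert over.idxmax() == len(log) - 1
        # re-running from the tuned params stops immediately if already over
        if over.any():
            _, log2 = finetune(tuned, tiny_X, tiny_graph, idx, y, small_train_config)
            assert len(log2) == 1

    def test_finetune_zero_epochs_is_noop(self, tiny_X, tiny_graph, small_train_config):
        import dataclasses

        cfg = dataclasses.replace(small_train_config, finetune_max_epochs=0)
        params = init_params(tiny_X.shape[1], 3, cfg)
        tuned, log = finetune(params, tiny_X, tiny_graph, [0, 1], [0, 1], cfg)
        assert log.empty
        np.testing.assert_array_equal(params.encoder[0][0], tuned.encoder[0][0])

    def test_finetune_rejects_out_of_range_class(self, tiny_X, tiny_graph, small_train_config):
        params = init_params(tiny_X.shape[1], 3, small_train_config)
        with pytest.raises(ValidationError):
            finetune(params, tiny_X, tiny_graph, [0], [7], small_train_config)


class TestCheckpoint:
    def test_params_roundtrip(self, tmp_path, small_train_config):
        params = init_params(20, 3, small_train_config)
        path = str(tmp_path / "ckpt.npz")
        params.save(path)
        back = ModelParams.load(path)
        np.testing.assert_array_equal(params.discriminator, back.discriminator)
        for (w0, b0), (w1, b1) in zip(params.classifier, back.classifier):
            np.testing.assert_array_equal(w0, w1)
            np.testing.assert_array_equal(b0, b1)
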