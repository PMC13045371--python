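import numpy as np
import pytest

from gcnsp.connectome import KnnGraph, NormalizedAdjacency, normalize_adjacency
from gcnsp.model import (
    GCNSPModel,
    Hyperparams,
    _backward_batch,
    _forward_batch,
    forward,
    gcn_layer,
    hierarchical_embedding,
    init_params,
    load_checkpoint,
    loss_total,
    pool_sizes,
    save_checkpoint,
    sparse_pool,
    train_epochs,
)
from gcnsp.synthdata import GeneratorConfig, generate_dataset


def random_a_hat(n, rng, p=0.4):
    a = (rng.random((n, n)) < p).astype(float)
    a = np.maximum(a, a.T)
    np.fill_diagonal(a, 0.0)
    return normalize_adjacency(KnnGraph(adjacency=a, k=1)).a_hat


class TestGcnLayer:
    def test_identity_operator_passes_through(self):
        h = np.arange(12.0).reshape(4, 3)
        out = gcn_layer(np.eye(4), h, np.eye(3), activation="id")
        assert np.array_equal(out, h)

    def test_matches_per_node_aggregation_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n, d, d2 = 5, 3, 4
            ah = random_a_hat(n, rng)
            h = rng.normal(size=(n, d))
            w = rng.normal(size=(d, d2))
            out = gcn_layer(ah, h, w, activation="id")
            # explicit sum_j A_ij H_j W, one node at a time
            expected = np.zeros((n, d2))
            for i in range(n):
                agg = np.zeros(d)
                for j in range(n):
                    agg += ah[i, j] * h[j]
                expected[i] = agg @ w
            assert np.allclose(out, expected, atol=1e-12)

    def test_relu_zeroes_negative_preactivations(self):
        out = gcn_layer(np.eye(2), np.array([[-1.0, 2.0], [3.0, -4.0]]),
                        np.eye(2), activation="relu")
        assert np.array_equal(out, [[0.0, 2.0], [3.0, 0.0]])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gcn_layer(np.eye(3), np.ones((4, 2)), np.ones((2, 2)))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        n, d = 6, 4
        ah = random_a_hat(n, rng)
        h = rng.normal(size=(n, d))
        w = rng.normal(size=(d, 3))
        for _ in range(10):
            p = rng.permutation(n)
            pm = np.eye(n)[p]
            lhs = gcn_layer(pm @ ah @ pm.T, pm @ h, w)
            rhs = pm @ gcn_layer(ah, h, w)
            assert np.allclose(lhs, rhs, atol=1e-10)


class TestSparsePool:
    def test_row_selector(self):
        z = np.arange(10.0).reshape(5, 2)
        theta = np.zeros((2, 5))
        theta[0, 3] = 1.0
        theta[1, 1] = 1.0
        out = sparse_pool(z, theta)
        assert np.array_equal(out, z[[3, 1]])

    def test_zero_theta_gives_zero(self):
        assert np.all(sparse_pool(np.ones((4, 3)), np.zeros((2, 4))) == 0)

    def test_matches_independent_matmul(self):
        rng = np.random.default_rng(2)
        theta = rng.normal(size=(3, 5))
        z = rng.normal(size=(5, 2))
        expected = np.array([[sum(theta[i, k] * z[k, j] for k in range(5))
                              for j in range(2)] for i in range(3)])
        assert np.allclose(sparse_pool(z, theta), expected, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sparse_pool(np.ones((4, 2)), np.ones((3, 5)))


class TestHierarchicalEmbedding:
    def test_single_layer_flatten(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=(4, 3))
        theta = rng.normal(size=(2, 4))
        emb = hierarchical_embedding(z, [theta])
        assert np.allclose(emb.z_g, (theta @ z).ravel())

    def test_pool_size_arithmetic(self):
        assert pool_sizes(4, 0.5, 2) == [2, 1]
        d2 = 3
        rng = np.random.default_rng(4)
        z = rng.normal(size=(4, d2))
        thetas = [rng.normal(size=(2, 4)), rng.normal(size=(1, 2))]
        emb = hierarchical_embedding(z, thetas)
        assert emb.z_g.shape == ((2 + 1) * d2,)

    def test_zero_embeddings_propagate(self):
        thetas = [np.ones((2, 4)), np.ones((1, 2))]
        emb = hierarchical_embedding(np.zeros((4, 3)), thetas)
        assert np.all(emb.z_g == 0)

    def test_chain_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_embedding(np.ones((4, 3)),
                                   [np.ones((2, 4)), np.ones((1, 3))])


class TestForward:
    def test_zero_input_gives_uniform_probs(self):
        hyper = Hyperparams(hidden_size=4, n_pool_layers=2)
        params = init_params(6, hyper, seed=0)
        pred, emb, acts = forward(np.eye(6), np.zeros((6, 6)), params)
        assert np.allclose(pred.probs, [0.5, 0.5], atol=1e-12)
        assert np.allclose(pred.logits, 0.0)

    def test_evaluation_mode_deterministic(self):
        rng = np.random.default_rng(5)
        hyper = Hyperparams(hidden_size=4)
        params = init_params(5, hyper, seed=1)
        ah = random_a_hat(5, rng)
        x = rng.normal(size=(5, 5))
        p1, _, _ = forward(ah, x, params)
        p2, _, _ = forward(ah, x, params)
        assert np.array_equal(p1.probs, p2.probs)

    def test_matches_composed_operations(self):
        rng = np.random.default_rng(6)
        n = 6
        hyper = Hyperparams(hidden_size=3, n_pool_layers=2)
        params = init_params(n, hyper, seed=2)
        ah = random_a_hat(n, rng)
        x = rng.normal(size=(n, n))
        pred, emb, _ = forward(ah, x, params)
        h1 = gcn_layer(ah, x, params.w0, "relu")
        z = gcn_layer(ah, h1, params.w1, "relu")
        ref = hierarchical_embedding(z, params.theta)
        logits = ref.z_g @ params.dense_w
        assert np.allclose(pred.logits, logits, atol=1e-12)
        assert np.allclose(emb.z_g, ref.z_g, atol=1e-12)

    def test_nonfinite_input_rejected(self):
        hyper = Hyperparams(hidden_size=3)
        params = init_params(4, hyper, seed=3)
        x = np.zeros((4, 4))
        x[0, 1] = np.nan
        with pytest.raises(ValueError):
            forward(np.eye(4), x, params)


class TestLoss:
    def test_uniform_probs_give_log_two(self):
        lb = loss_total(np.array([0.5, 0.5]), 1, [], 0.0, 0.0, [])
        assert lb.class_loss == pytest.approx(np.log(2.0), abs=1e-12)
        assert lb.total == lb.class_loss

    def test_default_sparse_penalty(self):
        assert Hyperparams().lambda_sparse == 5e-4

    def test_sparse_term_arithmetic(self):
        thetas = [np.array([[1.0, -2.0], [0.5, 0.0]])]
        lb = loss_total(np.array([0.9, 0.1]), 0, thetas, 0.1, 0.0, [])
        assert lb.sparse_loss == pytest.approx(0.1 * 3.5, abs=1e-12)

    def test_additivity(self):
        rng = np.random.default_rng(7)
        thetas = [rng.normal(size=(2, 3))]
        ws = [rng.normal(size=(3, 3))]
        lb = loss_total(np.array([0.3, 0.7]), 1, thetas, 0.01, 0.001, ws)
        assert lb.total == pytest.approx(
            lb.class_loss + lb.sparse_loss + lb.l2_loss, abs=1e-12)
        assert min(lb.class_loss, lb.sparse_loss, lb.l2_loss) >= 0

    def test_zero_prob_clamped(self):
        lb = loss_total(np.array([1.0, 0.0]), 1, [], 0.0, 0.0, [])
        assert np.isfinite(lb.class_loss)
        assert lb.class_loss == pytest.approx(-np.log(1e-12))


class TestInitParams:
    def test_seeded_reproducibility(self):
        hyper = Hyperparams(hidden_size=8)
        a = init_params(10, hyper, seed=42)
        b = init_params(10, hyper, seed=42)
        for (_, x), (_, y) in zip(a.items(), b.items()):
            assert np.array_equal(x, y)
        c = init_params(10, hyper, seed=43)
        assert not np.array_equal(a.w0, c.w0)

    def test_fan_scaled_spread(self):
        hyper = Hyperparams(hidden_size=50)
        params = init_params(100, hyper, seed=0)
        fan_in, fan_out = params.w0.shape
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        target_std = limit / np.sqrt(3.0)  # uniform(-L, L) std
        assert params.w0.std() == pytest.approx(target_std, rel=0.2)
        assert np.abs(params.w0).max() <= limit


class TestGradients:
    def test_backprop_matches_numerical_gradient(self):
        """The hand-derived gradients agree with central finite differences."""
        rng = np.random.default_rng(8)
        n = 6
        ah = random_a_hat(n, rng)
        hyper = Hyperparams(hidden_size=5, n_pool_layers=2, dropout=0.0)
        params = init_params(n, hyper, seed=1)
        x = rng.normal(size=(3, n, n))
        y = np.array([0, 1, 1])
        lam, l2 = 5e-4, 1e-4

        def total(p):
            cache = _forward_batch(ah, np.matmul(ah, x), p, 0.0, None,
                                   "sparse_pool")
            return loss_total(cache["probs"], y, p.theta, lam, l2,
                              [p.w0, p.w1, p.dense_w]).total

        cache = _forward_batch(ah, np.matmul(ah, x), params, 0.0, None,
                               "sparse_pool")
        grads = _backward_batch(ah, cache, y, params, lam, l2, "sparse_pool")
        flat = [("w0", params.w0, grads["w0"]),
                ("w1", params.w1, grads["w1"]),
                ("dense_w", params.dense_w, grads["dense_w"]),
                ("theta0", params.theta[0], grads["theta"][0]),
                ("theta1", params.theta[1], grads["theta"][1])]
        eps = 1e-6
        for name, arr, g in flat:
            for _ in range(5):
                ix = tuple(rng.integers(0, s) for s in arr.shape)
                old = arr[ix]
                arr[ix] = old + eps
                lp = total(params)
                arr[ix] = old - eps
                lm = total(params)
                arr[ix] = old
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(g[ix], rel=1e-4, abs=1e-8), name


class TestTraining:
    def _toy(self, seed=0):
        cfg = GeneratorConfig(
            n_rois=20, n_networks=2, n_sites=1,
            n_patients_per_site=20, n_controls_per_site=20,
            within_block_r=0.3, between_block_r=0.05,
            planted_edges=("network", 0), effect_delta=0.8,
            site_shift_sd=0.0, site_scale_sd=0.0, subject_noise_sd=0.1,
            seed=seed)
        ds, _ = generate_dataset(cfg)
        from gcnsp.connectome import (build_knn_graph, mean_connectivity,
                                      normalize_adjacency)
        graph = normalize_adjacency(
            build_knn_graph(mean_connectivity(ds, ds.subject_ids), 5))
        return ds, graph

    def test_zero_learning_rate_is_inert(self):
        ds, graph = self._toy()
        hyper = Hyperparams(hidden_size=4, epochs=3, learning_rate=0.0,
                            dropout=0.0, seed=0)
        start = init_params(20, hyper, seed=9)
        params, history = train_epochs(ds, graph, hyper, params=start)
        for (_, a), (_, b) in zip(start.items(), params.items()):
            assert np.array_equal(a, b)
        losses = [h["train_loss"] for h in history]
        assert max(losses) - min(losses) < 1e-12

    def test_single_class_rejected(self):
        ds, graph = self._toy()
        from gcnsp.connectome import MultiSiteDataset
        patients = MultiSiteDataset(
            [s for s in ds.subjects if s.label == "patient"])
        with pytest.raises(ValueError):
            train_epochs(patients, graph, Hyperparams(epochs=1))

    def test_default_batch_sizes(self):
        # pooled multi-site training uses 32; single-site fine-tuning
        # derives 16 from it inside the transfer protocol
        h = Hyperparams()
        assert h.batch_size == 32
        assert h.replace(batch_size=16).batch_size == 16

    def test_separable_toy_reaches_perfect_train_accuracy(self):
        # single-site small-sample conditions: batch size 16
        ds, graph = self._toy(seed=1)
        hyper = Hyperparams(seed=2, batch_size=16)
        params, history = train_epochs(ds, graph, hyper)
        from gcnsp.model import _eval_scores
        scores = _eval_scores(graph.a_hat, ds.stack(), params, "sparse_pool")
        assert (((scores > 0.5).astype(int)) == ds.labels()).all()
        assert len(history) == hyper.epochs

    def test_training_bit_reproducible(self):
        ds, graph = self._toy(seed=2)
        hyper = Hyperparams(hidden_size=8, epochs=5, seed=3)
        _, h1 = train_epochs(ds, graph, hyper)
        _, h2 = train_epochs(ds, graph, hyper)
        assert h1 == h2

    def test_callback_sees_every_epoch(self):
        ds, graph = self._toy()
        seen = []
        hyper = Hyperparams(hidden_size=4, epochs=4, seed=0)
        train_epochs(ds, graph, hyper,
                     epoch_callback=lambda e, p, r: seen.append(e))
        assert seen == [1, 2, 3, 4]


class TestModelResultsFrontEnd:
    def test_fit_predict_summary(self):
        cfg = GeneratorConfig(
            n_rois=16, n_networks=2, n_sites=1,
            n_patients_per_site=10, n_controls_per_site=10,
            effect_delta=0.5, site_shift_sd=0.0, site_scale_sd=0.0,
            subject_noise_sd=0.15, seed=3)
        ds, _ = generate_dataset(cfg)
        from gcnsp.connectome import (build_knn_graph, mean_connectivity,
                                      normalize_adjacency)
        graph = normalize_adjacency(
            build_knn_graph(mean_connectivity(ds, ds.subject_ids), 4))
        model = GCNSPModel(ds, graph, Hyperparams(hidden_size=4, epochs=10,
                                                  seed=0))
        res = model.fit()
        probs = res.predict_proba(ds)
        assert probs.shape == (20,)
        assert np.all((probs >= 0) & (probs <= 1))
        text = res.summary()
        assert "hidden size" in text and "final train accuracy" in text


class TestCheckpoint:
    def test_round_trip_bit_exact(self, tmp_path):
        hyper = Hyperparams(hidden_size=6)
        params = init_params(8, hyper, seed=4)
        rng = np.random.default_rng(10)
        graph = NormalizedAdjacency(a_hat=random_a_hat(8, rng))
        path = tmp_path / "ck.npz"
        save_checkpoint(path, params, hyper, graph, meta={"tag": "test"})
        p2, h2, g2, meta = load_checkpoint(path)
        for (_, a), (_, b) in zip(params.items(), p2.items()):
            assert np.array_equal(a, b)
        assert h2.to_dict() == hyper.to_dict()
        assert np.array_equal(graph.a_hat, g2.a_hat)
        assert meta["tag"] == "test"
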