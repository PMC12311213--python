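"""Two-layer GCN: forward oracle, gradients, training behaviour, estimator API."""

import numpy as np
import pytest

from lymphgraph.gcn import (
    GCNConfig,
    GCNNodeClassifier,
    GCNParams,
    _loss_and_grads,
    forward,
    glorot_init,
    one_hot,
    predict,
    train,
)
from lymphgraph.graph import NodeTable, assemble_graph, normalize_adjacency
from lymphgraph.synthetic import CohortSpec, generate_feature_cohort


def dense_oracle(P, X, params):
    """Term-by-term re-implementation of the two-layer propagation."""
    n = P.shape[0]
    h1 = params.W0.shape[1]
    h2 = params.W1.shape[1]
    H1 = np.zeros((n, h1))
    for i in range(n):
        for a in range(h1):
            s = 0.0
            for j in range(n):
                for b in range(X.shape[1]):
                    s += P[i, j] * X[j, b] * params.W0[b, a]
            H1[i, a] = max(s, 0.0)
    H2 = np.zeros((n, h2))
    for i in range(n):
        for a in range(h2):
            s = 0.0
            for j in range(n):
                for b in range(h1):
                    s += P[i, j] * H1[j, b] * params.W1[b, a]
            H2[i, a] = max(s, 0.0)
    logits = H2 @ params.W_fc
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


@pytest.fixture
def small_graph(rng):
    A = np.zeros((6, 6))
    for i, j in [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (0, 5)]:
        A[i, j] = A[j, i] = 1.0
    P = normalize_adjacency(A)
    X = rng.standard_normal((6, 4))
    return P, X


class TestOneHot:
    def test_binary_encodings(self):
        assert one_hot([1], 2).tolist() == [[0.0, 1.0]]
        assert one_hot([0], 2).tolist() == [[1.0, 0.0]]

    def test_round_trip(self, rng):
        y = rng.integers(0, 2, size=30)
        assert np.array_equal(np.argmax(one_hot(y), axis=1), y)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            one_hot([2], 2)


class TestForward:
    def test_matches_dense_oracle(self, small_graph):
        P, X = small_graph
        params = glorot_init(GCNConfig(hidden1=5, hidden2=3, seed=1), 4)
        Z, _, _, _ = forward(P, X, params)
        assert np.abs(Z - dense_oracle(P, X, params)).max() < 1e-8

    def test_rows_sum_to_one(self, small_graph):
        P, X = small_graph
        params = glorot_init(GCNConfig(seed=0), 4)
        Z, _, _, _ = forward(P, X, params)
        assert np.abs(Z.sum(axis=1) - 1.0).max() < 1e-9

    def test_equal_head_columns_give_uniform_probabilities(self, small_graph):
        P, X = small_graph
        params = glorot_init(GCNConfig(hidden2=3, seed=0), 4)
        params.W_fc[:, 1] = params.W_fc[:, 0]
        Z, _, _, _ = forward(P, X, params)
        assert Z == pytest.approx(np.full((6, 2), 0.5))

    def test_identity_propagation_reduces_to_rowwise_mlp(self, rng):
        # with P = I, each node's output depends on its own features only
        X = rng.standard_normal((5, 3))
        params = glorot_init(GCNConfig(seed=2), 3)
        Z, _, _, _ = forward(np.eye(5), X, params)
        X2 = X.copy()
        X2[0] += 10.0  # perturb one node
        Z2, _, _, _ = forward(np.eye(5), X2, params)
        assert np.allclose(Z[1:], Z2[1:])
        assert not np.allclose(Z[0], Z2[0])

    def test_permutation_equivariance(self, small_graph, rng):
        P, X = small_graph
        params = glorot_init(GCNConfig(seed=3), 4)
        Z, _, _, _ = forward(P, X, params)
        perm = rng.permutation(6)
        Zp, _, _, _ = forward(P[np.ix_(perm, perm)], X[perm], params)
        assert np.allclose(Zp, Z[perm], atol=1e-12)

    def test_shape_mismatch_rejected(self, small_graph):
        P, X = small_graph
        params = glorot_init(GCNConfig(seed=0), 7)
        with pytest.raises(ValueError):
            forward(P, X, params)


class TestGradients:
    def test_analytic_matches_finite_differences(self, rng):
        A = np.zeros((5, 5))
        A[0, 1] = A[1, 0] = A[2, 3] = A[3, 2] = 1.0
        P = normalize_adjacency(A)
        X = rng.standard_normal((5, 3))
        y1h = one_hot(np.array([0, 1, 0, 1, 1]))
        vis = np.ones(5, dtype=bool)
        params = glorot_init(GCNConfig(hidden1=4, hidden2=3, dropout_rate=0.0, seed=2), 3)
        _, _, grads = _loss_and_grads(P, X, params, y1h, vis, 0.0, 0)
        eps = 1e-6
        for name in ("W0", "W1", "W_fc"):
            W = getattr(params, name)
            G = getattr(grads, name)
            for idx in np.ndindex(W.shape):
                orig = W[idx]
                W[idx] = orig + eps
                lp, _, _ = _loss_and_grads(P, X, params, y1h, vis, 0.0, 0)
                W[idx] = orig - eps
                lm, _, _ = _loss_and_grads(P, X, params, y1h, vis, 0.0, 0)
                W[idx] = orig
                fd = (lp - lm) / (2 * eps)
                if abs(fd) > 1e-8:
                    rel = abs(fd - G[idx]) / max(abs(fd), abs(G[idx]))
                    assert rel < 1e-4, f"{name}{idx}: {rel}"


@pytest.fixture(scope="module")
def train_graph():
    spec = CohortSpec(n_patients=150, prevalence=0.4, n_features=10, n_informative=6,
                      n_redundant=0, class_separation=3.0, seed=4)
    c = generate_feature_cohort(spec)
    table = NodeTable(ids=c.ids, X=c.features, y=c.labels)
    return assemble_graph(table, 0.2)


class TestTraining:
    def test_zero_epochs_returns_initial_params(self, train_graph):
        cfg = GCNConfig(max_epochs=0, seed=1)
        params, hist = train(train_graph, config=cfg)
        init = glorot_init(cfg, train_graph.X.shape[1])
        assert np.array_equal(params.W0, init.W0)
        assert hist.train_loss == []

    def test_same_seed_identical_history(self, train_graph):
        cfg = GCNConfig(max_epochs=30, seed=8)
        _, h1 = train(train_graph, config=cfg)
        _, h2 = train(train_graph, config=cfg)
        assert h1.train_loss == h2.train_loss
        assert h1.mask_acc == h2.mask_acc

    def test_loss_decreases_on_separable_cohort(self, train_graph):
        _, hist = train(train_graph, config=GCNConfig(max_epochs=200, seed=0))
        assert hist.train_loss[-1] < hist.train_loss[0]
        assert hist.train_acc[-1] > 0.8

    def test_single_class_rejected(self, train_graph):
        with pytest.raises(ValueError):
            train(train_graph, labels=np.ones(train_graph.n_nodes, dtype=int))

    def test_history_bounded_by_max_epochs(self, train_graph):
        _, hist = train(train_graph, config=GCNConfig(max_epochs=25, seed=0))
        assert len(hist.train_loss) <= 25

    def test_predict_deterministic_probabilities(self, train_graph):
        params, _ = train(train_graph, config=GCNConfig(max_epochs=50, seed=3))
        p1 = predict(train_graph, params)
        p2 = predict(train_graph, params)
        assert np.array_equal(p1, p2)
        assert p1.min() >= 0.0 and p1.max() <= 1.0

    def test_null_signal_auc_near_half(self):
        from lymphgraph.evaluation import roc_auc

        spec = CohortSpec(n_patients=200, prevalence=0.4, n_features=8, n_informative=4,
                          n_redundant=0, class_separation=0.0, seed=6)
        c = generate_feature_cohort(spec)
        g = assemble_graph(NodeTable(ids=c.ids, X=c.features, y=c.labels), 0.3)
        params, _ = train(g, config=GCNConfig(max_epochs=100, seed=0))
        spec_v = CohortSpec(n_patients=400, prevalence=0.4, n_features=8, n_informative=4,
                            n_redundant=0, class_separation=0.0, seed=7, id_prefix="V")
        v = generate_feature_cohort(spec_v)
        gv = assemble_graph(NodeTable(ids=v.ids, X=v.features, y=v.labels), 0.3)
        _, auc = roc_auc(predict(gv, params), v.labels)
        assert auc == pytest.approx(0.5, abs=0.12)

    def test_params_json_round_trip(self, train_graph, tmp_path):
        cfg = GCNConfig(max_epochs=5, seed=0)
        params, _ = train(train_graph, config=cfg)
        p = params.to_json(tmp_path / "ck.json", cfg)
        back = GCNParams.from_json(p)
        assert np.allclose(back.W_fc, params.W_fc)


class TestEstimator:
    def test_sklearn_protocol(self, small_cohort):
        clf = GCNNodeClassifier(threshold=0.3, max_epochs=40, seed=0)
        assert clf.get_params()["threshold"] == 0.3
        clf.fit(small_cohort.features, small_cohort.labels)
        assert hasattr(clf, "classes_")
        proba = clf.predict_proba(small_cohort.features)
        assert proba.shape == (small_cohort.n_patients, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
        pred = clf.predict(small_cohort.features)
        assert set(np.unique(pred)) <= {0, 1}

    def test_clone_compatible(self, small_cohort):
        from sklearn.base import clone

        clf = GCNNodeClassifier(threshold=0.5, max_epochs=10, seed=1)
        clf2 = clone(clf)
        assert clf2.get_params() == clf.get_params()
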