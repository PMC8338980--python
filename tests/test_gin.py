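"""GIN forward/backward contracts: closed forms, permutation invariance,
dense-matrix and finite-difference oracles, checkpoint rule, determinism."""

import copy

import numpy as np
import pytest
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from ginscreen.errors import InvalidSpecError, VocabularyError
from ginscreen.gin import (
    CheckpointRule,
    GinConfig,
    GinModel,
    TrainConfig,
    bce_loss,
    select_checkpoint,
    train_gin,
)
from ginscreen.graphs import EdgeMatrix, NodeVocabulary, SubjectGraphSet

from conftest import one_hot_levels


def _graph_set(feats, edges, vocab, labels=None):
    return SubjectGraphSet(
        features=feats,
        edges=edges,
        vocab=vocab,
        subject_ids=np.arange(feats.shape[0]),
        labels=labels,
    )


def _zero_edges(vocab):
    n = len(vocab.names)
    return EdgeMatrix(names=vocab.names, weights=np.zeros((n, n)), threshold=0.6, method="spearman")


class TestForwardClosedForms:
    def test_isolated_node_identity_mlp_scores_k(self):
        """One node, no edges, eps=0, identity MLPs, sum classifier: the raw
        score is K (each layer reproduces the one-hot input, sum-pooled)."""
        vocab = NodeVocabulary(names=("x",), kinds={"x": "ordinal"})
        K = 3
        model = GinModel(
            GinConfig(n_layers=K, hidden_dim=6, activation="identity", eps_learnable=False),
            vocab,
        ).set_identity_mlps(classifier_weights=np.ones(6 * K))
        feats = one_hot_levels(np.array([[2]]))
        _, score = model.forward(_graph_set(feats, _zero_edges(vocab), vocab))
        assert score.raw[0] == pytest.approx(K)
        assert score.sigmoid[0] == pytest.approx(expit(K))

    def test_permutation_invariance(self, toy_vocab, toy_edges):
        rng = np.random.default_rng(1)
        model = GinModel(GinConfig(n_layers=3, hidden_dim=12), toy_vocab, seed=2)
        feats = one_hot_levels(rng.integers(1, 5, (6, 5)))
        _, s1 = model.forward(_graph_set(feats, toy_edges, toy_vocab))
        perm = rng.permutation(5)
        W = toy_edges.weights[np.ix_(perm, perm)]
        edges_p = EdgeMatrix(names=toy_vocab.names, weights=W, threshold=0.0, method="pearson")
        _, s2 = model.forward(_graph_set(feats[:, perm, :], edges_p, toy_vocab))
        assert np.allclose(s1.sigmoid, s2.sigmoid, atol=1e-6)

    def test_three_node_path_matches_dense_oracle(self):
        """Weighted path 0-(0.8)-1-(-0.7)-2, one layer, identity MLP: node
        features equal the brute-force dense matrix product (I + A) H."""
        vocab = NodeVocabulary(names=("a", "b", "c"), kinds={n: "ordinal" for n in "abc"})
        A = np.array([[0, 0.8, 0], [0.8, 0, -0.7], [0, -0.7, 0]])
        edges = EdgeMatrix(names=vocab.names, weights=A, threshold=0.0, method="pearson")
        model = GinModel(
            GinConfig(n_layers=1, hidden_dim=6, activation="identity", eps_learnable=False),
            vocab,
        ).set_identity_mlps(classifier_weights=np.zeros(6))
        H0 = one_hot_levels(np.array([[1, 3, 4], [2, 2, 1]]))
        expected = np.stack([(np.eye(3) + A) @ H0[i] for i in range(2)])
        got = model.layer_node_features(_graph_set(H0, edges, vocab))[0]
        assert np.allclose(got, expected, atol=1e-12)

    def test_sum_pooling_and_concatenation_invariants(self, toy_vocab, toy_edges):
        rng = np.random.default_rng(3)
        model = GinModel(GinConfig(n_layers=2, hidden_dim=8), toy_vocab, seed=5)
        gset = _graph_set(one_hot_levels(rng.integers(1, 5, (4, 5))), toy_edges, toy_vocab)
        emb, _ = model.forward(gset)
        H = model.layer_node_features(gset)
        for k in range(2):
            assert np.allclose(emb.per_layer[k], H[k].sum(axis=1))
        assert np.allclose(emb.concatenated, np.concatenate(emb.per_layer, axis=1))

    def test_vocabulary_mismatch_rejected(self, toy_vocab, toy_edges):
        other = NodeVocabulary(names=("p", "q"), kinds={"p": "ordinal", "q": "ordinal"})
        model = GinModel(GinConfig(n_layers=1, hidden_dim=4), other)
        feats = one_hot_levels(np.array([[1, 2, 3, 4, 1]]))
        with pytest.raises(VocabularyError):
            model.forward(_graph_set(feats, toy_edges, toy_vocab))


class TestBceLoss:
    def test_coin_flip_scores_give_ln2(self):
        assert bce_loss([0.5, 0.5, 0.5], [1, 0, 1]) == pytest.approx(np.log(2))

    def test_perfect_scores_clip_below_1e6(self):
        assert bce_loss([1.0, 0.0], [1, 0]) <= 1e-6

    def test_two_item_arithmetic(self):
        expected = -(np.log(0.9) + np.log(0.8)) / 2
        assert bce_loss([0.9, 0.2], [1, 0]) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bce_loss([], [])


class TestInputGradient:
    def test_linear_model_gradient_equals_classifier_weights(self, toy_vocab):
        """1 layer, identity MLP, no edges, eps=0: the model is linear, so
        every node's slot-j gradient is w_j; doubling w doubles gradients."""
        rng = np.random.default_rng(0)
        w = rng.normal(0, 1, 6)
        model = GinModel(
            GinConfig(n_layers=1, hidden_dim=6, activation="identity", eps_learnable=False),
            toy_vocab,
        ).set_identity_mlps(classifier_weights=w)
        gset = _graph_set(
            one_hot_levels(rng.integers(1, 5, (3, 5))), _zero_edges(toy_vocab), toy_vocab
        )
        g = model.input_gradient(gset)
        assert np.allclose(g, np.broadcast_to(w, g.shape), atol=1e-12)
        model.params["w_out"] = 2 * w
        assert np.allclose(model.input_gradient(gset), 2 * g, atol=1e-12)

    @pytest.mark.parametrize("batch_norm", [False, True])
    def test_matches_central_finite_differences(self, toy_vocab, toy_edges, batch_norm):
        rng = np.random.default_rng(8)
        model = GinModel(
            GinConfig(n_layers=3, hidden_dim=9, batch_norm=batch_norm), toy_vocab, seed=4
        )
        feats = one_hot_levels(rng.integers(1, 5, (2, 5)))
        gset = _graph_set(feats, toy_edges, toy_vocab)
        grad = model.input_gradient(gset)
        A = model._adjacency(toy_edges)
        h = 1e-4
        for _ in range(12):
            b, n, j = rng.integers(2), rng.integers(5), rng.integers(6)
            fp, fm = feats.copy(), feats.copy()
            fp[b, n, j] += h
            fm[b, n, j] -= h
            yp, _ = model._forward(fp, A, train=False)
            ym, _ = model._forward(fm, A, train=False)
            fd = (yp[b] - ym[b]) / (2 * h)
            assert grad[b, n, j] == pytest.approx(fd, rel=1e-4, abs=1e-7)


def test_readout_decomposition(toy_vocab, toy_edges):
    """Zeroing layer k's classifier block removes exactly that layer's
    contribution to the raw score."""
    rng = np.random.default_rng(2)
    C = 7
    model = GinModel(GinConfig(n_layers=3, hidden_dim=C), toy_vocab, seed=9)
    gset = _graph_set(one_hot_levels(rng.integers(1, 5, (4, 5))), toy_edges, toy_vocab)
    emb, score = model.forward(gset)
    for k in range(3):
        m2 = copy.deepcopy(model)
        w = m2.params["w_out"].copy()
        w[k * C : (k + 1) * C] = 0.0
        m2.params["w_out"] = w
        _, s2 = m2.forward(gset)
        contrib = emb.per_layer[k] @ model.params["w_out"][k * C : (k + 1) * C]
        assert np.allclose(s2.raw, score.raw - contrib, atol=1e-10)


def test_linear_limit_recovers_logistic_regression(toy_vocab):
    """K=1, identity MLP chain, zero adjacency: the GIN is logistic
    regression on the pooled one-hot counts; effective coefficients match a
    directly fitted model (up to the one-hot sum redundancy)."""
    rng = np.random.default_rng(0)
    levels = rng.integers(1, 5, (3000, 5))
    feats = one_hot_levels(levels)
    counts = feats.sum(axis=1)
    beta = np.array([0.8, -0.5, 0.3, 0.0, 0.0, 0.0])
    y = (rng.random(3000) < expit(-0.3 + counts @ beta)).astype(int)
    edges = _zero_edges(toy_vocab)
    tr = _graph_set(feats[:2400], edges, toy_vocab, y[:2400])
    va = _graph_set(feats[2400:], edges, toy_vocab, y[2400:])
    cfg = GinConfig(n_layers=1, hidden_dim=6, activation="identity", eps_learnable=False)
    model, _ = train_gin(
        tr, va, cfg, TrainConfig(lr=0.01, batch_size=256, epochs=200, seed=1),
        CheckpointRule(0.0, 0.0, 0.5),
    )
    eff = model.input_gradient(tr.subset(np.arange(1)))[0, 0]  # same for all nodes
    ref = LogisticRegression(C=1e6, max_iter=5000).fit(counts[:2400], y[:2400]).coef_[0]
    # only slots 0-3 are ever active; counts over them sum to N, so compare centered
    active = slice(0, 4)
    assert np.allclose(
        eff[active] - eff[active].mean(), ref[active] - ref[active].mean(), atol=0.1
    )


class TestCheckpointRule:
    def test_scripted_trace_selects_constrained_minimum(self):
        trace = [(0.5, 0.9, 0.9), (0.4, 0.7, 0.9), (0.45, 0.85, 0.81)]
        idx, met = select_checkpoint(trace, CheckpointRule())
        assert (idx, met) == (2, True)

    def test_fallback_to_min_loss_with_warning(self):
        trace = [(0.5, 0.7, 0.9), (0.4, 0.7, 0.9), (0.45, 0.75, 0.81)]
        with pytest.warns(UserWarning, match="constraint"):
            idx, met = select_checkpoint(trace, CheckpointRule())
        assert (idx, met) == (1, False)

    def test_nan_rates_fail_the_constraint(self):
        trace = [(0.5, float("nan"), 0.9), (0.6, 0.9, 0.9)]
        idx, met = select_checkpoint(trace, CheckpointRule())
        assert (idx, met) == (1, True)


def test_training_is_deterministic(toy_vocab, toy_edges):
    rng = np.random.default_rng(5)
    feats = one_hot_levels(rng.integers(1, 5, (200, 5)))
    y = rng.integers(0, 2, 200)
    tr = _graph_set(feats[:150], toy_edges, toy_vocab, y[:150])
    va = _graph_set(feats[150:], toy_edges, toy_vocab, y[150:])
    cfg = GinConfig(n_layers=2, hidden_dim=8, dropout=0.2)
    tcfg = TrainConfig(epochs=5, batch_size=32, seed=7)
    _, log1 = train_gin(tr, va, cfg, tcfg, CheckpointRule(0.0, 0.0, 0.5))
    _, log2 = train_gin(tr, va, cfg, tcfg, CheckpointRule(0.0, 0.0, 0.5))
    assert [r["loss"] for r in log1.trace] == [r["loss"] for r in log2.trace]


def test_single_class_training_rejected(toy_vocab, toy_edges):
    feats = one_hot_levels(np.ones((20, 5), dtype=int))
    s = _graph_set(feats, toy_edges, toy_vocab, np.zeros(20, dtype=int))
    with pytest.raises(ValueError, match="single class"):
        train_gin(s, s, GinConfig(n_layers=1, hidden_dim=4), TrainConfig(epochs=1))


def test_model_save_load_roundtrip(tmp_path, toy_vocab, toy_edges):
    rng = np.random.default_rng(6)
    model = GinModel(GinConfig(n_layers=2, hidden_dim=8), toy_vocab, seed=3)
    gset = _graph_set(one_hot_levels(rng.integers(1, 5, (5, 5))), toy_edges, toy_vocab)
    model.save(tmp_path / "model")
    back = GinModel.load(tmp_path / "model")
    assert np.allclose(back.predict(gset), model.predict(gset))


def test_invalid_configs_rejected():
    with pytest.raises(InvalidSpecError):
        GinConfig(n_layers=0)
    with pytest.raises(InvalidSpecError):
        GinConfig(dropout=1.0)
    with pytest.raises(InvalidSpecError):
        GinConfig(activation="tanh")
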