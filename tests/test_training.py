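import numpy as np
import pytest

from treetrigger import (
    AblationConfig,
    LabelSet,
    SynthConfig,
    TrainConfig,
    TriggerModel,
    classify,
    evaluate,
    f1_score,
    generate,
    loss,
    synthetic_embeddings,
    train,
)
from treetrigger.autodiff import Tensor
from treetrigger.training import ABLATION_GRID, merge_token_labels

from conftest import chain_tree


class TestClassify:
    def test_zero_weights_uniform(self):
        probs = classify(np.ones(4), np.zeros((3, 4)), np.zeros(3))
        assert np.allclose(np.asarray(probs), 1 / 3)

    def test_sums_to_one(self, rng):
        for _ in range(5):
            p = classify(rng.normal(size=6), rng.normal(size=(4, 6)), rng.normal(size=4))
            assert abs(float(np.asarray(p).sum()) - 1.0) < 1e-6

    def test_argmax_shift_invariant(self, rng):
        x = rng.normal(size=6)
        W = rng.normal(size=(4, 6))
        b = rng.normal(size=4)
        p1 = np.asarray(classify(x, W, b))
        p2 = np.asarray(classify(x, W, b + 10.0))
        assert np.argmax(p1) == np.argmax(p2)
        assert np.allclose(p1, p2, atol=1e-12)


class TestLoss:
    def one_hot(self, idx, m=3, eps=1e-12):
        p = np.full(m, eps)
        p[idx] = 1.0 - eps * (m - 1)
        return Tensor(p)

    def test_perfect_predictions_zero(self):
        preds = [self.one_hot(0), self.one_hot(2)]
        assert loss(preds, [0, 2]).item() == pytest.approx(0.0, abs=1e-9)

    def test_uniform_is_log_m(self):
        m = 5
        preds = [Tensor(np.full(m, 1 / m))] * 3
        assert loss(preds, [0, 1, 4]).item() == pytest.approx(np.log(m), abs=1e-12)

    def test_ridge_term_exact(self):
        theta = [Tensor(np.array([1.0, 2.0]), requires_grad=True)]
        val = loss([self.one_hot(1)], [1], theta, l2=0.003).item()
        assert val == pytest.approx(0.003 / 2 * 5.0, abs=1e-9)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            loss([], [])


class TestF1Score:
    @pytest.mark.parametrize(
        "p, r, expected",
        [
            (83.24, 80.90, 82.05),
            (76.84, 73.35, 75.05),
            (82.02, 80.55, 81.28),
            (61.25, 69.21, 64.99),
            (66.12, 45.12, 53.64),
            (47.88, 47.32, 47.60),
        ],
    )
    def test_published_pairs(self, p, r, expected):
        assert f1_score(p, r) == pytest.approx(expected, abs=1e-9)

    def test_symmetry_and_fixpoint(self, rng):
        for _ in range(20):
            p, r = rng.uniform(1, 100, size=2)
            assert f1_score(p, r) == f1_score(r, p)
            f = f1_score(p, r)
            assert min(p, r) - 0.01 <= f <= max(p, r) + 0.01
        assert f1_score(40.0, 40.0) == 40.0

    def test_both_zero_warns(self):
        with pytest.warns(UserWarning):
            assert f1_score(0, 0) == 0.0

    def test_range_validation(self):
        with pytest.raises(ValueError):
            f1_score(101, 50)


class TestEvaluate:
    def label_set(self):
        return LabelSet(["A", "B"])

    def test_identical_sets_are_perfect(self):
        gold = [("d1", "A", 0, 3), ("d1", "B", 5, 9)]
        m = evaluate(gold, gold, self.label_set())
        assert (m.micro_precision, m.micro_recall, m.micro_f1) == (100.0, 100.0, 100.0)

    def test_no_predictions_warns(self):
        with pytest.warns(UserWarning):
            m = evaluate([], [("d1", "A", 0, 3)], self.label_set())
        assert m.micro_precision == 0.0
        assert m.micro_recall == 0.0

    def test_counting_oracle(self):
        gold = [("d", "A", 0, 1), ("d", "A", 2, 3), ("d", "B", 4, 5), ("d", "B", 6, 7)]
        preds = [("d", "A", 0, 1), ("d", "A", 2, 3), ("d", "B", 8, 9)]
        m = evaluate(preds, gold, self.label_set())
        assert m.micro_precision == pytest.approx(66.67, abs=0.01)
        assert m.micro_recall == pytest.approx(50.00, abs=0.01)
        assert m.micro_f1 == pytest.approx(57.14, abs=0.01)
        assert (m.tp, m.fp, m.fn) == (2, 1, 2)

    def test_unknown_label_rejected(self):
        with pytest.raises(KeyError):
            evaluate([("d", "Z", 0, 1)], [], self.label_set())

    def test_per_class_counts(self):
        gold = [("d", "A", 0, 1), ("d", "B", 2, 3)]
        preds = [("d", "A", 0, 1)]
        m = evaluate(preds, gold, self.label_set())
        assert m.per_class["A"]["f1"] == 100.0
        assert m.per_class["B"]["recall"] == 0.0


class TestMergeTokenLabels:
    def test_adjacent_same_label_merge(self, label_set):
        tree = chain_tree(4)
        spans = merge_token_labels(tree, [0, 1, 1, 2], label_set)
        assert spans == [
            ("Binding", tree.tokens[1].char_start, tree.tokens[2].char_end),
            ("Regulation", tree.tokens[3].char_start, tree.tokens[3].char_end),
        ]

    def test_all_none_is_empty(self, label_set):
        assert merge_token_labels(chain_tree(3), [0, 0, 0], label_set) == []


def tiny_corpus_and_embeddings(seed=0, n=6):
    cfg = SynthConfig(n_sentences=n, seed=seed, embedding_dim=8, min_len=3, max_len=6,
                      sentences_per_doc=3)
    return generate(cfg), synthetic_embeddings(cfg), cfg


class TestTrain:
    def test_zero_learning_rate_keeps_parameters(self):
        corpus, emb, _ = tiny_corpus_and_embeddings()
        cfg = TrainConfig(epochs=2, hidden=4, embedding_dim=8, learning_rate=0.0,
                          batch_size=4, dropout=0.0, seed=1)
        model, _ = train(corpus, cfg, embeddings=emb)
        before = [np.asarray(p).copy() for p in model.parameters()]
        model2, _ = train(corpus, cfg, embeddings=emb, model=model)
        after = [np.asarray(p) for p in model2.parameters()]
        for b, a in zip(before, after):
            assert np.array_equal(b, a)

    def test_same_seed_identical_traces(self):
        corpus, emb, _ = tiny_corpus_and_embeddings()
        cfg = TrainConfig(epochs=3, hidden=4, embedding_dim=8, learning_rate=0.01,
                          batch_size=4, dropout=0.1, seed=5)
        _, t1 = train(corpus, cfg, embeddings=emb)
        _, t2 = train(corpus, cfg, embeddings=emb)
        assert t1 == t2

    def test_loss_decreases_on_planted_corpus(self):
        corpus, emb, _ = tiny_corpus_and_embeddings(n=12)
        cfg = TrainConfig(epochs=6, hidden=6, embedding_dim=8, learning_rate=0.02,
                          batch_size=6, dropout=0.0, l2=1e-4, seed=0, init_scale=0.2)
        _, trace = train(corpus, cfg, embeddings=emb)
        assert trace[-1] < trace[0]

    def test_patience_stops_early(self):
        corpus, emb, _ = tiny_corpus_and_embeddings()
        cfg = TrainConfig(epochs=30, hidden=4, embedding_dim=8, learning_rate=0.0,
                          batch_size=4, dropout=0.0, seed=1, patience=2)
        _, trace = train(corpus, cfg, embeddings=emb)
        assert len(trace) < 30


def finite_difference_check(ablation, rng, rel_tol=1e-4, n_probe=3):
    """Central finite differences against analytic gradients on a 5-token
    sentence for every parameter tensor of the given model variant."""
    from treetrigger import DependencyTree, PASGraph, Token

    tokens = [Token(i + 1, f"w{i}", f"w{i}", "NN") for i in range(5)]
    tree = DependencyTree("s", tokens, {1: 3, 2: 1, 3: 0, 4: 3, 5: 4})
    pas = PASGraph("s", [(3, 1, "arg1"), (3, 5, "arg2")], n_tokens=5)
    X = rng.normal(size=(5, 4))
    labels = [0, 1, 0, 2, 0]
    label_set = LabelSet(["A", "B"])
    model = TriggerModel(4, 3, label_set, ablation, rng=np.random.default_rng(7),
                        init_scale=0.4)
    params = model.parameters()

    def loss_value():
        probs, _, _ = model.forward(tree, pas, X)
        return loss([probs[j] for j in range(1, 6)], labels, params, l2=0.01)

    out = loss_value()
    for p in params:
        p.grad = None
    out.backward()
    grads = [None if p.grad is None else p.grad.copy() for p in params]
    eps = 1e-6
    for p, g in zip(params, grads):
        assert g is not None, "parameter received no gradient"
        flat = p.data.reshape(-1)
        idxs = rng.choice(flat.size, size=min(n_probe, flat.size), replace=False)
        for idx in idxs:
            orig = flat[idx]
            flat[idx] = orig + eps
            up = loss_value().item()
            flat[idx] = orig - eps
            down = loss_value().item()
            flat[idx] = orig
            fd = (up - down) / (2 * eps)
            an = g.reshape(-1)[idx]
            denom = max(abs(fd), abs(an), 1e-8)
            assert abs(fd - an) / denom < rel_tol, (fd, an)


class TestGradients:
    def test_full_model_gradients(self, rng):
        finite_difference_check(AblationConfig(), rng)

    def test_tree_only_gradients(self, rng):
        finite_difference_check(AblationConfig(use_pas=False), rng)

    def test_pas_only_gradients(self, rng):
        finite_difference_check(AblationConfig(use_dep=False), rng)

    def test_no_attention_gradients(self, rng):
        finite_difference_check(AblationConfig(attn_dep=False, attn_pas=False), rng)


class TestConfigs:
    def test_ablation_grid_has_eight_variants(self):
        assert len(ABLATION_GRID) == 8
        assert len({(a.use_dep, a.use_pas, a.attn_dep, a.attn_pas) for a in ABLATION_GRID}) == 8

    def test_degenerate_ablation_rejected(self):
        with pytest.raises(ValueError):
            AblationConfig(use_dep=False, use_pas=False)

    def test_train_config_defaults(self):
        cfg = TrainConfig()
        assert cfg.batch_size == 32
        assert cfg.dropout == 0.2
        assert cfg.learning_rate == 0.001
        assert cfg.epochs == 50
        assert cfg.l2 == 0.003
        assert (cfg.beta1, cfg.beta2) == (0.88, 0.90)
        assert cfg.hidden == 256
        assert cfg.embedding_dim == 720

    def test_train_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(dropout=1.5)

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("epochs: 7\nhidden: 12\nlearning_rate: 0.02\n")
        cfg = TrainConfig.from_file(path)
        assert (cfg.epochs, cfg.hidden, cfg.learning_rate) == (7, 12, 0.02)


class TestSerialization:
    def test_model_round_trip(self, tmp_path, rng, label_set, small_tree, small_pas):
        model = TriggerModel(4, 3, label_set, rng=np.random.default_rng(3))
        X = rng.normal(size=(5, 4))
        before = model.predict_labels(small_tree, small_pas, X)
        p1, _, _ = model.forward(small_tree, small_pas, X)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = TriggerModel.load(path)
        after = loaded.predict_labels(small_tree, small_pas, X)
        p2, _, _ = loaded.forward(small_tree, small_pas, X)
        assert before == after
        for j in p1:
            assert np.allclose(np.asarray(p1[j]), np.asarray(p2[j]), atol=1e-15)
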