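"""Contextual KGE model: embeddings, encoder, masked prediction, training."""

import numpy as np
import pytest

from pathcoke import nn
from pathcoke.kg import KnowledgeGraph, Triple, Vocabulary
from pathcoke.model import (
    CokeModel,
    ModelConfig,
    cross_entropy,
    make_instances,
    score_sequences,
    smooth_labels,
    train_coke,
)
from pathcoke.paths import PathInstance


@pytest.fixture(scope="module")
def tiny_kg(request):
    schema = request.getfixturevalue("schema")
    triples = [
        Triple("disease:00", "disease=>symptom", "symptom:00"),
        Triple("disease:00", "disease=>drug", "drug:00"),
        Triple("symptom:00", "symptom=>drug", "drug:00"),
        Triple("disease:01", "disease=>symptom", "symptom:00"),
    ]
    return KnowledgeGraph(triples, schema)


@pytest.fixture(scope="module")
def tiny_model(tiny_kg):
    vocab = Vocabulary(tiny_kg.entities, tiny_kg.schema.names)
    cfg = ModelConfig(hidden_size=8, layers=2, heads=2, feedforward_size=16,
                      dropout=0.0, dtype="float64", seed=0)
    return CokeModel(vocab, cfg), vocab, cfg


class TestConfig:
    def test_hidden_divisible_by_heads(self):
        with pytest.raises(ValueError):
            ModelConfig(hidden_size=10, heads=4)

    def test_label_smoothing_range(self):
        with pytest.raises(ValueError):
            ModelConfig(label_smoothing=1.0)


class TestSmoothLabels:
    def test_printed_formula_v5(self):
        y = smooth_labels(2, V=5, epsilon=0.8)
        np.testing.assert_allclose(y, [0.05, 0.05, 0.8, 0.05, 0.05])
        assert abs(y.sum() - 1.0) < 1e-12

    def test_near_one_limit_is_one_hot(self):
        y = smooth_labels(0, V=4, epsilon=1 - 1e-12)
        np.testing.assert_allclose(y, [1, 0, 0, 0], atol=1e-11)

    def test_v2(self):
        np.testing.assert_allclose(smooth_labels(0, 2, 0.9), [0.9, 0.1])

    @pytest.mark.parametrize("V,eps", [(2, 0.5), (10, 0.8), (300, 0.99)])
    def test_sums_to_one(self, V, eps):
        assert abs(smooth_labels(1, V, eps).sum() - 1.0) < 1e-12


class TestCrossEntropy:
    def test_one_hot_match_is_zero(self):
        p = np.array([0.0 + 1e-300, 1.0, 1e-300])
        p = np.array([1e-12, 1.0, 1e-12]); p /= p.sum()
        y = np.array([0.0, 1.0, 0.0])
        assert cross_entropy(p, y) < 1e-9

    def test_uniform_p_gives_log_v(self):
        V = 7
        p = np.full(V, 1.0 / V)
        y = smooth_labels(3, V, 0.8)
        np.testing.assert_allclose(cross_entropy(p, y), np.log(V), atol=1e-12)

    def test_matches_high_precision_sum(self):
        rng = np.random.default_rng(0)
        p = rng.random(50); p /= p.sum()
        y = rng.random(50); y /= y.sum()
        expected = -sum(float(yi) * float(np.log(pi)) for yi, pi in zip(y, p))
        assert abs(cross_entropy(p, y) - expected) < 1e-10


class TestMakeInstances:
    def test_edge_and_path_counts_and_lengths(self, tiny_kg):
        vocab = Vocabulary(tiny_kg.entities, tiny_kg.schema.names)
        path = PathInstance("disease:00", ("disease=>symptom", "symptom=>drug"),
                            "drug:00", ("symptom:00",))
        batch = make_instances(tiny_kg.triples[:1], [path], vocab, 8)
        assert len(batch) == 4
        assert sorted(batch.lengths.tolist()) == [3, 3, 4, 4]

    def test_each_instance_has_exactly_one_mask(self, tiny_kg):
        vocab = Vocabulary(tiny_kg.entities, tiny_kg.schema.names)
        batch = make_instances(tiny_kg.triples, None, vocab, 8)
        assert len(batch) == 2 * len(tiny_kg.triples)
        for row, pos in zip(batch.ids, batch.mask_positions):
            assert (row == Vocabulary.MASK_ID).sum() == 1
            assert row[pos] == Vocabulary.MASK_ID
            assert pos in (0, len(row[row != Vocabulary.PAD_ID]) - 1)

    def test_empty_input(self, tiny_kg):
        vocab = Vocabulary(tiny_kg.entities, tiny_kg.schema.names)
        assert len(make_instances([], None, vocab, 8)) == 0

    def test_overlong_path_rejected(self, tiny_kg):
        vocab = Vocabulary(tiny_kg.entities, tiny_kg.schema.names)
        path = PathInstance("disease:00", tuple(["disease=>symptom"] * 9),
                            "drug:00", tuple(["symptom:00"] * 8))
        with pytest.raises(ValueError):
            make_instances([], [path], vocab, 8)


class TestEmbedEncode:
    def test_embed_positions_independent(self, tiny_model):
        model, vocab, cfg = tiny_model
        ids = np.array([[2, 3, 4, 5]])
        h1 = model.embed_inputs(ids).data
        ids2 = np.array([[2, 4, 3, 5]])  # swap middle tokens
        h2 = model.embed_inputs(ids2).data
        assert np.allclose(h1[0, 0], h2[0, 0]) and np.allclose(h1[0, 3], h2[0, 3])
        assert not np.allclose(h1[0, 1], h2[0, 1])

    def test_sequence_longer_than_positional_table_rejected(self, tiny_model):
        model, vocab, cfg = tiny_model
        with pytest.raises(ValueError):
            model.embed_inputs(np.zeros((1, cfg.max_sequence_length + 1),
                                        dtype=np.intp))

    def test_zero_layer_encoder_is_identity(self, tiny_kg):
        vocab = Vocabulary(tiny_kg.entities, tiny_kg.schema.names)
        cfg = ModelConfig(hidden_size=8, layers=0, heads=2, feedforward_size=16,
                          dropout=0.0, dtype="float64")
        model = CokeModel(vocab, cfg)
        ids = np.array([[2, 3, 4]])
        h = model.embed_inputs(ids)
        hL, hiddens, attns = model.encode(h, ids)
        np.testing.assert_array_equal(hL.data, h.data)
        assert hiddens == [] and attns == []

    def test_single_head_hand_computed_attention(self):
        # one layer, one head, hand-set weights on a length-3 sequence
        vocab = Vocabulary(["e0", "e1"], ["r"])
        cfg = ModelConfig(hidden_size=2, layers=1, heads=1, feedforward_size=2,
                          dropout=0.0, dtype="float64", seed=0)
        model = CokeModel(vocab, cfg)
        P = model.params
        for name in ("Wq", "Wk", "Wv", "Wo"):
            P[f"l0.{name}"].data = np.eye(2)
        for name in ("bq", "bk", "bv", "bo"):
            P[f"l0.{name}"].data = np.zeros(2)
        P["l0.W1"].data = np.zeros((2, 2))
        P["l0.b1"].data = np.zeros(2)
        P["l0.W2"].data = np.zeros((2, 2))
        P["l0.b2"].data = np.zeros(2)
        h0 = np.array([[[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]])
        ids = np.array([[2, 4, 3]])
        hL, hiddens, attns = model.encode(nn.Tensor(h0), ids)
        # hand-computed: scores = h h^T / sqrt(2), row-softmax
        scores = h0[0] @ h0[0].T / np.sqrt(2.0)
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        A = e / e.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(attns[0].data[0, 0], A, atol=1e-6)
        ctx = A @ h0[0]          # Wv = Wo = I
        resid = h0[0] + ctx      # FFN is zero; then layer norms
        def ln(x):
            mu = x.mean(-1, keepdims=True)
            v = ((x - mu) ** 2).mean(-1, keepdims=True)
            return (x - mu) / np.sqrt(v + 1e-5)
        np.testing.assert_allclose(hL.data[0], ln(ln(resid)), atol=1e-6)

    def test_attention_rows_sum_to_one(self, tiny_model, tiny_kg):
        model, vocab, cfg = tiny_model
        batch = make_instances(tiny_kg.triples, None, vocab, 8)
        _, aux = model.forward(batch)
        for A in aux["attentions"]:
            np.testing.assert_allclose(A.data.sum(axis=-1),
                                       np.ones(A.shape[:-1]), atol=1e-9)


class TestPredictMasked:
    def test_probabilities_sum_to_one(self, tiny_model, tiny_kg):
        model, vocab, cfg = tiny_model
        batch = make_instances(tiny_kg.triples, None, vocab, 8)
        p = model.predict_masked(batch)
        assert p.shape == (len(batch), vocab.n_entities)
        assert (p >= 0).all()
        np.testing.assert_allclose(p.sum(axis=1), np.ones(len(batch)), atol=1e-6)

    def test_uniform_when_logits_constant(self, tiny_kg):
        vocab = Vocabulary(tiny_kg.entities, tiny_kg.schema.names)
        cfg = ModelConfig(hidden_size=8, layers=1, heads=2, feedforward_size=16,
                          dropout=0.0, dtype="float64")
        model = CokeModel(vocab, cfg)
        model.params["emb"].data[:] = 0.0   # tied output weights all zero
        model.params["out_bias"].data[:] = 0.0
        batch = make_instances(tiny_kg.triples[:1], None, vocab, 8)
        p = model.predict_masked(batch)
        np.testing.assert_allclose(p, 1.0 / vocab.n_entities, atol=1e-12)

    def test_argmax_matches_brute_force_dot_products(self, tiny_model, tiny_kg):
        model, vocab, cfg = tiny_model
        batch = make_instances(tiny_kg.triples, None, vocab, 8)
        logits, aux = model.forward(batch)
        z = aux["z"].data
        emb = model.params["emb"].data
        off = Vocabulary.ENTITY_OFFSET
        E = emb[off:off + vocab.n_entities]
        brute = z @ E.T + model.params["out_bias"].data
        assert (logits.data.argmax(axis=1) == brute.argmax(axis=1)).all()

    def test_weight_tying_mutation_moves_logits(self, tiny_kg):
        vocab = Vocabulary(tiny_kg.entities, tiny_kg.schema.names)
        cfg = ModelConfig(hidden_size=8, layers=1, heads=2, feedforward_size=16,
                          dropout=0.0, dtype="float64", seed=1)
        model = CokeModel(vocab, cfg)
        batch = make_instances(tiny_kg.triples[:1], None, vocab, 8)
        before = model.predict_masked(batch)
        t = 0  # entity index 0; perturb one coordinate of its embedding row
        model.params["emb"].data[Vocabulary.ENTITY_OFFSET + t, 0] += 5.0
        after = model.predict_masked(batch)
        assert not np.allclose(before[:, t], after[:, t])


class TestTraining:
    def test_loss_decreases_and_deterministic(self, tiny_kg):
        cfg = ModelConfig(hidden_size=16, layers=2, heads=2, feedforward_size=32,
                          epochs=50, batch_size=8, seed=4)
        model1, trace1 = train_coke(tiny_kg, cfg)
        model2, trace2 = train_coke(tiny_kg, cfg)
        assert trace1[-1] < trace1[0]
        assert trace1 == trace2
        for k in model1.params:
            np.testing.assert_array_equal(model1.params[k].data,
                                          model2.params[k].data)

    def test_full_loss_gradcheck(self, tiny_model, tiny_kg):
        model, vocab, cfg = tiny_model
        batch = make_instances(tiny_kg.triples, None, vocab, 8)

        def loss_value():
            logits, _ = model.forward(batch)
            return model.smoothed_loss(logits, batch.targets).item()

        logits, _ = model.forward(batch)
        loss = model.smoothed_loss(logits, batch.targets)
        for p in model.parameters():
            p.grad = None
        loss.backward()
        rng = np.random.default_rng(0)
        for name in ("emb", "pos", "l0.Wq", "l1.W2", "head_W", "out_bias"):
            p = model.params[name]
            flat = p.data.reshape(-1)
            gflat = p.grad.reshape(-1)
            for idx in rng.choice(flat.size, size=3, replace=False):
                eps = 1e-6
                orig = flat[idx]
                flat[idx] = orig + eps
                hi = loss_value()
                flat[idx] = orig - eps
                lo = loss_value()
                flat[idx] = orig
                assert abs((hi - lo) / (2 * eps) - gflat[idx]) < 1e-3

    def test_save_load_roundtrip(self, tmp_path, tiny_kg):
        cfg = ModelConfig(hidden_size=8, layers=1, heads=2, feedforward_size=16,
                          epochs=3, seed=0)
        model, _ = train_coke(tiny_kg, cfg)
        model.save(tmp_path / "m")
        back = CokeModel.load(tmp_path / "m")
        batch = make_instances(tiny_kg.triples, None, model.vocab, 8)
        np.testing.assert_array_equal(model.predict_masked(batch),
                                      back.predict_masked(batch))


def test_score_sequences_masks_requested_position(tiny_model, tiny_kg):
    model, vocab, cfg = tiny_model
    p_tail = score_sequences(model, [["disease:00", "disease=>symptom",
                                      "symptom:00"]], [2])
    p_head = score_sequences(model, [["disease:00", "disease=>symptom",
                                      "symptom:00"]], [0])
    assert p_tail.shape == p_head.shape == (1, vocab.n_entities)
    assert not np.allclose(p_tail, p_head)
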