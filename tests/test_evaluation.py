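"""Filtered ranking: rank computation, MRR/Hits@N, link and path queries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathcoke.evaluation import (
    FilterIndex,
    PathQuery,
    RandomScorer,
    evaluate_link_prediction,
    evaluate_path_query,
    filtered_rank,
    hits_at_n,
    make_path_queries,
    mrr,
    path_query_targets,
    random_hits_expectation,
)
from pathcoke.kg import KnowledgeGraph, Triple, Vocabulary
from pathcoke.synthetic import SynthConfig, generate_kg


def sort_oracle_rank(scores, target, known_true):
    """Rank of the target in the descending sort of allowed candidates."""
    allowed = [i for i in range(len(scores))
               if i == target or i not in known_true]
    order = sorted(allowed, key=lambda i: -scores[i])
    return order.index(target) + 1


class TestFilteredRank:
    def test_unique_top_score_rank_one(self):
        rng = np.random.default_rng(0)
        scores = np.array([0.1, 0.9, 0.3])
        assert filtered_rank(scores, 1, set(), rng) == 1

    def test_worked_example_filtering(self):
        # 5 entities, scores (.9,.8,.7,.6,.5), target third, second filtered
        rng = np.random.default_rng(0)
        scores = np.array([0.9, 0.8, 0.7, 0.6, 0.5])
        assert filtered_rank(scores, 2, {1}, rng) == 2

    def test_matches_sort_oracle_on_random_continuous_scores(self):
        rng = np.random.default_rng(1)
        tie_rng = np.random.default_rng(2)
        for _ in range(300):
            n = int(rng.integers(2, 200))
            scores = rng.normal(size=n)
            target = int(rng.integers(n))
            k = int(rng.integers(0, n // 2 + 1))
            known = set(int(x) for x in rng.choice(n, size=k, replace=False)) \
                - {target}
            assert filtered_rank(scores, target, known, tie_rng) == \
                sort_oracle_rank(scores, target, known)

    def test_all_tied_mean_rank(self):
        # 10 tied candidates: expected rank 5.5 under random tie-breaking
        rng = np.random.default_rng(3)
        scores = np.ones(10)
        ranks = [filtered_rank(scores, 4, set(), rng) for _ in range(10_000)]
        assert abs(np.mean(ranks) - 5.5) < 0.1

    def test_filtering_never_increases_rank(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            n = int(rng.integers(3, 50))
            scores = rng.normal(size=n)
            target = int(rng.integers(n))
            known = set(int(x) for x in
                        rng.choice(n, size=n // 3, replace=False)) - {target}
            raw = filtered_rank(scores, target, set(), np.random.default_rng(0))
            filt = filtered_rank(scores, target, known, np.random.default_rng(0))
            assert filt <= raw

    def test_target_out_of_range(self):
        with pytest.raises(IndexError):
            filtered_rank(np.zeros(3), 5, set(), np.random.default_rng(0))


class TestAggregates:
    def test_mrr_direct_formula(self):
        assert abs(mrr([1, 2, 4]) - (1 + 0.5 + 0.25) / 3) < 1e-12

    def test_mrr_all_ones(self):
        assert mrr([1] * 10 ) == 1.0

    def test_mrr_empty_rejected(self):
        with pytest.raises(ValueError):
            mrr([])

    def test_hits_worked_example(self):
        assert hits_at_n([1, 2, 4, 5], 3) == 0.5

    def test_hits_large_n_is_one(self):
        assert hits_at_n([3, 9, 100], 10**9) == 1.0

    @given(st.lists(st.integers(min_value=1, max_value=500), min_size=1,
                    max_size=200), st.integers(min_value=1, max_value=50))
    @settings(max_examples=50, deadline=None)
    def test_match_counting_oracles(self, ranks, N):
        assert abs(mrr(ranks) - sum(1 / r for r in ranks) / len(ranks)) < 1e-12
        assert abs(hits_at_n(ranks, N)
                   - sum(r <= N for r in ranks) / len(ranks)) < 1e-12
        # Hits@N non-decreasing in N
        assert hits_at_n(ranks, N) <= hits_at_n(ranks, N + 1)

    def test_invariant_to_query_order(self):
        rng = np.random.default_rng(5)
        ranks = list(rng.integers(1, 100, size=50))
        perm = list(rng.permutation(ranks))
        assert abs(mrr(ranks) - mrr(perm)) < 1e-12
        assert hits_at_n(ranks, 10) == hits_at_n(perm, 10)


class TestFilterIndex:
    def test_both_directions_indexed(self, schema):
        kg = KnowledgeGraph([Triple("disease:00", "disease=>drug", "drug:00")],
                            schema)
        idx = FilterIndex.from_splits(kg)
        assert idx.tails[("disease:00", "disease=>drug")] == {"drug:00"}
        assert idx.heads[("disease=>drug", "drug:00")] == {"disease:00"}


class PerfectScorer:
    """Oracle scorer: 1 on the true triple's answer, 0 elsewhere."""

    def __init__(self, vocab, truth_tail, truth_head):
        self.vocab = vocab
        self._tail = truth_tail
        self._head = truth_head

    def score_all_tails(self, head, relation):
        s = np.zeros(self.vocab.n_entities)
        s[self._tail[(head, relation)]] = 1.0
        return s

    def score_all_heads(self, relation, tail):
        s = np.zeros(self.vocab.n_entities)
        s[self._head[(relation, tail)]] = 1.0
        return s


class TestEvaluateLinkPrediction:
    def test_perfect_scorer_mrr_one(self, schema):
        triples = [Triple(f"disease:{i:02d}", "disease=>drug", f"drug:{i:02d}")
                   for i in range(5)]
        kg = KnowledgeGraph(triples, schema)
        vocab = Vocabulary(kg.entities, schema.names)
        rel = vocab.relation_tokens.index("disease=>drug")
        tails = {(vocab.entity_index(t.head), rel): vocab.entity_index(t.tail)
                 for t in triples}
        heads = {(rel, vocab.entity_index(t.tail)): vocab.entity_index(t.head)
                 for t in triples}
        scorer = PerfectScorer(vocab, tails, heads)
        res = evaluate_link_prediction(scorer, triples,
                                       FilterIndex.from_splits(kg), seed=0)
        assert res.mrr == 1.0
        assert res.hits(1) == 1.0

    def test_random_scorer_matches_closed_form_expectation(self, schema):
        triples = [Triple(f"disease:{i:02d}", "disease=>drug", f"drug:{i:02d}")
                   for i in range(10)]
        kg = KnowledgeGraph(triples, schema)
        vocab = Vocabulary(kg.entities, schema.names)
        V = vocab.n_entities
        expected = np.mean([1.0 / r for r in range(1, V + 1)])
        mrrs = [evaluate_link_prediction(RandomScorer(vocab, seed=s), triples,
                                         FilterIndex.from_splits(kg),
                                         seed=s).mrr
                for s in range(50)]
        sem = np.std(mrrs) / np.sqrt(len(mrrs))
        assert abs(np.mean(mrrs) - expected) < 3 * sem + 1e-9


class TestPathQueries:
    def test_targets_by_exhaustive_traversal(self, metformin_kg):
        targets = path_query_targets(metformin_kg, "metformin",
                                     ["mechanism", "treat"])
        assert targets == {"diabetes mellitus"}

    def test_correct_entity_present_in_ranking(self, metformin_kg):
        # untrained model: the true answer must simply appear as a candidate
        from pathcoke.model import CokeModel, ModelConfig
        vocab = Vocabulary(metformin_kg.entities, metformin_kg.schema.names)
        model = CokeModel(vocab, ModelConfig(hidden_size=8, layers=1, heads=2,
                                             feedforward_size=16, dropout=0.0))
        q = PathQuery("metformin", ("mechanism", "treat"), "diabetes mellitus")
        res = evaluate_path_query(model, [q], metformin_kg, seed=0)
        assert len(res.ranks) == 1
        assert 1 <= res.ranks[0].rank <= vocab.n_entities

    def test_empty_query_set_rejected(self, metformin_kg):
        from pathcoke.model import CokeModel, ModelConfig
        vocab = Vocabulary(metformin_kg.entities, metformin_kg.schema.names)
        model = CokeModel(vocab, ModelConfig(hidden_size=8, layers=1, heads=2,
                                             feedforward_size=16))
        with pytest.raises(ValueError):
            evaluate_path_query(model, [], metformin_kg)

    def test_ledger_queries_align_with_heldout(self):
        cfg = SynthConfig(n_per_type=15, seed=3)
        kg, ledger = generate_kg(cfg)
        queries = make_path_queries(ledger, kg)
        assert len(queries) == len(ledger.heldout)
        for q, (rule_idx, t) in zip(queries, ledger.heldout):
            rule = ledger.rules[rule_idx]
            assert q.source == t.head and q.target == t.tail
            assert q.relations == (rule.first, rule.second)

    def test_random_hits_expectation_formula(self):
        from pathcoke.evaluation import QueryRank, RankingResult
        res = RankingResult([QueryRank("q", "t", 1, 20),
                             QueryRank("q", "t", 2, 5)])
        mean, sigma = random_hits_expectation(res, N=10)
        ps = np.array([0.5, 1.0])
        assert abs(mean - ps.mean()) < 1e-12
        assert abs(sigma - np.sqrt((ps * (1 - ps)).sum()) / 2) < 1e-12
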