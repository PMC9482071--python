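"""Filtered link-prediction and path-query evaluation.

For every test triple (e_i, r, e_j) two queries are scored — (?, r, e_j)
and (e_i, r, ?) — over the full entity candidate set.  Under the *filtered*
protocol every other entity known to complete a true triple (over train,
valid and test) is removed from the candidate list before the target's rank
is computed, so a model is never penalised for ranking a different correct
answer above the queried one.  Ties are broken by a random permutation
among tied scores under the run's seed (optimistic tie-breaking is known to
inflate results).

Aggregates are the mean reciprocal rank over all 2*|test| queries and
Hits@N, the fraction of queries whose target ranks within the top N.

Path queries (source, r_1...r_k, target) are answered by masking the
terminal entity of the path sequence; the filter set is every entity
reachable from the source via the relation path over the full graph.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path as _Path
from typing import Iterable, Sequence

import numpy as np

from .kg import KnowledgeGraph, Triple, Vocabulary
from .model import CokeModel, score_sequences

__all__ = [
    "FilterIndex",
    "QueryRank",
    "RankingResult",
    "RandomScorer",
    "filtered_rank",
    "mrr",
    "hits_at_n",
    "evaluate_link_prediction",
    "PathQuery",
    "path_query_targets",
    "make_path_queries",
    "evaluate_path_query",
    "random_hits_expectation",
]


class FilterIndex:
    """Known-true tails per (head, relation) and heads per (relation, tail)."""

    def __init__(self, triples: Iterable[Triple] = ()):
        self.tails: dict[tuple[str, str], set[str]] = {}
        self.heads: dict[tuple[str, str], set[str]] = {}
        self.add(triples)

    def add(self, triples: Iterable[Triple]) -> None:
        for t in triples:
            self.tails.setdefault((t.head, t.relation), set()).add(t.tail)
            self.heads.setdefault((t.relation, t.tail), set()).add(t.head)

    @classmethod
    def from_splits(cls, *splits: KnowledgeGraph | Iterable[Triple]) -> "FilterIndex":
        index = cls()
        for split in splits:
            index.add(split.triples if isinstance(split, KnowledgeGraph) else split)
        return index


def filtered_rank(scores: np.ndarray, target: int, known_true: Iterable[int],
                  rng: np.random.Generator) -> int:
    """Rank of `target` among candidates not in `known_true` (1-based).

    rank = 1 + #{better-scoring allowed candidates} + a uniform draw over
    the positions within the target's tie group.
    """
    scores = np.asarray(scores)
    if not 0 <= target < scores.shape[0]:
        raise IndexError(f"target {target} out of range for {scores.shape[0]}")
    allowed = np.ones(scores.shape[0], dtype=bool)
    kt = list(known_true)
    if kt:
        allowed[np.asarray(kt, dtype=np.intp)] = False
    allowed[target] = False  # re-admitted as the single positive below
    s_t = scores[target]
    better = int(np.count_nonzero(allowed & (scores > s_t)))
    ties = int(np.count_nonzero(allowed & (scores == s_t)))
    offset = int(rng.integers(ties + 1)) if ties else 0
    return 1 + better + offset


def mrr(ranks: Sequence[int]) -> float:
    if len(ranks) == 0:
        raise ValueError("empty rank list")
    return float(np.mean(1.0 / np.asarray(ranks, dtype=np.float64)))


def hits_at_n(ranks: Sequence[int], N: int) -> float:
    if N < 1:
        raise ValueError("N must be >= 1")
    r = np.asarray(ranks)
    return float(np.mean(r <= N)) if r.size else 0.0


@dataclass(frozen=True)
class QueryRank:
    query: str
    target: str
    rank: int
    n_candidates: int     # candidate-set size after filtering (incl. target)


@dataclass
class RankingResult:
    ranks: list[QueryRank] = field(default_factory=list)

    @property
    def rank_values(self) -> list[int]:
        return [q.rank for q in self.ranks]

    @property
    def mrr(self) -> float:
        return mrr(self.rank_values)

    def hits(self, N: int) -> float:
        return hits_at_n(self.rank_values, N)

    def summary(self) -> dict[str, float]:
        return {"mrr": self.mrr, "hits1": self.hits(1),
                "hits3": self.hits(3), "hits10": self.hits(10),
                "n_queries": len(self.ranks)}

    def save(self, path: str | _Path) -> None:
        payload = {
            "summary": self.summary(),
            "queries": [vars(q) for q in self.ranks],
        }
        _Path(path).write_text(json.dumps(payload, ensure_ascii=False, indent=1)
                               + "\n", encoding="utf-8")


class RandomScorer:
    """Uniform-random scorer: the chance floor for ranking metrics."""

    def __init__(self, vocab: Vocabulary, seed: int = 0):
        self.vocab = vocab
        self._rng = np.random.default_rng(seed)

    def score_all_tails(self, head: int, relation: int) -> np.ndarray:
        return self._rng.random(self.vocab.n_entities)

    def score_all_heads(self, relation: int, tail: int) -> np.ndarray:
        return self._rng.random(self.vocab.n_entities)


def _candidate_scores(model, triple: Triple, direction: str) -> np.ndarray:
    """Scores over all entities for the head- or tail-query of a triple."""
    vocab = model.vocab
    if isinstance(model, CokeModel):
        if direction == "tail":
            seq, pos = [triple.head, triple.relation, triple.tail], 2
        else:
            seq, pos = [triple.head, triple.relation, triple.tail], 0
        return score_sequences(model, [seq], [pos])[0]
    rel = vocab.relation_tokens.index(triple.relation)
    if direction == "tail":
        return model.score_all_tails(vocab.entity_index(triple.head), rel)
    return model.score_all_heads(rel, vocab.entity_index(triple.tail))


def evaluate_link_prediction(model, test_triples: Sequence[Triple] | KnowledgeGraph,
                             filter_index: FilterIndex,
                             seed: int = 0) -> RankingResult:
    """Filtered head- and tail-ranking of every test triple (2 queries each)."""
    triples = (test_triples.triples if isinstance(test_triples, KnowledgeGraph)
               else list(test_triples))
    vocab = model.vocab
    rng = np.random.default_rng(seed)
    result = RankingResult()

    coke = isinstance(model, CokeModel)
    if coke:  # batch all queries through the transformer at once
        seqs = []
        positions = []
        for t in triples:
            seqs.append([t.head, t.relation, t.tail])
            positions.append(2)
            seqs.append([t.head, t.relation, t.tail])
            positions.append(0)
        all_scores = score_sequences(model, seqs, positions) if triples else None

    for i, t in enumerate(triples):
        for j, direction in enumerate(("tail", "head")):
            if coke:
                scores = all_scores[2 * i + j]
            else:
                scores = _candidate_scores(model, t, direction)
            if direction == "tail":
                known_tokens = filter_index.tails.get((t.head, t.relation), set())
                target_tok = t.tail
            else:
                known_tokens = filter_index.heads.get((t.relation, t.tail), set())
                target_tok = t.head
            target = vocab.entity_index(target_tok)
            known = {vocab.entity_index(e) for e in known_tokens
                     if e != target_tok}
            rank = filtered_rank(scores, target, known, rng)
            result.ranks.append(QueryRank(
                query=f"({t.head}, {t.relation}, ?)" if direction == "tail"
                      else f"(?, {t.relation}, {t.tail})",
                target=target_tok,
                rank=rank,
                n_candidates=vocab.n_entities - len(known),
            ))
    return result


# -- path queries -----------------------------------------------------------


@dataclass(frozen=True)
class PathQuery:
    source: str
    relations: tuple[str, ...]
    target: str


def path_query_targets(kg: KnowledgeGraph, source: str,
                       relations: Sequence[str]) -> set[str]:
    """All entities reachable from source via the relation path (exhaustive)."""
    frontier = {source}
    for rel in relations:
        nxt: set[str] = set()
        adj = kg.out.get(rel, {})
        for node in frontier:
            nxt.update(adj.get(node, ()))
        frontier = nxt
    return frontier


def make_path_queries(ledger, kg_full: KnowledgeGraph) -> list[PathQuery]:
    """2-hop queries for every held-out implied edge, from the generator ledger."""
    queries = []
    for rule_idx, t in ledger.heldout:
        rule = ledger.rules[rule_idx]
        queries.append(PathQuery(t.head, (rule.first, rule.second), t.tail))
    return queries


def evaluate_path_query(model: CokeModel, queries: Sequence[PathQuery],
                        kg_full: KnowledgeGraph, seed: int = 0) -> RankingResult:
    """Rank each query's target among all entities, filtering other true targets."""
    if not queries:
        raise ValueError("empty query set")
    vocab = model.vocab
    rng = np.random.default_rng(seed)
    seqs = [[q.source, *q.relations, q.target] for q in queries]
    positions = [len(s) - 1 for s in seqs]
    all_scores = score_sequences(model, seqs, positions)
    result = RankingResult()
    for q, scores in zip(queries, all_scores):
        truth = path_query_targets(kg_full, q.source, q.relations)
        target = vocab.entity_index(q.target)
        known = {vocab.entity_index(e) for e in truth if e != q.target}
        rank = filtered_rank(scores, target, known, rng)
        result.ranks.append(QueryRank(
            query=f"({q.source}, {'/'.join(q.relations)}, ?)",
            target=q.target, rank=rank,
            n_candidates=vocab.n_entities - len(known)))
    return result


def random_hits_expectation(result: RankingResult, N: int = 10
                            ) -> tuple[float, float]:
    """(mean, sigma) of Hits@N under uniform-random ranking of each query."""
    ps = np.array([min(N, q.n_candidates) / q.n_candidates for q in result.ranks])
    mean = float(ps.mean())
    sigma = float(np.sqrt((ps * (1 - ps)).sum()) / len(ps))
    return mean, sigma
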