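"""Causal-constraint multihop path mining.

A 2-hop path a -r1-> b -r2-> c is only evidence of a causal chain when the
relation pair (r1, r2) is causally interpretable — e.g. drug=>mechanism
followed by mechanism=>disease ("metformin acts on insulin resistance,
insulin resistance underlies diabetes mellitus").  Pure co-occurrence
fan-outs (two symptoms of the same disease sharing a head) never chain and
are rejected by construction, because chaining is directional: the tail of
step i must equal the head of step i+1.

The miner therefore has two stages: :func:`enumerate_chains` yields every
directionally chainable, cycle-free path up to ``max_hops``, and
:func:`filter_causal` keeps only paths whose relation sequence matches a
whitelist of composition rules, labelling each kept path with a composed
pseudo-relation (default join "-", e.g. "mechanism-treat").  Kept paths can
then be re-expressed as triples (source, composed_label, target) for
training and path-query evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

from .kg import KnowledgeGraph, Triple

__all__ = [
    "CompositionRule",
    "PathInstance",
    "enumerate_chains",
    "filter_causal",
    "paths_to_triples",
]


@dataclass(frozen=True)
class CompositionRule:
    first: str
    second: str
    label: str | None = None

    @property
    def composed_label(self) -> str:
        return self.label if self.label else f"{self.first}-{self.second}"


@dataclass(frozen=True)
class PathInstance:
    source: str
    relations: tuple[str, ...]
    target: str
    intermediates: tuple[str, ...]
    label: str | None = None

    def __post_init__(self):
        if len(self.relations) < 2:
            raise ValueError("a path needs at least 2 hops")
        if len(self.intermediates) != len(self.relations) - 1:
            raise ValueError("intermediates must number k-1 for a k-hop path")

    @property
    def hops(self) -> int:
        return len(self.relations)


def enumerate_chains(kg: KnowledgeGraph, max_hops: int = 2) -> Iterator[PathInstance]:
    """Yield every directionally chainable path of 2..max_hops hops.

    The tail of each step is the head of the next; no path revisits an
    entity (cycle exclusion — causal chains do not loop back).  Output order
    is deterministic: sources in sorted token order, steps in sorted
    (relation, tail) order at each depth.
    """
    if max_hops < 2:
        raise ValueError("max_hops must be >= 2")
    # flattened sorted adjacency: head -> [(relation, tail), ...]
    adj: dict[str, list[tuple[str, str]]] = {}
    for rel in kg.schema.names:
        for head, tails in kg.out[rel].items():
            adj.setdefault(head, []).extend((rel, t) for t in tails)
    for head in adj:
        adj[head].sort()

    def dfs(source: str, node: str, rels: tuple[str, ...],
            mids: tuple[str, ...], seen: set[str]) -> Iterator[PathInstance]:
        for rel, nxt in adj.get(node, ()):
            if nxt in seen:
                continue
            if rels:  # a second (or later) hop completes a reportable path
                yield PathInstance(source, rels + (rel,), nxt, mids + (node,))
            if len(rels) + 1 < max_hops:
                seen.add(nxt)
                yield from dfs(source, nxt, rels + (rel,),
                               mids + ((node,) if rels else ()), seen)
                seen.remove(nxt)

    for source in sorted(adj):
        yield from dfs(source, source, (), (), {source})


def filter_causal(paths: Iterable[PathInstance],
                  rules: Sequence[CompositionRule]) -> list[PathInstance]:
    """Keep paths whose relation sequence matches the rule whitelist.

    2-hop paths match a rule's (first, second) pair directly; longer paths
    must reduce through a left-to-right rule cascade in which the composed
    label of the first two steps matches a further rule's ``first`` slot.
    Output is deduplicated on (source, composed_label, target).
    """
    by_pair = {(r.first, r.second): r.composed_label for r in rules}

    def cascade(relseq: tuple[str, ...]) -> str | None:
        label = relseq[0]
        for nxt in relseq[1:]:
            label = by_pair.get((label, nxt))
            if label is None:
                return None
        return label

    kept: list[PathInstance] = []
    seen: set[tuple[str, str, str]] = set()
    for p in paths:
        label = cascade(p.relations)
        if label is None:
            continue
        key = (p.source, label, p.target)
        if key in seen:
            continue
        seen.add(key)
        kept.append(PathInstance(p.source, p.relations, p.target,
                                 p.intermediates, label))
    return kept


def paths_to_triples(paths: Sequence[PathInstance],
                     base_relations: Iterable[str] = ()) -> list[Triple]:
    """Re-express labelled paths as (source, composed_label, target) triples.

    Composed labels form a derived relation vocabulary and must never
    collide with base relation names.
    """
    base = set(base_relations)
    out: list[Triple] = []
    seen: set[tuple[str, str, str]] = set()
    for p in paths:
        label = p.label if p.label else "-".join(p.relations)
        if label in base:
            raise ValueError(
                f"composed label {label!r} collides with a base relation")
        key = (p.source, label, p.target)
        if key in seen:
            continue
        seen.add(key)
        out.append(Triple(*key))
    return out
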