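"""Data model for clinical knowledge graphs.

A knowledge graph is G = (E, R, S): entities E, typed relations R, and
(head, relation, tail) triples S.  Triples travel as 3-column tab-separated
files with no header (the de-facto standard for KG-embedding datasets), and
every relation carries endpoint entity categories (disease, symptom, drug,
mechanism, department, body_part) through a :class:`RelationSchema`.

The default schema contains the 17 relation types of a clinical
disease-symptom-drug-mechanism graph, e.g. ``disease=>symptom`` or
``mechanism=>department``.  One relation name, ``mechanism =>disease``,
contains an embedded space; that spelling is intentional and preserved.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

ENTITY_TYPES = ("disease", "symptom", "drug", "mechanism", "department", "body_part")

#: Relation name -> (head entity category, tail entity category).
DEFAULT_RELATION_TYPES: dict[str, tuple[str, str]] = {
    "symptom=>symptom": ("symptom", "symptom"),
    "disease=>symptom": ("disease", "symptom"),
    "disease=>drug": ("disease", "drug"),
    "mechanism=>mechanism": ("mechanism", "mechanism"),
    "symptom=>drug": ("symptom", "drug"),
    "symptom=>mechanism": ("symptom", "mechanism"),
    "symptom=>disease": ("symptom", "disease"),
    "mechanism=>department": ("mechanism", "department"),
    "symptom=>body parts": ("symptom", "body_part"),
    "mechanism=>body parts": ("mechanism", "body_part"),
    "mechanism=>symptom": ("mechanism", "symptom"),
    "symptom=>department": ("symptom", "department"),
    "disease=>mechanism": ("disease", "mechanism"),
    "disease=>body parts": ("disease", "body_part"),
    "disease=>department": ("disease", "department"),
    "disease=>disease": ("disease", "disease"),
    "mechanism =>disease": ("mechanism", "disease"),
}


class RelationSchema:
    """Ordered relation vocabulary with endpoint entity categories."""

    def __init__(self, relations: Sequence[tuple[str, str, str]]):
        names = [r[0] for r in relations]
        if len(set(names)) != len(names):
            raise ValueError("relation names must be unique")
        for name, head_type, tail_type in relations:
            if not name:
                raise ValueError("relation name must be non-empty")
            if not head_type or not tail_type:
                raise ValueError(f"relation {name!r} is missing an endpoint type")
        self._relations = [tuple(r) for r in relations]
        self._types = {name: (h, t) for name, h, t in self._relations}

    @classmethod
    def default(cls) -> "RelationSchema":
        return cls([(n, h, t) for n, (h, t) in DEFAULT_RELATION_TYPES.items()])

    @property
    def names(self) -> list[str]:
        return [r[0] for r in self._relations]

    def head_type(self, name: str) -> str:
        return self._types[name][0]

    def tail_type(self, name: str) -> str:
        return self._types[name][1]

    def __contains__(self, name: str) -> bool:
        return name in self._types

    def __len__(self) -> int:
        return len(self._relations)

    def __eq__(self, other) -> bool:
        return isinstance(other, RelationSchema) and self._relations == other._relations

    def extended(self, extra: Sequence[tuple[str, str, str]]) -> "RelationSchema":
        """New schema with additional relations appended."""
        return RelationSchema(self._relations + [tuple(r) for r in extra])

    # -- I/O (YAML or JSON list of {name, head_type, tail_type}) ------------

    @classmethod
    def load(cls, path: str | Path) -> "RelationSchema":
        text = Path(path).read_text(encoding="utf-8")
        records = yaml.safe_load(text)  # YAML superset covers JSON
        return cls([(r["name"], r["head_type"], r["tail_type"]) for r in records])

    def save(self, path: str | Path) -> None:
        records = [
            {"name": n, "head_type": h, "tail_type": t} for n, h, t in self._relations
        ]
        Path(path).write_text(
            json.dumps(records, ensure_ascii=False, indent=1) + "\n", encoding="utf-8"
        )


@dataclass(frozen=True, order=True)
class Triple:
    head: str
    relation: str
    tail: str

    def __post_init__(self):
        if not (self.head and self.relation and self.tail):
            raise ValueError("triple tokens must be non-empty")


class KnowledgeGraph:
    """Entities, relation schema, and a deduplicated triple list.

    Entity order is first-occurrence order over the triple list; duplicate
    triples are dropped (count logged).  An adjacency index keyed by relation
    is kept consistent with the triple list.
    """

    def __init__(self, triples: Iterable[Triple], schema: RelationSchema,
                 entities: Sequence[str] | None = None):
        self.schema = schema
        seen: set[Triple] = set()
        kept: list[Triple] = []
        dropped = 0
        for t in triples:
            if t.relation not in schema:
                raise ValueError(f"unknown relation token: {t.relation!r}")
            if t in seen:
                dropped += 1
                continue
            seen.add(t)
            kept.append(t)
        if dropped:
            logger.info("dropped %d duplicate triples", dropped)
        self.triples: list[Triple] = kept
        self.n_duplicates_dropped = dropped

        ent: dict[str, None] = {}
        for t in kept:
            ent.setdefault(t.head)
            ent.setdefault(t.tail)
        if entities is not None:
            for e in entities:
                ent.setdefault(e)
        self.entities: list[str] = list(ent)

        # relation-keyed adjacency: head -> tails and tail -> heads
        self.out: dict[str, dict[str, list[str]]] = {r: {} for r in schema.names}
        self.inn: dict[str, dict[str, list[str]]] = {r: {} for r in schema.names}
        for t in kept:
            self.out[t.relation].setdefault(t.head, []).append(t.tail)
            self.inn[t.relation].setdefault(t.tail, []).append(t.head)
        self._triple_set = seen

    @property
    def relations(self) -> RelationSchema:
        return self.schema

    def __len__(self) -> int:
        return len(self.triples)

    def __contains__(self, triple: Triple) -> bool:
        return triple in self._triple_set


def load_triples(path: str | Path, schema: RelationSchema) -> KnowledgeGraph:
    """Read a 3-column TSV of (head, relation, tail) into a KnowledgeGraph.

    Malformed lines and unknown relation tokens raise with the offending
    line numbers; duplicate triples are dropped with a logged count.
    """
    triples: list[Triple] = []
    unknown: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3 or not all(parts):
                raise ValueError(f"{path}: malformed line {lineno}: {line!r}")
            head, relation, tail = parts
            if relation not in schema:
                unknown.append(f"line {lineno}: {relation!r}")
                continue
            triples.append(Triple(head, relation, tail))
    if unknown:
        raise ValueError(f"{path}: unknown relation tokens: " + "; ".join(unknown))
    return KnowledgeGraph(triples, schema)


def write_triples(kg: KnowledgeGraph, path: str | Path) -> None:
    """Write the deduplicated canonical TSV form (first-occurrence order)."""
    with open(path, "w", encoding="utf-8") as fh:
        for t in kg.triples:
            fh.write(f"{t.head}\t{t.relation}\t{t.tail}\n")


def split_kg(kg: KnowledgeGraph, fractions: tuple[float, float, float],
             seed: int) -> tuple[KnowledgeGraph, KnowledgeGraph, KnowledgeGraph]:
    """Leakage-safe train/valid/test partition of the triple list.

    Every entity and relation appearing in valid/test must also appear in at
    least one training triple; violating triples are reassigned to train
    (the filtered ranking protocol is undefined for never-seen tokens).
    Identical seeds produce identical splits.
    """
    if any(f <= 0 for f in fractions):
        raise ValueError("fractions must be positive")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(kg.triples))
    n = len(kg.triples)
    n_train = int(round(fractions[0] * n))
    n_valid = int(round(fractions[1] * n))
    idx_train = list(order[:n_train])
    idx_valid = list(order[n_train:n_train + n_valid])
    idx_test = list(order[n_train + n_valid:])

    triples = kg.triples

    def covered(indices: list[int]) -> set[str]:
        toks: set[str] = set()
        for i in indices:
            t = triples[i]
            toks.update((t.head, t.relation, t.tail))
        return toks

    moved = 0
    while True:
        train_tokens = covered(idx_train)
        new_valid, new_test = [], []
        changed = False
        for bucket, new in ((idx_valid, new_valid), (idx_test, new_test)):
            for i in bucket:
                t = triples[i]
                if (t.head in train_tokens and t.relation in train_tokens
                        and t.tail in train_tokens):
                    new.append(i)
                else:
                    idx_train.append(i)
                    moved += 1
                    changed = True
        idx_valid, idx_test = new_valid, new_test
        if not changed:
            break
    if moved:
        logger.info(
            "reassigned %d triples to train for coverage; final sizes %d/%d/%d",
            moved, len(idx_train), len(idx_valid), len(idx_test))

    def sub(indices: list[int]) -> KnowledgeGraph:
        return KnowledgeGraph([triples[i] for i in sorted(indices)], kg.schema)

    return sub(idx_train), sub(idx_valid), sub(idx_test)


def relation_stats(kg: KnowledgeGraph) -> pd.DataFrame:
    """Per-relation (distinct heads, distinct tails, triple count) table."""
    rows = []
    for r in kg.schema.names:
        heads = kg.out[r]
        tails = kg.inn[r]
        rows.append({
            "relation": r,
            "heads": len(heads),
            "tails": len(tails),
            "triples": sum(len(v) for v in heads.values()),
        })
    return pd.DataFrame(rows).set_index("relation")


class Vocabulary:
    """Token-id map over entities, relations, and the [PAD]/[MASK] specials.

    Ids are deterministic: [PAD]=0, [MASK]=1, then entities in sorted-token
    order (a contiguous block, so the prediction softmax can address entity
    candidates by slice), then relations in sorted-token order.
    """

    PAD = "[PAD]"
    MASK = "[MASK]"
    PAD_ID = 0
    MASK_ID = 1
    ENTITY_OFFSET = 2

    def __init__(self, entities: Iterable[str], relations: Iterable[str]):
        self.entity_tokens = sorted(set(entities))
        self.relation_tokens = sorted(set(relations))
        overlap = set(self.entity_tokens) & set(self.relation_tokens)
        if overlap:
            raise ValueError(f"tokens used as both entity and relation: {overlap}")
        self._id = {self.PAD: self.PAD_ID, self.MASK: self.MASK_ID}
        for tok in self.entity_tokens:
            self._id[tok] = len(self._id)
        for tok in self.relation_tokens:
            self._id[tok] = len(self._id)
        self._token = {i: t for t, i in self._id.items()}

    @property
    def n_entities(self) -> int:
        return len(self.entity_tokens)

    @property
    def n_relations(self) -> int:
        return len(self.relation_tokens)

    def __len__(self) -> int:
        return len(self._id)

    def id(self, token: str) -> int:
        return self._id[token]

    def token(self, idx: int) -> str:
        return self._token[idx]

    def entity_index(self, token: str) -> int:
        """Index of an entity within the contiguous entity block [0, V)."""
        i = self._id[token]
        if not (self.ENTITY_OFFSET <= i < self.ENTITY_OFFSET + self.n_entities):
            raise KeyError(f"{token!r} is not an entity token")
        return i - self.ENTITY_OFFSET

    def entity_token(self, index: int) -> str:
        return self.entity_tokens[index]

    def to_json(self) -> dict:
        return {"entities": self.entity_tokens, "relations": self.relation_tokens}

    @classmethod
    def from_json(cls, obj: dict) -> "Vocabulary":
        return cls(obj["entities"], obj["relations"])
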