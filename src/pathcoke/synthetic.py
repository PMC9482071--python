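"""Seeded synthetic clinical knowledge graphs and syndrome case tables.

Real clinical triple stores of this kind (disease-symptom-drug-mechanism
graphs and multilabel syndrome-diagnosis records) are not publicly
deposited, so every component of this package is exercised on synthetic
data with *planted*, fully book-kept structure:

* :func:`generate_kg` draws schema-conformant base edges, then materializes
  the closure of user-supplied 2-hop compositional rules (r1 ∘ r2 →
  r_implied).  A fraction of the implied edges is withheld from training and
  emitted as a test set, so link-prediction models can be scored on exactly
  the compositional regularity that was planted.  A ledger records every
  implied edge together with the base-edge pair(s) that generated it.

* :func:`generate_cases` emits multilabel syndrome-diagnosis case tables:
  binary symptom feature vectors (default 121 symptoms), 8 syndrome classes,
  2-5 positive labels per case, where each syndrome owns a fixed symptom
  subset and a case's features are the noisy union of its syndromes'
  symptom sets.

All outputs are byte-identical under identical configuration (single
`numpy.random.default_rng(seed)` stream).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kg import ENTITY_TYPES, KnowledgeGraph, RelationSchema, Triple

__all__ = [
    "PatternRule",
    "SynthConfig",
    "GenerationLedger",
    "generate_kg",
    "CaseTable",
    "generate_cases",
    "syndrome_kg",
    "DEFAULT_PATTERN_RULES",
]


@dataclass(frozen=True)
class PatternRule:
    """Compositional rule: an r1-edge chained into an r2-edge implies r_implied."""
    first: str
    second: str
    implied: str


#: Default planted patterns, chosen so premise, chain and conclusion all lie
#: inside the default 17-relation schema:
#:   disease=>mechanism ∘ mechanism =>disease  →  disease=>disease
#:   symptom=>mechanism ∘ mechanism=>symptom   →  symptom=>symptom
DEFAULT_PATTERN_RULES = (
    PatternRule("disease=>mechanism", "mechanism =>disease", "disease=>disease"),
    PatternRule("symptom=>mechanism", "mechanism=>symptom", "symptom=>symptom"),
)


@dataclass
class SynthConfig:
    n_per_type: int = 50
    edge_density: float = 3.0           # expected out-degree per relation
    pattern_rules: tuple[PatternRule, ...] = DEFAULT_PATTERN_RULES
    closure_rate: float = 0.8
    holdout_rate: float = 0.2
    noise_rate: float = 0.05
    seed: int = 1
    schema: RelationSchema = field(default_factory=RelationSchema.default)

    def __post_init__(self):
        for name in ("closure_rate", "holdout_rate", "noise_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_per_type < 1:
            raise ValueError("n_per_type must be >= 1")
        for rule in self.pattern_rules:
            for rel in (rule.first, rule.second, rule.implied):
                if rel not in self.schema:
                    raise ValueError(f"rule relation {rel!r} not in schema")
            if self.schema.tail_type(rule.first) != self.schema.head_type(rule.second):
                raise ValueError(f"rule {rule} is not chainable (type mismatch)")
            if (self.schema.head_type(rule.first) != self.schema.head_type(rule.implied)
                    or self.schema.tail_type(rule.second)
                    != self.schema.tail_type(rule.implied)):
                raise ValueError(f"rule {rule} implied relation has wrong endpoint types")


def _triple_key(t: Triple) -> tuple[str, str, str]:
    return (t.head, t.relation, t.tail)


@dataclass
class GenerationLedger:
    """Ground-truth bookkeeping for a generated KG."""
    base: list[Triple]
    #: per rule: {(head, tail): [intermediate entities]} over base edges only
    implied_candidates: list[dict[tuple[str, str], list[str]]]
    materialized: list[tuple[int, Triple]]      # (rule index, triple)
    heldout: list[tuple[int, Triple]]
    noise: list[Triple]
    rules: tuple[PatternRule, ...]

    def to_json(self) -> dict:
        return {
            "rules": [vars(r) for r in self.rules],
            "base": [_triple_key(t) for t in self.base],
            "implied_candidates": [
                [{"head": h, "tail": t, "witnesses": w} for (h, t), w in cand.items()]
                for cand in self.implied_candidates
            ],
            "materialized": [[i, _triple_key(t)] for i, t in self.materialized],
            "heldout": [[i, _triple_key(t)] for i, t in self.heldout],
            "noise": [_triple_key(t) for t in self.noise],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_json(), ensure_ascii=False, indent=1) + "\n",
            encoding="utf-8")

    @property
    def heldout_triples(self) -> list[Triple]:
        return [t for _, t in self.heldout]


def _entity_pools(config: SynthConfig) -> dict[str, list[str]]:
    return {
        etype: [f"{etype}:{i:03d}" for i in range(config.n_per_type)]
        for etype in ENTITY_TYPES
    }


def generate_kg(config: SynthConfig) -> tuple[KnowledgeGraph, GenerationLedger]:
    """Generate a training KG with planted 2-hop closure and its ledger.

    Procedure (single seeded stream, fully deterministic):

    1. Base edges: for every schema relation and every head entity, draw a
       Poisson(edge_density) number of distinct tails (self-loops excluded).
    2. Closure: for every rule and every chainable base-edge pair
       (a -r1-> b -r2-> c, a != c) the implied edge (a, r_implied, c) is
       materialized with probability ``closure_rate`` unless it already
       exists as a base edge.
    3. Holdout: a ``holdout_rate`` fraction of the materialized implied
       edges is withheld from the training KG (returned via the ledger).
    4. Noise: ``noise_rate`` * |train| random schema-valid edges are added,
       never duplicating existing or held-out edges.
    """
    rng = np.random.default_rng(config.seed)
    pools = _entity_pools(config)
    schema = config.schema

    base: list[Triple] = []
    base_set: set[tuple[str, str, str]] = set()
    for rel in schema.names:
        heads = pools[schema.head_type(rel)]
        tails = pools[schema.tail_type(rel)]
        same = schema.head_type(rel) == schema.tail_type(rel)
        for head in heads:
            pool = [t for t in tails if not (same and t == head)]
            k = min(int(rng.poisson(config.edge_density)), len(pool))
            if k == 0:
                continue
            for tail in rng.choice(pool, size=k, replace=False):
                t = Triple(head, rel, str(tail))
                if _triple_key(t) not in base_set:
                    base_set.add(_triple_key(t))
                    base.append(t)

    # chainable pairs over base edges only
    implied_candidates: list[dict[tuple[str, str], list[str]]] = []
    for rule in config.pattern_rules:
        first_edges = [(t.head, t.tail) for t in base if t.relation == rule.first]
        second_out: dict[str, list[str]] = {}
        for t in base:
            if t.relation == rule.second:
                second_out.setdefault(t.head, []).append(t.tail)
        cand: dict[tuple[str, str], list[str]] = {}
        for a, b in first_edges:
            for c in second_out.get(b, ()):
                if a != c:
                    cand.setdefault((a, c), []).append(b)
        implied_candidates.append(cand)

    materialized: list[tuple[int, Triple]] = []
    train: list[Triple] = list(base)
    train_set = set(base_set)
    for rule_idx, (rule, cand) in enumerate(
            zip(config.pattern_rules, implied_candidates)):
        for (a, c) in sorted(cand):
            key = (a, rule.implied, c)
            if key in base_set:
                continue  # closure already present as a base edge
            if rng.random() < config.closure_rate:
                materialized.append((rule_idx, Triple(*key)))

    n_hold = int(round(config.holdout_rate * len(materialized)))
    hold_idx = set(
        rng.choice(len(materialized), size=n_hold, replace=False).tolist()
    ) if n_hold else set()
    heldout: list[tuple[int, Triple]] = []
    for i, (rule_idx, t) in enumerate(materialized):
        if i in hold_idx:
            heldout.append((rule_idx, t))
        elif _triple_key(t) not in train_set:
            train_set.add(_triple_key(t))
            train.append(t)

    heldout_keys = {_triple_key(t) for _, t in heldout}
    noise: list[Triple] = []
    n_noise = int(round(config.noise_rate * len(train)))
    attempts = 0
    rel_names = schema.names
    while len(noise) < n_noise and attempts < 50 * max(n_noise, 1):
        attempts += 1
        rel = rel_names[int(rng.integers(len(rel_names)))]
        head = pools[schema.head_type(rel)][int(rng.integers(config.n_per_type))]
        tail = pools[schema.tail_type(rel)][int(rng.integers(config.n_per_type))]
        key = (head, rel, tail)
        if head == tail or key in train_set or key in heldout_keys:
            continue
        train_set.add(key)
        t = Triple(*key)
        noise.append(t)
        train.append(t)

    all_entities = [e for etype in ENTITY_TYPES for e in pools[etype]]
    kg = KnowledgeGraph(train, schema, entities=all_entities)
    ledger = GenerationLedger(
        base=base,
        implied_candidates=implied_candidates,
        materialized=materialized,
        heldout=heldout,
        noise=noise,
        rules=tuple(config.pattern_rules),
    )
    return kg, ledger


# ---------------------------------------------------------------------------
# Multilabel syndrome-diagnosis case tables
# ---------------------------------------------------------------------------


@dataclass
class CaseTable:
    """Case-by-symptom binary features with multilabel syndrome targets."""
    features: np.ndarray                 # (n_cases, n_symptoms) in {0,1}
    labels: np.ndarray                   # (n_cases, n_syndromes) in {0,1}
    symptom_names: list[str]
    syndrome_names: list[str]
    syndrome_symptoms: list[list[int]]   # symptom column indices owned per syndrome

    @property
    def n_cases(self) -> int:
        return self.features.shape[0]

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd
        df = pd.DataFrame(
            np.hstack([self.features, self.labels]),
            columns=self.symptom_names + self.syndrome_names,
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, n_labels: int = 8) -> "CaseTable":
        import pandas as pd
        df = pd.read_csv(path)
        cols = list(df.columns)
        feats, labs = cols[:-n_labels], cols[-n_labels:]
        return cls(
            features=df[feats].to_numpy(dtype=np.int8),
            labels=df[labs].to_numpy(dtype=np.int8),
            symptom_names=feats,
            syndrome_names=labs,
            syndrome_symptoms=[],
        )


def generate_cases(
    n_cases: int,
    noise: float = 0.1,
    seed: int = 0,
    n_symptoms: int = 121,
    n_syndromes: int = 8,
    symptoms_per_syndrome: int = 15,
    expression: float = 0.7,
    symptom_names: list[str] | None = None,
    syndrome_names: list[str] | None = None,
) -> CaseTable:
    """Draw multilabel diagnosis cases with 2-5 syndromes per case.

    Each syndrome owns a fixed random subset of ``symptoms_per_syndrome``
    symptoms (overlap between syndromes is allowed, as in real symptom
    profiles).  A case's noiseless feature vector is the union of the
    symptoms its syndromes *express*: each owned symptom of an active
    syndrome is present with probability ``expression`` (patients rarely
    show a textbook-complete symptom profile).  Each bit is then flipped
    with probability ``noise``, implemented as replacement by a fair coin
    with probability 2*noise (capped at 1): this matches the flip rate
    while making noise=1 fully independent of the labels rather than a
    deterministic complement.  noise=0 with expression=1 reproduces the
    exact union.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    if not 0.0 <= noise <= 1.0:
        raise ValueError("noise must be in [0, 1]")
    if not 0.0 < expression <= 1.0:
        raise ValueError("expression must be in (0, 1]")
    if n_syndromes < 5:
        raise ValueError("need at least 5 syndromes to draw up to 5 labels")
    rng = np.random.default_rng(seed)
    if symptom_names is None:
        symptom_names = [f"symptom:{i:03d}" for i in range(n_symptoms)]
    if syndrome_names is None:
        syndrome_names = [f"disease:syndrome{j}" for j in range(n_syndromes)]
    if len(symptom_names) != n_symptoms or len(syndrome_names) != n_syndromes:
        raise ValueError("name lists must match the requested counts")

    ownership = [
        sorted(rng.choice(n_symptoms, size=symptoms_per_syndrome,
                          replace=False).tolist())
        for _ in range(n_syndromes)
    ]

    labels = np.zeros((n_cases, n_syndromes), dtype=np.int8)
    clean = np.zeros((n_cases, n_symptoms), dtype=np.int8)
    for i in range(n_cases):
        k = int(rng.integers(2, 6))  # 2-5 labels per case
        syn = rng.choice(n_syndromes, size=k, replace=False)
        labels[i, syn] = 1
        for j in syn:
            for s in ownership[j]:
                if expression >= 1.0 or rng.random() < expression:
                    clean[i, s] = 1

    randomize = rng.random(clean.shape) < min(2.0 * noise, 1.0)
    coins = (rng.random(clean.shape) < 0.5).astype(np.int8)
    features = np.where(randomize, coins, clean).astype(np.int8)

    return CaseTable(
        features=features,
        labels=labels,
        symptom_names=symptom_names,
        syndrome_names=syndrome_names,
        syndrome_symptoms=ownership,
    )


def syndrome_kg(cases: CaseTable,
                schema: RelationSchema | None = None) -> KnowledgeGraph:
    """KG linking each syndrome (as a disease entity) to its owned symptoms.

    Training a KG-embedding model on this graph yields symptom embeddings
    whose geometry reflects syndrome membership — the input the
    KGE-augmented classifier expects.
    """
    if not cases.syndrome_symptoms:
        raise ValueError("case table carries no syndrome->symptom ownership")
    schema = schema or RelationSchema.default()
    triples = [
        Triple(cases.syndrome_names[j], "disease=>symptom", cases.symptom_names[s])
        for j in range(len(cases.syndrome_names))
        for s in cases.syndrome_symptoms[j]
    ]
    return KnowledgeGraph(triples, schema,
                          entities=cases.syndrome_names + cases.symptom_names)
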