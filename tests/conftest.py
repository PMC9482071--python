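import numpy as np
import pytest

from pathcoke.kg import KnowledgeGraph, RelationSchema, Triple


@pytest.fixture(scope="session")
def schema() -> RelationSchema:
    return RelationSchema.default()


@pytest.fixture(scope="session")
def fig_schema(schema) -> RelationSchema:
    """Default schema extended with the drug-chain relations used in the
    worked metformin example (drug acts on a mechanism, the mechanism
    underlies / is treated in a disease)."""
    return schema.extended([
        ("mechanism", "drug", "mechanism"),
        ("treat", "mechanism", "disease"),
    ])


@pytest.fixture(scope="session")
def metformin_kg(fig_schema) -> KnowledgeGraph:
    """The positive 2-hop chain: metformin acts on insulin resistance,
    which is treatable in diabetes mellitus."""
    return KnowledgeGraph([
        Triple("metformin", "mechanism", "insulin resistance"),
        Triple("insulin resistance", "treat", "diabetes mellitus"),
    ], fig_schema)


@pytest.fixture(scope="session")
def cooccurrence_kg(schema) -> KnowledgeGraph:
    """The negative example: two symptom edges sharing a head entity
    (pure co-occurrence, not chainable)."""
    return KnowledgeGraph([
        Triple("dyslipidemia", "symptom=>disease", "diabetes mellitus"),
        Triple("dyslipidemia", "symptom=>disease", "CKD"),
    ], schema)


def random_kg(rng: np.random.Generator, n_entities: int = 20,
              n_triples: int = 80, schema: RelationSchema | None = None
              ) -> KnowledgeGraph:
    """Small random schema-valid KG for brute-force comparisons."""
    schema = schema or RelationSchema.default()
    from pathcoke.kg import ENTITY_TYPES
    pools = {t: [f"{t}:{i:02d}" for i in range(n_entities)] for t in ENTITY_TYPES}
    names = schema.names
    triples = []
    seen = set()
    attempts = 0
    while len(triples) < n_triples and attempts < 20 * n_triples:
        attempts += 1
        rel = names[int(rng.integers(len(names)))]
        h = pools[schema.head_type(rel)][int(rng.integers(n_entities))]
        t = pools[schema.tail_type(rel)][int(rng.integers(n_entities))]
        if h == t or (h, rel, t) in seen:
            continue
        seen.add((h, rel, t))
        triples.append(Triple(h, rel, t))
    return KnowledgeGraph(triples, schema)
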