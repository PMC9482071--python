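"""Contextualized knowledge-graph embedding with a transformer encoder.

Edges and mined multihop paths are unified as token sequences
``(s, r_1, ..., r_k, o)``.  Each sequence yields two training instances:
one with the head replaced by [MASK] (predict s) and one with the tail
replaced (predict o).  The masked sequence is embedded as the sum of an
element embedding and a learned positional embedding, passed through L
post-norm transformer encoder layers with multi-head self-attention, and
the final hidden state at the masked position is projected through a
feedforward layer; a softmax over the entity vocabulary — whose output
weight matrix is *the same storage* as the input element embedding rows of
the entities — produces the predicted distribution.  Training minimises
label-smoothed cross-entropy in which the target entity receives
probability ε and every incorrect entity (1-ε)/(V-1).

Relations inside paths are fed as their individual base tokens; composed
labels (e.g. "mechanism-treat") are bookkeeping for path-query grouping
only, which keeps the relation vocabulary closed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import nn
from .kg import KnowledgeGraph, Triple, Vocabulary
from .nn import Tensor, gather_rows, layer_norm, log_softmax

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "InputBatch",
    "CokeModel",
    "make_instances",
    "smooth_labels",
    "cross_entropy",
    "train_coke",
    "score_sequences",
]


@dataclass
class ModelConfig:
    hidden_size: int = 64
    layers: int = 2
    heads: int = 4
    feedforward_size: int = 128
    dropout: float = 0.1
    max_sequence_length: int = 8
    label_smoothing: float = 0.8     # probability mass given to the target
    learning_rate: float = 2e-3
    batch_size: int = 1024
    epochs: int = 200
    seed: int = 0
    dtype: str = "float32"           # training precision; float64 for checks

    def __post_init__(self):
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be 'float32' or 'float64'")
        if self.hidden_size % self.heads != 0:
            raise ValueError("hidden_size must be divisible by heads")
        if self.max_sequence_length < 3:
            raise ValueError("max_sequence_length must be >= 3")
        if not 0.0 < self.label_smoothing < 1.0:
            raise ValueError("label_smoothing must be in (0, 1)")


@dataclass
class InputBatch:
    """Padded masked sequences: ids (N, L), one [MASK] per row."""
    ids: np.ndarray            # int token ids, [PAD]-padded
    mask_positions: np.ndarray  # (N,) index of the [MASK] token per row
    targets: np.ndarray        # (N,) entity *indices* in [0, V)
    lengths: np.ndarray        # (N,) true sequence lengths

    def __len__(self) -> int:
        return self.ids.shape[0]

    def take(self, idx: np.ndarray) -> "InputBatch":
        return InputBatch(self.ids[idx], self.mask_positions[idx],
                          self.targets[idx], self.lengths[idx])


def make_instances(
    triples: Iterable[Triple],
    paths: Sequence | None,
    vocab: Vocabulary,
    max_sequence_length: int,
) -> InputBatch:
    """Two masked instances per edge and per path.

    Edges become length-3 sequences (s, r, o); a k-hop path becomes the
    length-(k+2) sequence (s, r_1, ..., r_k, o).  For each sequence one
    instance masks position 1 (predict s) and one masks position n
    (predict o).
    """
    seqs: list[list[int]] = []
    for t in triples:
        seqs.append([vocab.id(t.head), vocab.id(t.relation), vocab.id(t.tail)])
    if paths:
        for p in paths:
            seq = ([vocab.id(p.source)]
                   + [vocab.id(r) for r in p.relations]
                   + [vocab.id(p.target)])
            if len(seq) > max_sequence_length:
                raise ValueError(
                    f"path of {len(p.relations)} hops exceeds "
                    f"max_sequence_length={max_sequence_length}")
            seqs.append(seq)

    n = 2 * len(seqs)
    length = max((len(s) for s in seqs), default=3)
    ids = np.full((n, length), Vocabulary.PAD_ID, dtype=np.intp)
    mask_pos = np.zeros(n, dtype=np.intp)
    targets = np.zeros(n, dtype=np.intp)
    lengths = np.zeros(n, dtype=np.intp)
    for i, seq in enumerate(seqs):
        for j, (pos) in enumerate((0, len(seq) - 1)):
            row = 2 * i + j
            ids[row, :len(seq)] = seq
            targets[row] = ids[row, pos] - Vocabulary.ENTITY_OFFSET
            ids[row, pos] = Vocabulary.MASK_ID
            mask_pos[row] = pos
            lengths[row] = len(seq)
    return InputBatch(ids, mask_pos, targets, lengths)


def smooth_labels(target: int, V: int, epsilon: float) -> np.ndarray:
    """Smoothed label vector: y[target] = ε, y[other] = (1-ε)/(V-1)."""
    if V < 2:
        raise ValueError("V must be >= 2")
    if not 0.0 < epsilon < 1.0:
        raise ValueError("epsilon must be in (0, 1)")
    y = np.full(V, (1.0 - epsilon) / (V - 1))
    y[target] = epsilon
    return y


def cross_entropy(p: np.ndarray, y: np.ndarray) -> float:
    """L = -Σ_t y_t log p_t for probability vector p and label vector y."""
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError("p and y must have the same length")
    if np.any(p <= 0):
        raise ValueError("p must be strictly positive")
    return float(-(y * np.log(p)).sum())


class CokeModel:
    """Transformer encoder over masked edge/path sequences.

    Parameters live in ``self.params`` (name -> Tensor).  The entity rows of
    the element embedding matrix double as the output projection of the
    prediction softmax (weight tying), so mutating an entity's embedding
    changes both its input encoding and its output logit.
    """

    def __init__(self, vocab: Vocabulary, config: ModelConfig):
        self.vocab = vocab
        self.config = config
        rng = np.random.default_rng(config.seed)
        D, F = config.hidden_size, config.feedforward_size
        n_tokens = len(vocab)
        dt = np.float32 if config.dtype == "float32" else np.float64

        def normal(*shape):
            return nn.Parameter(rng.normal(0.0, 0.02, size=shape).astype(dt))

        def zeros(*shape):
            return nn.Parameter(np.zeros(shape, dtype=dt))

        def ones(*shape):
            return nn.Parameter(np.ones(shape, dtype=dt))

        p: dict[str, Tensor] = {
            "emb": normal(n_tokens, D),
            "pos": normal(config.max_sequence_length, D),
            "emb_ln_g": ones(D),
            "emb_ln_b": zeros(D),
            "head_W": normal(D, D),
            "head_b": zeros(D),
            "head_ln_g": ones(D),
            "head_ln_b": zeros(D),
            "out_bias": zeros(vocab.n_entities),
        }
        for l in range(config.layers):
            for name in ("Wq", "Wk", "Wv", "Wo"):
                p[f"l{l}.{name}"] = normal(D, D)
                p[f"l{l}.{name.replace('W', 'b')}"] = zeros(D)
            p[f"l{l}.attn_ln_g"] = ones(D)
            p[f"l{l}.attn_ln_b"] = zeros(D)
            p[f"l{l}.W1"] = normal(D, F)
            p[f"l{l}.b1"] = zeros(F)
            p[f"l{l}.W2"] = normal(F, D)
            p[f"l{l}.b2"] = zeros(D)
            p[f"l{l}.ffn_ln_g"] = ones(D)
            p[f"l{l}.ffn_ln_b"] = zeros(D)
        self.params = p
        self._dtype = dt

    # -- parameter plumbing --------------------------------------------------

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def set_trainable(self, flag: bool) -> None:
        for t in self.params.values():
            t.requires_grad = flag

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    # -- forward -------------------------------------------------------------

    def embed_inputs(self, ids: np.ndarray, training: bool = False,
                     rng: np.random.Generator | None = None) -> Tensor:
        """Element + positional embedding, layer-norm, dropout (the input map)."""
        n = ids.shape[-1]
        if n > self.config.max_sequence_length:
            raise ValueError(
                f"sequence length {n} exceeds positional table "
                f"({self.config.max_sequence_length})")
        tok = gather_rows(self.params["emb"], ids)             # (B, n, D)
        pos = gather_rows(self.params["pos"], np.arange(n))    # (n, D)
        h = layer_norm(tok + pos, self.params["emb_ln_g"], self.params["emb_ln_b"])
        return nn.dropout(h, self.config.dropout if training else 0.0, rng)

    def encode(self, h: Tensor, ids: np.ndarray, training: bool = False,
               rng: np.random.Generator | None = None
               ) -> tuple[Tensor, list[Tensor], list[Tensor]]:
        """Post-norm transformer stack; returns (h^L, per-layer h, attention)."""
        cfg = self.config
        B, n, D = h.shape
        nh, dk = cfg.heads, D // cfg.heads
        pdrop = cfg.dropout if training else 0.0
        key_mask = (ids != Vocabulary.PAD_ID)
        attn_bias = np.where(key_mask, 0.0, -1e9)[:, None, None, :] \
            .astype(self._dtype)

        hiddens: list[Tensor] = []
        attentions: list[Tensor] = []
        for l in range(cfg.layers):
            P = self.params

            def heads_view(x: Tensor) -> Tensor:
                return x.reshape(B, n, nh, dk).swapaxes(1, 2)   # (B, nh, n, dk)

            q = heads_view(nn.linear(h, P[f"l{l}.Wq"], P[f"l{l}.bq"]))
            k = heads_view(nn.linear(h, P[f"l{l}.Wk"], P[f"l{l}.bk"]))
            v = heads_view(nn.linear(h, P[f"l{l}.Wv"], P[f"l{l}.bv"]))
            scores = (q @ k.T) * (1.0 / np.sqrt(dk)) + Tensor(attn_bias)
            attn = nn.softmax(scores, axis=-1)                  # (B, nh, n, n)
            ctx = nn.dropout(attn, pdrop, rng) @ v              # (B, nh, n, dk)
            ctx = ctx.swapaxes(1, 2).reshape(B, n, D)
            out = nn.dropout(nn.linear(ctx, P[f"l{l}.Wo"], P[f"l{l}.bo"]),
                             pdrop, rng)
            h = layer_norm(h + out, P[f"l{l}.attn_ln_g"], P[f"l{l}.attn_ln_b"])
            # ReLU feedforward (cheap at desk scale; gelu kept for the head)
            f = nn.linear(nn.linear(h, P[f"l{l}.W1"], P[f"l{l}.b1"]).relu(),
                          P[f"l{l}.W2"], P[f"l{l}.b2"])
            f = nn.dropout(f, pdrop, rng)
            h = layer_norm(h + f, P[f"l{l}.ffn_ln_g"], P[f"l{l}.ffn_ln_b"])
            hiddens.append(h)
            attentions.append(attn)
        return h, hiddens, attentions

    def forward(self, batch: InputBatch, training: bool = False,
                rng: np.random.Generator | None = None) -> tuple[Tensor, dict]:
        """Logits over the entity vocabulary at each row's masked position."""
        ids = batch.ids
        B, n = ids.shape
        emb_out = self.embed_inputs(ids, training, rng)
        hL, hiddens, attentions = self.encode(emb_out, ids, training, rng)

        D = self.config.hidden_size
        flat = hL.reshape(B * n, D)
        at_mask = gather_rows(flat, np.arange(B) * n + batch.mask_positions)
        z = layer_norm(nn.gelu(nn.linear(at_mask, self.params["head_W"],
                                         self.params["head_b"])),
                       self.params["head_ln_g"], self.params["head_ln_b"])
        V = self.vocab.n_entities
        ent_rows = gather_rows(
            self.params["emb"],
            np.arange(Vocabulary.ENTITY_OFFSET, Vocabulary.ENTITY_OFFSET + V))
        logits = z @ ent_rows.T + self.params["out_bias"]       # (B, V)
        aux = {"embedding_out": emb_out, "hiddens": hiddens,
               "attentions": attentions, "z": z}
        return logits, aux

    def predict_masked(self, batch: InputBatch) -> np.ndarray:
        """Probabilities over the entity vocabulary (eval mode, rows sum to 1)."""
        logits, _ = self.forward(batch, training=False)
        x = logits.data
        x = x - x.max(axis=-1, keepdims=True)
        e = np.exp(x)
        return e / e.sum(axis=-1, keepdims=True)

    def smoothed_loss(self, logits: Tensor, targets: np.ndarray) -> Tensor:
        """Mean label-smoothed cross-entropy over the batch."""
        eps = self.config.label_smoothing
        V = self.vocab.n_entities
        u = (1.0 - eps) / (V - 1)
        B = logits.shape[0]
        logp = log_softmax(logits, axis=-1)
        flat = logp.reshape(B * V, 1)
        lp_target = gather_rows(flat, np.arange(B) * V + targets).reshape(B)
        total = (eps - u) * lp_target + u * logp.sum(axis=-1)
        return -total.mean()

    # -- persistence ----------------------------------------------------------

    def save(self, dirpath: str | Path) -> None:
        d = Path(dirpath)
        (d / "weights").mkdir(parents=True, exist_ok=True)
        (d / "config.json").write_text(
            json.dumps(asdict(self.config), indent=1) + "\n", encoding="utf-8")
        (d / "vocabulary.json").write_text(
            json.dumps(self.vocab.to_json(), ensure_ascii=False) + "\n",
            encoding="utf-8")
        for name, t in sorted(self.params.items()):
            np.save(d / "weights" / f"{name}.npy", t.data)

    @classmethod
    def load(cls, dirpath: str | Path) -> "CokeModel":
        d = Path(dirpath)
        config = ModelConfig(**json.loads((d / "config.json").read_text()))
        vocab = Vocabulary.from_json(
            json.loads((d / "vocabulary.json").read_text()))
        model = cls(vocab, config)
        for name in model.params:
            model.params[name].data = np.load(d / "weights" / f"{name}.npy")
        return model

    def entity_embeddings(self) -> dict[str, np.ndarray]:
        """Entity token -> embedding row (the tied input/output table)."""
        emb = self.params["emb"].data
        off = Vocabulary.ENTITY_OFFSET
        return {tok: emb[off + i].copy()
                for i, tok in enumerate(self.vocab.entity_tokens)}


def train_coke(
    kg: KnowledgeGraph,
    config: ModelConfig,
    paths: Sequence | None = None,
    vocab: Vocabulary | None = None,
) -> tuple[CokeModel, list[float]]:
    """Train by masked-entity prediction; returns (model, per-epoch loss trace).

    Deterministic under ``config.seed`` (init, shuffling and dropout all
    draw from generators derived from it).
    """
    vocab = vocab or Vocabulary(kg.entities, kg.schema.names)
    data = make_instances(kg.triples, paths, vocab, config.max_sequence_length)
    if len(data) == 0:
        raise ValueError("no training instances")
    model = CokeModel(vocab, config)
    rng = np.random.default_rng(config.seed + 1)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    trace: list[float] = []
    n = len(data)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            sub = data.take(order[start:start + config.batch_size])
            logits, _ = model.forward(sub, training=True, rng=rng)
            loss = model.smoothed_loss(logits, sub.targets)
            val = loss.item()
            if not np.isfinite(val):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}; last finite epoch mean: "
                    f"{trace[-1] if trace else 'n/a'}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(val * len(sub))
        trace.append(float(np.sum(losses) / n))
    logger.info("trained CoKE: %d instances, final loss %.4f",
                n, trace[-1] if trace else float("nan"))
    return model, trace


def score_sequences(model: CokeModel, sequences: Sequence[Sequence[str]],
                    mask_positions: Sequence[int]) -> np.ndarray:
    """Entity probabilities for arbitrary masked token sequences (eval mode).

    Each sequence is a list of tokens in which exactly one position will be
    replaced by [MASK] (the given position; its current token is ignored).
    """
    vocab = model.vocab
    length = max(len(s) for s in sequences)
    ids = np.full((len(sequences), length), Vocabulary.PAD_ID, dtype=np.intp)
    mpos = np.asarray(mask_positions, dtype=np.intp)
    for i, seq in enumerate(sequences):
        ids[i, :len(seq)] = [vocab.id(tok) for tok in seq]
        ids[i, mpos[i]] = Vocabulary.MASK_ID
    batch = InputBatch(ids, mpos, np.zeros(len(sequences), dtype=np.intp),
                       np.array([len(s) for s in sequences], dtype=np.intp))
    return model.predict_masked(batch)
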