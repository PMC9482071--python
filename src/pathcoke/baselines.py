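"""Canonical KG-embedding baseline scorers behind one interface.

Eight classical scoring families — translational (TransE/H/R/D), bilinear
(DistMult, ComplEx, SimplE) and rotational (RotatE) — each score a triple
(h, r, t) with higher = more plausible:

* TransE     -||h + r - t||_p
* TransH     TransE distance after projecting h, t off the relation normal
* TransR     TransE distance after the relation-specific linear map M_r
* TransD     TransE distance after the dynamic map (I + r_p e_p^T)
* DistMult   sum(h * r * t)
* ComplEx    Re(<h, r, conj(t)>) in complex coordinates
* SimplE     (<h_head, r, t_tail> + <t_head, r_inv, h_tail>) / 2
* RotatE     -sum |h * e^{i theta_r} - t| in complex coordinates
             (relation phases have unit modulus by construction)

Training is margin-based ranking with uniform negative sampling (corrupt
head or tail with probability 1/2), deterministic under the seed.  These
models are the static-embedding comparators for the contextual transformer
model; they share the same filtered ranking evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import nn
from .kg import KnowledgeGraph, Vocabulary
from .nn import Tensor, gather_rows

logger = logging.getLogger(__name__)

FAMILIES = ("transe", "transh", "transr", "transd",
            "distmult", "complex", "simple", "rotate")

__all__ = ["FAMILIES", "BaselineConfig", "ScoringModel", "train_baseline"]


@dataclass
class BaselineConfig:
    family: str = "transe"
    dim: int = 32
    margin: float = 2.0
    norm: int = 1                  # p-norm for translational distances
    learning_rate: float = 0.01
    batch_size: int = 512
    epochs: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family: {self.family!r}")
        if self.norm not in (1, 2):
            raise ValueError("norm must be 1 or 2")


class ScoringModel:
    """Entity/relation parameter tables for one scoring family."""

    def __init__(self, vocab: Vocabulary, config: BaselineConfig):
        self.vocab = vocab
        self.config = config
        rng = np.random.default_rng(config.seed)
        d = config.dim
        nE, nR = vocab.n_entities, vocab.n_relations
        scale = 1.0 / np.sqrt(d)

        def table(*shape):
            return nn.Parameter(rng.uniform(-scale, scale, size=shape))

        f = config.family
        p: dict[str, Tensor] = {}
        if f in ("transe", "transh", "transr", "transd", "distmult"):
            p["E"] = table(nE, d)
            p["R"] = table(nR, d)
            if f == "transh":
                p["Wn"] = table(nR, d)          # relation hyperplane normals
            elif f == "transr":
                eye = np.tile(np.eye(d), (nR, 1, 1))
                p["M"] = nn.Parameter(eye + rng.normal(0, 0.05, size=(nR, d, d)))
            elif f == "transd":
                p["Ep"] = table(nE, d)
                p["Rp"] = table(nR, d)
        elif f == "complex":
            p["E_re"], p["E_im"] = table(nE, d), table(nE, d)
            p["R_re"], p["R_im"] = table(nR, d), table(nR, d)
        elif f == "simple":
            p["E_head"], p["E_tail"] = table(nE, d), table(nE, d)
            p["R"], p["R_inv"] = table(nR, d), table(nR, d)
        elif f == "rotate":
            p["E_re"], p["E_im"] = table(nE, d), table(nE, d)
            p["phase"] = nn.Parameter(rng.uniform(-np.pi, np.pi, size=(nR, d)))
        self.params = p

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    # -- differentiable scoring (used in training) ---------------------------

    def score_triples(self, h_idx: np.ndarray, r_idx: np.ndarray,
                      t_idx: np.ndarray) -> Tensor:
        """Scores of index triples, shape (B,); higher = more plausible."""
        f = self.config.family
        P = self.params

        def dist(d: Tensor) -> Tensor:
            if self.config.norm == 1:
                return d.abs().sum(axis=-1)
            return ((d * d).sum(axis=-1) + 1e-12).sqrt()

        if f in ("transe", "transh", "transr", "transd"):
            h = gather_rows(P["E"], h_idx)
            r = gather_rows(P["R"], r_idx)
            t = gather_rows(P["E"], t_idx)
            if f == "transh":
                w = gather_rows(P["Wn"], r_idx)
                w = w / ((w * w).sum(axis=-1, keepdims=True) + 1e-12).sqrt()
                h = h - (h * w).sum(axis=-1, keepdims=True) * w
                t = t - (t * w).sum(axis=-1, keepdims=True) * w
            elif f == "transr":
                M = _gather_mats(P["M"], r_idx)
                h = (M @ h.reshape(*h.shape, 1)).reshape(h.shape)
                t = (M @ t.reshape(*t.shape, 1)).reshape(t.shape)
            elif f == "transd":
                hp = gather_rows(P["Ep"], h_idx)
                tp = gather_rows(P["Ep"], t_idx)
                rp = gather_rows(P["Rp"], r_idx)
                h = h + (h * hp).sum(axis=-1, keepdims=True) * rp
                t = t + (t * tp).sum(axis=-1, keepdims=True) * rp
            return -dist(h + r - t)
        if f == "distmult":
            h = gather_rows(P["E"], h_idx)
            r = gather_rows(P["R"], r_idx)
            t = gather_rows(P["E"], t_idx)
            return (h * r * t).sum(axis=-1)
        if f == "complex":
            hr, hi = gather_rows(P["E_re"], h_idx), gather_rows(P["E_im"], h_idx)
            rr, ri = gather_rows(P["R_re"], r_idx), gather_rows(P["R_im"], r_idx)
            tr, ti = gather_rows(P["E_re"], t_idx), gather_rows(P["E_im"], t_idx)
            return (hr * rr * tr + hi * rr * ti
                    + hr * ri * ti - hi * ri * tr).sum(axis=-1)
        if f == "simple":
            hh = gather_rows(P["E_head"], h_idx)
            tt = gather_rows(P["E_tail"], t_idx)
            th = gather_rows(P["E_head"], t_idx)
            ht = gather_rows(P["E_tail"], h_idx)
            r = gather_rows(P["R"], r_idx)
            ri = gather_rows(P["R_inv"], r_idx)
            return 0.5 * ((hh * r * tt).sum(axis=-1) + (th * ri * ht).sum(axis=-1))
        if f == "rotate":
            hr, hi = gather_rows(P["E_re"], h_idx), gather_rows(P["E_im"], h_idx)
            tr, ti = gather_rows(P["E_re"], t_idx), gather_rows(P["E_im"], t_idx)
            ph = gather_rows(P["phase"], r_idx)
            c, s = ph.cos(), ph.sin()
            rot_re = hr * c - hi * s
            rot_im = hr * s + hi * c
            mod = ((rot_re - tr) * (rot_re - tr)
                   + (rot_im - ti) * (rot_im - ti) + 1e-12).sqrt()
            return -mod.sum(axis=-1)
        raise ValueError(f"unknown model family: {f!r}")

    # -- fast candidate scoring (evaluation; pure NumPy) ---------------------

    def score_all_tails(self, head: int, relation: int) -> np.ndarray:
        nE = self.vocab.n_entities
        return self._score_np(np.full(nE, head), np.full(nE, relation),
                              np.arange(nE))

    def score_all_heads(self, relation: int, tail: int) -> np.ndarray:
        nE = self.vocab.n_entities
        return self._score_np(np.arange(nE), np.full(nE, relation),
                              np.full(nE, tail))

    def _score_np(self, h, r, t) -> np.ndarray:
        flags = [p.requires_grad for p in self.parameters()]
        for p in self.parameters():
            p.requires_grad = False
        try:
            return self.score_triples(h, r, t).data
        finally:
            for p, fl in zip(self.parameters(), flags):
                p.requires_grad = fl


def _gather_mats(M: Tensor, idx: np.ndarray) -> Tensor:
    """Row-gather for a 3-D table of per-relation matrices."""
    n, d1, d2 = M.data.shape
    return gather_rows(M.reshape(n, d1 * d2), idx).reshape(len(idx), d1, d2)


def score(model: ScoringModel, head: str, relation: str, tail: str) -> float:
    """Score one token triple with the model's family scoring function."""
    v = model.vocab
    if relation not in v.relation_tokens:
        raise KeyError(f"unknown relation {relation!r}")
    h = np.array([v.entity_index(head)])
    r = np.array([v.relation_tokens.index(relation)])
    t = np.array([v.entity_index(tail)])
    return float(model._score_np(h, r, t)[0])


def train_baseline(kg: KnowledgeGraph, config: BaselineConfig,
                   vocab: Vocabulary | None = None) -> ScoringModel:
    """Margin ranking loss with uniform head-or-tail corruption."""
    vocab = vocab or Vocabulary(kg.entities, kg.schema.names)
    rel_index = {tok: i for i, tok in enumerate(vocab.relation_tokens)}
    H = np.array([vocab.entity_index(t.head) for t in kg.triples])
    R = np.array([rel_index[t.relation] for t in kg.triples])
    T = np.array([vocab.entity_index(t.tail) for t in kg.triples])
    n = len(H)
    if n == 0:
        raise ValueError("empty training KG")
    model = ScoringModel(vocab, config)
    rng = np.random.default_rng(config.seed + 1)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    nE = vocab.n_entities
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            h, r, t = H[idx], R[idx], T[idx]
            corrupt_head = rng.random(len(idx)) < 0.5
            rand_ent = rng.integers(nE, size=len(idx))
            h_neg = np.where(corrupt_head, rand_ent, h)
            t_neg = np.where(corrupt_head, t, rand_ent)
            s_pos = model.score_triples(h, r, t)
            s_neg = model.score_triples(h_neg, r, t_neg)
            loss = (Tensor(config.margin) - s_pos + s_neg).relu().mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
    return model
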