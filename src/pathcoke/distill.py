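"""Three-level knowledge distillation of a trained contextual KGE model.

A compact student transformer is trained to match a frozen teacher at three
levels (the TinyBERT recipe, adapted to KG sequences):

* embedding layer — MSE between the student's embedding-layer output,
  projected by a trainable matrix W_e (d x d0), and the teacher's;
* transformer layers, mapped in k-layer intervals (student layer i matches
  teacher layer i*k, k = T/S): per mapped layer, the mean over attention
  heads of the MSE between attention matrices, plus the MSE between hidden
  states after a per-layer trainable projection W_h;
* prediction layer — cross-entropy between the teacher's
  temperature-softened output distribution softmax(z_T / t) and the
  student's log-softmax(z_S / t).

Teacher parameters are never updated.  Head counts must agree between
teacher and student (the attention loss is undefined otherwise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import nn
from .kg import KnowledgeGraph
from .model import CokeModel, InputBatch, ModelConfig, make_instances
from .nn import Tensor, log_softmax

logger = logging.getLogger(__name__)

__all__ = [
    "DistillConfig",
    "DistillPair",
    "layer_map",
    "embedding_loss",
    "attention_loss",
    "hidden_loss",
    "prediction_loss",
    "distill",
    "distill_losses",
]


@dataclass
class DistillConfig:
    student_layers: int = 1
    student_hidden: int = 32
    student_feedforward: int = 128
    temperature: float = 1.0   # softening for the prediction loss; 1 = plain softmax
    w_emb: float = 1.0
    w_attn: float = 1.0
    w_hidn: float = 1.0
    w_pred: float = 1.0
    learning_rate: float = 1e-3
    batch_size: int = 256
    epochs: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if min(self.w_emb, self.w_attn, self.w_hidn, self.w_pred) < 0:
            raise ValueError("loss weights must be >= 0")


def layer_map(student_layers: int, teacher_layers: int) -> dict[int, int]:
    """Interval mapping i -> i*(T/S) for student layers i = 1..S (1-based)."""
    if teacher_layers % student_layers != 0:
        raise ValueError(
            f"teacher layers ({teacher_layers}) must be divisible by "
            f"student layers ({student_layers})")
    k = teacher_layers // student_layers
    return {i: i * k for i in range(1, student_layers + 1)}


def _mse(a: Tensor, b: Tensor) -> Tensor:
    d = a - b
    return (d * d).mean()


def embedding_loss(E_S, E_T, W_e) -> Tensor:
    """MSE(E_S @ W_e, E_T) — student embeddings projected into teacher space."""
    E_S, E_T, W_e = map(nn.as_tensor, (E_S, E_T, W_e))
    if E_S.shape[:-1] != E_T.shape[:-1] or (E_S.shape[-1], E_T.shape[-1]) != W_e.shape:
        raise ValueError("embedding/projection shape mismatch")
    return _mse(E_S @ W_e, E_T)


def attention_loss(student_attn, teacher_attn) -> Tensor:
    """Mean over heads of MSE between attention matrices (one mapped layer).

    Accepts (h, l, l) or batched (B, h, l, l) tensors.  Because the MSE of
    each head averages over identical shapes, the mean over heads equals the
    MSE over the stacked tensor.
    """
    A_S, A_T = nn.as_tensor(student_attn), nn.as_tensor(teacher_attn)
    if A_S.shape != A_T.shape:
        raise ValueError(f"attention shape mismatch: {A_S.shape} vs {A_T.shape}")
    return _mse(A_S, A_T)


def hidden_loss(H_S, H_T, W_h) -> Tensor:
    """MSE(H_S @ W_h, H_T) for one mapped transformer layer."""
    H_S, H_T, W_h = map(nn.as_tensor, (H_S, H_T, W_h))
    if H_S.shape[:-1] != H_T.shape[:-1] or (H_S.shape[-1], H_T.shape[-1]) != W_h.shape:
        raise ValueError("hidden-state/projection shape mismatch")
    return _mse(H_S @ W_h, H_T)


def prediction_loss(z_T, z_S, temperature: float) -> Tensor:
    """CE between softmax(z_T/t) (target) and log-softmax(z_S/t).

    Follows the distillation convention of the architecture this mirrors:
    the teacher supplies the target distribution.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    z_T, z_S = nn.as_tensor(z_T), nn.as_tensor(z_S)
    if z_T.shape != z_S.shape:
        raise ValueError("logit shape mismatch")
    zt = z_T.data / temperature
    zt = zt - zt.max(axis=-1, keepdims=True)
    p_T = np.exp(zt)
    p_T /= p_T.sum(axis=-1, keepdims=True)
    logp_S = log_softmax(z_S * (1.0 / temperature), axis=-1)
    per_row = -(Tensor(p_T) * logp_S).sum(axis=-1)
    return per_row.mean() if per_row.ndim else per_row


@dataclass
class DistillPair:
    teacher: CokeModel
    student: CokeModel
    W_e: Tensor                  # d x d0 embedding projection
    W_h: list[Tensor]            # one d x d0 projection per mapped student layer
    layer_map: dict[int, int]

    @classmethod
    def create(cls, teacher: CokeModel, config: DistillConfig) -> "DistillPair":
        tcfg = teacher.config
        mapping = layer_map(config.student_layers, tcfg.layers)
        scfg = ModelConfig(
            hidden_size=config.student_hidden,
            layers=config.student_layers,
            heads=tcfg.heads,                    # equal head counts required
            feedforward_size=config.student_feedforward,
            dropout=tcfg.dropout,
            max_sequence_length=tcfg.max_sequence_length,
            label_smoothing=tcfg.label_smoothing,
            learning_rate=config.learning_rate,
            batch_size=config.batch_size,
            epochs=config.epochs,
            seed=config.seed,
        )
        student = CokeModel(teacher.vocab, scfg)
        rng = np.random.default_rng(config.seed + 17)
        d, d0 = config.student_hidden, tcfg.hidden_size
        W_e = nn.Parameter(rng.normal(0.0, 0.02, size=(d, d0)))
        W_h = [nn.Parameter(rng.normal(0.0, 0.02, size=(d, d0)))
               for _ in range(config.student_layers)]
        return cls(teacher, student, W_e, W_h, mapping)

    @classmethod
    def identity(cls, teacher: CokeModel) -> "DistillPair":
        """Student = copy of teacher with identity projections (diagnostics)."""
        import copy
        student = CokeModel(teacher.vocab, copy.deepcopy(teacher.config))
        for name in teacher.params:
            student.params[name].data = teacher.params[name].data.copy()
        d = teacher.config.hidden_size
        eye = np.eye(d)
        return cls(teacher, student, nn.Parameter(eye.copy()),
                   [nn.Parameter(eye.copy()) for _ in range(teacher.config.layers)],
                   layer_map(teacher.config.layers, teacher.config.layers))

    def trainable(self) -> list[Tensor]:
        return self.student.parameters() + [self.W_e] + self.W_h


def distill_losses(pair: DistillPair, batch: InputBatch, temperature: float = 1.0,
                   training: bool = False,
                   rng: np.random.Generator | None = None) -> dict[str, Tensor]:
    """The four distillation loss terms on one batch (teacher in eval mode)."""
    if pair.teacher.config.heads != pair.student.config.heads:
        raise ValueError("teacher and student must have equal head counts")
    if pair.teacher.vocab.entity_tokens != pair.student.vocab.entity_tokens:
        raise ValueError("teacher/student vocabulary mismatch")
    t_logits, t_aux = pair.teacher.forward(batch, training=False)
    s_logits, s_aux = pair.student.forward(batch, training=training, rng=rng)

    losses = {
        "emb": embedding_loss(s_aux["embedding_out"], t_aux["embedding_out"],
                              pair.W_e),
        "pred": prediction_loss(t_logits, s_logits, temperature),
    }
    attn = None
    hidn = None
    for i_student, i_teacher in pair.layer_map.items():
        a = attention_loss(s_aux["attentions"][i_student - 1],
                           t_aux["attentions"][i_teacher - 1])
        h = hidden_loss(s_aux["hiddens"][i_student - 1],
                        t_aux["hiddens"][i_teacher - 1],
                        pair.W_h[i_student - 1])
        attn = a if attn is None else attn + a
        hidn = h if hidn is None else hidn + h
    losses["attn"] = attn
    losses["hidn"] = hidn
    return losses


def distill(
    teacher: CokeModel,
    config: DistillConfig,
    kg: KnowledgeGraph,
    paths: Sequence | None = None,
) -> tuple[CokeModel, list[dict[str, float]]]:
    """Train a compact student against the frozen teacher.

    Returns the student and a per-epoch trace of the four loss terms.
    The teacher's parameters are byte-identical before and after.
    """
    pair = DistillPair.create(teacher, config)
    data = make_instances(kg.triples, paths, teacher.vocab,
                          teacher.config.max_sequence_length)
    rng = np.random.default_rng(config.seed + 1)
    opt = nn.Adam(pair.trainable(), lr=config.learning_rate)

    was_trainable = [p.requires_grad for p in teacher.parameters()]
    teacher.set_trainable(False)
    trace: list[dict[str, float]] = []
    try:
        n = len(data)
        for epoch in range(config.epochs):
            order = rng.permutation(n)
            sums = {"emb": 0.0, "attn": 0.0, "hidn": 0.0, "pred": 0.0}
            for start in range(0, n, config.batch_size):
                sub = data.take(order[start:start + config.batch_size])
                terms = distill_losses(pair, sub, config.temperature,
                                       training=True, rng=rng)
                total = (config.w_emb * terms["emb"]
                         + config.w_attn * terms["attn"]
                         + config.w_hidn * terms["hidn"]
                         + config.w_pred * terms["pred"])
                val = total.item()
                if not np.isfinite(val):
                    raise RuntimeError(f"NaN/inf distillation loss at epoch {epoch}")
                opt.zero_grad()
                total.backward()
                opt.step()
                for k in sums:
                    sums[k] += terms[k].item() * len(sub)
            trace.append({k: v / n for k, v in sums.items()})
    finally:
        for p, flag in zip(teacher.parameters(), was_trainable):
            p.requires_grad = flag
    logger.info("distilled student: final losses %s", trace[-1] if trace else {})
    return pair.student, trace
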