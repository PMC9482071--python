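"""KGE-augmented multilabel syndrome diagnosis.

Two arms share one training/evaluation pipeline:

* ``plain`` — a feedforward network on the binary symptom vector
  (the DNN comparator);
* ``kge_sequence`` — the same feedforward branch *plus* a bidirectional
  recurrent encoder over the sequence of knowledge-graph embeddings of the
  case's present symptoms (canonical sorted-symptom order, zero-padded),
  mean-pooled per direction and concatenated with the feedforward branch
  before the output layer (the DNN+BiRNN-KGE arm).

Both end in 8 sigmoid outputs trained with binary cross-entropy and
thresholded at τ for prediction.  Reporting is Hamming loss plus micro- and
macro-averaged precision/recall/F1 under stratified k-fold cross-validation
(stratified by per-case label count; metric computation delegates to
scikit-learn and is oracle-checked in the test-suite).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import hamming_loss as _sk_hamming
from sklearn.metrics import precision_recall_fscore_support as _sk_prfs
from sklearn.model_selection import StratifiedKFold

from . import nn
from .nn import Tensor, concat
from .synthetic import CaseTable

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierConfig",
    "MultilabelReport",
    "CaseFeatures",
    "build_case_features",
    "MultilabelClassifier",
    "train_classifier",
    "multilabel_metrics",
    "cross_validate",
]


@dataclass
class ClassifierConfig:
    mode: str = "kge_sequence"          # "plain" | "kge_sequence"
    hidden_size: int = 64
    hidden_layers: int = 2
    rnn_size: int = 32
    epochs: int = 150
    learning_rate: float = 3e-3
    threshold: float = 0.5
    folds: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("plain", "kge_sequence"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass
class CaseFeatures:
    """Model inputs for one case table."""
    binary: np.ndarray                    # (n, n_symptoms)
    emb_seq: np.ndarray | None = None     # (n, T, Dk) zero-padded
    seq_mask: np.ndarray | None = None    # (n, T) 1 on real steps

    def __len__(self) -> int:
        return self.binary.shape[0]

    def take(self, idx) -> "CaseFeatures":
        return CaseFeatures(
            self.binary[idx],
            None if self.emb_seq is None else self.emb_seq[idx],
            None if self.seq_mask is None else self.seq_mask[idx])


def build_case_features(cases: CaseTable, kge: dict[str, np.ndarray] | None,
                        mode: str) -> CaseFeatures:
    """Binary vectors, plus per-case symptom-embedding sequences in kge mode.

    The embedding sequence lists the case's *present* symptoms in canonical
    (sorted symptom-name) order, so the output is invariant to any
    permutation of the input's symptom columns.  A zero-symptom case gets a
    single zero ([PAD]-like) step and is flagged in the log.
    """
    x = cases.features.astype(np.float64)
    if mode == "plain":
        return CaseFeatures(binary=x)
    if kge is None:
        raise ValueError("kge_sequence mode requires an entity-embedding table")
    missing = [s for s in cases.symptom_names if s not in kge]
    if missing:
        raise ValueError(f"symptoms without a KG embedding: {missing}")

    order = np.argsort(cases.symptom_names)   # canonical symptom order
    emb = np.stack([kge[cases.symptom_names[i]] for i in order])
    present = cases.features[:, order].astype(bool)

    counts = present.sum(axis=1)
    n_empty = int((counts == 0).sum())
    if n_empty:
        logger.warning("%d cases report no symptoms; padded with a zero step",
                       n_empty)
    T = max(int(counts.max()), 1)
    D = emb.shape[1]
    n = cases.n_cases
    seq = np.zeros((n, T, D))
    mask = np.zeros((n, T))
    for i in range(n):
        idx = np.nonzero(present[i])[0]
        if idx.size == 0:
            mask[i, 0] = 1.0   # single padding step so pooling is defined
            continue
        seq[i, :idx.size] = emb[idx]
        mask[i, :idx.size] = 1.0
    return CaseFeatures(binary=x, emb_seq=seq, seq_mask=mask)


class MultilabelClassifier:
    """Feedforward (+ optional bidirectional recurrent) multilabel network."""

    def __init__(self, config: ClassifierConfig, n_features: int,
                 n_labels: int, emb_dim: int | None = None):
        self.config = config
        rng = np.random.default_rng(config.seed)

        def glorot(n_in, n_out):
            s = np.sqrt(6.0 / (n_in + n_out))
            return nn.Parameter(rng.uniform(-s, s, size=(n_in, n_out)))

        h = config.hidden_size
        p: dict[str, Tensor] = {}
        sizes = [n_features] + [h] * config.hidden_layers
        for i, (a, b) in enumerate(zip(sizes[:-1], sizes[1:])):
            p[f"ff{i}.W"], p[f"ff{i}.b"] = glorot(a, b), nn.Parameter(np.zeros(b))
        top = h
        if config.mode == "kge_sequence":
            if emb_dim is None:
                raise ValueError("emb_dim required for kge_sequence mode")
            r = config.rnn_size
            for d in ("fwd", "bwd"):
                p[f"rnn_{d}.Wx"] = glorot(emb_dim, r)
                p[f"rnn_{d}.Wh"] = glorot(r, r)
                p[f"rnn_{d}.b"] = nn.Parameter(np.zeros(r))
            top = h + 2 * r
        p["out.W"], p["out.b"] = glorot(top, n_labels), nn.Parameter(np.zeros(n_labels))
        self.params = p

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def _rnn_pool(self, seq: np.ndarray, mask: np.ndarray,
                  direction: str) -> Tensor:
        """Masked Elman recurrence; returns the masked mean of the outputs."""
        P = self.params
        B, T, _ = seq.shape
        r = self.config.rnn_size
        steps = range(T) if direction == "fwd" else range(T - 1, -1, -1)
        hstate = Tensor(np.zeros((B, r)))
        total = Tensor(np.zeros((B, r)))
        for t in steps:
            m = Tensor(mask[:, t:t + 1])
            x = Tensor(seq[:, t, :])
            new = (x @ P[f"rnn_{direction}.Wx"]
                   + hstate @ P[f"rnn_{direction}.Wh"]
                   + P[f"rnn_{direction}.b"]).tanh()
            hstate = new * m + hstate * (Tensor(1.0) - m)
            total = total + new * m
        denom = Tensor(np.maximum(mask.sum(axis=1, keepdims=True), 1.0))
        return total / denom

    def logits(self, feats: CaseFeatures) -> Tensor:
        P = self.params
        h = Tensor(feats.binary)
        for i in range(self.config.hidden_layers):
            h = (h @ P[f"ff{i}.W"] + P[f"ff{i}.b"]).relu()
        if self.config.mode == "kge_sequence":
            fwd = self._rnn_pool(feats.emb_seq, feats.seq_mask, "fwd")
            bwd = self._rnn_pool(feats.emb_seq, feats.seq_mask, "bwd")
            h = concat([h, fwd, bwd], axis=-1)
        return h @ P["out.W"] + P["out.b"]

    def predict_proba(self, feats: CaseFeatures) -> np.ndarray:
        return self.logits(feats).sigmoid().data

    def predict(self, feats: CaseFeatures) -> np.ndarray:
        return (self.predict_proba(feats) >= self.config.threshold).astype(np.int8)


def _bce(logits: Tensor, y: np.ndarray) -> Tensor:
    """Numerically stable binary cross-entropy from logits."""
    yt = Tensor(y.astype(np.float64))
    return (logits.relu() - logits * yt
            + (Tensor(1.0) + (-logits.abs()).exp()).log()).mean()


def train_classifier(feats: CaseFeatures, labels: np.ndarray,
                     config: ClassifierConfig) -> MultilabelClassifier:
    """Full-batch Adam on binary cross-entropy; deterministic under seed."""
    emb_dim = None if feats.emb_seq is None else feats.emb_seq.shape[2]
    clf = MultilabelClassifier(config, feats.binary.shape[1],
                               labels.shape[1], emb_dim)
    opt = nn.Adam(clf.parameters(), lr=config.learning_rate)
    for epoch in range(config.epochs):
        loss = _bce(clf.logits(feats), labels)
        if not np.isfinite(loss.item()):
            raise RuntimeError(f"NaN/inf classifier loss at epoch {epoch}")
        opt.zero_grad()
        loss.backward()
        opt.step()
    return clf


@dataclass
class MultilabelReport:
    hamming: float
    micro_precision: float
    micro_recall: float
    micro_f1: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    per_fold: list["MultilabelReport"] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in (
            "hamming", "micro_precision", "micro_recall", "micro_f1",
            "macro_precision", "macro_recall", "macro_f1")}


def multilabel_metrics(predicted: np.ndarray, true: np.ndarray) -> MultilabelReport:
    """Hamming loss + micro/macro P, R, F1 (zero-division counts as 0)."""
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.shape != true.shape:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {true.shape}")
    mi_p, mi_r, mi_f, _ = _sk_prfs(true, predicted, average="micro",
                                   zero_division=0)
    ma_p, ma_r, ma_f, _ = _sk_prfs(true, predicted, average="macro",
                                   zero_division=0)
    return MultilabelReport(
        hamming=float(_sk_hamming(true, predicted)),
        micro_precision=float(mi_p), micro_recall=float(mi_r),
        micro_f1=float(mi_f),
        macro_precision=float(ma_p), macro_recall=float(ma_r),
        macro_f1=float(ma_f))


def cross_validate(cases: CaseTable, config: ClassifierConfig,
                   kge: dict[str, np.ndarray] | None = None) -> MultilabelReport:
    """Stratified k-fold CV (stratified by per-case label count)."""
    if config.folds > cases.n_cases:
        raise ValueError("more folds than cases")
    feats = build_case_features(cases, kge, config.mode)
    labels = cases.labels
    strata = labels.sum(axis=1)
    skf = StratifiedKFold(n_splits=config.folds, shuffle=True,
                          random_state=config.seed)
    fold_reports: list[MultilabelReport] = []
    for train_idx, test_idx in skf.split(np.zeros(len(strata)), strata):
        clf = train_classifier(feats.take(train_idx), labels[train_idx], config)
        pred = clf.predict(feats.take(test_idx))
        fold_reports.append(multilabel_metrics(pred, labels[test_idx]))
    mean = {k: float(np.mean([getattr(r, k) for r in fold_reports]))
            for k in fold_reports[0].as_dict()}
    return MultilabelReport(per_fold=fold_reports, **mean)
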