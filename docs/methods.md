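# Methods

## The problem

Clinical knowledge in traditional-medicine practice accumulates as triples
over a typed entity space — diseases, symptoms, drugs, pathological
mechanisms, hospital departments, body parts — connected by a fixed
vocabulary of 17 directed relation types (`disease=>symptom`,
`mechanism=>department`, …; one name, `mechanism =>disease`, carries an
embedded space and is kept verbatim).  Such graphs are incomplete, and two
downstream uses depend on completing them: ranking candidate entities for
queries (h, r, ?) / (?, r, t), and supplying entity embeddings as features
to clinical prediction models (here: multilabel syndrome diagnosis from
symptom profiles).

## Causal-constraint multihop mining

A 2-hop chain a →r1→ b →r2→ c is only causal evidence when (r1, r2) is a
causally interpretable composition (drug acts on mechanism, mechanism
underlies disease).  Co-occurrence fan-outs — two edges sharing a *head* —
never chain, because chaining is directional: the tail of step i must be
the head of step i+1.  The miner enumerates all directionally chainable,
cycle-free paths up to `max_hops` (default 2: every worked clinical example
is 2-hop; longer chains reduce through left-to-right rule cascades) and
keeps only paths whose relation sequence matches a user-supplied whitelist
of ordered relation pairs.  Kept paths get a composed pseudo-relation label
(join character "-", e.g. `mechanism-treat`) and can be re-expressed as
triples (source, composed label, target).

## Contextual KG embedding (masked entity prediction)

Edges and mined paths are unified as token sequences (s, r1, …, rk, o).
Each sequence yields two instances: mask the head (predict s) or mask the
tail (predict o).  The encoder is a BERT-style post-norm transformer:

- input state: element embedding + learned positional embedding, layer-norm,
  dropout;
- L encoder layers of multi-head self-attention plus a feedforward block
  (ReLU inner activation — a desk-scale choice; the prediction head keeps
  gelu), each sublayer followed by residual + layer-norm;
- prediction: the final state at the masked position passes through a
  feedforward transform, then a softmax over the entity vocabulary whose
  projection matrix **is** the entity block of the input embedding matrix
  (weight tying), plus a per-entity bias.  Relations and special tokens are
  never candidates.

Training minimises label-smoothed cross-entropy where the *target* receives
probability ε and every incorrect entity (1−ε)/(V−1).  ε defaults to 0.8:
the formula only makes sense with the target holding the large share —
a small ε would make the target nearly the least-likely label.  Relations
inside paths are fed as their individual base tokens; composed labels are
used only for bookkeeping and path-query grouping, keeping the relation
vocabulary closed.

Optimisation choices (all in `ModelConfig`): Adam, fixed learning rate
2e-3, batch size 1024, dropout 0.1, learned positional embeddings,
float32 parameters (float64 available for gradient checking; the autodiff
layer preserves whichever dtype the parameters carry).  Defaults are
desk-scale: D = 64, L = 2, h = 4, feedforward 128.

## Knowledge distillation

A compact student is trained against a frozen teacher at three levels
(the TinyBERT recipe):

1. embedding layer: MSE between the student's embedding-layer output
   projected by a trainable W_e (d × d0) and the teacher's;
2. transformer layers, mapped in k-layer intervals (student layer i ↔
   teacher layer i·k, k = T/S, T divisible by S): per mapped layer, the
   mean over heads of the MSE between attention matrices plus the MSE
   between hidden states through a per-layer trainable projection W_h
   (per-layer rather than global projections; layer losses are summed,
   with weight knobs to renormalise);
3. prediction layer: cross-entropy between the teacher's
   temperature-softened distribution softmax(z_T/t) and the student's
   log-softmax(z_S/t) — the teacher is the target distribution.

Temperature defaults to t = 1 and is exposed in `DistillConfig`.  Teacher
and student must have equal head counts, otherwise the attention loss is
undefined.  Teacher parameters are byte-identical before and after.

## Baseline scorers

Eight classical families behind one interface (TransE/H/R/D, DistMult,
ComplEx, SimplE, RotatE), each with its canonical scoring function
(higher = more plausible) and margin-based ranking training with uniform
head-or-tail corruption (the simplest regime; configurable margin, norm,
dimension).  RotatE stores relation phases directly, so unit modulus holds
by construction; SimplE keeps two vectors per entity; ComplEx splits each
dimension into real/imaginary halves.  These are comparators, not the
contribution; they share the filtered evaluation below.

## Filtered evaluation

For each test triple both queries (h, r, ?) and (?, r, t) are scored over
all entities.  The filtered protocol removes every *other* entity known to
complete a true triple across train ∪ valid ∪ test before ranking the
target; the target itself is re-admitted as the single positive.  Ties are
broken by a uniform draw over the tie group under the run's seed —
optimistic tie-breaking is known to inflate results.  Aggregates: MRR over
all 2·|test| queries and Hits@N (N = 1, 3, 10).  Path queries
(s, r1…rk, ?) mask the terminal entity of the path sequence and filter
against all entities reachable from s via the relation path (exhaustive
traversal of the full graph).

## Synthetic study conditions

No clinical triple store of this kind is publicly deposited, so all
experiments run on a seeded generator with planted, fully book-kept
structure:

- **KG**: 6 entity types × 50 entities; base edges per relation drawn with
  Poisson out-degree `edge_density` (default 3); two compositional rules
  entirely inside the 17-relation schema
  (`disease=>mechanism` ∘ `mechanism =>disease` → `disease=>disease`;
  `symptom=>mechanism` ∘ `mechanism=>symptom` → `symptom=>symptom`);
  implied edges materialized with probability `closure_rate` (0.8), a
  `holdout_rate` (0.2) fraction withheld from training as the test set;
  5% random schema-valid noise edges, never duplicating planted or
  held-out edges.  A ledger records every implied edge with its generating
  base-edge pair(s), so path mining and link prediction can be scored
  against ground truth.
- **Cases**: 886 cases, 121 binary symptom features, 8 syndrome classes,
  2–5 labels per case.  Each syndrome owns a fixed random subset of 15
  symptoms; an active syndrome *expresses* each owned symptom with
  probability 0.7 (patients rarely show textbook-complete profiles; full
  expression makes the task trivially separable, unlike real records).
  On top, each bit is flipped with probability `noise` (default 0.1),
  implemented as replacement by a fair coin with probability 2·noise: the
  flip rate matches, while noise = 1 yields features fully independent of
  labels instead of a deterministic complement.

What the generator does **not** emulate: real co-occurrence statistics,
degree heavy tails, annotation biases, inter-annotator label noise, or
text-derived extraction errors.  Passing tests therefore demonstrate that
the algorithms recover *planted* compositional structure and that the
pipeline's pieces are internally correct — not that the models reach any
particular accuracy on real clinical graphs.

## KGE-augmented multilabel diagnosis

Two arms share one pipeline.  `plain` is a feedforward network on the
binary symptom vector.  `kge_sequence` adds a bidirectional recurrent
encoder (Elman tanh units; masked, per-direction mean pooling) over the
sequence of KG embeddings of the case's *present* symptoms in canonical
sorted-symptom order, concatenated with the feedforward branch before the
8-way sigmoid output — the "DNN + bidirectional recurrent KGE" design.
Both train with binary cross-entropy and threshold at τ = 0.5.  Symptom
embeddings come from the contextual KGE model trained on a graph linking
each syndrome to its owned symptoms.  Reporting: Hamming loss, micro and
macro precision/recall/F1 (zero-division counts as 0), stratified k-fold
cross-validation stratified by per-case label count.

## Problem sizes used by the test suite and acceptance script

The end-to-end checks train on `edge_density = 1.5` (≈1,450 training
triples, ≈30 held-out implied edges per seed) with the model at
D = 64, L = 2, h = 4, 200 epochs; the distilled student is 1 layer at
d = 32, 100 epochs; the classifier comparison uses 3-fold cross-validation
at 150 epochs per fold, 5 seeds.  Because the random-scorer MRR on a small
holdout is noisy, the chance floor is estimated as the mean over 10
random-scorer seeds.  These sizes are the package's chosen study
conditions for its own verification; the defaults above remain the
generator's reference conditions.

## Numerical and degenerate-input choices

- Autodiff runs in the parameters' dtype; gradients were verified against
  central finite differences at float64 (tolerances 1e-6 per op, 1e-3 for
  the full transformer loss).
- Layer-norm ε = 1e-5; softmax and log-softmax are max-shifted.
- Duplicate triples are dropped with a logged count; triples whose tokens
  would otherwise be unseen in training are reassigned from valid/test to
  train, because filtered ranking is undefined for never-seen tokens.
- A zero-symptom case receives a single zero embedding step (flagged in
  the log) so pooling stays defined.
- Composed path labels must not collide with base relation names (error).
- NaN/inf training loss aborts with a diagnostic rather than continuing.

## Known limitations

- Desk-scale only: embedding dimensions and graph sizes are far below
  production KGs; no GPU path.
- The distillation temperature default (t = 1) is a choice, not an
  empirically tuned value.
- Rule sets for causal filtering are user-supplied configuration; the
  package ships only the two schema-internal defaults and does not learn
  rule reliability from data.
- Baseline hyperparameters are not tuned; baselines are directional
  comparators only.
- Inverse relations are never synthesised; chains never traverse an edge
  backwards.
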