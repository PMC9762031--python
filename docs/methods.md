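# Methods

`medrec` implements a medication-recommendation pipeline for the regime
where longitudinal (multi-visit) electronic medical records are scarce but
single-visit records are plentiful. This note describes the model, the
synthetic data it is exercised on, and the numerical and design choices a
maintainer would want spelled out.

## Problem setting

A patient record is a sequence of visits; visit *t* carries three sets: ICD-10
style diagnosis codes *d_t*, 14-digit NDC-style drug codes *m_t*, and symptom
terms *s_t*. From the second visit onward, the task is multi-label
prediction of the visit's drug set from (a) the patient's earlier visits and
(b) the current visit's diagnoses and symptoms. Current drugs are the label
and are never fed to the predictor.

## Model

**Ontology-attention code embeddings.** Diagnosis and drug codes are leaves
of rooted classification trees. A leaf's embedding is computed by multi-head
graph attention over the leaf and all its ancestors on the root path: for
head *k*, a learned matrix W^k transforms the node vectors, a leaky-ReLU of a
learned linear form on (transformed leaf, transformed neighbor) scores each
pair, a softmax over the neighborhood normalizes the scores, and the head
output is the ELU of the attention-weighted sum; heads are concatenated.
Codes that share ancestry therefore share representation — the mechanism by
which the coding hierarchy's knowledge enters the model. Published
descriptions of this family leave the attention scorer and the placement of
the nonlinearity open; we adopt the standard graph-attention conventions
(leaky-ReLU pairwise scorer, per-head nonlinearity before concatenation) and
a single attention layer over the full root path.

**Visit encoder.** Each field of a visit is encoded independently by a
transformer (default 2 layers, 4 heads) over `[CLS]` plus the field's token
embeddings — ontology-attention embeddings for codes, a learned dictionary
table for symptoms, learned vectors for special tokens. No positional
encodings are used: a field is a set, so the `[CLS]`-state visit embedding is
(and is tested to be) invariant to token order and padding. Padded positions
are excluded from attention. The three field encoders share hyperparameters
but not weights (configurable), letting field semantics diverge. The
embedding width *l* defaults to 64 (32 in the desk-scale config); it is a
free parameter of this implementation.

**Pretraining (single-visit pool).** Two self-supervised objectives:

- *Masked-field recovery*: each real token is masked with probability 0.15
  (at least one per non-empty field), and the field's own visit embedding
  must recover the field's full code set via a linear-logistic head —
  multi-label binary cross entropy over the vocabulary. Absent codes
  contribute −log(1−P); the printed form of this objective in the source
  literature has a sign slip that would make it unbounded below, and its
  stated intent (binary cross entropy) is what is implemented.
- *Cross-field correlation*: each field's embedding predicts the other
  fields' code sets (six linear heads, one per ordered source→target pair).

The combined objective is the unweighted sum of the three self terms and the
three pairwise cross terms (the published combination lists one term twice;
the diagnosis–symptom term is the evident intent and is used — the reading is
recorded in the config metadata).

**Prediction head.** For target visit *t*, the features are the
concatenation of five *l*-vectors — the arithmetic means of the previous
visits' diagnosis, symptom and drug embeddings, plus the current visit's
diagnosis and symptom embeddings — mapped by one sigmoid linear layer to a
probability per drug code (the printed weight-matrix width of 3*l* is
inconsistent with the five-way concatenation it multiplies; 5*l* is used).
Drugs with probability above θ (default 0.5) are recommended. The loss is
the per-patient mean over visits 2..T of the multi-label binary cross
entropy, averaged over patients.

**FGM adversarial fine-tuning.** Each training step runs a clean pass, then
perturbs the diagnosis and drug code-embedding tables by
r_adv = −ε·g/‖g‖₂ (g = the clean loss's gradient with respect to those
tables; ε default 1.0; the sign is kept as printed in the source
formulation, with a flag for the conventional +ε), reruns the forward on the
perturbed embeddings, and applies one optimizer update on the accumulated
gradient. The two passes are weighted ½ each so that ε = 0 reproduces the
plain step exactly under any optimizer state. The perturbation is applied
functionally on the recomputed embedding tables, so stored parameters are
never touched; restoration is therefore exact by construction and asserted
bit-wise in tests.

**Alternating schedule.** Training interleaves pretraining and fine-tuning
at epoch granularity: C cycles of (k_pre pretraining epochs, k_fit
fine-tuning epochs), with ontology tables, encoders and pretraining heads
shared across phases and optimizer moments persisting per phase. The
alternation keeps the fine-tuned encoder anchored to the pretraining signal
instead of drifting (the forgetting problem). Cadence defaults: C=3 with
k_pre=5/k_fit=10 at full scale; the desk-scale config uses C=3 with
k_pre=8/k_fit=8 and a pretraining learning rate of 1e-3, sized so the
pretraining phase reaches a useful representation within the smaller budget.
The fine-tuning learning rate is 5e-4 (the method's stated setting); the
pretraining rate is unstated there and is a package default. Adam is used
throughout; batch sizes default to 64 (pretraining) and 32 patients
(fine-tuning; 8 in the desk-scale config, which at ~200 training patients
gives a usable number of optimizer steps per epoch).

## Numerical core

No deep-learning framework is used: the models run on a small reverse-mode
autodiff engine over float64 NumPy arrays (`medrec.autodiff`), implementing
exactly the operations the models need. Float64 keeps the loop-oracle
comparisons in the test suite meaningful at 1e-6..1e-9 tolerances and makes
runs bit-reproducible on a fixed BLAS. Losses are computed in logit space
(softplus form) for stability; masked softmax uses a −1e30 additive penalty
whose exponential underflows to exactly zero. Single-threaded execution
gives bitwise-identical reruns; this is asserted end-to-end in the tests.

## Synthetic data

Real corpora of this kind are private, so the package ships a generator that
emulates their published shape statistics:

- **Ontologies.** ICD-10-like diagnosis trees (chapter → 3-character
  category → leaf such as `J98.4`) and 14-digit drug codes segmented
  2/1/5/5/1 (country/category/enterprise/product/final) with an internal
  node at every boundary. Requested leaf counts exceeding the label space
  raise a capacity error.
- **Disease profiles.** Each diagnosis leaf gets a drug distribution whose
  support is seeded from one enterprise-level branch of the drug ontology
  (so the hierarchy is genuinely informative), a 1–3-term symptom
  distribution, and a persistence probability (Beta around the configured
  chronic-persistence mean of 0.7).
- **Corpora.** Single-visit records draw diagnosis counts, drug counts and
  symptom counts from truncated Poissons whose rates are calibrated by
  bisection so the *truncated* means hit the configured targets exactly
  (defaults 2.233 / 16.77 / 1.0 per single visit; 1.400 / 3.943 / 0.774 per
  multi-visit visit; 2.27 visits per multi-visit patient, capped at 8).
  Drugs and symptoms are drawn from the mixture of the active diagnoses'
  profiles plus a 5% uniform background; diagnosis popularity is Zipf-like.
  Multi-visit patients carry each diagnosis into the next visit with its
  profile persistence. Single- and multi-visit patient pools are disjoint.
  The truncated-Poisson family is a stand-in: the emulated statistics
  publish only means and maxima, not the distribution family.
- **Sparsity.** A profile's drug support size is Binomial(n_drugs, 0.05 by
  default) — with 100 drugs, about 5 drugs per diagnosis.

What the generator does *not* emulate: real co-prescription constraints,
drug–drug interactions, temporal trends, coding noise, or free-text
symptoms (terms are pre-tokenized; the delimiter-based segmenter stands in
for real-language word segmentation). Passing tests therefore demonstrate
that the pipeline recovers planted compositional structure under realistic
sparsity — not clinical validity on real records.

## Evaluation

Per-visit Jaccard |Y∩Ŷ|/|Y∪Ŷ| and F1 between the true and recommended drug
sets, averaged over all evaluated (patient, visit ≥ 2) pairs, plus PR-AUC
computed as micro-averaged average precision over all (visit, drug) pairs
(the aggregation is a package choice; the metric's source names it without
defining one). Conventions: an empty-truth/empty-prediction visit scores
Jaccard 1 (logged per occurrence); a visit with zero precision or recall
denominator contributes F1 0. The printed precision/recall definitions in
the source swap the usual denominators; F1 is invariant to the swap and the
conventional naming is used in outputs.

Baselines: per-drug L1/L2-regularized logistic regression on summed
multi-hot history features plus current diagnosis/symptom multi-hots; a
label-frequency recommender; and a per-diagnosis drug-frequency lookup used
to certify that generated corpora carry learnable signal. The ablation
harness trains the full model and the seven variants obtained by removing
knowledge enhancement (plain lookup embeddings), pretraining (random
initialization, fine-tuning only) and/or the adversarial pass, on identical
splits and seeds (asserted by fingerprinting).

## Known limitations

- The engine is CPU-bound and unbatched across patients' history lengths;
  it is sized for the desk-scale studies in `configs/`, not for
  production-scale corpora.
- Visit order is admission-sequence only; no timestamps, hence no
  time-interval modeling.
- Probabilities are not calibrated; θ is a fixed threshold.
- Drug–drug-interaction constraints and sequential decoding of drug sets
  are out of scope.
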