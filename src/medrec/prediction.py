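"""Drug-set prediction over a visit sequence, with FGM-regularized training.

For a target visit t >= 2 the model concatenates the arithmetic means of the
patient's previous diagnosis, symptom and drug visit embeddings with the
*current* visit's diagnosis and symptom embeddings (current drugs are the
label and must not leak), and maps this 5l-vector through a sigmoid linear
head to per-drug probabilities.  Training minimizes multi-label binary cross
entropy averaged over a patient's target visits, and is regularized by the
fast gradient method: a perturbation of L2 norm epsilon along the (negated)
loss gradient is added to the diagnosis and drug code embeddings, and the
gradients of the clean and perturbed passes are accumulated (each with
weight 1/2, so a zero-magnitude perturbation reproduces the plain step
exactly) before one optimizer update.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from .autodiff import Adam, Parameter, Tensor, concatenate
from .encoder import FIELDS, VisitEncoder
from .pretraining import bce_with_logits
from .records import PatientHistory, TokenizedVisit, Vocabulary, tokenize_visit


class PredictionHead:
    """Linear-sigmoid multi-label head: probabilities over the drug vocabulary.

    The weight matrix maps the 5l concatenation (three history means plus the
    current diagnosis and symptom embeddings) to one logit per drug code.
    """

    def __init__(self, width: int, n_drugs: int, rng: np.random.Generator,
                 threshold: float = 0.5, epsilon: float = 1.0,
                 positive_sign: bool = False):
        if not 0 < threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        self.width = width
        self.n_drugs = n_drugs
        self.threshold = threshold
        self.epsilon = epsilon
        self.positive_sign = positive_sign
        self.W = Parameter(rng.normal(0.0, 1.0 / np.sqrt(5 * width),
                                      size=(5 * width, n_drugs)), name="pred.W")
        self.b = Parameter(np.zeros(n_drugs), name="pred.b")

    @property
    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]

    def logits(self, features: Tensor) -> Tensor:
        if features.shape[-1] != 5 * self.width:
            raise ValueError(f"expected feature width {5 * self.width}, "
                             f"got {features.shape[-1]}")
        return features @ self.W + self.b


def aggregate_history(embeddings: Mapping[str, Tensor], t: int) -> dict[str, Tensor]:
    """Arithmetic means of each field's visit embeddings over visits < t.

    ``embeddings[f]`` is the (T, l) matrix of one patient's field-f visit
    embeddings; visits are 1-indexed, so the mean runs over rows 0..t-2.
    """
    if t < 2:
        raise ValueError("history aggregation needs t >= 2")
    return {f: embeddings[f][:t - 1, :].mean(axis=0) for f in FIELDS}


def predict_medications(history_means: Mapping[str, Tensor], current_d: Tensor,
                        current_s: Tensor, head: PredictionHead) -> Tensor:
    """Per-drug probabilities y_t for one target visit."""
    feats = concatenate([history_means["d"], history_means["s"], history_means["m"],
                         current_d, current_s], axis=-1)
    return head.logits(feats.reshape(1, -1)).sigmoid().reshape(head.n_drugs)

def recommendation_set(probabilities: np.ndarray, drug_vocab: Vocabulary,
                       threshold: float) -> frozenset[str]:
    """Drug codes whose probability exceeds the threshold (possibly empty)."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    probs = np.asarray(probabilities)
    return frozenset(drug_vocab.codes[i] for i in np.flatnonzero(probs > threshold))


def prediction_loss(probabilities: Sequence[np.ndarray] | np.ndarray,
                    truths: Sequence[np.ndarray] | np.ndarray) -> float:
    """Mean over target visits t=2..T of the multi-label BCE (reference form).

    Operates on plain probability arrays; the training loop uses the logit
    formulation for stability, which agrees with this to rounding.
    """
    probs = np.atleast_2d(np.asarray(probabilities, dtype=np.float64))
    y = np.atleast_2d(np.asarray(truths, dtype=np.float64))
    if probs.shape != y.shape:
        raise ValueError("probabilities and truths must align")
    if probs.shape[0] < 1:
        raise ValueError("need at least one target visit (T >= 2)")
    eps = 1e-12
    p = np.clip(probs, eps, 1 - eps)
    per_visit = -(y * np.log(p) + (1 - y) * np.log(1 - p)).sum(axis=1)
    return float(per_visit.mean())


def fgm_perturbation(gradient: np.ndarray, epsilon: float,
                     positive_sign: bool = False) -> np.ndarray:
    """FGM disturbance: -epsilon * g / ||g||_2 (sign flipped if requested).

    Zero gradient (or zero epsilon) gives a zero perturbation; otherwise the
    result has L2 norm exactly epsilon.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    g = np.asarray(gradient, dtype=np.float64)
    norm = np.linalg.norm(g)
    if norm == 0.0 or epsilon == 0.0:
        return np.zeros_like(g)
    sign = 1.0 if positive_sign else -1.0
    return sign * epsilon * g / norm


# -- batched training ---------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class HistoryBatch:
    """All visits of a group of patients flattened for one encoder pass.

    ``prefix`` is the (n_targets, n_visits) matrix averaging each target's
    strict history (weights 1/(t-1)); ``current`` selects the target visit
    itself; ``weights`` averages targets per patient, and ``labels`` holds
    each target's true drug multi-hot.
    """

    visits: tuple[TokenizedVisit, ...]
    prefix: np.ndarray
    current: np.ndarray
    weights: np.ndarray
    labels: np.ndarray
    truth_sets: tuple[frozenset[str], ...]

    @property
    def n_targets(self) -> int:
        return self.prefix.shape[0]


def build_history_batch(histories: Sequence[PatientHistory],
                        vocabularies: tuple[Vocabulary, Vocabulary, Vocabulary],
                        max_len: Mapping[str, int] | None = None) -> HistoryBatch:
    """Flatten patients into one batch; patients with fewer than 2 visits are
    skipped (they contribute no target visit)."""
    visits: list[TokenizedVisit] = []
    rows_prefix, rows_current, weights, labels, truths = [], [], [], [], []
    drug_vocab = vocabularies[1]
    offset = 0
    usable = [h for h in histories if h.n_visits >= 2]
    if not usable:
        raise ValueError("no patient has two or more visits")
    for hist in usable:
        T = hist.n_visits
        for v in hist.visits:
            visits.append(tokenize_visit(v, vocabularies, max_len))
        for t in range(2, T + 1):
            rows_prefix.append((offset, t - 1))
            rows_current.append(offset + t - 1)
            weights.append(1.0 / (T - 1))
            labels.append(drug_vocab.multi_hot(hist.visits[t - 1].drugs))
            truths.append(hist.visits[t - 1].drugs)
        offset += T
    n_targets = len(rows_current)
    prefix = np.zeros((n_targets, len(visits)))
    current = np.zeros((n_targets, len(visits)))
    for i, ((start, hist_len), cur) in enumerate(zip(rows_prefix, rows_current)):
        prefix[i, start:start + hist_len] = 1.0 / hist_len
        current[i, cur] = 1.0
    w = np.asarray(weights) / len(usable)
    return HistoryBatch(tuple(visits), prefix, current, w, np.stack(labels),
                        tuple(truths))


def batch_prediction_loss(encoder: VisitEncoder, head: PredictionHead,
                          batch: HistoryBatch,
                          perturbations: Mapping[str, np.ndarray] | None = None,
                          ) -> tuple[Tensor, Tensor]:
    """Forward pass on a history batch.

    Returns (loss, probabilities); the loss is the patient-averaged mean of
    per-target BCE (each patient's targets weighted 1/(T-1)).
    """
    embeds = encoder.encode_visits(list(batch.visits), perturbations)
    feats = concatenate([
        Tensor(batch.prefix) @ embeds["d"],
        Tensor(batch.prefix) @ embeds["s"],
        Tensor(batch.prefix) @ embeds["m"],
        Tensor(batch.current) @ embeds["d"],
        Tensor(batch.current) @ embeds["s"],
    ], axis=-1)
    logits = head.logits(feats)
    per_target = bce_with_logits(logits, batch.labels).sum(axis=-1)
    loss = (per_target * Tensor(batch.weights)).sum()
    return loss, logits.sigmoid()


def adversarial_step(encoder: VisitEncoder, head: PredictionHead,
                     batch: HistoryBatch, optimizer: Adam,
                     epsilon: float | None = None,
                     adversarial: bool = True) -> float:
    """One FGM training update on a batch of patient histories.

    Pass 1 runs the clean objective; the perturbations for the diagnosis and
    drug code-embedding tables are computed from its gradients; pass 2 reruns
    the forward with the perturbed code embeddings.  Both passes' gradients
    are accumulated (weight 1/2 each) and applied in a single optimizer
    update.  The perturbation is applied functionally on top of the recomputed
    embedding tables, so no stored parameter is ever modified.
    """
    eps = head.epsilon if epsilon is None else epsilon
    optimizer.zero_grad()
    if not adversarial:
        loss, _ = batch_prediction_loss(encoder, head, batch)
        if not np.isfinite(loss.data):
            raise FloatingPointError("prediction loss diverged")
        loss.backward()
        optimizer.step()
        return float(loss.data)

    loss_clean, _ = batch_prediction_loss(encoder, head, batch)
    if not np.isfinite(loss_clean.data):
        raise FloatingPointError("prediction loss diverged")
    (loss_clean * 0.5).backward()
    perturbations = {}
    for f in ("d", "m"):
        table = encoder.embedders[f].last_code_table
        g = table.grad if table is not None and table.grad is not None \
            else np.zeros(table.shape)
        perturbations[f] = fgm_perturbation(g, eps, head.positive_sign)
    loss_adv, _ = batch_prediction_loss(encoder, head, batch, perturbations)
    (loss_adv * 0.5).backward()
    optimizer.step()
    return float(0.5 * (loss_clean.data + loss_adv.data))


@dataclasses.dataclass
class FineTuneResult:
    loss_log: list[dict[str, float]]
    best_val_loss: float
    best_state: dict[str, np.ndarray]


def fine_tune(train: Sequence[PatientHistory], val: Sequence[PatientHistory],
              vocabularies: tuple[Vocabulary, Vocabulary, Vocabulary],
              encoder: VisitEncoder, head: PredictionHead,
              all_params: Sequence[Parameter], epochs: int, seed: int,
              batch_size: int = 32, lr: float = 5e-4,
              adversarial: bool = True, optimizer: Adam | None = None,
              max_len: Mapping[str, int] | None = None) -> FineTuneResult:
    """Adversarially regularized fine-tuning on the multi-visit training pool.

    Logs per-epoch training and validation loss; the parameter state with the
    best validation loss is recorded.  Deterministic given the seed.
    """
    usable = [h for h in train if h.n_visits >= 2]
    if not usable:
        raise ValueError("training set has no multi-visit patient")
    rng = np.random.default_rng(seed)
    opt = optimizer or Adam(all_params, lr=lr)
    val_batch = None
    val_usable = [h for h in val if h.n_visits >= 2]
    if val_usable:
        val_batch = build_history_batch(val_usable, vocabularies, max_len)
    from .pretraining import _state_of  # shared state snapshot helper

    log: list[dict[str, float]] = []
    best_val = np.inf
    best_state = _state_of(all_params)
    for epoch in range(epochs):
        perm = rng.permutation(len(usable))
        losses = []
        for start in range(0, len(perm), batch_size):
            group = [usable[i] for i in perm[start:start + batch_size]]
            batch = build_history_batch(group, vocabularies, max_len)
            losses.append(adversarial_step(encoder, head, batch, opt,
                                           adversarial=adversarial))
        entry = {"epoch": float(epoch), "train": float(np.mean(losses))}
        if val_batch is not None:
            val_loss, _ = batch_prediction_loss(encoder, head, val_batch)
            entry["val"] = float(val_loss.data)
        else:
            entry["val"] = entry["train"]
        if entry["val"] < best_val:
            best_val = entry["val"]
            best_state = _state_of(all_params)
        log.append(entry)
    return FineTuneResult(log, best_val, best_state)
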