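"""Self-supervised pretraining of the visit model on single-visit records.

Two objectives are combined.  The masked-field task hides a random subset of
each field's code tokens and asks the field's own visit embedding to recover
the field's full code set (multi-label binary cross entropy over the
vocabulary).  The correlation task asks each field's visit embedding to
predict the *other* fields' code sets, tying diagnoses, drugs and symptoms
together.  The total objective is the unweighted sum of the three self terms
and the three pairwise cross terms.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from .autodiff import Adam, Parameter, Tensor
from .encoder import FIELDS, VisitEncoder
from .records import TokenizedVisit, Vocabulary

#: the six prediction directions: (source field supplying the embedding,
#: target field whose code set is predicted)
HEAD_PAIRS = [(src, tgt) for src in FIELDS for tgt in FIELDS]


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Elementwise binary cross entropy from logits, numerically stable.

    softplus(z) - z*t, with softplus evaluated as relu(z) + log1p(exp(-|z|)).
    """
    t = np.asarray(targets, dtype=np.float64)
    neg_abs = -(logits.relu() + (-logits).relu())
    softplus = logits.relu() + (neg_abs.exp() + 1.0).log()
    return softplus - logits * t


@dataclasses.dataclass(frozen=True)
class MaskedVisit:
    """A tokenized visit with some code tokens replaced by [MASK].

    Targets are the *original* full code sets as multi-hot vectors over each
    vocabulary's code block; masking never alters them.
    """

    tokens: Mapping[str, np.ndarray]
    valid: Mapping[str, np.ndarray]
    mask_positions: Mapping[str, np.ndarray]
    targets: Mapping[str, np.ndarray]

    def as_tokenized(self) -> TokenizedVisit:
        return TokenizedVisit(self.tokens["d"], self.tokens["m"], self.tokens["s"],
                              dict(self.valid))


def mask_visit(visit: TokenizedVisit,
               vocabularies: tuple[Vocabulary, Vocabulary, Vocabulary],
               mask_rate: float, rng: np.random.Generator,
               mask_symptoms: bool = True) -> MaskedVisit:
    """Independently mask each real code token with probability ``mask_rate``.

    A non-empty field always gets at least one mask (if the random draw masks
    none, one position is chosen uniformly), so every visit contributes a
    recovery problem even at low rates.
    """
    if not 0 <= mask_rate <= 1:
        raise ValueError("mask_rate must be in [0, 1]")
    vocabs = dict(zip(FIELDS, vocabularies))
    tokens, valid, positions, targets = {}, {}, {}, {}
    for f in FIELDS:
        vocab = vocabs[f]
        seq = visit.field(f).copy()
        val = visit.valid[f]
        code_pos = np.flatnonzero(val[1:]) + 1  # real tokens, [CLS] excluded
        if f == "s" and not mask_symptoms:
            chosen = np.array([], dtype=np.intp)
        elif len(code_pos):
            hit = rng.random(len(code_pos)) < mask_rate
            if not hit.any():
                hit[rng.integers(len(code_pos))] = True
            chosen = code_pos[hit]
        else:
            chosen = np.array([], dtype=np.intp)
        targets[f] = vocab.multi_hot(vocab.token(i) for i in visit.field(f)[val])
        seq[chosen] = vocab.index("[MASK]")
        tokens[f] = seq
        valid[f] = val.copy()
        positions[f] = chosen
    return MaskedVisit(tokens, valid, positions, targets)


class PretrainHeads:
    """Six linear-logistic scoring heads P(code | visit embedding).

    One head per (source field, target field) pair; output dimension is the
    target vocabulary's code count (special tokens excluded).
    """

    def __init__(self, width: int, vocab_sizes: Mapping[str, int],
                 rng: np.random.Generator):
        self.W: dict[tuple[str, str], Parameter] = {}
        self.b: dict[tuple[str, str], Parameter] = {}
        for src, tgt in HEAD_PAIRS:
            self.W[(src, tgt)] = Parameter(
                rng.normal(0.0, 1.0 / np.sqrt(width), size=(width, vocab_sizes[tgt])),
                name=f"head.{src}->{tgt}.W")
            self.b[(src, tgt)] = Parameter(np.zeros(vocab_sizes[tgt]))

    @property
    def parameters(self) -> list[Parameter]:
        return [*self.W.values(), *self.b.values()]

    def logits(self, src: str, tgt: str, v: Tensor) -> Tensor:
        return v @ self.W[(src, tgt)] + self.b[(src, tgt)]


def self_prediction_loss(v: Tensor, targets: np.ndarray, heads: PretrainHeads,
                         field: str) -> Tensor:
    """Recover a field's full code set from its own (masked) visit embedding.

    Multi-label BCE summed over the vocabulary, averaged over the batch.
    """
    targets = np.atleast_2d(targets)
    logits = heads.logits(field, field, v)
    if logits.shape[-1] != targets.shape[-1]:
        raise ValueError("head output dimension does not match target vocabulary")
    return bce_with_logits(logits, targets).sum(axis=-1).mean()


def correlation_loss(v: Mapping[str, Tensor], targets: Mapping[str, np.ndarray],
                     heads: PretrainHeads) -> dict[str, Tensor]:
    """The three pairwise cross-prediction losses L_dm, L_ds, L_ms.

    Each pair's loss is the sum of the two cross directions, e.g. the
    diagnosis-drug term predicts diagnoses from the drug embedding and drugs
    from the diagnosis embedding.
    """
    def cross(src: str, tgt: str) -> Tensor:
        t = np.atleast_2d(targets[tgt])
        return bce_with_logits(heads.logits(src, tgt, v[src]), t).sum(axis=-1).mean()

    return {
        "dm": cross("m", "d") + cross("d", "m"),
        "ds": cross("s", "d") + cross("d", "s"),
        "ms": cross("s", "m") + cross("m", "s"),
    }


def pretrain_loss(components: Mapping[str, Tensor]) -> Tensor:
    """Unweighted sum of the six pretraining terms."""
    expected = ("self_d", "self_m", "self_s", "dm", "ds", "ms")
    missing = [k for k in expected if k not in components]
    if missing:
        raise ValueError(f"missing loss components: {missing}")
    total = components[expected[0]]
    for key in expected[1:]:
        total = total + components[key]
    return total


def batch_pretrain_loss(encoder: VisitEncoder, heads: PretrainHeads,
                        batch: Sequence[MaskedVisit]) -> tuple[Tensor, dict[str, float]]:
    """Forward pass of the combined objective on a masked batch."""
    embeds = encoder.encode_visits([mv.as_tokenized() for mv in batch])
    targets = {f: np.stack([mv.targets[f] for mv in batch]) for f in FIELDS}
    comps: dict[str, Tensor] = {
        f"self_{f}": self_prediction_loss(embeds[f], targets[f], heads, f)
        for f in FIELDS
    }
    comps.update(correlation_loss(embeds, targets, heads))
    total = pretrain_loss(comps)
    return total, {k: float(vv.data) for k, vv in comps.items()}


@dataclasses.dataclass
class PretrainResult:
    loss_log: list[dict[str, float]]
    best_val_loss: float
    best_state: dict[str, np.ndarray]


def _state_of(params: Sequence[Parameter]) -> dict[str, np.ndarray]:
    return {f"p{i}": p.data.copy() for i, p in enumerate(params)}


def _restore(params: Sequence[Parameter], state: Mapping[str, np.ndarray]) -> None:
    for i, p in enumerate(params):
        p.data[...] = state[f"p{i}"]


def run_pretraining(visits: Sequence[TokenizedVisit],
                    vocabularies: tuple[Vocabulary, Vocabulary, Vocabulary],
                    encoder: VisitEncoder, heads: PretrainHeads,
                    all_params: Sequence[Parameter],
                    epochs: int, seed: int,
                    mask_rate: float = 0.15, batch_size: int = 64,
                    lr: float = 5e-4, val_fraction: float = 0.1,
                    optimizer: Adam | None = None,
                    mask_symptoms: bool = True) -> PretrainResult:
    """Epochs of masked-batch optimization of the combined objective.

    A held-back fraction of the corpus is used as validation; the parameter
    state with the best validation loss is recorded.  Fully deterministic
    given the seed.
    """
    if not visits:
        raise ValueError("empty pretraining corpus")
    rng = np.random.default_rng(seed)
    n_val = int(len(visits) * val_fraction)
    order = rng.permutation(len(visits))
    val_idx, train_idx = order[:n_val], order[n_val:]
    opt = optimizer or Adam(all_params, lr=lr)
    log: list[dict[str, float]] = []
    best_val = np.inf
    best_state = _state_of(all_params)
    for epoch in range(epochs):
        perm = rng.permutation(len(train_idx))
        epoch_comps: dict[str, list[float]] = {}
        for start in range(0, len(perm), batch_size):
            idx = train_idx[perm[start:start + batch_size]]
            batch = [mask_visit(visits[i], vocabularies, mask_rate, rng,
                                mask_symptoms) for i in idx]
            opt.zero_grad()
            total, comps = batch_pretrain_loss(encoder, heads, batch)
            if not np.isfinite(total.data):
                raise FloatingPointError(f"pretraining loss diverged at epoch {epoch}")
            total.backward()
            opt.step()
            comps["total"] = float(total.data)
            for k, vv in comps.items():
                epoch_comps.setdefault(k, []).append(vv)
        entry = {"epoch": float(epoch)}
        entry.update({k: float(np.mean(vv)) for k, vv in epoch_comps.items()})
        if len(val_idx):
            val_batch = [mask_visit(visits[i], vocabularies, mask_rate,
                                    np.random.default_rng(seed + 10_000 + epoch),
                                    mask_symptoms) for i in val_idx]
            val_total, _ = batch_pretrain_loss(encoder, heads, val_batch)
            entry["val_total"] = float(val_total.data)
        else:
            entry["val_total"] = entry["total"]
        if entry["val_total"] < best_val:
            best_val = entry["val_total"]
            best_state = _state_of(all_params)
        log.append(entry)
    return PretrainResult(log, best_val, best_state)


def write_loss_log(log: Sequence[Mapping[str, float]], path) -> None:
    import csv
    from pathlib import Path

    keys = sorted({k for row in log for k in row}, key=lambda k: (k != "epoch", k))
    with Path(path).open("w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=keys)
        w.writeheader()
        for row in log:
            w.writerow(row)
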