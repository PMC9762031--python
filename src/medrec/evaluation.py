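"""Recommendation metrics, shallow baselines and the ablation harness.

Metrics follow the multi-label drug-recommendation conventions: per-visit
Jaccard between true and recommended drug sets, per-visit F1, and
micro-averaged precision-recall AUC (average precision) over all
(visit, drug) pairs, each averaged over every evaluated (patient, visit >= 2)
pair of the test split.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score

from .records import PatientHistory, build_vocabularies

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class MetricReport:
    jaccard: float
    f1: float
    pr_auc: float
    n_patients: int
    n_visits: int

    def __post_init__(self):
        for name in ("jaccard", "f1", "pr_auc"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def jaccard_score(truth_sets: Sequence[frozenset], predicted_sets: Sequence[frozenset],
                  ) -> float:
    """Mean per-visit |Y n Yhat| / |Y u Yhat|.

    A visit where both sets are empty counts as a perfect match (1.0); each
    occurrence is logged.
    """
    if len(truth_sets) != len(predicted_sets):
        raise ValueError("truth and prediction lists must have equal length")
    scores = []
    for y, yhat in zip(truth_sets, predicted_sets):
        y, yhat = frozenset(y), frozenset(yhat)
        union = y | yhat
        if not union:
            logger.info("empty-vs-empty visit scored as Jaccard 1.0")
            scores.append(1.0)
        else:
            scores.append(len(y & yhat) / len(union))
    return float(np.mean(scores))


def average_f1(truth_sets: Sequence[frozenset], predicted_sets: Sequence[frozenset],
               ) -> float:
    """Mean per-visit F1 = 2PR/(P+R); zero-denominator visits contribute 0."""
    if len(truth_sets) != len(predicted_sets):
        raise ValueError("truth and prediction lists must have equal length")
    scores = []
    for y, yhat in zip(truth_sets, predicted_sets):
        y, yhat = frozenset(y), frozenset(yhat)
        inter = len(y & yhat)
        if not y or not yhat or inter == 0:
            scores.append(0.0)
            continue
        p = inter / len(y)
        r = inter / len(yhat)
        scores.append(2 * p * r / (p + r))
    return float(np.mean(scores))


def pr_auc(probabilities: np.ndarray, truths: np.ndarray) -> float:
    """Micro-averaged average precision over all (visit, drug) pairs."""
    probs = np.atleast_2d(np.asarray(probabilities, dtype=np.float64))
    y = np.atleast_2d(np.asarray(truths))
    if probs.shape != y.shape:
        raise ValueError("probabilities and truths must align")
    flat_y = y.ravel().astype(int)
    if flat_y.sum() == 0:
        raise ValueError("PR-AUC undefined with no positive labels")
    return float(average_precision_score(flat_y, probs.ravel()))


def report_from_predictions(truth_sets, predicted_sets, probabilities, truths,
                            n_patients: int) -> MetricReport:
    return MetricReport(
        jaccard=jaccard_score(truth_sets, predicted_sets),
        f1=average_f1(truth_sets, predicted_sets),
        pr_auc=pr_auc(probabilities, truths),
        n_patients=n_patients,
        n_visits=len(truth_sets),
    )


# -- targets shared by model and baselines ------------------------------------


def _targets(histories: Sequence[PatientHistory]):
    """(history, t) pairs evaluated: every visit from the second onward."""
    out = []
    for hist in histories:
        if hist.n_visits < 2:
            logger.warning("patient %s has a single visit; skipped", hist.patient_id)
            continue
        for t in range(2, hist.n_visits + 1):
            out.append((hist, t))
    return out


# -- model evaluation ---------------------------------------------------------


def evaluate_model(encoder, head, histories: Sequence[PatientHistory],
                   vocabularies, threshold: float | None = None,
                   max_len=None) -> MetricReport:
    """Score a trained encoder+head on every visit >= 2 of each patient."""
    from .prediction import batch_prediction_loss, build_history_batch, recommendation_set

    theta = head.threshold if threshold is None else threshold
    usable = [h for h in histories if h.n_visits >= 2]
    for h in histories:
        if h.n_visits < 2:
            logger.warning("patient %s has a single visit; skipped", h.patient_id)
    batch = build_history_batch(usable, vocabularies, max_len)
    _, probs = batch_prediction_loss(encoder, head, batch)
    drug_vocab = vocabularies[1]
    predicted = [recommendation_set(row, drug_vocab, theta) for row in probs.data]
    return report_from_predictions(list(batch.truth_sets), predicted,
                                   probs.data, batch.labels, len(usable))


# -- baselines ----------------------------------------------------------------


def _baseline_features(hist: PatientHistory, t: int, vocabs) -> np.ndarray:
    dvoc, mvoc, svoc = vocabs
    prior = hist.visits[:t - 1]
    hist_vec = np.concatenate([
        sum((dvoc.multi_hot(v.diagnoses) for v in prior), np.zeros(dvoc.n_codes)),
        sum((mvoc.multi_hot(v.drugs) for v in prior), np.zeros(mvoc.n_codes)),
        sum((svoc.multi_hot(v.symptoms) for v in prior), np.zeros(svoc.n_codes)),
    ])
    cur = hist.visits[t - 1]
    return np.concatenate([hist_vec, dvoc.multi_hot(cur.diagnoses),
                           svoc.multi_hot(cur.symptoms)])


def lr_baseline(train: Sequence[PatientHistory], test: Sequence[PatientHistory],
                vocabularies=None, threshold: float = 0.5,
                penalty: str = "l2", C: float = 1.0) -> MetricReport:
    """Independent per-drug logistic classifiers on summed multi-hot features.

    Features for a target visit are the element-wise sums of the prior
    visits' diagnosis/drug/symptom multi-hot vectors plus the current visit's
    diagnosis and symptom multi-hots.  Drugs whose training labels are
    single-class get a constant predictor at the observed rate.
    """
    vocabs = vocabularies or build_vocabularies(list(train) + list(test))
    mvoc = vocabs[1]
    train_t = _targets(train)
    test_t = _targets(test)
    if not train_t or not test_t:
        raise ValueError("both splits need patients with >= 2 visits")
    X = np.stack([_baseline_features(h, t, vocabs) for h, t in train_t])
    Y = np.stack([mvoc.multi_hot(h.visits[t - 1].drugs) for h, t in train_t])
    Xte = np.stack([_baseline_features(h, t, vocabs) for h, t in test_t])
    probs = np.zeros((len(test_t), mvoc.n_codes))
    for j in range(mvoc.n_codes):
        yj = Y[:, j]
        if yj.min() == yj.max():
            probs[:, j] = yj.mean()
            continue
        kwargs = {"l1_ratio": 1.0} if penalty == "l1" else {}
        clf = LogisticRegression(C=C, solver="liblinear", max_iter=200, **kwargs)
        clf.fit(X, yj)
        probs[:, j] = clf.predict_proba(Xte)[:, 1]
    truth_sets = [h.visits[t - 1].drugs for h, t in test_t]
    predicted = [frozenset(mvoc.codes[i] for i in np.flatnonzero(row > threshold))
                 for row in probs]
    labels = np.stack([mvoc.multi_hot(s) for s in truth_sets])
    return report_from_predictions(truth_sets, predicted, probs, labels,
                                   len({h.patient_id for h, _ in test_t}))


def frequency_baseline(train: Sequence[PatientHistory],
                       test: Sequence[PatientHistory],
                       vocabularies=None, threshold: float = 0.5) -> MetricReport:
    """Label-frequency recommender: every target visit gets the same per-drug
    probability, the drug's frequency among training target visits."""
    vocabs = vocabularies or build_vocabularies(list(train) + list(test))
    mvoc = vocabs[1]
    train_t = _targets(train)
    test_t = _targets(test)
    if not train_t or not test_t:
        raise ValueError("both splits need patients with >= 2 visits")
    freq = np.mean([mvoc.multi_hot(h.visits[t - 1].drugs) for h, t in train_t], axis=0)
    probs = np.tile(freq, (len(test_t), 1))
    rec = frozenset(mvoc.codes[i] for i in np.flatnonzero(freq > threshold))
    truth_sets = [h.visits[t - 1].drugs for h, t in test_t]
    labels = np.stack([mvoc.multi_hot(s) for s in truth_sets])
    return report_from_predictions(truth_sets, [rec] * len(test_t), probs, labels,
                                   len({h.patient_id for h, _ in test_t}))


def per_diagnosis_frequency_recommender(train: Sequence[PatientHistory],
                                        test: Sequence[PatientHistory],
                                        vocabularies=None,
                                        threshold: float = 0.5) -> MetricReport:
    """Lookup recommender: per current diagnosis, the drugs' co-occurrence
    frequency in training; a target's probabilities average over its current
    diagnoses.  Used to verify the corpus carries diagnosis->drug signal."""
    vocabs = vocabularies or build_vocabularies(list(train) + list(test))
    dvoc, mvoc, _ = vocabs
    train_t = _targets(train)
    test_t = _targets(test)
    counts = np.zeros((dvoc.n_codes, mvoc.n_codes))
    seen = np.zeros(dvoc.n_codes)
    global_freq = np.zeros(mvoc.n_codes)
    for h, t in train_t:
        drug_vec = mvoc.multi_hot(h.visits[t - 1].drugs)
        global_freq += drug_vec / len(train_t)
        for d in h.visits[t - 1].diagnoses:
            if d in dvoc and dvoc.index(d) >= dvoc.n_specials:
                i = dvoc.code_position(d)
                counts[i] += drug_vec
                seen[i] += 1
    rates = np.divide(counts, seen[:, None], out=np.tile(global_freq, (dvoc.n_codes, 1)),
                      where=seen[:, None] > 0)
    probs = []
    for h, t in test_t:
        idx = [dvoc.code_position(d) for d in h.visits[t - 1].diagnoses
               if d in dvoc and dvoc.index(d) >= dvoc.n_specials and seen[dvoc.code_position(d)] > 0]
        probs.append(rates[idx].mean(axis=0) if idx else global_freq)
    probs = np.stack(probs)
    truth_sets = [h.visits[t - 1].drugs for h, t in test_t]
    predicted = [frozenset(mvoc.codes[i] for i in np.flatnonzero(row > threshold))
                 for row in probs]
    labels = np.stack([mvoc.multi_hot(s) for s in truth_sets])
    return report_from_predictions(truth_sets, predicted, probs, labels,
                                   len({h.patient_id for h, _ in test_t}))


# -- ablation harness ---------------------------------------------------------

#: the eight toggled variants: (knowledge, pretraining, adversarial)
ABLATION_VARIANTS: dict[str, tuple[bool, bool, bool]] = {
    "full": (True, True, True),
    "no_knowledge": (False, True, True),
    "no_pretrain": (True, False, True),
    "no_adversarial": (True, True, False),
    "no_knowledge_pretrain": (False, False, True),
    "no_knowledge_adversarial": (False, True, False),
    "no_pretrain_adversarial": (True, False, False),
    "all_removed": (False, False, False),
}


def ablation_suite(dataset, config, seeds: Sequence[int],
                   variants: Mapping[str, tuple[bool, bool, bool]] | None = None,
                   ) -> "object":
    """Train and score every variant on identical data and seeds.

    Returns a pandas DataFrame with one row per (variant, seed) plus the
    baselines, and per-variant loss logs attached in ``df.attrs``.  Split
    fingerprints are asserted identical across variants.
    """
    import pandas as pd

    from .orchestration import train_and_evaluate
    from .records import split_patients

    variants = dict(variants or ABLATION_VARIANTS)
    rows = []
    logs: dict[str, list] = {}
    fingerprints = set()
    for seed in seeds:
        for name, (use_k, use_p, use_a) in variants.items():
            cfg = dataclasses.replace(config, use_ontology=use_k,
                                      use_pretraining=use_p, use_adversarial=use_a)
            result = train_and_evaluate(dataset, cfg, seed)
            fingerprints.add((seed, result.split_fingerprint))
            rows.append({"variant": name, "seed": seed,
                         **result.test_report.as_dict()})
            logs[f"{name}/seed{seed}"] = result.finetune_log
        splits = split_patients(dataset.multi_visit, seed=seed)
        for bname, fn in (("lr", lr_baseline), ("frequency", frequency_baseline)):
            rep = fn(list(splits[0]) + list(splits[1]), splits[2],
                     threshold=config.threshold)
            rows.append({"variant": bname, "seed": seed, **rep.as_dict()})
    assert len({f for _, f in fingerprints}) == len(seeds), \
        "variants saw different splits"
    df = pd.DataFrame(rows)
    df.attrs["loss_logs"] = logs
    return df
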