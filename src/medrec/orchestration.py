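"""Experiment orchestration: configs, the alternating training schedule,
checkpointing, and the model/results user-facing API.

Training interleaves pretraining and fine-tuning in cycles (epoch-level
alternation) with the ontology tables, encoders and pretraining heads shared
across phases, which is what lets the fine-tune phase keep refreshing the
pretrained representation instead of forgetting it.  The user-facing surface
follows the model/results convention: build a :class:`MedicationRecommender`
from corpora, call :meth:`~MedicationRecommender.fit`, and read estimates,
diagnostics and a summary off the returned :class:`RecommenderResults`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .autodiff import Adam, Parameter
from .encoder import EncoderConfig, VisitEncoder
from .evaluation import MetricReport, evaluate_model
from .ontology import CodeOntology, GraphAttentionEmbedding
from .prediction import PredictionHead, fine_tune
from .pretraining import PretrainHeads, _restore, _state_of, run_pretraining
from .records import (PatientHistory, Vocabulary, VisitRecord,
                      build_vocabularies, split_patients, tokenize_visit)

CHECKPOINT_VERSION = 1

#: interpretation notes carried in every config (and checkpoint) so readers
#: know which readings of the published formulation this package fixes.
CONFIG_METADATA = {
    "combined_pretrain_loss":
        "sum of three self terms and the three pairwise cross terms "
        "(diagnosis-drug, diagnosis-symptom, drug-symptom)",
    "absent_code_loss": "binary cross entropy: absent codes contribute -log(1-P)",
    "prediction_feature_width": "5l: three history means + current diagnosis "
                                "and symptom embeddings",
}


@dataclasses.dataclass(frozen=True)
class ExperimentConfig:
    """Hyperparameters of the full pipeline (defaults follow the method's
    stated settings where it states them: 2 encoder layers with 4 heads,
    4 ontology-attention heads, learning rate 5e-4)."""

    width: int = 64
    layers: int = 2
    heads: int = 4
    gat_heads: int = 4
    ff_width: int | None = None
    learning_rate: float = 5e-4
    pretrain_learning_rate: float = 1e-3
    mask_rate: float = 0.15
    epsilon: float = 1.0
    threshold: float = 0.5
    cycles: int = 3
    pretrain_epochs: int = 5
    finetune_epochs: int = 10
    pretrain_batch: int = 64
    finetune_batch: int = 32
    split_ratio: tuple[int, int, int] = (4, 1, 1)
    max_len: Mapping[str, int] | None = None
    val_fraction: float = 0.1
    use_ontology: bool = True
    use_pretraining: bool = True
    use_adversarial: bool = True
    share_field_weights: bool = False
    fgm_positive_sign: bool = False
    mask_symptoms: bool = True
    max_pretrain_visits: int | None = None

    def __post_init__(self):
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        for name in ("pretrain_epochs", "finetune_epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def encoder_config(self) -> EncoderConfig:
        return EncoderConfig(width=self.width, layers=self.layers, heads=self.heads,
                             ff_width=self.ff_width, gat_heads=self.gat_heads,
                             share_field_weights=self.share_field_weights,
                             use_ontology=self.use_ontology)

    @property
    def metadata(self) -> dict[str, str]:
        return dict(CONFIG_METADATA)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["split_ratio"] = list(self.split_ratio)
        d["max_len"] = dict(self.max_len) if self.max_len else None
        d["metadata"] = self.metadata
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExperimentConfig":
        d = {k: v for k, v in d.items() if k != "metadata"}
        if "split_ratio" in d and d["split_ratio"] is not None:
            d["split_ratio"] = tuple(d["split_ratio"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with Path(path).open() as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


# -- network bundle -----------------------------------------------------------


@dataclasses.dataclass
class NetworkBundle:
    """Everything trainable, plus the fixed vocabularies and ontologies."""

    config: ExperimentConfig
    vocabularies: tuple[Vocabulary, Vocabulary, Vocabulary]
    diagnosis_ontology: CodeOntology
    drug_ontology: CodeOntology
    encoder: VisitEncoder
    pretrain_heads: PretrainHeads
    prediction_head: PredictionHead

    @property
    def parameters(self) -> list[Parameter]:
        params = list(self.encoder.parameters)
        if self.config.use_ontology:
            for emb in (self.encoder.embedders["d"], self.encoder.embedders["m"]):
                params.extend(emb.gat.parameters)
        params.extend(self.pretrain_heads.parameters)
        params.extend(self.prediction_head.parameters)
        return params

    @property
    def shared_parameters(self) -> list[Parameter]:
        """Parameters updated by the pretraining phase."""
        return [p for p in self.parameters
                if p not in self.prediction_head.parameters]


def build_network(vocabularies, diagnosis_ontology: CodeOntology,
                  drug_ontology: CodeOntology, config: ExperimentConfig,
                  seed: int) -> NetworkBundle:
    """Seeded construction of every trainable component."""
    rng = np.random.default_rng(seed)
    enc_cfg = config.encoder_config()
    diag_gat = drug_gat = None
    if config.use_ontology:
        diag_gat = GraphAttentionEmbedding(diagnosis_ontology, enc_cfg.width,
                                           config.gat_heads, rng=rng)
        drug_gat = GraphAttentionEmbedding(drug_ontology, enc_cfg.width,
                                           config.gat_heads, rng=rng)
    encoder = VisitEncoder(vocabularies, enc_cfg, rng, diag_gat, drug_gat)
    sizes = {"d": vocabularies[0].n_codes, "m": vocabularies[1].n_codes,
             "s": vocabularies[2].n_codes}
    heads = PretrainHeads(enc_cfg.width, sizes, rng)
    pred = PredictionHead(enc_cfg.width, vocabularies[1].n_codes, rng,
                          threshold=config.threshold, epsilon=config.epsilon,
                          positive_sign=config.fgm_positive_sign)
    return NetworkBundle(config, vocabularies, diagnosis_ontology, drug_ontology,
                         encoder, heads, pred)


# -- alternating schedule -----------------------------------------------------


@dataclasses.dataclass
class TrainingRun:
    network: NetworkBundle
    pretrain_log: list[dict[str, float]]
    finetune_log: list[dict[str, float]]
    best_val_loss: float
    split_fingerprint: str
    test_report: MetricReport | None = None


def _fingerprint(splits) -> str:
    h = hashlib.sha256()
    for part in splits:
        for hist in part:
            h.update(hist.patient_id.encode())
        h.update(b"|")
    return h.hexdigest()[:16]


def alternating_train(single_visit: Sequence[VisitRecord],
                      splits: tuple[Sequence[PatientHistory], ...],
                      network: NetworkBundle, seed: int) -> TrainingRun:
    """Cycles of (pretraining epochs, fine-tuning epochs) on shared parameters.

    The pretraining phase updates the ontology tables, encoders and
    pretraining heads; the fine-tuning phase additionally updates the
    prediction head.  Optimizer moments persist across cycles.  The final
    parameter state is the fine-tuning phase's best-validation state.
    """
    cfg = network.config
    train, val, test = splits
    vocabs = network.vocabularies
    pre_visits = [tokenize_visit(r, vocabs, cfg.max_len) for r in single_visit]
    if cfg.max_pretrain_visits:
        pre_visits = pre_visits[: cfg.max_pretrain_visits]
    all_params = network.parameters
    pre_opt = Adam(network.shared_parameters, lr=cfg.pretrain_learning_rate)
    fit_opt = Adam(all_params, lr=cfg.learning_rate)
    pretrain_log: list[dict[str, float]] = []
    finetune_log: list[dict[str, float]] = []
    best_val = np.inf
    best_state = _state_of(all_params)
    for cycle in range(cfg.cycles):
        if cfg.use_pretraining:
            pre = run_pretraining(
                pre_visits, vocabs, network.encoder, network.pretrain_heads,
                network.shared_parameters, epochs=cfg.pretrain_epochs,
                seed=seed + 101 * cycle, mask_rate=cfg.mask_rate,
                batch_size=cfg.pretrain_batch, lr=cfg.pretrain_learning_rate,
                val_fraction=cfg.val_fraction, optimizer=pre_opt,
                mask_symptoms=cfg.mask_symptoms)
            for row in pre.loss_log:
                pretrain_log.append({"cycle": float(cycle), **row})
        fit = fine_tune(
            train, val, vocabs, network.encoder, network.prediction_head,
            all_params, epochs=cfg.finetune_epochs, seed=seed + 211 * cycle,
            batch_size=cfg.finetune_batch, lr=cfg.learning_rate,
            adversarial=cfg.use_adversarial, optimizer=fit_opt,
            max_len=cfg.max_len)
        for row in fit.loss_log:
            finetune_log.append({"cycle": float(cycle), **row})
        if fit.best_val_loss < best_val:
            best_val = fit.best_val_loss
            best_state = fit.best_state
    _restore(all_params, best_state)
    return TrainingRun(network, pretrain_log, finetune_log, float(best_val),
                       _fingerprint(splits))


def train_and_evaluate(dataset, config: ExperimentConfig, seed: int) -> TrainingRun:
    """Split, build, train and score one model on a synthetic dataset."""
    splits = split_patients(dataset.multi_visit, seed=seed,
                            ratio=config.split_ratio)
    corpus = [PatientHistory(r.patient_id, (r,)) for r in dataset.single_visit]
    corpus += list(dataset.multi_visit)
    vocabs = build_vocabularies(corpus)
    network = build_network(vocabs, dataset.diagnosis_ontology,
                            dataset.drug_ontology, config, seed)
    run = alternating_train(dataset.single_visit, splits, network, seed)
    run.test_report = evaluate_model(network.encoder, network.prediction_head,
                                     splits[2], vocabs,
                                     threshold=config.threshold,
                                     max_len=config.max_len)
    return run


# -- checkpointing ------------------------------------------------------------


def save_checkpoint(network: NetworkBundle, path: str | Path) -> None:
    """Serialize all parameters plus the config, vocabularies and ontologies."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": network.config.to_dict(),
        "vocabularies": {
            "d": list(network.vocabularies[0].codes),
            "m": list(network.vocabularies[1].codes),
            "s": list(network.vocabularies[2].codes),
        },
        "diagnosis_parent": dict(network.diagnosis_ontology.parent),
        "drug_parent": dict(network.drug_ontology.parent),
    }
    params = network.parameters
    arrays = {f"p{i}": p.data for i, p in enumerate(params)}
    buf = io.BytesIO()
    np.savez(buf, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)
    Path(path).write_bytes(buf.getvalue())


def load_checkpoint(path: str | Path) -> NetworkBundle:
    """Restore a checkpoint; raises on version mismatch or truncation."""
    import zipfile
    try:
        with np.load(Path(path)) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            if meta.get("version") != CHECKPOINT_VERSION:
                raise ValueError(f"checkpoint version {meta.get('version')} "
                                 f"!= supported {CHECKPOINT_VERSION}")
            arrays = {k: data[k] for k in data.files if k != "meta"}
    except (OSError, ValueError, KeyError, zipfile.BadZipFile) as exc:
        if isinstance(exc, ValueError) and "checkpoint version" in str(exc):
            raise
        raise ValueError(f"unreadable or truncated checkpoint {path}") from exc
    config = ExperimentConfig.from_dict(meta["config"])
    vocabs = (Vocabulary(meta["vocabularies"]["d"]),
              Vocabulary(meta["vocabularies"]["m"]),
              Vocabulary(meta["vocabularies"]["s"]))
    diag = CodeOntology("diagnosis", meta["diagnosis_parent"])
    drug = CodeOntology("drug", meta["drug_parent"])
    network = build_network(vocabs, diag, drug, config, seed=0)
    params = network.parameters
    if len(arrays) != len(params):
        raise ValueError("checkpoint parameter count mismatch")
    for i, p in enumerate(params):
        stored = arrays[f"p{i}"]
        if stored.shape != p.data.shape:
            raise ValueError("checkpoint parameter shape mismatch")
        p.data[...] = stored
    return network


# -- model/results facade -----------------------------------------------------


class MedicationRecommender:
    """Drug-set recommendation model over longitudinal EMR corpora.

    Parameters
    ----------
    single_visit : sequence of VisitRecord
        Large single-visit pool used for self-supervised pretraining.
    multi_visit : sequence of PatientHistory
        Small longitudinal pool, split 4:1:1 by patient for fine-tuning,
        validation and testing.
    diagnosis_ontology, drug_ontology : CodeOntology
        Code trees supplying the knowledge-enhanced embeddings.
    config : ExperimentConfig, optional

    Examples
    --------
    >>> model = MedicationRecommender.from_dataset(dataset, config)
    >>> results = model.fit(seed=0)
    >>> print(results.summary())
    """

    def __init__(self, single_visit, multi_visit, diagnosis_ontology,
                 drug_ontology, config: ExperimentConfig | None = None):
        self.single_visit = list(single_visit)
        self.multi_visit = list(multi_visit)
        self.diagnosis_ontology = diagnosis_ontology
        self.drug_ontology = drug_ontology
        self.config = config or ExperimentConfig()

    @classmethod
    def from_dataset(cls, dataset, config: ExperimentConfig | None = None):
        return cls(dataset.single_visit, dataset.multi_visit,
                   dataset.diagnosis_ontology, dataset.drug_ontology, config)

    def fit(self, seed: int = 0) -> "RecommenderResults":
        """Run the alternating schedule and score the held-out test patients."""
        splits = split_patients(self.multi_visit, seed=seed,
                                ratio=self.config.split_ratio)
        corpus = [PatientHistory(r.patient_id, (r,)) for r in self.single_visit]
        corpus += list(self.multi_visit)
        vocabs = build_vocabularies(corpus)
        network = build_network(vocabs, self.diagnosis_ontology,
                                self.drug_ontology, self.config, seed)
        run = alternating_train(self.single_visit, splits, network, seed)
        report = evaluate_model(network.encoder, network.prediction_head,
                                splits[2], vocabs, threshold=self.config.threshold,
                                max_len=self.config.max_len)
        return RecommenderResults(self, network, run, report, splits, seed)


class RecommenderResults:
    """Fitted state, diagnostics and prediction interface of a recommender."""

    def __init__(self, model: MedicationRecommender, network: NetworkBundle,
                 run: TrainingRun, test_report: MetricReport, splits, seed: int):
        self.model = model
        self.network = network
        self.run = run
        self.test_report = test_report
        self.splits = splits
        self.seed = seed

    @property
    def jaccard(self) -> float:
        return self.test_report.jaccard

    @property
    def f1(self) -> float:
        return self.test_report.f1

    @property
    def pr_auc(self) -> float:
        return self.test_report.pr_auc

    def predict(self, history: PatientHistory) -> list[dict]:
        """Per-visit (t >= 2) drug probabilities and recommended sets."""
        from .prediction import (batch_prediction_loss, build_history_batch,
                                 recommendation_set)
        batch = build_history_batch([history], self.network.vocabularies,
                                    self.model.config.max_len)
        _, probs = batch_prediction_loss(self.network.encoder,
                                         self.network.prediction_head, batch)
        drug_vocab = self.network.vocabularies[1]
        out = []
        for t, row in enumerate(probs.data, start=2):
            out.append({
                "visit": t,
                "probabilities": {c: float(p) for c, p
                                  in zip(drug_vocab.codes, row)},
                "recommended": recommendation_set(
                    row, drug_vocab, self.network.prediction_head.threshold),
            })
        return out

    def save(self, path: str | Path) -> None:
        save_checkpoint(self.network, path)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Medication recommendation results",
            "=" * 49,
            f"{'seed':<30}{self.seed:>19}",
            f"{'single-visit records':<30}{len(self.model.single_visit):>19}",
            f"{'multi-visit patients':<30}{len(self.model.multi_visit):>19}",
            f"{'train/val/test patients':<30}"
            f"{'/'.join(str(len(s)) for s in self.splits):>19}",
            f"{'cycles x (pretrain, finetune)':<30}"
            f"{f'{cfg.cycles} x ({cfg.pretrain_epochs}, {cfg.finetune_epochs})':>19}",
            f"{'knowledge / pretrain / FGM':<30}"
            f"{f'{cfg.use_ontology} / {cfg.use_pretraining} / {cfg.use_adversarial}':>19}",
            "-" * 49,
            f"{'test Jaccard':<30}{self.test_report.jaccard:>19.4f}",
            f"{'test average F1':<30}{self.test_report.f1:>19.4f}",
            f"{'test PR-AUC':<30}{self.test_report.pr_auc:>19.4f}",
            f"{'evaluated visits':<30}{self.test_report.n_visits:>19}",
            f"{'best validation loss':<30}{self.run.best_val_loss:>19.4f}",
            "=" * 49,
        ]
        return "\n".join(lines)
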