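"""Shared fixtures: micro-scale synthetic data and networks.

Everything is generated programmatically and seeded; fixtures are module- or
session-scoped where construction is expensive.
"""

import numpy as np
import pytest

from medrec import ExperimentConfig, SyntheticConfig, generate_dataset
from medrec.orchestration import build_network
from medrec.records import PatientHistory, build_vocabularies


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def micro_config():
    """A corpus small enough for second-scale training tests."""
    return SyntheticConfig(n_diag_leaves=20, n_drug_leaves=40, n_symptoms=20,
                           n_single_visit_patients=300,
                           n_multi_visit_patients=60, seed=7)


@pytest.fixture(scope="session")
def micro_dataset(micro_config):
    return generate_dataset(micro_config)


@pytest.fixture(scope="session")
def micro_vocabs(micro_dataset):
    corpus = [PatientHistory(r.patient_id, (r,)) for r in micro_dataset.single_visit]
    corpus += list(micro_dataset.multi_visit)
    return build_vocabularies(corpus)


@pytest.fixture(scope="session")
def micro_experiment():
    return ExperimentConfig(width=16, layers=1, heads=2, gat_heads=2,
                            cycles=1, pretrain_epochs=2, finetune_epochs=3,
                            max_len={"d": 8, "m": 16, "s": 4})


@pytest.fixture()
def micro_network(micro_dataset, micro_vocabs, micro_experiment):
    return build_network(micro_vocabs, micro_dataset.diagnosis_ontology,
                         micro_dataset.drug_ontology, micro_experiment, seed=5)
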