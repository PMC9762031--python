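"""The synthetic-EMR generator: label grammars, shape statistics, determinism,
and the presence of learnable diagnosis->drug signal."""

import dataclasses
import re

import numpy as np
import pytest

from medrec.ontology import ancestor_set
from medrec.records import write_emr_table, PatientHistory
from medrec.synthetic import (CapacityError, DiseaseProfile, SyntheticConfig,
                              corpus_summary, generate_dataset,
                              generate_disease_profiles,
                              generate_multi_visit_corpus, generate_ontology,
                              generate_single_visit_corpus, ndc_segments,
                              symptom_dictionary)


@pytest.fixture(scope="module")
def base_config():
    return SyntheticConfig(n_diag_leaves=30, n_drug_leaves=60, n_symptoms=25,
                           n_single_visit_patients=500,
                           n_multi_visit_patients=120, seed=42)


@pytest.fixture(scope="module")
def ontologies(base_config):
    rng = np.random.default_rng(0)
    return {"diagnosis": generate_ontology("diagnosis", base_config, rng),
            "drug": generate_ontology("drug", base_config, rng)}


class TestOntologyGeneration:
    def test_diagnosis_labels_follow_icd10_grammar(self, ontologies):
        onto = ontologies["diagnosis"]
        for leaf in onto.leaves:
            assert re.fullmatch(r"[A-Z]\d{2}\.\d", leaf)
            assert onto.parent[leaf] == leaf[:3]          # J98.4 under J98
            assert onto.parent[leaf[:3]] == leaf[0]       # J98 under chapter J

    def test_drug_labels_are_14_digits_with_segment_nodes(self, ontologies):
        onto = ontologies["drug"]
        for leaf in onto.leaves:
            country, category, enterprise, product, final = ndc_segments(leaf)
            assert (country, len(category), len(enterprise), len(product),
                    len(final)) == ("86", 1, 5, 5, 1)
            # parent chain: leaf -> product -> enterprise -> category -> country
            path = ancestor_set(onto, leaf)
            assert path[1] == leaf[:13]
            assert path[2] == leaf[:8]
            assert path[3] == leaf[:3]
            assert path[4] == leaf[:2]

    def test_example_code_segments(self):
        assert ndc_segments("86900450000011") == ("86", "9", "00450", "00001", "1")

    def test_requested_leaf_counts_are_exact(self, ontologies, base_config):
        assert len(ontologies["diagnosis"].leaves) == base_config.n_diag_leaves
        assert len(ontologies["drug"].leaves) == base_config.n_drug_leaves

    def test_single_leaf_tree_is_a_path(self):
        cfg = SyntheticConfig(n_diag_leaves=1, n_drug_leaves=1)
        onto = generate_ontology("diagnosis", cfg, np.random.default_rng(0))
        assert len(onto.leaves) == 1
        path = ancestor_set(onto, onto.leaves[0])
        assert path[-1] == onto.root
        assert len(path) == onto.n_nodes

    def test_capacity_error_on_oversized_request(self):
        cfg = dataclasses.replace(SyntheticConfig(), n_diag_leaves=30_000)
        with pytest.raises(CapacityError):
            generate_ontology("diagnosis", cfg, np.random.default_rng(0))


class TestDiseaseProfiles:
    def test_single_drug_forces_unit_weight(self):
        cfg = SyntheticConfig(n_diag_leaves=3, n_drug_leaves=1,
                              profile_sparsity=1.0)
        rng = np.random.default_rng(1)
        onts = {"diagnosis": generate_ontology("diagnosis", cfg, rng),
                "drug": generate_ontology("drug", cfg, rng)}
        profiles = generate_disease_profiles(onts, cfg, rng)
        for p in profiles.values():
            assert list(p.drug_distribution.values()) == [1.0]

    def test_same_seed_gives_identical_profiles(self, base_config, ontologies):
        p1 = generate_disease_profiles(ontologies, base_config,
                                       np.random.default_rng(9))
        p2 = generate_disease_profiles(ontologies, base_config,
                                       np.random.default_rng(9))
        assert p1 == p2

    def test_mean_support_size_tracks_sparsity(self):
        cfg = SyntheticConfig(n_diag_leaves=1000, n_drug_leaves=100,
                              profile_sparsity=0.1)
        rng = np.random.default_rng(2)
        onts = {"diagnosis": generate_ontology("diagnosis", cfg, rng),
                "drug": generate_ontology("drug", cfg, rng)}
        profiles = generate_disease_profiles(onts, cfg, rng)
        sizes = [len(p.drug_distribution) for p in profiles.values()]
        assert abs(np.mean(sizes) - 10) < 1.0  # ~Binomial(100, 0.1) mean

    def test_distributions_validate(self):
        with pytest.raises(ValueError):
            DiseaseProfile("J00.0", {}, {"fever": 1.0}, 0.5)
        with pytest.raises(ValueError):
            DiseaseProfile("J00.0", {"n": 0.7}, {}, 0.5)


class TestCorpora:
    def test_single_visit_means_near_targets(self):
        cfg = SyntheticConfig(n_diag_leaves=100, n_drug_leaves=200,
                              n_symptoms=60, n_single_visit_patients=10_000,
                              n_multi_visit_patients=0, seed=5)
        ds = generate_dataset(cfg)
        s = corpus_summary(ds.single_visit)
        assert abs(s.avg_diagnoses - 2.233) / 2.233 < 0.10
        assert abs(s.avg_drugs - 16.77) / 16.77 < 0.10
        assert abs(s.avg_symptoms - 1.0) < 0.10

    def test_multi_visit_mean_visits_near_target(self):
        cfg = SyntheticConfig(n_diag_leaves=50, n_drug_leaves=100,
                              n_symptoms=30, n_single_visit_patients=0,
                              n_multi_visit_patients=1000, seed=6)
        ds = generate_dataset(cfg)
        m = corpus_summary(ds.multi_visit)
        assert abs(m.avg_visits - 2.27) / 2.27 < 0.10
        assert m.max_visits <= cfg.max_visits
        assert min(h.n_visits for h in ds.multi_visit) >= 2

    def test_every_record_has_diagnosis_and_drug(self, base_config):
        ds = generate_dataset(base_config)
        for r in ds.single_visit:
            assert r.diagnoses and r.drugs
        for h in ds.multi_visit:
            for v in h.visits:
                assert v.diagnoses and v.drugs

    def test_emitted_codes_are_ontology_leaves_and_dictionary_terms(self, base_config):
        ds = generate_dataset(base_config)
        diag_leaves = set(ds.diagnosis_ontology.leaves)
        drug_leaves = set(ds.drug_ontology.leaves)
        terms = set(ds.symptoms)
        visits = list(ds.single_visit) + [v for h in ds.multi_visit for v in h.visits]
        for v in visits:
            assert v.diagnoses <= diag_leaves
            assert v.drugs <= drug_leaves
            assert v.symptoms <= terms

    def test_zero_patients_give_empty_corpora(self):
        cfg = SyntheticConfig(n_diag_leaves=5, n_drug_leaves=10,
                              n_single_visit_patients=0,
                              n_multi_visit_patients=0)
        ds = generate_dataset(cfg)
        assert ds.single_visit == [] and ds.multi_visit == []

    def test_empty_profiles_rejected(self, base_config):
        with pytest.raises(ValueError):
            generate_single_visit_corpus({}, base_config, np.random.default_rng(0))
        with pytest.raises(ValueError):
            generate_multi_visit_corpus({}, base_config, np.random.default_rng(0))

    def test_visit_distribution_below_two_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(visit_count_distribution={1: 0.5, 2: 0.5})

    def test_full_persistence_repeats_the_diagnosis_set(self):
        cfg = SyntheticConfig(n_diag_leaves=1, n_drug_leaves=10,
                              chronic_persistence=1.0,
                              n_multi_visit_patients=20,
                              n_single_visit_patients=0, seed=3)
        ds = generate_dataset(cfg)
        for h in ds.multi_visit:
            sets = {v.diagnoses for v in h.visits}
            assert len(sets) == 1

    def test_patient_ids_shared_and_admissions_increase(self, base_config):
        ds = generate_dataset(base_config)
        for h in ds.multi_visit:
            assert all(v.patient_id == h.patient_id for v in h.visits)
            admissions = [v.admission_id for v in h.visits]
            assert admissions == sorted(admissions)
        singles = [r.patient_id for r in ds.single_visit]
        assert len(set(singles)) == len(singles)

    def test_byte_identical_corpora_for_identical_config(self, base_config,
                                                         tmp_path):
        paths = []
        for i, ds in enumerate((generate_dataset(base_config),
                                generate_dataset(base_config))):
            p = tmp_path / f"run{i}.csv"
            write_emr_table(ds.multi_visit, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]


class TestSummary:
    def test_counts_on_a_tiny_handmade_corpus(self):
        from medrec.records import VisitRecord
        v = VisitRecord("p", "a", frozenset("ABC"), frozenset("x"), frozenset())
        s = corpus_summary([v])
        assert (s.avg_diagnoses, s.max_diagnoses, s.avg_visits) == (3.0, 3, 1.0)
        h1 = PatientHistory("q", tuple(
            VisitRecord("q", f"b{i}", frozenset("A"), frozenset("x"), frozenset())
            for i in range(2)))
        h2 = PatientHistory("r", tuple(
            VisitRecord("r", f"c{i}", frozenset("A"), frozenset("x"), frozenset())
            for i in range(4)))
        s2 = corpus_summary([h1, h2])
        assert (s2.avg_visits, s2.max_visits) == (3.0, 4)

    def test_summary_matches_brute_force_recount(self, base_config):
        ds = generate_dataset(base_config)
        s = corpus_summary(ds.multi_visit)
        visits = [v for h in ds.multi_visit for v in h.visits]
        assert s.n_records == len(visits)
        assert s.avg_drugs == pytest.approx(
            sum(len(v.drugs) for v in visits) / len(visits))
        assert s.n_drug_codes == len({d for v in visits for d in v.drugs})
        assert s.max_symptoms == max(len(v.symptoms) for v in visits)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            corpus_summary([])

    def test_dictionary_is_deterministic_and_sized(self):
        assert symptom_dictionary(10) == symptom_dictionary(10)
        assert len(symptom_dictionary(137)) == 137
        assert len(set(symptom_dictionary(137))) == 137
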