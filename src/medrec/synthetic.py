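"""Synthetic EMR corpora with ontology-structured diagnosis->drug signal.

Real longitudinal EMR corpora of the kind this package targets are private,
so this module generates stand-in data with the statistical shape the method
assumes: a large single-visit pool (for pretraining) and a small multi-visit
pool (for fine-tuning), ICD-10-style and 14-digit NDC-style code ontologies,
and per-diagnosis "disease profiles" that give the corpus a learnable
diagnosis -> drug/symptom structure.  Drug weights within a profile
concentrate on one branch of the drug ontology, so the code hierarchy is
genuinely informative for the embedding model.

Count distributions are truncated Poissons whose rate is calibrated so the
*truncated* mean hits the configured target exactly.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .ontology import CodeOntology, ancestor_set
from .records import PatientHistory, VisitRecord, write_emr_table


class CapacityError(ValueError):
    """Requested more leaves than the label space can hold."""


@dataclasses.dataclass(frozen=True)
class FieldCounts:
    """Per-visit count model for one field: target mean and truncation range."""

    mean: float
    max_count: int
    min_count: int = 1

    def __post_init__(self):
        if not (self.min_count <= self.mean <= self.max_count):
            raise ValueError(f"mean {self.mean} outside [{self.min_count}, {self.max_count}]")


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    """Shape parameters of the synthetic EMR study population.

    Defaults follow the corpus statistics the generator emulates: per
    single-visit record about 2.23 diagnosis codes, 16.77 drug codes and
    1.0 symptom; per multi-visit patient about 1.40 diagnoses, 3.94 drugs
    and 0.774 symptoms per visit and 2.27 visits on average (8 at most).
    Vocabulary and population sizes default to a desk-scale corpus roughly
    one tenth of the motivating dataset.
    """

    n_diag_leaves: int = 400
    n_drug_leaves: int = 1000
    n_symptoms: int = 150
    n_single_visit_patients: int = 20000
    n_multi_visit_patients: int = 1000
    visit_count_distribution: Mapping[int, float] | None = None
    single_visit_counts: Mapping[str, FieldCounts] = dataclasses.field(
        default_factory=lambda: {
            "diagnoses": FieldCounts(2.233, 26),
            "drugs": FieldCounts(16.77, 34),
            "symptoms": FieldCounts(1.0, 2, 0),
        })
    multi_visit_counts: Mapping[str, FieldCounts] = dataclasses.field(
        default_factory=lambda: {
            "diagnoses": FieldCounts(1.400, 30),
            "drugs": FieldCounts(3.943, 69),
            "symptoms": FieldCounts(0.774, 7, 0),
        })
    mean_visits: float = 2.27
    max_visits: int = 8
    profile_sparsity: float = 0.05
    chronic_persistence: float = 0.7
    background_drug_weight: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("n_diag_leaves", "n_drug_leaves", "n_symptoms"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_single_visit_patients < 0 or self.n_multi_visit_patients < 0:
            raise ValueError("patient counts must be non-negative")
        if not 0 < self.profile_sparsity <= 1:
            raise ValueError("profile_sparsity must be in (0, 1]")
        for name in ("chronic_persistence", "background_drug_weight"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.visit_count_distribution is not None:
            dist = dict(self.visit_count_distribution)
            if any(k < 2 for k in dist):
                raise ValueError("multi-visit patients need at least 2 visits; "
                                 "visit_count_distribution has mass below 2")
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError("visit_count_distribution must sum to 1")

    def resolved_visit_distribution(self) -> dict[int, float]:
        if self.visit_count_distribution is not None:
            return dict(self.visit_count_distribution)
        pmf = _truncated_poisson_pmf(self.mean_visits, 2, self.max_visits)
        return {k: float(p) for k, p in zip(range(2, self.max_visits + 1), pmf)}


@dataclasses.dataclass(frozen=True)
class DiseaseProfile:
    """What one diagnosis implies: drug and symptom distributions, persistence."""

    diagnosis_leaf: str
    drug_distribution: Mapping[str, float]
    symptom_distribution: Mapping[str, float]
    persistence: float

    def __post_init__(self):
        for dist, label in ((self.drug_distribution, "drug"),
                            (self.symptom_distribution, "symptom")):
            total = sum(dist.values())
            if dist and (any(w < 0 for w in dist.values()) or abs(total - 1.0) > 1e-9):
                raise ValueError(f"{label} distribution must be non-negative and sum to 1")
        if not self.drug_distribution:
            raise ValueError("profile needs at least one nonzero drug weight")
        if not 0 <= self.persistence <= 1:
            raise ValueError("persistence must be a probability")


# -- truncated Poisson calibration -------------------------------------------

_PMF_CACHE: dict[tuple[float, int, int], np.ndarray] = {}


def _poisson_pmf_range(lam: float, low: int, high: int) -> np.ndarray:
    k = np.arange(low, high + 1)
    logp = k * math.log(lam) - lam - np.array([math.lgamma(x + 1) for x in k])
    p = np.exp(logp)
    return p / p.sum()


def _truncated_poisson_pmf(target_mean: float, low: int, high: int) -> np.ndarray:
    """PMF on {low..high} of a Poisson truncated to that range, with the rate
    calibrated (by bisection) so the truncated mean equals ``target_mean``."""
    key = (round(target_mean, 9), low, high)
    if key in _PMF_CACHE:
        return _PMF_CACHE[key]
    if high == low:
        pmf = np.array([1.0])
        _PMF_CACHE[key] = pmf
        return pmf
    if not low < target_mean < high:
        if target_mean == low:
            pmf = np.zeros(high - low + 1)
            pmf[0] = 1.0
            _PMF_CACHE[key] = pmf
            return pmf
        raise ValueError(f"target mean {target_mean} not attainable on [{low}, {high}]")

    def trunc_mean(lam: float) -> float:
        pmf = _poisson_pmf_range(lam, low, high)
        return float(np.arange(low, high + 1) @ pmf)

    lo, hi = 1e-9, float(high * 3 + 10)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if trunc_mean(mid) < target_mean:
            lo = mid
        else:
            hi = mid
    pmf = _poisson_pmf_range(0.5 * (lo + hi), low, high)
    _PMF_CACHE[key] = pmf
    return pmf


def _sample_count(rng: np.random.Generator, counts: FieldCounts) -> int:
    pmf = _truncated_poisson_pmf(counts.mean, counts.min_count, counts.max_count)
    return int(rng.choice(np.arange(counts.min_count, counts.max_count + 1), p=pmf))


# -- ontology generation ------------------------------------------------------

_DIAG_ROOT = "ICD10-ROOT"
_DRUG_ROOT = "NDC-ROOT"
_CHAPTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def generate_ontology(kind: str, config: SyntheticConfig,
                      rng: np.random.Generator) -> CodeOntology:
    """Generate a diagnosis or drug code tree with the requested leaf count.

    Diagnosis leaves look like ``J98.4`` with parent ``J98`` and grandparent
    chapter ``J``; drug leaves are 14-digit strings segmented 2/1/5/5/1
    (country / category / enterprise / product / final) with an internal node
    at every segment boundary.
    """
    if kind == "diagnosis":
        return _generate_diag_ontology(config.n_diag_leaves, rng)
    if kind == "drug":
        return _generate_drug_ontology(config.n_drug_leaves, rng)
    raise ValueError(f"unknown ontology kind {kind!r}")


def _generate_diag_ontology(n_leaves: int, rng: np.random.Generator) -> CodeOntology:
    if n_leaves < 1:
        raise ValueError("need at least one leaf")
    if n_leaves > 26 * 100 * 10:
        raise CapacityError(f"{n_leaves} leaves exceed the letter+2-digit+.digit space")
    edges: list[tuple[str, str]] = []
    leaves_made = 0
    chapter_i = category_i = 0
    while leaves_made < n_leaves:
        chapter = _CHAPTERS[chapter_i]
        category = f"{chapter}{category_i:02d}"
        edges.append((_DIAG_ROOT, chapter))
        edges.append((chapter, category))
        per_cat = int(rng.integers(2, 7))  # a handful of sibling leaves per category
        for sub in range(min(per_cat, n_leaves - leaves_made, 10)):
            edges.append((category, f"{category}.{sub}"))
            leaves_made += 1
        category_i += 1
        if category_i == 100:
            category_i = 0
            chapter_i += 1
    # drop duplicate edges while keeping order
    seen = set()
    uniq = [e for e in edges if not (e in seen or seen.add(e))]
    return CodeOntology.from_edges("diagnosis", uniq)


def _generate_drug_ontology(n_leaves: int, rng: np.random.Generator) -> CodeOntology:
    if n_leaves < 1:
        raise ValueError("need at least one leaf")
    capacity = 10 * 100000 * 100000 * 10
    if n_leaves > capacity:
        raise CapacityError(f"{n_leaves} leaves exceed the 14-digit label space")
    edges: list[tuple[str, str]] = []
    country = "86"
    edges.append((_DRUG_ROOT, country))
    leaves_made = 0
    category_i = 1
    enterprise_i = 1
    while leaves_made < n_leaves:
        if category_i > 9:
            raise CapacityError("exhausted drug category digits")
        category = f"{country}{category_i}"
        edges.append((country, category))
        # ~40 enterprises per category keeps branches a useful size
        for _ in range(40):
            if leaves_made >= n_leaves:
                break
            enterprise = f"{category}{enterprise_i:05d}"
            enterprise_i += 1
            if enterprise_i > 99999:
                raise CapacityError("exhausted enterprise identifiers")
            edges.append((category, enterprise))
            n_products = int(rng.integers(3, 9))
            for prod in range(1, n_products + 1):
                if leaves_made >= n_leaves:
                    break
                product = f"{enterprise}{prod:05d}"
                edges.append((enterprise, product))
                n_final = int(rng.integers(1, 3))
                for final in range(1, n_final + 1):
                    if leaves_made >= n_leaves:
                        break
                    edges.append((product, f"{product}{final}"))
                    leaves_made += 1
        category_i += 1
    return CodeOntology.from_edges("drug", edges)


def ndc_segments(code: str) -> tuple[str, str, str, str, str]:
    """Split a 14-digit drug code into country/category/enterprise/product/final."""
    if len(code) != 14 or not code.isdigit():
        raise ValueError(f"{code!r} is not a 14-digit drug code")
    return code[:2], code[2], code[3:8], code[8:13], code[13]


# -- symptom dictionary -------------------------------------------------------

_BASE_SYMPTOMS = [
    "fever", "cough", "headache", "dizziness", "fatigue", "nausea", "vomiting",
    "diarrhea", "constipation", "dyspnea", "wheezing", "palpitations",
    "chest-pain", "back-pain", "joint-pain", "abdominal-pain", "sore-throat",
    "rash", "itching", "edema", "insomnia", "anorexia", "weight-loss",
    "night-sweats", "chills", "hemoptysis", "dysuria", "polyuria", "thirst",
    "blurred-vision", "tinnitus", "numbness", "tremor", "weakness",
    "confusion", "anxiety", "depression-mood", "syncope", "epistaxis",
    "hoarseness", "dysphagia", "heartburn", "bloating", "cramping",
    "stiffness", "swelling", "bruising", "paleness",
]


def symptom_dictionary(n_symptoms: int) -> tuple[str, ...]:
    """A deterministic dictionary of pre-tokenized symptom terms."""
    terms = list(_BASE_SYMPTOMS)
    i = 1
    while len(terms) < n_symptoms:
        terms.append(f"{_BASE_SYMPTOMS[(i - 1) % len(_BASE_SYMPTOMS)]}-{i // len(_BASE_SYMPTOMS) + 2}")
        i += 1
    return tuple(terms[:n_symptoms])


# -- disease profiles ---------------------------------------------------------


def generate_disease_profiles(ontologies: Mapping[str, CodeOntology],
                              config: SyntheticConfig,
                              rng: np.random.Generator) -> dict[str, DiseaseProfile]:
    """One profile per diagnosis leaf.

    Drug support is seeded from a single branch (enterprise subtree) of the
    drug ontology and topped up from the rest, so drugs under a common branch
    receive correlated weights across profiles.
    """
    diag = ontologies["diagnosis"]
    drug = ontologies["drug"]
    drug_leaves = list(drug.leaves)
    symptoms = symptom_dictionary(config.n_symptoms)
    # leaves grouped by their enterprise-level ancestor (depth: leaf,product,enterprise,...)
    branch_of: dict[str, list[str]] = {}
    for leaf in drug_leaves:
        path = ancestor_set(drug, leaf)
        anchor = path[2] if len(path) > 2 else path[-1]
        branch_of.setdefault(anchor, []).append(leaf)
    branches = [sorted(v) for _, v in sorted(branch_of.items())]

    profiles: dict[str, DiseaseProfile] = {}
    for leaf in diag.leaves:
        k = max(1, int(rng.binomial(len(drug_leaves), config.profile_sparsity)))
        support: list[str] = []
        branch = branches[int(rng.integers(len(branches)))]
        take = min(k, len(branch))
        support.extend(rng.choice(branch, size=take, replace=False).tolist())
        if len(support) < k:
            rest = sorted(set(drug_leaves) - set(support))
            extra = rng.choice(rest, size=min(k - len(support), len(rest)), replace=False)
            support.extend(extra.tolist())
        weights = rng.dirichlet(np.full(len(support), 2.0))
        weights = weights / weights.sum()
        n_sym = int(rng.integers(1, 4))
        sym_support = rng.choice(len(symptoms), size=min(n_sym, len(symptoms)),
                                 replace=False)
        sym_weights = rng.dirichlet(np.full(len(sym_support), 2.0))
        sym_weights = sym_weights / sym_weights.sum()
        if config.chronic_persistence in (0.0, 1.0):
            persistence = config.chronic_persistence
        else:
            conc = 10.0
            persistence = float(rng.beta(config.chronic_persistence * conc,
                                         (1 - config.chronic_persistence) * conc))
        profiles[leaf] = DiseaseProfile(
            diagnosis_leaf=leaf,
            drug_distribution={d: float(w) for d, w in zip(support, weights)},
            symptom_distribution={symptoms[i]: float(w)
                                  for i, w in zip(sym_support, sym_weights)},
            persistence=persistence,
        )
    return profiles


def _popularity(leaves: Sequence[str], alpha: float = 0.7) -> np.ndarray:
    """Zipf-like diagnosis popularity, deterministic in sorted-label order."""
    ranks = np.arange(1, len(leaves) + 1, dtype=np.float64)
    w = ranks ** -alpha
    return w / w.sum()


def _mixture(dists: Sequence[Mapping[str, float]], universe: Sequence[str],
             background: float) -> np.ndarray:
    index = {c: i for i, c in enumerate(universe)}
    mix = np.zeros(len(universe))
    for dist in dists:
        for code, w in dist.items():
            mix[index[code]] += w / len(dists)
    mix = (1 - background) * mix + background / len(universe)
    return mix / mix.sum()


def _sample_set(rng: np.random.Generator, universe: Sequence[str],
                probs: np.ndarray, size: int) -> frozenset[str]:
    size = min(size, int(np.count_nonzero(probs)))
    if size == 0:
        return frozenset()
    picks = rng.choice(len(universe), size=size, replace=False, p=probs)
    return frozenset(universe[i] for i in picks)


def _draw_visit_fields(rng, profiles, active_diags, drug_universe, symptoms,
                       counts, background):
    active = [profiles[d] for d in sorted(active_diags)]
    drug_mix = _mixture([p.drug_distribution for p in active], drug_universe, background)
    n_drugs = max(1, _sample_count(rng, counts["drugs"]))
    drugs = _sample_set(rng, drug_universe, drug_mix, n_drugs)
    sym_mix = _mixture([p.symptom_distribution for p in active], symptoms, background)
    n_sym = _sample_count(rng, counts["symptoms"])
    syms = _sample_set(rng, symptoms, sym_mix, n_sym)
    return drugs, syms


def generate_single_visit_corpus(profiles: Mapping[str, DiseaseProfile],
                                 config: SyntheticConfig,
                                 rng: np.random.Generator) -> list[VisitRecord]:
    """The large pretraining pool: one visit per patient."""
    if not profiles:
        raise ValueError("profile map is empty")
    diag_leaves = sorted(profiles)
    pop = _popularity(diag_leaves)
    drug_universe = sorted({d for p in profiles.values() for d in p.drug_distribution})
    symptoms = symptom_dictionary(config.n_symptoms)
    records = []
    for i in range(config.n_single_visit_patients):
        n_diag = _sample_count(rng, config.single_visit_counts["diagnoses"])
        diags = _sample_set(rng, diag_leaves, pop, max(1, n_diag))
        drugs, syms = _draw_visit_fields(
            rng, profiles, diags, drug_universe, symptoms,
            config.single_visit_counts, config.background_drug_weight)
        records.append(VisitRecord(
            patient_id=f"S{i:06d}", admission_id=f"SA{i:06d}",
            diagnoses=diags, drugs=drugs, symptoms=syms))
    return records


def generate_multi_visit_corpus(profiles: Mapping[str, DiseaseProfile],
                                config: SyntheticConfig,
                                rng: np.random.Generator) -> list[PatientHistory]:
    """The small longitudinal pool: >=2 visits per patient, with chronic
    diagnoses recurring across visits so history carries predictive value."""
    if not profiles:
        raise ValueError("profile map is empty")
    dist = config.resolved_visit_distribution()
    ks = sorted(dist)
    pvals = np.array([dist[k] for k in ks])
    diag_leaves = sorted(profiles)
    pop = _popularity(diag_leaves)
    drug_universe = sorted({d for p in profiles.values() for d in p.drug_distribution})
    symptoms = symptom_dictionary(config.n_symptoms)
    histories = []
    for i in range(config.n_multi_visit_patients):
        pid = f"M{i:05d}"
        n_visits = int(rng.choice(ks, p=pvals))
        visits: list[VisitRecord] = []
        current: frozenset[str] = frozenset()
        for t in range(n_visits):
            if t == 0:
                n_diag = max(1, _sample_count(rng, config.multi_visit_counts["diagnoses"]))
                current = _sample_set(rng, diag_leaves, pop, n_diag)
            else:
                kept = frozenset(d for d in sorted(current)
                                 if rng.random() < profiles[d].persistence)
                n_diag = max(1, _sample_count(rng, config.multi_visit_counts["diagnoses"]))
                fresh_needed = max(0, n_diag - len(kept))
                fresh = _sample_set(rng, diag_leaves, pop, fresh_needed) if fresh_needed else frozenset()
                current = kept | fresh
                if not current:
                    current = _sample_set(rng, diag_leaves, pop, 1)
            drugs, syms = _draw_visit_fields(
                rng, profiles, current, drug_universe, symptoms,
                config.multi_visit_counts, config.background_drug_weight)
            visits.append(VisitRecord(
                patient_id=pid, admission_id=f"{pid}V{t:02d}",
                diagnoses=current, drugs=drugs, symptoms=syms))
        histories.append(PatientHistory(pid, tuple(visits)))
    return histories


# -- summary ------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class CorpusSummary:
    n_records: int
    n_patients: int
    n_diagnosis_codes: int
    n_drug_codes: int
    n_symptoms: int
    avg_diagnoses: float
    avg_drugs: float
    avg_symptoms: float
    max_diagnoses: int
    max_drugs: int
    max_symptoms: int
    avg_visits: float
    max_visits: int

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def corpus_summary(corpus: Sequence[VisitRecord | PatientHistory]) -> CorpusSummary:
    """Recount the corpus-shape statistics from an emitted corpus."""
    if not corpus:
        raise ValueError("empty corpus")
    histories = [c if isinstance(c, PatientHistory) else PatientHistory(c.patient_id, (c,))
                 for c in corpus]
    visits = [v for h in histories for v in h.visits]
    diag_sets = [v.diagnoses for v in visits]
    drug_sets = [v.drugs for v in visits]
    sym_sets = [v.symptoms for v in visits]
    return CorpusSummary(
        n_records=len(visits),
        n_patients=len({h.patient_id for h in histories}),
        n_diagnosis_codes=len(set().union(*diag_sets)),
        n_drug_codes=len(set().union(*drug_sets)),
        n_symptoms=len(set().union(*sym_sets)),
        avg_diagnoses=float(np.mean([len(s) for s in diag_sets])),
        avg_drugs=float(np.mean([len(s) for s in drug_sets])),
        avg_symptoms=float(np.mean([len(s) for s in sym_sets])),
        max_diagnoses=max(len(s) for s in diag_sets),
        max_drugs=max(len(s) for s in drug_sets),
        max_symptoms=max(len(s) for s in sym_sets),
        avg_visits=float(np.mean([h.n_visits for h in histories])),
        max_visits=max(h.n_visits for h in histories),
    )


# -- one-call dataset ---------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class SyntheticDataset:
    config: SyntheticConfig
    diagnosis_ontology: CodeOntology
    drug_ontology: CodeOntology
    symptoms: tuple[str, ...]
    profiles: Mapping[str, DiseaseProfile]
    single_visit: list[VisitRecord]
    multi_visit: list[PatientHistory]


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate ontologies, profiles and both corpora from one seeded config."""
    rng = np.random.default_rng(config.seed)
    diag = generate_ontology("diagnosis", config, rng)
    drug = generate_ontology("drug", config, rng)
    profiles = generate_disease_profiles(
        {"diagnosis": diag, "drug": drug}, config, rng)
    single = generate_single_visit_corpus(profiles, config, rng)
    multi = generate_multi_visit_corpus(profiles, config, rng)
    return SyntheticDataset(config, diag, drug, symptom_dictionary(config.n_symptoms),
                            profiles, single, multi)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path,
                  dialect: str = "csv") -> None:
    """Write corpora, ontologies and the symptom dictionary to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = "csv" if dialect == "csv" else "jsonl"
    singles = [PatientHistory(r.patient_id, (r,)) for r in dataset.single_visit]
    write_emr_table(singles, outdir / f"single_visit.{ext}", dialect=dialect)
    write_emr_table(dataset.multi_visit, outdir / f"multi_visit.{ext}", dialect=dialect)
    dataset.diagnosis_ontology.write_edge_list(outdir / "diagnosis_ontology.tsv")
    dataset.drug_ontology.write_edge_list(outdir / "drug_ontology.tsv")
    (outdir / "symptoms.txt").write_text("\n".join(dataset.symptoms) + "\n")
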