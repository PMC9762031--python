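"""EMR data model, table I/O, symptom segmentation and dataset splitting.

A visit is one hospital admission: a set of diagnosis codes, a set of drug
codes and a set of symptom terms.  A patient history is the admission-ordered
sequence of a patient's visits.  Tables are exchanged as CSV or JSON-lines
with columns ``SUBJECT ID, HADM ID, ICD-10, NDC, SYM``; multi-valued cells
are delimiter-joined (semicolon by default).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

COLUMNS = ["SUBJECT ID", "HADM ID", "ICD-10", "NDC", "SYM"]

#: reserved special tokens, in index order
PAD, CLS, MASK, UNK = "[PAD]", "[CLS]", "[MASK]", "[UNK]"
SPECIALS = (PAD, CLS, MASK, UNK)


class SchemaError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class VisitRecord:
    """One admission's observations: diagnosis, drug and symptom sets."""

    patient_id: str
    admission_id: str
    diagnoses: frozenset[str]
    drugs: frozenset[str]
    symptoms: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "diagnoses", frozenset(self.diagnoses))
        object.__setattr__(self, "drugs", frozenset(self.drugs))
        object.__setattr__(self, "symptoms", frozenset(self.symptoms))


@dataclasses.dataclass(frozen=True)
class PatientHistory:
    """A patient's admission-ordered visit sequence."""

    patient_id: str
    visits: tuple[VisitRecord, ...]

    def __post_init__(self):
        object.__setattr__(self, "visits", tuple(self.visits))
        if not self.visits:
            raise ValueError("a patient history needs at least one visit")
        if any(v.patient_id != self.patient_id for v in self.visits):
            raise ValueError("all visits must share the history's patient id")

    @property
    def n_visits(self) -> int:
        return len(self.visits)


def segment_symptoms(text: str, stopwords: Iterable[str] = (),
                     delimiters: str = " ,;") -> frozenset[str]:
    """Split a symptom string into a lower-cased, stopword-free term set."""
    stop = {w.lower() for w in stopwords}
    terms = [text]
    for d in delimiters:
        terms = [piece for t in terms for piece in t.split(d)]
    return frozenset(t.lower() for t in (s.strip() for s in terms)
                     if t and t.lower() not in stop)


def load_stopwords(path: str | Path) -> frozenset[str]:
    return frozenset(w.strip().lower() for w in Path(path).read_text().splitlines()
                     if w.strip())


# -- table I/O ----------------------------------------------------------------


def _row_to_visit(row: Mapping[str, object], delimiter: str) -> VisitRecord:
    def split(cell) -> frozenset[str]:
        if cell is None or (isinstance(cell, float) and np.isnan(cell)):
            return frozenset()
        text = str(cell).strip()
        if not text:
            return frozenset()
        return frozenset(p.strip() for p in text.split(delimiter) if p.strip())

    return VisitRecord(
        patient_id=str(row["SUBJECT ID"]),
        admission_id=str(row["HADM ID"]),
        diagnoses=split(row["ICD-10"]),
        drugs=split(row["NDC"]),
        symptoms=split(row["SYM"]),
    )


def read_emr_table(path: str | Path, dialect: str = "csv",
                   delimiter: str = ";") -> list[PatientHistory]:
    """Read an EMR table and group rows into admission-ordered patient histories.

    ``dialect`` is ``"csv"`` or ``"jsonl"``.  Visit order within a patient is
    the row order of the file (admission sequence).
    """
    path = Path(path)
    if dialect == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        rows = df.to_dict("records")
        missing = [c for c in COLUMNS if c not in df.columns]
    elif dialect == "jsonl":
        rows = [json.loads(line) for line in path.read_text().splitlines() if line.strip()]
        missing = [c for c in COLUMNS if rows and c not in rows[0]]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")

    seen_adm: set[str] = set()
    per_patient: dict[str, list[VisitRecord]] = {}
    order: list[str] = []
    for row in rows:
        visit = _row_to_visit(row, delimiter)
        if visit.admission_id in seen_adm:
            raise SchemaError(f"duplicate admission id {visit.admission_id!r}")
        seen_adm.add(visit.admission_id)
        if visit.patient_id not in per_patient:
            order.append(visit.patient_id)
        per_patient.setdefault(visit.patient_id, []).append(visit)
    return [PatientHistory(pid, tuple(per_patient[pid])) for pid in order]


def write_emr_table(histories: Sequence[PatientHistory], path: str | Path,
                    dialect: str = "csv", delimiter: str = ";") -> None:
    """Write histories as one row per visit, ordered by (patient, visit)."""
    rows = []
    for hist in histories:
        for visit in hist.visits:
            rows.append({
                "SUBJECT ID": visit.patient_id,
                "HADM ID": visit.admission_id,
                "ICD-10": delimiter.join(sorted(visit.diagnoses)),
                "NDC": delimiter.join(sorted(visit.drugs)),
                "SYM": delimiter.join(sorted(visit.symptoms)),
            })
    path = Path(path)
    if dialect == "csv":
        pd.DataFrame(rows, columns=COLUMNS).to_csv(path, index=False)
    elif dialect == "jsonl":
        path.write_text("".join(json.dumps(r) + "\n" for r in rows))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# -- vocabularies and tokenization -------------------------------------------


class Vocabulary:
    """Code/term <-> contiguous integer index, with reserved special tokens.

    Indices 0..3 are ``[PAD], [CLS], [MASK], [UNK]``; observed codes follow
    in sorted order, which makes vocabulary construction deterministic.
    """

    def __init__(self, codes: Iterable[str]):
        ordered = sorted(set(codes) - set(SPECIALS))
        self._tokens: tuple[str, ...] = SPECIALS + tuple(ordered)
        self._index = {t: i for i, t in enumerate(self._tokens)}

    def __len__(self) -> int:
        return len(self._tokens)

    def __contains__(self, token: str) -> bool:
        return token in self._index

    @property
    def n_specials(self) -> int:
        return len(SPECIALS)

    @property
    def n_codes(self) -> int:
        """Number of real codes (specials excluded)."""
        return len(self._tokens) - len(SPECIALS)

    @property
    def codes(self) -> tuple[str, ...]:
        return self._tokens[len(SPECIALS):]

    def index(self, token: str) -> int:
        return self._index.get(token, self._index[UNK])

    def token(self, index: int) -> str:
        return self._tokens[index]

    def code_position(self, token: str) -> int:
        """Index into the specials-free code block (for multi-hot targets)."""
        i = self.index(token)
        if i < len(SPECIALS):
            raise KeyError(f"{token!r} is not an indexed code")
        return i - len(SPECIALS)

    def multi_hot(self, tokens: Iterable[str]) -> np.ndarray:
        """Binary indicator over the code block; unknown tokens are dropped."""
        v = np.zeros(self.n_codes, dtype=np.float64)
        for t in tokens:
            if t in self._index and self._index[t] >= len(SPECIALS):
                v[self._index[t] - len(SPECIALS)] = 1.0
        return v


def build_vocabularies(histories: Sequence[PatientHistory],
                       ) -> tuple[Vocabulary, Vocabulary, Vocabulary]:
    """Build (diagnosis, drug, symptom) vocabularies from a corpus."""
    if not histories:
        raise ValueError("cannot build vocabularies from an empty corpus")
    diag, drug, sym = set(), set(), set()
    for hist in histories:
        for v in hist.visits:
            diag |= v.diagnoses
            drug |= v.drugs
            sym |= v.symptoms
    return Vocabulary(diag), Vocabulary(drug), Vocabulary(sym)


@dataclasses.dataclass(frozen=True)
class TokenizedVisit:
    """Per-field index sequences of one visit, [CLS]-prefixed and padded.

    ``valid`` flags mark positions that carry information ([CLS] plus real
    tokens); padded tails are flagged 0 and must be excluded from attention.
    """

    diagnoses: np.ndarray
    drugs: np.ndarray
    symptoms: np.ndarray
    valid: dict[str, np.ndarray]

    def field(self, name: str) -> np.ndarray:
        return {"d": self.diagnoses, "m": self.drugs, "s": self.symptoms}[name]


#: default per-field maximum sequence lengths ([CLS] included); chosen from
#: the corpus maxima the generator targets (26-30 diagnoses, up to ~69 drugs,
#: up to 7 symptoms), rounded up.
DEFAULT_MAX_LEN = {"d": 32, "m": 72, "s": 8}


def _tokenize_field(tokens: Iterable[str], vocab: Vocabulary, max_len: int,
                    ) -> tuple[np.ndarray, np.ndarray]:
    if max_len < 2:
        raise ValueError("max_len must be at least 2 ([CLS] plus one token)")
    # sets are unordered; sort by vocabulary index for a deterministic layout
    idx = sorted(vocab.index(t) for t in tokens)[: max_len - 1]
    seq = np.full(max_len, vocab.index(PAD), dtype=np.intp)
    valid = np.zeros(max_len, dtype=bool)
    seq[0] = vocab.index(CLS)
    valid[0] = True
    seq[1:1 + len(idx)] = idx
    valid[1:1 + len(idx)] = True
    return seq, valid


def tokenize_visit(visit: VisitRecord, vocabularies: tuple[Vocabulary, Vocabulary, Vocabulary],
                   max_len: Mapping[str, int] | None = None) -> TokenizedVisit:
    """Turn a visit's three code sets into [CLS]-prefixed padded index rows."""
    max_len = dict(DEFAULT_MAX_LEN, **(max_len or {}))
    dvoc, mvoc, svoc = vocabularies
    d, dv = _tokenize_field(visit.diagnoses, dvoc, max_len["d"])
    m, mv = _tokenize_field(visit.drugs, mvoc, max_len["m"])
    s, sv = _tokenize_field(visit.symptoms, svoc, max_len["s"])
    return TokenizedVisit(d, m, s, {"d": dv, "m": mv, "s": sv})


# -- splitting ----------------------------------------------------------------


def split_patients(histories: Sequence[PatientHistory], seed: int,
                   ratio: tuple[int, int, int] = (4, 1, 1),
                   ) -> tuple[list[PatientHistory], list[PatientHistory], list[PatientHistory]]:
    """Patient-level train/validation/test split in the given ratio.

    Patients are shuffled with the seed and cut at floor proportions with the
    remainder going to training, so no patient spans two splits.
    """
    total = sum(ratio)
    if len(histories) < total:
        raise ValueError(f"need at least {total} patients to split {ratio}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(histories))
    n = len(histories)
    n_val = max(1, int(n * ratio[1] / total))
    n_test = max(1, int(n * ratio[2] / total))
    shuffled = [histories[i] for i in order]
    train = shuffled[: n - n_val - n_test]
    val = shuffled[n - n_val - n_test: n - n_test]
    test = shuffled[n - n_test:]
    return train, val, test
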