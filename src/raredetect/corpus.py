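"""Patient-level EHR corpus data model and JSON-lines I/O.

A corpus is a collection of patient records; each record is demographics
plus zero or more typed documents.  Documents carry two kinds of payload:
``structured_fields`` (field name -> whole-value text, e.g. a diagnosis
name or a lab test name) and ``text_fields`` (field name -> free text,
e.g. a clinical note body).  The on-disk format is UTF-8 JSON-lines, one
patient object per line, with an explicit ``schema_version`` field so
fixtures stay diffable and corpora stream at scale.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

SCHEMA_VERSION = 1

__all__ = [
    "DocType",
    "Document",
    "Demographics",
    "PatientRecord",
    "Corpus",
    "CorpusParseError",
    "CorpusValidationError",
    "read_corpus",
    "write_corpus",
    "merge_corpora",
    "corpus_summary",
    "write_summary",
]


class CorpusParseError(ValueError):
    """A line of a corpus file is not a well-formed patient object."""


class CorpusValidationError(ValueError):
    """A corpus or record violates a structural invariant."""


class DocType(str, Enum):
    """The sixteen EHR document types a patient record may contain."""

    CURRENT_MEDICATIONS = "Current Medications"
    DEMOGRAPHICS = "Demographics"
    ENCOUNTER_ATTRIBUTES = "Encounter Attributes"
    ENCOUNTER_DIAGNOSES = "Encounter Diagnoses"
    HOSPITAL_ENCOUNTERS = "Hospital Encounters"
    LAB_RESULTS = "Lab Results"
    ORDERED_MEDICATIONS = "Ordered Medications"
    MICROBIOLOGY_RESULTS = "Microbiology Results"
    NOTES = "Notes"
    PROBLEM_LIST = "Problem List"
    PROCEDURES_ORDERED = "Procedures Ordered"
    RESULT_COMMENTS = "Result Comments"
    SURGERIES = "Surgeries"
    VITALS = "Vitals"
    ADMINISTERED_MEDICATIONS = "Administered Medications"
    AMBULATORY_ENCOUNTERS = "Ambulatory Encounters"


@dataclass
class Document:
    """One typed document inside a patient record.

    ``encounter_id`` and ``timestamp`` (ISO-8601 date) are optional: the
    downstream analysis consumes occurrence counts, not time.  A field
    name may appear in structured_fields or text_fields but not both.
    """

    doc_type: DocType
    encounter_id: str | None = None
    timestamp: str | None = None
    structured_fields: dict[str, str] = field(default_factory=dict)
    text_fields: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.doc_type = DocType(self.doc_type)
        overlap = set(self.structured_fields) & set(self.text_fields)
        if overlap:
            raise CorpusValidationError(
                f"field names appear in both structured and text payloads: {sorted(overlap)}"
            )

    def content_key(self) -> tuple:
        """Hashable content identity used for merge-time deduplication."""
        return (
            self.doc_type.value,
            self.encounter_id,
            self.timestamp,
            tuple(sorted(self.structured_fields.items())),
            tuple(sorted(self.text_fields.items())),
        )

    def to_json(self) -> dict:
        return {
            "doc_type": self.doc_type.value,
            "encounter_id": self.encounter_id,
            "timestamp": self.timestamp,
            "structured_fields": self.structured_fields,
            "text_fields": self.text_fields,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "Document":
        return cls(
            doc_type=DocType(obj["doc_type"]),
            encounter_id=obj.get("encounter_id"),
            timestamp=obj.get("timestamp"),
            structured_fields=dict(obj.get("structured_fields", {})),
            text_fields=dict(obj.get("text_fields", {})),
        )


@dataclass
class Demographics:
    age_years: float = 0.0
    sex: str = "other"  # {male, female, other}
    deceased: bool = False

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise CorpusValidationError(f"age_years must be non-negative, got {self.age_years}")
        if self.sex not in ("male", "female", "other"):
            raise CorpusValidationError(f"sex must be male/female/other, got {self.sex!r}")

    def to_json(self) -> dict:
        return {"age_years": self.age_years, "sex": self.sex, "deceased": self.deceased}

    @classmethod
    def from_json(cls, obj: dict) -> "Demographics":
        return cls(
            age_years=obj.get("age_years", 0.0),
            sex=obj.get("sex", "other"),
            deceased=bool(obj.get("deceased", False)),
        )


@dataclass
class PatientRecord:
    """One patient: the unit of sampling, labeling and feature extraction."""

    patient_id: str
    demographics: Demographics = field(default_factory=Demographics)
    documents: list[Document] = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "patient_id": self.patient_id,
            "demographics": self.demographics.to_json(),
            "documents": [d.to_json() for d in self.documents],
        }

    @classmethod
    def from_json(cls, obj: dict) -> "PatientRecord":
        return cls(
            patient_id=str(obj["patient_id"]),
            demographics=Demographics.from_json(obj.get("demographics", {})),
            documents=[Document.from_json(d) for d in obj.get("documents", [])],
        )


@dataclass
class Corpus:
    """An ordered collection of patient records with unique patient ids."""

    patients: list[PatientRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.patients:
            if p.patient_id in seen:
                raise CorpusValidationError(f"duplicate patient_id: {p.patient_id!r}")
            seen.add(p.patient_id)

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.patients)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return self.patients == other.patients

    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    def get(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)


def read_corpus(path: str | Path) -> Corpus:
    """Read a JSON-lines corpus, one patient object per line.

    Raises :class:`CorpusParseError` naming the line number on a malformed
    line and :class:`CorpusValidationError` on a duplicate patient id.
    """
    patients: list[PatientRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                patients.append(PatientRecord.from_json(obj))
            except CorpusValidationError:
                raise
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise CorpusParseError(f"line {lineno}: malformed patient record ({exc})") from exc
    return Corpus(patients)


def write_corpus(corpus: Corpus, path: str | Path) -> Path:
    """Write a corpus as JSON-lines; round-trips through :func:`read_corpus`."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for p in corpus:
            fh.write(json.dumps(p.to_json(), sort_keys=True) + "\n")
    return path


def _merge_documents(base: list[Document], extra: list[Document]) -> list[Document]:
    """Union two document lists, collapsing content-identical duplicates."""
    merged = list(base)
    seen = {d.content_key() for d in base}
    for d in extra:
        key = d.content_key()
        if key not in seen:
            merged.append(d)
            seen.add(key)
    return merged


def merge_corpora(base: Corpus, enriched: Corpus) -> Corpus:
    """Merge a base corpus with an enrichment corpus.

    Each patient id appears exactly once in the result; for ids present in
    both corpora the document lists are unioned with content-identical
    documents collapsed, so a patient pulled twice still counts as a
    single sample.
    """
    by_id: dict[str, PatientRecord] = {}
    order: list[str] = []
    for p in base:
        by_id[p.patient_id] = PatientRecord(p.patient_id, p.demographics, list(p.documents))
        order.append(p.patient_id)
    for p in enriched:
        if p.patient_id in by_id:
            existing = by_id[p.patient_id]
            existing.documents = _merge_documents(existing.documents, p.documents)
        else:
            by_id[p.patient_id] = PatientRecord(p.patient_id, p.demographics, list(p.documents))
            order.append(p.patient_id)
    return Corpus([by_id[pid] for pid in order])


def corpus_summary(corpus: Corpus) -> pd.DataFrame:
    """Per-document-type volume summary.

    One row per document type present in the corpus with the number of
    patients having at least one such document, the total record count,
    the median per patient-with-type and the maximum per patient.
    """
    per_type: dict[DocType, list[int]] = {}
    for p in corpus:
        counts: dict[DocType, int] = {}
        for d in p.documents:
            counts[d.doc_type] = counts.get(d.doc_type, 0) + 1
        for dt, n in counts.items():
            per_type.setdefault(dt, []).append(n)
    rows = []
    for dt in DocType:
        if dt not in per_type:
            continue
        counts_list = per_type[dt]
        rows.append(
            {
                "doc_type": dt.value,
                "patients": len(counts_list),
                "records": sum(counts_list),
                "median_per_patient": statistics.median(counts_list),
                "max_per_patient": max(counts_list),
            }
        )
    return pd.DataFrame(
        rows, columns=["doc_type", "patients", "records", "median_per_patient", "max_per_patient"]
    )


def write_summary(summary: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    summary.to_csv(path, sep="\t", index=False)
    return path
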