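"""Wildcard term-search enrichment and gold-standard labeling.

A base corpus is enriched with patients matching any of four
case-insensitive trailing-star wildcard criteria (diagnosis name,
medication name, procedure name, note text).  Candidates for the positive
class are then listed by a structured diagnosis code; confirmed positives
arrive from external adjudication (chart review), and every other patient
— including code-matched candidates whose diagnosis could not be
confirmed — is presumed negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from raredetect.corpus import Corpus, Document, DocType
from raredetect.features import tokenize

__all__ = [
    "EnrichmentCriteria",
    "LabelSet",
    "match_wildcard",
    "select_enrichment",
    "list_candidates",
    "build_labels",
    "write_labels",
    "read_labels",
]

# Field families over which each wildcard criterion is evaluated:
# (document types, name-field predicate).  "name" fields are structured
# fields whose field name ends with "_name"; note text is any text field
# of note-like documents.
DIAGNOSIS_DOC_TYPES = (DocType.ENCOUNTER_DIAGNOSES, DocType.PROBLEM_LIST)
MEDICATION_DOC_TYPES = (
    DocType.CURRENT_MEDICATIONS,
    DocType.ORDERED_MEDICATIONS,
    DocType.ADMINISTERED_MEDICATIONS,
)
PROCEDURE_DOC_TYPES = (DocType.PROCEDURES_ORDERED, DocType.SURGERIES)
NOTE_DOC_TYPES = (DocType.NOTES, DocType.RESULT_COMMENTS)


class WildcardError(ValueError):
    """Unsupported wildcard pattern syntax."""


@dataclass
class EnrichmentCriteria:
    """Trailing-star wildcard patterns, one per field family.

    Matching is always case-insensitive.  Defaults target a porphyria-like
    disease: "porph*" in diagnosis/procedure names and note text, the
    treatment drug stem "hemin*" in medication names.
    """

    diagnosis_term: str = "porph*"
    medication_term: str = "hemin*"
    procedure_term: str = "porph*"
    note_term: str = "porph*"

    def __post_init__(self) -> None:
        for name in ("diagnosis_term", "medication_term", "procedure_term", "note_term"):
            _pattern_stem(getattr(self, name))  # validates


@dataclass
class LabelSet:
    """Partition of a corpus into positives and presumed negatives.

    ``candidates`` are the code-matched patients prior to adjudication;
    unconfirmed candidates stay in ``negatives``.
    """

    positives: set[str] = field(default_factory=set)
    candidates: set[str] = field(default_factory=set)
    negatives: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(f"patients labeled both positive and negative: {sorted(overlap)[:5]}")

    def label_of(self, patient_id: str) -> int:
        if patient_id in self.positives:
            return 1
        if patient_id in self.negatives:
            return 0
        raise KeyError(patient_id)

    def y(self, patient_ids: list[str]) -> list[int]:
        return [self.label_of(pid) for pid in patient_ids]


def _pattern_stem(pattern: str) -> str:
    if not pattern or not pattern.endswith("*") or "*" in pattern[:-1] or len(pattern) < 2:
        raise WildcardError(
            f"pattern {pattern!r} is not trailing-star prefix syntax (e.g. 'porph*')"
        )
    return pattern[:-1].lower()


def match_wildcard(value: str, pattern: str) -> bool:
    """True iff any token of ``value`` begins with the pattern stem.

    Tokenization matches the featurizer's: case-folded maximal
    alphanumeric runs, so "PORPHYRIA cutanea" matches "porph*" and the
    match cannot straddle token boundaries.
    """
    stem = _pattern_stem(pattern)
    unigrams, _ = tokenize(value)
    return any(tok.startswith(stem) for tok in unigrams)


def _name_values(doc: Document) -> list[str]:
    return [v for f, v in doc.structured_fields.items() if f.endswith("_name")]


def select_enrichment(corpus: Corpus, criteria: EnrichmentCriteria) -> set[str]:
    """Patients matching ANY of the four wildcard criteria."""
    selected: set[str] = set()
    for p in corpus:
        hit = False
        for doc in p.documents:
            if doc.doc_type in DIAGNOSIS_DOC_TYPES:
                hit = any(match_wildcard(v, criteria.diagnosis_term) for v in _name_values(doc))
            elif doc.doc_type in MEDICATION_DOC_TYPES:
                hit = any(match_wildcard(v, criteria.medication_term) for v in _name_values(doc))
            elif doc.doc_type in PROCEDURE_DOC_TYPES:
                hit = any(match_wildcard(v, criteria.procedure_term) for v in _name_values(doc))
            elif doc.doc_type in NOTE_DOC_TYPES:
                hit = any(
                    match_wildcard(text, criteria.note_term) for text in doc.text_fields.values()
                )
            if hit:
                selected.add(p.patient_id)
                break
    return selected


def list_candidates(corpus: Corpus, code: str) -> set[str]:
    """Patients carrying ``code`` in a structured diagnosis-document field.

    Codes are structured-field matches only: the code string appearing in
    free-text notes does not make a patient a candidate.
    """
    if not code:
        raise ValueError("diagnosis code must be non-empty")
    code_l = code.strip().lower()
    out: set[str] = set()
    for p in corpus:
        for doc in p.documents:
            if doc.doc_type in DIAGNOSIS_DOC_TYPES and any(
                v.strip().lower() == code_l for v in doc.structured_fields.values()
            ):
                out.add(p.patient_id)
                break
    return out


def build_labels(
    corpus: Corpus, candidates: set[str], adjudicated_positives: set[str]
) -> LabelSet:
    """Label adjudicated positives; presume everyone else negative.

    Code-matched candidates whose diagnosis was not confirmed remain in
    the negative class, mirroring the treatment of unconfirmed coded
    patients in the motivating study.
    """
    all_ids = set(corpus.patient_ids())
    missing = adjudicated_positives - all_ids
    if missing:
        raise ValueError(f"adjudicated positives not in corpus: {sorted(missing)[:5]}")
    return LabelSet(
        positives=set(adjudicated_positives),
        candidates=set(candidates),
        negatives=all_ids - set(adjudicated_positives),
    )


def write_labels(labels: LabelSet, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("patient_id\tlabel\tcandidate_flag\n")
        for pid in sorted(labels.positives | labels.negatives):
            lab = "positive" if pid in labels.positives else "negative"
            fh.write(f"{pid}\t{lab}\t{int(pid in labels.candidates)}\n")
    return path


def read_labels(path: str | Path) -> LabelSet:
    positives: set[str] = set()
    candidates: set[str] = set()
    negatives: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            pid, lab, cand = line.rstrip("\n").split("\t")
            (positives if lab == "positive" else negatives).add(pid)
            if cand == "1":
                candidates.add(pid)
    return LabelSet(positives, candidates, negatives)
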