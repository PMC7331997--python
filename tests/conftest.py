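"""Shared fixtures: tiny hand-built corpora and random generators."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp

from raredetect.corpus import Corpus, Demographics, Document, DocType, PatientRecord
from raredetect.enrichment import LabelSet
from raredetect.features import FeatureKey, FeatureMatrix


def make_patient(pid: str, docs: list[Document] | None = None, **demo) -> PatientRecord:
    return PatientRecord(pid, Demographics(**demo), docs or [])


def note(text: str, field: str = "note_text", doc_type: DocType = DocType.NOTES) -> Document:
    return Document(doc_type, text_fields={field: text})


def dx(name: str, code: str, doc_type: DocType = DocType.ENCOUNTER_DIAGNOSES) -> Document:
    return Document(doc_type, structured_fields={"diagnosis_name": name, "diagnosis_code": code})


def lab(name: str) -> Document:
    return Document(DocType.LAB_RESULTS, structured_fields={"lab_name": name})


def med(name: str, doc_type: DocType = DocType.ORDERED_MEDICATIONS) -> Document:
    return Document(doc_type, structured_fields={"medication_name": name})


@pytest.fixture
def two_patient_corpus() -> Corpus:
    return Corpus(
        [
            make_patient("p1", [note("severe abdominal pain"), dx("migraine", "G43")]),
            make_patient("p2", [lab("lipase"), med("ibuprofen")], age_years=40, sex="male"),
        ]
    )


@pytest.fixture
def all_doctype_corpus() -> Corpus:
    docs = []
    for i, dt in enumerate(DocType):
        if dt in (DocType.NOTES, DocType.RESULT_COMMENTS):
            docs.append(Document(dt, text_fields={"t": f"text {i}"}))
        else:
            docs.append(Document(dt, structured_fields={"v": f"value {i}"}))
    return Corpus([make_patient("p1", docs)])


def random_feature_matrix(
    rng: np.random.Generator, n_patients: int, n_features: int
) -> FeatureMatrix:
    """Random sparse count matrix over a few document types."""
    doc_types = [DocType.NOTES, DocType.LAB_RESULTS, DocType.PROBLEM_LIST]
    vocab = [
        FeatureKey(doc_types[j % len(doc_types)], "f", f"tok{j:04d}") for j in range(n_features)
    ]
    dense = rng.poisson(0.3, size=(n_patients, n_features))
    return FeatureMatrix(
        patient_ids=[f"p{i:03d}" for i in range(n_patients)],
        vocabulary=vocab,
        counts=sp.csr_matrix(dense),
    )


def random_labels(rng: np.random.Generator, patient_ids: list[str], n_pos: int) -> LabelSet:
    pos = set(rng.choice(patient_ids, size=n_pos, replace=False).tolist())
    return LabelSet(positives=pos, candidates=set(), negatives=set(patient_ids) - pos)
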