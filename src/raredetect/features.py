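"""Record deconstruction into provenance-labeled count features.

Every feature is identified by a :class:`FeatureKey` = (document type,
source field, token): the same token appearing under different document
types or fields yields distinct features, so a diagnosis name in a
problem-list code field is distinguished from the same text in a free
note.  Structured fields contribute one feature per whole (lowercased)
field value; free-text fields are parsed into unigrams and bigrams.
Feature values are occurrence counts pooled over the entire record.

Counts are held in a scipy sparse matrix; three bounded encodings map
counts into [0, 1] for modeling:

``binary``   1 if the count is positive, else 0
``linear``   count / per-feature corpus maximum
``log``      ln(1 + count) / ln(1 + per-feature corpus maximum)
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import scipy.io
import scipy.sparse as sp

from raredetect.corpus import Corpus, DocType, PatientRecord

__all__ = [
    "FeatureKey",
    "FeatureMatrix",
    "EncodedMatrix",
    "ENCODING_SCHEMES",
    "tokenize",
    "extract_features",
    "build_matrix",
    "encode",
]

ENCODING_SCHEMES = ("binary", "linear", "log")

_TOKEN_RE = re.compile(r"[a-z0-9]+")


class FeatureKey(NamedTuple):
    """Provenance-labeled feature identifier."""

    doc_type: DocType
    field: str
    token: str

    def sort_key(self) -> tuple[str, str, str]:
        return (self.doc_type.value, self.field, self.token)


def tokenize(text: str) -> tuple[list[str], list[str]]:
    """Lowercase and split free text into unigrams and adjacent bigrams.

    Tokens are maximal alphanumeric runs; order and duplicates are
    preserved.  Bigrams never cross field-instance boundaries because the
    caller tokenizes one field instance at a time.
    """
    unigrams = _TOKEN_RE.findall(text.lower())
    bigrams = [f"{a} {b}" for a, b in zip(unigrams, unigrams[1:])]
    return unigrams, bigrams


def extract_features(record: PatientRecord) -> Counter:
    """Map a patient record to FeatureKey -> occurrence count.

    Counts pool all documents in the record: two notes each containing a
    token once yield count 2 for that (Notes, field, token) feature.
    Single-character tokens and pure numbers are retained — filtering is
    the screening stage's job, and lab-value fields are legitimately
    numeric.
    """
    counts: Counter = Counter()
    for doc in record.documents:
        for fname, value in doc.structured_fields.items():
            counts[FeatureKey(doc.doc_type, fname, value.strip().lower())] += 1
        for fname, text in doc.text_fields.items():
            unigrams, bigrams = tokenize(text)
            for tok in unigrams:
                counts[FeatureKey(doc.doc_type, fname, tok)] += 1
            for tok in bigrams:
                counts[FeatureKey(doc.doc_type, fname, tok)] += 1
    return counts


@dataclass
class FeatureMatrix:
    """Sparse patient x feature occurrence-count matrix.

    ``vocabulary`` is sorted by (doc_type, field, token) so the matrix is
    invariant to patient and document iteration order; ``per_feature_max``
    is the per-feature maximum count over the corpus, the normalizer for
    the linear and log encodings.
    """

    patient_ids: list[str]
    vocabulary: list[FeatureKey]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.patient_ids), len(self.vocabulary)):
            raise ValueError(
                f"matrix shape {self.counts.shape} inconsistent with "
                f"{len(self.patient_ids)} patients x {len(self.vocabulary)} features"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("feature counts must be non-negative")

    @property
    def per_feature_max(self) -> np.ndarray:
        if self.counts.shape[0] == 0:
            return np.zeros(len(self.vocabulary), dtype=np.int64)
        return np.asarray(self.counts.max(axis=0).todense()).ravel()

    def column_of(self, feature: FeatureKey) -> int:
        try:
            return self._index[feature]
        except AttributeError:
            self._index = {fk: j for j, fk in enumerate(self.vocabulary)}
            return self._index[feature]

    def select(self, features: Iterable[FeatureKey]) -> "FeatureMatrix":
        """Restrict to a feature subset (e.g. the post-veto selected set)."""
        cols = [self.column_of(f) for f in features]
        return FeatureMatrix(
            patient_ids=list(self.patient_ids),
            vocabulary=[self.vocabulary[j] for j in cols],
            counts=self.counts[:, cols],
        )


@dataclass
class EncodedMatrix:
    """A FeatureMatrix whose counts were mapped into [0, 1]."""

    patient_ids: list[str]
    vocabulary: list[FeatureKey]
    values: sp.csr_matrix
    scheme: str
    per_feature_max: np.ndarray


def build_matrix(corpus: Corpus) -> FeatureMatrix:
    """Union-vocabulary count matrix over a corpus; row i is patient i."""
    vocab_index: dict[FeatureKey, int] = {}
    rows: list[int] = []
    cols: list[int] = []
    data: list[int] = []
    patient_ids: list[str] = []
    for i, record in enumerate(corpus):
        patient_ids.append(record.patient_id)
        for fk, c in extract_features(record).items():
            j = vocab_index.setdefault(fk, len(vocab_index))
            rows.append(i)
            cols.append(j)
            data.append(c)

    vocabulary = sorted(vocab_index, key=FeatureKey.sort_key)
    remap = np.empty(len(vocab_index), dtype=np.int64)
    for new_j, fk in enumerate(vocabulary):
        remap[vocab_index[fk]] = new_j
    mat = sp.coo_matrix(
        (
            np.asarray(data, dtype=np.int64),
            (np.asarray(rows, dtype=np.int64), remap[np.asarray(cols, dtype=np.int64)]),
        ),
        shape=(len(patient_ids), len(vocabulary)),
    ).tocsr()
    return FeatureMatrix(patient_ids, vocabulary, mat)


def encode(matrix: FeatureMatrix, scheme: str) -> EncodedMatrix:
    """Encode occurrence counts into [0, 1] under one of three schemes.

    Features whose corpus maximum is zero encode to zero.  Linear and log
    encodings are strictly increasing in the count whenever the feature's
    maximum is at least 1; binary encoding is idempotent.
    """
    if scheme not in ENCODING_SCHEMES:
        raise ValueError(f"unknown encoding scheme {scheme!r}; expected one of {ENCODING_SCHEMES}")
    counts = matrix.counts.tocoo(copy=True)
    if counts.nnz and counts.data.min() < 0:
        raise ValueError("feature counts must be non-negative")
    fmax = matrix.per_feature_max.astype(np.float64)
    data = counts.data.astype(np.float64)
    if scheme == "binary":
        values = (data > 0).astype(np.float64)
    else:
        denom = fmax[counts.col]
        with np.errstate(divide="ignore", invalid="ignore"):
            if scheme == "linear":
                values = np.where(denom > 0, data / denom, 0.0)
            else:  # log
                values = np.where(denom > 0, np.log1p(data) / np.log1p(denom), 0.0)
    encoded = sp.coo_matrix((values, (counts.row, counts.col)), shape=counts.shape).tocsr()
    return EncodedMatrix(
        patient_ids=list(matrix.patient_ids),
        vocabulary=list(matrix.vocabulary),
        values=encoded,
        scheme=scheme,
        per_feature_max=matrix.per_feature_max,
    )


def top_frequency_features(
    matrix: FeatureMatrix,
    k: int,
    doc_types: tuple[DocType, ...] | None = None,
    features: Iterable[FeatureKey] | None = None,
) -> list[FeatureKey]:
    """The k features with the highest document frequency (patients with
    count > 0), optionally restricted to given doc types or a feature
    subset.  Label-independent by construction: the natural feature set
    for permutation-null evaluations of the detector, where label-driven
    screening would bias even a null corpus optimistically.  Ties break
    lexicographically.
    """
    pres = np.asarray((matrix.counts > 0).sum(axis=0)).ravel()
    pool = list(features) if features is not None else list(matrix.vocabulary)
    if doc_types is not None:
        pool = [fk for fk in pool if fk.doc_type in doc_types]
    pool.sort(key=lambda fk: (-pres[matrix.column_of(fk)], fk.sort_key()))
    return pool[:k]


def write_matrix(matrix: FeatureMatrix, prefix: str | Path) -> dict[str, Path]:
    """Write counts as MatrixMarket plus a vocabulary TSV and id list."""
    prefix = Path(prefix)
    mtx = prefix.with_suffix(".mtx")
    vocab = prefix.with_suffix(".vocab.tsv")
    ids = prefix.with_suffix(".patients.txt")
    scipy.io.mmwrite(str(mtx), matrix.counts)
    fmax = matrix.per_feature_max
    with open(vocab, "w", encoding="utf-8") as fh:
        fh.write("index\tdoc_type\tfield\ttoken\tper_feature_max\n")
        for j, fk in enumerate(matrix.vocabulary):
            fh.write(f"{j}\t{fk.doc_type.value}\t{fk.field}\t{fk.token}\t{int(fmax[j])}\n")
    with open(ids, "w", encoding="utf-8") as fh:
        fh.write("\n".join(matrix.patient_ids) + ("\n" if matrix.patient_ids else ""))
    return {"mtx": mtx, "vocab": vocab, "patients": ids}


def read_matrix(prefix: str | Path) -> FeatureMatrix:
    prefix = Path(prefix)
    counts = sp.csr_matrix(scipy.io.mmread(str(prefix.with_suffix(".mtx"))))
    vocabulary: list[FeatureKey] = []
    with open(prefix.with_suffix(".vocab.tsv"), encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            _, dt, fname, token, _ = line.rstrip("\n").split("\t")
            vocabulary.append(FeatureKey(DocType(dt), fname, token))
    with open(prefix.with_suffix(".patients.txt"), encoding="utf-8") as fh:
        patient_ids = [l.strip() for l in fh if l.strip()]
    return FeatureMatrix(patient_ids, vocabulary, counts.astype(np.int64))
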