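"""Synthetic EHR corpus generator with planted rare-disease signal.

The generator emulates the statistical structure the detection pipeline
assumes: sixteen document types with skewed per-type volumes, a rare
positive class at configurable prevalence, elevated symptom-token rates
among positives, and *diagnostic leakage* — data elements caused by the
diagnosis itself (a disease code, a disease-specific lab test, a
treatment medication, and the disease name in clinical notes).

Three ground-truth classes are emitted per patient:

``diagnosed_positive``
    carries the symptom signal AND leakage features (the disease code is
    always present so code-based candidate listing finds them);
``undiagnosed_positive``
    carries the symptom signal but NO leakage feature — these are the
    detection targets hiding in the presumed-negative class;
``negative``
    background only, except that a small fraction are spuriously miscoded
    with the disease code (charting-error analogue) and another fraction
    carry the disease term only in note text (boilerplate mentions such as
    transplant-evaluation documentation or medication precautions).

Background free text is a bag of tokens drawn from a Zipf-like
distribution over a configurable vocabulary; the featurizer only consumes
unigrams and bigrams, so no grammatical structure is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from raredetect.corpus import Corpus, Demographics, Document, DocType, PatientRecord

__all__ = [
    "SignalSpec",
    "LeakageSpec",
    "SimConfig",
    "GroundTruth",
    "simulate_corpus",
    "describe_truth",
    "write_truth",
    "read_truth",
    "CLASSES",
]

CLASSES = ("diagnosed_positive", "undiagnosed_positive", "negative")

GroundTruth = dict  # patient_id -> class name in CLASSES


class SimConfigError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclass
class SignalSpec:
    """Planted symptom signal: Poisson token counts, elevated in positives.

    Each symptom token (unigram or bigram) is planted in note text with
    per-record count ~ Poisson(base_rate) for negatives and
    Poisson(base_rate * rate_ratio) for positives.  Defaults model the
    nonspecific neurovisceral symptom complex of an acute-attack disease
    (unexplained abdominal pain, nausea, vomiting and related complaints).
    """

    symptom_tokens: tuple[str, ...] = (
        "abdominal pain",
        "nausea",
        "vomiting",
        "constipation",
        "muscle weakness",
    )
    rate_ratio: float = 8.0
    base_rate: float = 0.4

    def __post_init__(self) -> None:
        if self.rate_ratio < 1:
            raise SimConfigError(f"rate_ratio must be >= 1, got {self.rate_ratio}")
        if self.base_rate < 0:
            raise SimConfigError(f"base_rate must be >= 0, got {self.base_rate}")


@dataclass
class LeakageSpec:
    """Diagnosis-linked features planted in diagnosed positives.

    ``sensitivity`` is the fraction of diagnosed positives carrying each
    leakage feature beyond the always-present disease code;
    ``miscode_rate`` is the fraction of negatives spuriously carrying the
    disease code (rule-out encounters, inaccurate history, charting
    errors); ``boilerplate_rate`` is the fraction of negatives whose notes
    mention the disease term without any code or lab (transplant
    documentation, medication precautions).
    """

    disease_code: str = "E80.21"
    disease_lab_name: str = "urine porphobilinogen"
    treatment_med: str = "hemin"
    disease_term: str = "porphyria"
    sensitivity: float = 0.9
    miscode_rate: float = 0.0006
    boilerplate_rate: float = 0.01

    def __post_init__(self) -> None:
        for name in ("sensitivity", "miscode_rate", "boilerplate_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must be in [0,1], got {v}")


@dataclass
class SimConfig:
    """All knobs of the synthetic corpus.

    The default prevalence of 1e-5 matches the ~1 per 100,000 diagnosed
    prevalence of the motivating disease family; simulations at desk scale
    raise it for statistical power.  ``undiagnosed_fraction`` splits the
    positive class into detection targets (no leakage) and confirmed cases.
    """

    n_patients: int = 1000
    prevalence: float = 1e-5
    undiagnosed_fraction: float = 0.5
    signal: SignalSpec = field(default_factory=SignalSpec)
    leakage: LeakageSpec = field(default_factory=LeakageSpec)
    vocab_size: int = 250
    deceased_rate: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise SimConfigError(f"n_patients must be >= 0, got {self.n_patients}")
        if not 0.0 <= self.prevalence <= 1.0:
            raise SimConfigError(f"prevalence must be in [0,1], got {self.prevalence}")
        if not 0.0 <= self.undiagnosed_fraction <= 1.0:
            raise SimConfigError(
                f"undiagnosed_fraction must be in [0,1], got {self.undiagnosed_fraction}"
            )
        if self.vocab_size < 2:
            raise SimConfigError(f"vocab_size must be >= 2, got {self.vocab_size}")
        if not 0.0 <= self.deceased_rate <= 1.0:
            raise SimConfigError(f"deceased_rate must be in [0,1], got {self.deceased_rate}")


# Mean document counts per patient by type: a coarse volume skew with
# notes, diagnoses, labs and vitals dominating, surgeries and micro rare.
_DOC_MEANS: dict[DocType, float] = {
    DocType.CURRENT_MEDICATIONS: 1.5,
    DocType.ENCOUNTER_ATTRIBUTES: 1.0,
    DocType.ENCOUNTER_DIAGNOSES: 2.5,
    DocType.HOSPITAL_ENCOUNTERS: 0.4,
    DocType.LAB_RESULTS: 2.5,
    DocType.ORDERED_MEDICATIONS: 1.5,
    DocType.MICROBIOLOGY_RESULTS: 0.2,
    DocType.NOTES: 2.5,
    DocType.PROBLEM_LIST: 1.0,
    DocType.PROCEDURES_ORDERED: 0.8,
    DocType.RESULT_COMMENTS: 0.4,
    DocType.SURGERIES: 0.1,
    DocType.VITALS: 1.5,
    DocType.ADMINISTERED_MEDICATIONS: 0.6,
    DocType.AMBULATORY_ENCOUNTERS: 1.2,
}

# Sizes of the structured-value vocabularies (diagnosis names, lab names,
# medication names, procedure names) relative to the free-text vocabulary.
_N_DX = 120
_N_LAB = 80
_N_MED = 80
_N_PROC = 60


def _zipf_weights(k: int, exponent: float = 1.1) -> np.ndarray:
    w = 1.0 / np.arange(1, k + 1) ** exponent
    return w / w.sum()


def _note_text(rng: np.random.Generator, vocab: np.ndarray, weights: np.ndarray, n_tokens: int) -> list[str]:
    if n_tokens <= 0:
        return []
    return list(vocab[rng.choice(len(vocab), size=n_tokens, p=weights)])


def simulate_corpus(config: SimConfig) -> tuple[Corpus, GroundTruth]:
    """Generate a synthetic corpus and its ground-truth class map.

    The number of positives is exactly ``round(n_patients * prevalence)``
    and the number of undiagnosed positives exactly
    ``round(undiagnosed_fraction * positives)`` — deterministic rounding
    rather than Binomial sampling keeps extreme-rare classes testable at
    small n.  A fixed seed yields a byte-identical corpus.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    n_pos = int(round(n * config.prevalence))
    n_undiag = int(round(config.undiagnosed_fraction * n_pos))

    # Class assignment: positive positions drawn without replacement.
    classes = np.full(n, 2, dtype=np.int8)  # 2 = negative
    if n_pos:
        pos_idx = rng.choice(n, size=n_pos, replace=False)
        undiag_idx = set(pos_idx[:n_undiag].tolist())
        for i in pos_idx:
            classes[i] = 1 if int(i) in undiag_idx else 0  # 0 diagnosed, 1 undiagnosed

    vocab = np.array([f"w{i:04d}" for i in range(config.vocab_size)])
    vocab_w = _zipf_weights(config.vocab_size)
    dx_w = _zipf_weights(_N_DX)
    lab_w = _zipf_weights(_N_LAB)
    med_w = _zipf_weights(_N_MED)
    proc_w = _zipf_weights(_N_PROC)

    leak = config.leakage
    sig = config.signal

    patients: list[PatientRecord] = []
    truth: GroundTruth = {}
    width = max(6, len(str(max(n - 1, 0))))
    for i in range(n):
        pid = f"P{i:0{width}d}"
        cls = CLASSES[classes[i]]
        truth[pid] = cls
        is_positive = cls != "negative"
        is_diagnosed = cls == "diagnosed_positive"

        demo = Demographics(
            age_years=float(np.clip(rng.normal(52.0, 18.0), 0.0, 95.0).round(1)),
            sex=("female" if rng.random() < 0.55 else "male") if rng.random() > 0.02 else "other",
            deceased=bool(rng.random() < config.deceased_rate),
        )

        docs: list[Document] = [
            Document(
                DocType.DEMOGRAPHICS,
                structured_fields={"sex": demo.sex, "age_band": f"{int(demo.age_years) // 10 * 10}s"},
            )
        ]

        # Background documents with per-type volume skew.
        for dt, mean in _DOC_MEANS.items():
            k = int(rng.poisson(mean))
            for j in range(k):
                enc = f"{pid}e{len(docs)}"
                if dt == DocType.NOTES:
                    docs.append(
                        Document(
                            dt,
                            encounter_id=enc,
                            text_fields={
                                "note_text": " ".join(
                                    _note_text(rng, vocab, vocab_w, int(rng.poisson(8)))
                                )
                            },
                        )
                    )
                elif dt == DocType.RESULT_COMMENTS:
                    docs.append(
                        Document(
                            dt,
                            encounter_id=enc,
                            text_fields={
                                "comment_text": " ".join(
                                    _note_text(rng, vocab, vocab_w, int(rng.poisson(4)))
                                )
                            },
                        )
                    )
                elif dt in (DocType.ENCOUNTER_DIAGNOSES, DocType.PROBLEM_LIST):
                    d = int(rng.choice(_N_DX, p=dx_w))
                    docs.append(
                        Document(
                            dt,
                            encounter_id=enc,
                            structured_fields={
                                "diagnosis_name": f"condition {d:03d}",
                                "diagnosis_code": f"D{d:03d}",
                            },
                        )
                    )
                elif dt == DocType.LAB_RESULTS:
                    l = int(rng.choice(_N_LAB, p=lab_w))
                    docs.append(
                        Document(
                            dt,
                            encounter_id=enc,
                            structured_fields={
                                "lab_name": f"assay {l:03d}",
                                "lab_flag": "high" if rng.random() < 0.3 else "normal",
                            },
                        )
                    )
                elif dt in (
                    DocType.CURRENT_MEDICATIONS,
                    DocType.ORDERED_MEDICATIONS,
                    DocType.ADMINISTERED_MEDICATIONS,
                ):
                    m = int(rng.choice(_N_MED, p=med_w))
                    docs.append(
                        Document(dt, encounter_id=enc, structured_fields={"medication_name": f"drug{m:03d}"})
                    )
                elif dt in (DocType.PROCEDURES_ORDERED, DocType.SURGERIES):
                    pr = int(rng.choice(_N_PROC, p=proc_w))
                    docs.append(
                        Document(dt, encounter_id=enc, structured_fields={"procedure_name": f"procedure {pr:03d}"})
                    )
                elif dt == DocType.VITALS:
                    docs.append(
                        Document(
                            dt,
                            encounter_id=enc,
                            structured_fields={"heart_rate_band": f"hr{int(rng.normal(80, 15)) // 10 * 10}"},
                        )
                    )
                else:  # encounter-shaped documents carry a visit-class value
                    docs.append(
                        Document(
                            dt,
                            encounter_id=enc,
                            structured_fields={"visit_class": f"class{int(rng.integers(0, 6))}"},
                        )
                    )

        # Planted symptom signal in note text.
        rate = sig.base_rate * (sig.rate_ratio if is_positive else 1.0)
        symptom_tokens: list[str] = []
        for tok in sig.symptom_tokens:
            c = int(rng.poisson(rate))
            symptom_tokens.extend([tok] * c)
        if symptom_tokens:
            rng.shuffle(symptom_tokens)
            note_idxs = [k for k, d in enumerate(docs) if d.doc_type == DocType.NOTES]
            if not note_idxs:
                docs.append(Document(DocType.NOTES, text_fields={"note_text": ""}))
                note_idxs = [len(docs) - 1]
            for tok in symptom_tokens:
                k = int(rng.choice(note_idxs))
                existing = docs[k].text_fields["note_text"]
                docs[k].text_fields["note_text"] = (existing + " " + tok).strip()

        # Leakage features.
        if is_diagnosed:
            docs.append(
                Document(
                    DocType.ENCOUNTER_DIAGNOSES,
                    structured_fields={
                        "diagnosis_name": "acute intermittent porphyria",
                        "diagnosis_code": leak.disease_code,
                    },
                )
            )
            if rng.random() < leak.sensitivity:
                docs.append(
                    Document(
                        DocType.PROBLEM_LIST,
                        structured_fields={
                            "diagnosis_name": "acute hepatic porphyria",
                            "diagnosis_code": leak.disease_code,
                        },
                    )
                )
            if rng.random() < leak.sensitivity:
                docs.append(
                    Document(
                        DocType.LAB_RESULTS,
                        structured_fields={"lab_name": leak.disease_lab_name},
                    )
                )
            if rng.random() < leak.sensitivity:
                docs.append(
                    Document(
                        DocType.ORDERED_MEDICATIONS,
                        structured_fields={"medication_name": leak.treatment_med},
                    )
                )
            if rng.random() < leak.sensitivity:
                # Disease term embedded in ordinary note language (here:
                # background tokens), so only the term itself leaks.
                ctx = _note_text(rng, vocab, vocab_w, int(rng.poisson(4)))
                k = int(rng.integers(0, len(ctx) + 1))
                ctx.insert(k, leak.disease_term)
                docs.append(Document(DocType.NOTES, text_fields={"note_text": " ".join(ctx)}))
        elif cls == "negative":
            u = rng.random()
            if u < leak.miscode_rate:
                # Spurious disease code without any other leakage.
                docs.append(
                    Document(
                        DocType.ENCOUNTER_DIAGNOSES,
                        structured_fields={
                            "diagnosis_name": "acute intermittent porphyria",
                            "diagnosis_code": leak.disease_code,
                        },
                    )
                )
            elif u < leak.miscode_rate + leak.boilerplate_rate:
                # Note-only mention: no code, no disease lab, by construction.
                boiler = (
                    f"transplant evaluation differential includes {leak.disease_term}"
                    if rng.random() < 0.5
                    else f"medication precaution {leak.disease_term} risk"
                )
                docs.append(Document(DocType.NOTES, text_fields={"note_text": boiler}))

        patients.append(PatientRecord(pid, demo, docs))

    return Corpus(patients), truth


def describe_truth(truth: GroundTruth) -> dict[str, int]:
    """Count patients per ground-truth class; counts sum to len(truth)."""
    counts = {c: 0 for c in CLASSES}
    for cls in truth.values():
        counts[cls] += 1
    return counts


def write_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("patient_id\tclass\n")
        for pid, cls in truth.items():
            fh.write(f"{pid}\t{cls}\n")
    return path


def read_truth(path: str | Path) -> GroundTruth:
    truth: GroundTruth = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        assert header.strip().split("\t") == ["patient_id", "class"]
        for line in fh:
            pid, cls = line.rstrip("\n").split("\t")
            truth[pid] = cls
    return truth
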