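"""Apply-back ranking analysis and structured chart-review support.

After the final detector scores the whole corpus, two disjoint review
cohorts are drawn from the top of the ranking among patients who are not
known positives:

* cohort A — *no mention*: no disease term anywhere in the notes, no
  related diagnosis code, no disease-specific lab test.  These are the
  detection targets: patients whose symptom constellation scores high but
  in whom the disease has never been considered.
* cohort B — *note mention only*: the disease term appears in note text
  but there is no related code and no disease-specific lab.  High scores
  here probe the model's clinical face validity (and catch patients whose
  workup happened elsewhere).

The chart-review rubrics that the motivating study applied by hand are
encoded as deterministic functions over boolean annotations (the human
judgments — triad symptoms, alternative cause, substantial history,
documented suspicion — remain inputs).  The *classic triad* is abdominal
pain, central nervous system abnormalities, and peripheral neuropathy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

from raredetect.corpus import PatientRecord, DocType
from raredetect.enrichment import (
    DIAGNOSIS_DOC_TYPES,
    NOTE_DOC_TYPES,
    LabelSet,
    match_wildcard,
)

__all__ = [
    "MentionFlags",
    "NoMentionCategory",
    "MentionCategory",
    "ReviewAnnotation",
    "DEFAULT_RELATED_CODES",
    "DEFAULT_LAB_PATTERNS",
    "mention_flags",
    "select_review_cohorts",
    "score_overlap",
    "classify_no_mention",
    "classify_mention",
    "expected_cases",
    "write_cohorts",
]

# Related-code family for a porphyria-like disease: the legacy ICD-9 code
# plus the ICD-10 E80.x disorders-of-porphyrin-metabolism block.
DEFAULT_RELATED_CODES = (
    "277.1",
    "E80.0",
    "E80.1",
    "E80.20",
    "E80.21",
    "E80.29",
    "E80.4",
    "E80.6",
    "E80.7",
)

DEFAULT_LAB_PATTERNS = ("porph*", "porphobilinogen*", "pbg*")


@dataclass(frozen=True)
class MentionFlags:
    """Structured-data mention indicators used for cohort eligibility."""

    term_in_notes: bool
    disease_dx_code: bool
    disease_lab: bool


class NoMentionCategory(str, Enum):
    LIKELY_INDICATED = "likely_indicated"
    POSSIBLY_INDICATED = "possibly_indicated"
    UNLIKELY_INDICATED = "unlikely_indicated"
    DECEASED = "deceased"


class MentionCategory(str, Enum):
    SUSPECTED_IN_CHART = "suspected_in_chart"
    SUSPECTED_RULED_OUT = "suspected_ruled_out"
    POSSIBLY_INDICATED_NOT_SUSPECTED = "possibly_indicated_not_suspected"
    UNLIKELY = "unlikely"
    DIAGNOSED_IN_CHART = "diagnosed_in_chart"
    UNKNOWN = "unknown"
    DECEASED = "deceased"


@dataclass(frozen=True)
class ReviewAnnotation:
    """Boolean chart-review judgments; inputs to the rubric functions."""

    triad_abdominal: bool = False
    triad_cns: bool = False
    triad_neuropathy: bool = False
    alternative_cause: bool = False
    substantial_history: bool = False
    suspicion_documented: bool = False
    ruled_out_documented: bool = False
    diagnosis_mentioned: bool = False
    deceased: bool = False


def mention_flags(
    record: PatientRecord,
    term: str = "porph*",
    code_list: tuple[str, ...] = DEFAULT_RELATED_CODES,
    lab_patterns: tuple[str, ...] = DEFAULT_LAB_PATTERNS,
) -> MentionFlags:
    """Compute the three mention flags from structured data and note text.

    ``term_in_notes``: the wildcard term matches any note-like text field;
    ``disease_dx_code``: any structured diagnosis-document field equals a
    code in ``code_list`` (case-insensitive); ``disease_lab``: any lab
    name field matches a lab pattern.
    """
    codes = {c.strip().lower() for c in code_list}
    term_in_notes = False
    dx_code = False
    lab = False
    for doc in record.documents:
        if not term_in_notes and doc.doc_type in NOTE_DOC_TYPES:
            term_in_notes = any(match_wildcard(t, term) for t in doc.text_fields.values())
        if not dx_code and doc.doc_type in DIAGNOSIS_DOC_TYPES:
            dx_code = any(v.strip().lower() in codes for v in doc.structured_fields.values())
        if not lab and doc.doc_type == DocType.LAB_RESULTS:
            lab = any(
                match_wildcard(v, pat)
                for f, v in doc.structured_fields.items()
                if f.endswith("_name")
                for pat in lab_patterns
            )
    return MentionFlags(term_in_notes=term_in_notes, disease_dx_code=dx_code, disease_lab=lab)


def select_review_cohorts(
    rankings: dict[str, float],
    flags: dict[str, MentionFlags],
    known_positives: set[str] = frozenset(),
    top_n: int = 100,
) -> tuple[list[str], list[str]]:
    """The two top-``top_n`` review cohorts, each sorted by score descending.

    Eligibility (known positives are excluded from both):
      cohort A: no note mention, no related code, no disease lab;
      cohort B: note mention only — term in notes, no code, no lab.
    The eligibility predicates are mutually exclusive, so the cohorts are
    disjoint by construction.  If fewer patients are eligible than
    ``top_n`` the whole eligible set is returned with a warning.
    """
    def rank_key(pid: str):
        return (-rankings[pid], pid)

    eligible_a = [
        pid
        for pid in rankings
        if pid not in known_positives
        and not flags[pid].term_in_notes
        and not flags[pid].disease_dx_code
        and not flags[pid].disease_lab
    ]
    eligible_b = [
        pid
        for pid in rankings
        if pid not in known_positives
        and flags[pid].term_in_notes
        and not flags[pid].disease_dx_code
        and not flags[pid].disease_lab
    ]
    cohorts = []
    for name, eligible in (("A", eligible_a), ("B", eligible_b)):
        if len(eligible) < top_n:
            warnings.warn(
                f"cohort {name}: only {len(eligible)} eligible patients (requested {top_n})",
                stacklevel=2,
            )
        cohorts.append(sorted(eligible, key=rank_key)[:top_n])
    return cohorts[0], cohorts[1]


def score_overlap(rankings: dict[str, float], labels: LabelSet) -> int:
    """Negative patients scoring at or above the minimum positive score."""
    pos_scores = [rankings[pid] for pid in rankings if pid in labels.positives]
    if not pos_scores:
        raise ValueError("score overlap undefined with zero positives")
    threshold = min(pos_scores)
    return sum(
        1 for pid in rankings if pid in labels.negatives and rankings[pid] >= threshold
    )


def classify_no_mention(annotation: ReviewAnnotation) -> NoMentionCategory:
    """Rubric for the no-mention cohort.

    *Likely indicated* requires all three classic-triad symptom groups,
    no alternative cause identified, and a substantial symptom history;
    *possibly indicated* requires at least one triad group under the same
    two conditions; everything else is *unlikely indicated*.  Deceased
    patients are set aside first.
    """
    a = annotation
    if a.deceased:
        return NoMentionCategory.DECEASED
    triad_count = sum((a.triad_abdominal, a.triad_cns, a.triad_neuropathy))
    if triad_count == 3 and not a.alternative_cause and a.substantial_history:
        return NoMentionCategory.LIKELY_INDICATED
    if triad_count >= 1 and not a.alternative_cause and a.substantial_history:
        return NoMentionCategory.POSSIBLY_INDICATED
    return NoMentionCategory.UNLIKELY_INDICATED


def classify_mention(annotation: ReviewAnnotation) -> MentionCategory:
    """Rubric for the note-mention cohort.

    Precedence: deceased, then a diagnosis mentioned in the chart, then
    suspicion that was ruled out, then documented suspicion, then at
    least one triad symptom group without an alternative cause (testing
    possibly indicated though the disease was never suspected), else
    unlikely.
    """
    a = annotation
    if a.deceased:
        return MentionCategory.DECEASED
    if a.diagnosis_mentioned:
        return MentionCategory.DIAGNOSED_IN_CHART
    if a.ruled_out_documented:
        return MentionCategory.SUSPECTED_RULED_OUT
    if a.suspicion_documented:
        return MentionCategory.SUSPECTED_IN_CHART
    if (a.triad_abdominal or a.triad_cns or a.triad_neuropathy) and not a.alternative_cause:
        return MentionCategory.POSSIBLY_INDICATED_NOT_SUSPECTED
    return MentionCategory.UNLIKELY


def expected_cases(n_reviewed: int, prevalence: float) -> float:
    """Expected positives among ``n_reviewed`` under random sampling."""
    if n_reviewed < 0:
        raise ValueError(f"n_reviewed must be >= 0, got {n_reviewed}")
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError(f"prevalence must be in [0,1], got {prevalence}")
    return n_reviewed * prevalence


def write_cohorts(
    cohort_a: list[str],
    cohort_b: list[str],
    rankings: dict[str, float],
    flags: dict[str, MentionFlags],
    path: str | Path,
) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("patient_id\tscore\trank\tcohort\tterm_in_notes\tdisease_dx_code\tdisease_lab\n")
        for name, cohort in (("A", cohort_a), ("B", cohort_b)):
            for rank, pid in enumerate(cohort, start=1):
                f = flags[pid]
                fh.write(
                    f"{pid}\t{rankings[pid]:.10g}\t{rank}\t{name}\t"
                    f"{int(f.term_in_notes)}\t{int(f.disease_dx_code)}\t{int(f.disease_lab)}\n"
                )
    return path
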