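"""Univariate odds-ratio feature screening with a per-document-type cap.

Each feature is reduced to presence/absence (count > 0) and crossed with
the positive/negative label in a 2x2 contingency table.  The association
statistic is the odds ratio (a*d)/(b*c) — for a single binary predictor
this is exactly what a univariate logistic regression estimates — with
the Haldane–Anscombe 0.5 correction applied to every cell whenever any
cell is zero, so the ratio is always finite and positive.  The p-value is
the two-sided exact test of independence on the uncorrected table,
avoiding the separation failures a Wald test suffers when positives
number in the tens.

The three-part filter: keep features with p < alpha (default 0.01) that
occur in at least ``min_pos`` positive patients (default 4), then within
each document type independently select the top ``per_type_k`` (default
100) survivors ranked by odds ratio descending, ties broken by smaller
p-value then lexicographic feature key.  No multiple-testing correction
is applied; the raw threshold is deliberate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.stats

from raredetect.corpus import DocType
from raredetect.enrichment import LabelSet
from raredetect.features import FeatureKey, FeatureMatrix

__all__ = [
    "ContingencyTable",
    "ScreenParams",
    "ScreenRecord",
    "contingency",
    "odds_ratio_test",
    "screen_features",
    "write_screen_report",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 presence/label table: a,b over positives; c,d over negatives."""

    a: int  # positives with feature
    b: int  # positives without
    c: int  # negatives with feature
    d: int  # negatives without

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")


@dataclass
class ScreenParams:
    alpha: float = 0.01
    min_pos: int = 4
    per_type_k: int = 100

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.min_pos < 0:
            raise ValueError(f"min_pos must be >= 0, got {self.min_pos}")
        if self.per_type_k < 1:
            raise ValueError(f"per_type_k must be >= 1, got {self.per_type_k}")


@dataclass
class ScreenRecord:
    """Per-feature univariate screening result with selection flags."""

    feature: FeatureKey
    odds_ratio: float
    p_value: float
    n_pos_patients: int
    passed_alpha: bool
    passed_min_pos: bool
    selected: bool


def contingency(matrix: FeatureMatrix, feature: FeatureKey, labels: LabelSet) -> ContingencyTable:
    """Presence/label 2x2 table for one feature (presence = count > 0)."""
    j = matrix.column_of(feature)  # KeyError if unknown
    col = np.asarray(matrix.counts[:, j].todense()).ravel()
    present = col > 0
    y = np.asarray(labels.y(matrix.patient_ids), dtype=bool)
    a = int(np.sum(present & y))
    c = int(np.sum(present & ~y))
    return ContingencyTable(a=a, b=int(y.sum()) - a, c=c, d=int((~y).sum()) - c)


def _odds_ratio(a: float, b: float, c: float, d: float) -> float:
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def odds_ratio_test(table: ContingencyTable) -> tuple[float, float]:
    """Odds ratio (Haldane–Anscombe corrected on zeros) and exact p-value.

    The p-value is Fisher's two-sided exact test of independence on the
    uncorrected table.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if a == b == c == d == 0:
        raise ValueError("odds ratio undefined: all four cells are zero")
    oratio = _odds_ratio(a, b, c, d)
    _, p = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return oratio, float(p)


def screen_features(
    matrix: FeatureMatrix, labels: LabelSet, params: ScreenParams | None = None
) -> list[ScreenRecord]:
    """Screen every feature; flag per-document-type top-k survivors.

    Returns one record per vocabulary feature in vocabulary order.
    Raises if either label class is empty (screening is undefined with
    zero positives or zero negatives).
    """
    params = params or ScreenParams()
    y = np.asarray(labels.y(matrix.patient_ids), dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"screening undefined with an empty label class (positives={n_pos}, negatives={n_neg})"
        )

    presence = (matrix.counts > 0).astype(np.int64)
    a_vec = np.asarray(presence[y].sum(axis=0)).ravel()
    c_vec = np.asarray(presence[~y].sum(axis=0)).ravel()

    # Fisher p-values memoized on the table: at rare-disease scale most
    # features share a handful of distinct (a, c) pairs.
    p_cache: dict[tuple[int, int], float] = {}

    def fisher_p(a: int, c: int) -> float:
        key = (a, c)
        if key not in p_cache:
            _, p = scipy.stats.fisher_exact(
                [[a, n_pos - a], [c, n_neg - c]], alternative="two-sided"
            )
            p_cache[key] = float(p)
        return p_cache[key]

    records: list[ScreenRecord] = []
    for j, fk in enumerate(matrix.vocabulary):
        a, c = int(a_vec[j]), int(c_vec[j])
        oratio = _odds_ratio(a, n_pos - a, c, n_neg - c)
        p = fisher_p(a, c)
        records.append(
            ScreenRecord(
                feature=fk,
                odds_ratio=oratio,
                p_value=p,
                n_pos_patients=a,
                passed_alpha=p < params.alpha,
                passed_min_pos=a >= params.min_pos,
                selected=False,
            )
        )

    by_type: dict[DocType, list[ScreenRecord]] = {}
    for r in records:
        if r.passed_alpha and r.passed_min_pos:
            by_type.setdefault(r.feature.doc_type, []).append(r)
    for survivors in by_type.values():
        survivors.sort(key=lambda r: (-r.odds_ratio, r.p_value, r.feature.sort_key()))
        for r in survivors[: params.per_type_k]:
            r.selected = True
    return records


def write_screen_report(records: list[ScreenRecord], path: str | Path) -> Path:
    """TSV report sorted by document type then rank (OR desc, p asc, key)."""
    path = Path(path)
    ordered = sorted(
        records,
        key=lambda r: (
            r.feature.doc_type.value,
            not r.selected,
            -r.odds_ratio,
            r.p_value,
            r.feature.sort_key(),
        ),
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("doc_type\tfield\ttoken\todds_ratio\tp_value\tn_pos\tselected\n")
        for r in ordered:
            fh.write(
                f"{r.feature.doc_type.value}\t{r.feature.field}\t{r.feature.token}\t"
                f"{r.odds_ratio:.6g}\t{r.p_value:.6g}\t{r.n_pos_patients}\t{int(r.selected)}\n"
            )
    return path
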