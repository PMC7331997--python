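"""Knowledge-engineered removal of diagnosis-linked (leakage) features.

A detector for an undiagnosed disease must learn symptoms, not the
diagnosis: features caused by the diagnosis or its workup — the disease
code, disease-specific lab tests, treatment medications, the disease name
in notes — would otherwise dominate the model and select exactly the
patients already found.  The veto is applied in two passes:

1. a *pattern blocklist* (this module's :func:`apply_veto`) run before
   modeling, expressed as data — case-insensitive regular-expression
   rules with an optional document-type scope and a written reason — so
   the expert judgment it encodes is reproducible and auditable;
2. a *model-informed review* run after training, which ranks every
   modeled feature by permutation importance (mean decrease in ranking
   AUC when the feature's column is shuffled) so an expert can spot
   remaining leakage; removal happens by adding rules and re-running the
   blocklist pass.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score

from raredetect.corpus import DocType
from raredetect.enrichment import LabelSet
from raredetect.features import EncodedMatrix, FeatureKey

__all__ = [
    "VetoRule",
    "VetoReport",
    "apply_veto",
    "model_informed_review",
    "leakage_veto_rules",
    "read_rules",
    "write_rules",
    "write_veto_report",
]


@dataclass
class VetoRule:
    """One blocklist rule: regex over the token, optional doc-type scope."""

    pattern: str
    scope: DocType | None = None
    reason: str = ""

    def __post_init__(self) -> None:
        if not self.reason:
            raise ValueError(f"veto rule {self.pattern!r} needs a written reason")
        try:
            self._rx = re.compile(self.pattern, re.IGNORECASE)
        except re.error as exc:
            raise ValueError(f"invalid veto pattern {self.pattern!r}: {exc}") from exc

    def matches(self, feature: FeatureKey) -> bool:
        if self.scope is not None and feature.doc_type != self.scope:
            return False
        return bool(self._rx.search(feature.token))


@dataclass
class VetoReport:
    """Partition of the input features into removed (with the first
    matching rule) and retained."""

    removed: list[tuple[FeatureKey, VetoRule]]
    retained: list[FeatureKey]


def apply_veto(features: list[FeatureKey], rules: list[VetoRule]) -> VetoReport:
    """Remove every feature matched by at least one rule.

    The first matching rule (in rule-list order) is recorded for the
    audit trail.  Idempotent: retained features match no rule.
    """
    removed: list[tuple[FeatureKey, VetoRule]] = []
    retained: list[FeatureKey] = []
    for fk in features:
        for rule in rules:
            if rule.matches(fk):
                removed.append((fk, rule))
                break
        else:
            retained.append(fk)
    return VetoReport(removed=removed, retained=retained)


def leakage_veto_rules(leakage) -> list[VetoRule]:
    """Blocklist matching a synthetic generator's planted leakage terms.

    Mirrors the kind of first-pass rule set an expert writes for a real
    disease: the disease name stem, the treatment drug, the diagnosis
    code, and the disease-specific lab test name.
    """
    rules = [
        VetoRule(pattern=re.escape(leakage.disease_term[:5]), reason="disease name stem"),
        VetoRule(pattern=re.escape(leakage.treatment_med), reason="treatment medication"),
        VetoRule(pattern=re.escape(leakage.disease_code), reason="disease diagnosis code"),
    ]
    for tok in leakage.disease_lab_name.split():
        rules.append(VetoRule(pattern=re.escape(tok), reason="disease-specific lab test"))
    return rules


def model_informed_review(
    detector,
    features: list[FeatureKey],
    matrix: EncodedMatrix,
    labels: LabelSet,
    n_permutations: int = 5,
    seed: int = 0,
) -> list[tuple[FeatureKey, float]]:
    """Rank modeled features by permutation importance for expert review.

    Influence of a feature is the mean decrease in ranking AUC over
    ``n_permutations`` shuffles of its column, against the detector's
    margins on the supplied matrix.  A constant column has influence
    exactly 0 (shuffling changes nothing).  Output is sorted by influence
    descending, ties broken by feature key; deterministic given the seed.
    """
    from raredetect.model import _margins_for  # local import: avoids cycle

    if list(features) != list(detector.feature_list):
        raise ValueError("feature set does not match the detector's feature list")
    X = matrix.values.toarray()
    y = np.asarray(labels.y(matrix.patient_ids))
    base_auc = roc_auc_score(y, _margins_for(detector, X))
    rng = np.random.default_rng(seed)
    influences: list[tuple[FeatureKey, float]] = []
    for j, fk in enumerate(features):
        col = X[:, j]
        if np.all(col == col[0]):
            influences.append((fk, 0.0))
            continue
        drops = []
        for _ in range(n_permutations):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(col)
            drops.append(base_auc - roc_auc_score(y, _margins_for(detector, Xp)))
        influences.append((fk, float(np.mean(drops))))
    influences.sort(key=lambda t: (-t[1], t[0].sort_key()))
    return influences


def write_rules(rules: list[VetoRule], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("pattern\tscope\treason\n")
        for r in rules:
            scope = r.scope.value if r.scope else ""
            fh.write(f"{r.pattern}\t{scope}\t{r.reason}\n")
    return path


def read_rules(path: str | Path) -> list[VetoRule]:
    rules: list[VetoRule] = []
    with open(path, encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            pattern, scope, reason = line.rstrip("\n").split("\t")
            rules.append(
                VetoRule(pattern=pattern, scope=DocType(scope) if scope else None, reason=reason)
            )
    return rules


def write_veto_report(report: VetoReport, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("doc_type\tfield\ttoken\tstatus\tmatched_rule\n")
        for fk, rule in report.removed:
            fh.write(f"{fk.doc_type.value}\t{fk.field}\t{fk.token}\tremoved\t{rule.pattern}\n")
        for fk in report.retained:
            fh.write(f"{fk.doc_type.value}\t{fk.field}\t{fk.token}\tretained\t\n")
    return path
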