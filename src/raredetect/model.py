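"""Margin-ranking kernel classifier: training, CV evaluation, scoring.

The detector is a support vector machine (default: RBF kernel,
gamma = 0.04, C = 1) trained on the full labeled corpus with [0,1]-encoded
count features.  Its signed decision value — the margin distance — is the
patient ranking score; by the standard margin convention samples inside
the boundary region score within [-1, +1], and no clipping is applied
outside it.  Model selection and evaluation use repeated stratified
2-fold cross-validation (default 5 repetitions = 10 fold-evaluations);
folds are stratified because an unstratified 2-fold split of a class with
a few dozen members is degenerate.

Ranking metrics: AUC (probability a random positive outscores a random
negative, ties counting one half), average precision (precision averaged
at each positive's rank), precision@k (positive fraction of the k
top-scored patients, ties broken by patient id), and log loss on
calibrated probabilities.  Margins are not probabilities, so log loss
uses a logistic (Platt) calibration map; the full-data detector fits the
map on out-of-fold margins.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, log_loss, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from raredetect.enrichment import LabelSet
from raredetect.features import EncodedMatrix, FeatureKey

__all__ = [
    "DetectorConfig",
    "TrainedDetector",
    "CVResult",
    "train",
    "score",
    "cross_validate",
    "precision_at_k",
    "ranking_metrics",
    "calibrated_probabilities",
    "write_scores",
]

KERNELS = ("rbf", "linear", "poly2")


@dataclass
class DetectorConfig:
    kernel: str = "rbf"
    gamma: float = 0.04
    cost: float = 1.0
    encoding: str = "log"
    cv_reps: int = 5
    cv_folds: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel not in KERNELS:
            raise ValueError(f"kernel must be one of {KERNELS}, got {self.kernel!r}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if self.cost <= 0:
            raise ValueError(f"cost must be positive, got {self.cost}")
        if self.cv_folds < 2:
            raise ValueError(f"cv_folds must be >= 2, got {self.cv_folds}")
        if self.cv_reps < 1:
            raise ValueError(f"cv_reps must be >= 1, got {self.cv_reps}")


@dataclass
class TrainedDetector:
    """A fitted margin-scoring model plus its probability calibration."""

    config: DetectorConfig
    feature_list: list[FeatureKey]
    model: SVC
    calibration: LogisticRegression

    def state_hash(self) -> str:
        """Deterministic digest of the fitted state (support vectors,
        dual coefficients, intercept, calibration parameters)."""
        def dense(a) -> np.ndarray:
            return a.toarray() if hasattr(a, "toarray") else np.asarray(a)

        h = hashlib.sha256()
        h.update(np.ascontiguousarray(dense(self.model.support_vectors_)).tobytes())
        h.update(np.ascontiguousarray(dense(self.model.dual_coef_)).tobytes())
        h.update(np.ascontiguousarray(self.model.intercept_).tobytes())
        h.update(np.ascontiguousarray(self.calibration.coef_).tobytes())
        h.update(np.ascontiguousarray(self.calibration.intercept_).tobytes())
        return h.hexdigest()


@dataclass
class CVResult:
    """Aggregate and per-fold repeated-CV ranking metrics."""

    auc: float
    average_precision: float
    precision_at_100: float
    log_loss: float
    fold_auc: list[float] = field(default_factory=list)
    fold_average_precision: list[float] = field(default_factory=list)
    fold_precision_at_100: list[float] = field(default_factory=list)
    fold_log_loss: list[float] = field(default_factory=list)

    @property
    def n_fold_evaluations(self) -> int:
        return len(self.fold_auc)


def _make_svc(config: DetectorConfig) -> SVC:
    kernel = {"rbf": "rbf", "linear": "linear", "poly2": "poly"}[config.kernel]
    return SVC(kernel=kernel, gamma=config.gamma, C=config.cost, degree=2, coef0=1.0)


def _margins_for(detector: TrainedDetector, X) -> np.ndarray:
    return detector.model.decision_function(X)


def _fit_platt(margins: np.ndarray, y: np.ndarray) -> LogisticRegression:
    lr = LogisticRegression(C=1e6, solver="lbfgs", max_iter=1000)
    lr.fit(margins.reshape(-1, 1), y)
    return lr


def _validate_alignment(encoded: EncodedMatrix, feature_list: list[FeatureKey]) -> None:
    if list(encoded.vocabulary) != list(feature_list):
        raise ValueError("matrix vocabulary is not aligned to the detector's feature list")


def train(encoded: EncodedMatrix, labels: LabelSet, config: DetectorConfig) -> TrainedDetector:
    """Train the full-data detector.

    The probability calibration (used only for log loss) is fitted on
    out-of-fold margins from an internal stratified split, so it is not
    contaminated by the optimism of in-sample margins.  Deterministic
    given the config seed.
    """
    y = np.asarray(labels.y(encoded.patient_ids))
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both label classes")
    if int(y.sum()) < config.cv_folds or int((1 - y).sum()) < config.cv_folds:
        raise ValueError(
            f"each class needs >= cv_folds={config.cv_folds} members for the calibration split"
        )
    X = encoded.values

    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    oof_margins = np.zeros(len(y))
    for tr, te in skf.split(X, y):
        m = _make_svc(config).fit(X[tr], y[tr])
        oof_margins[te] = m.decision_function(X[te])
    calibration = _fit_platt(oof_margins, y)

    model = _make_svc(config).fit(X, y)
    return TrainedDetector(
        config=config, feature_list=list(encoded.vocabulary), model=model, calibration=calibration
    )


def score(detector: TrainedDetector, encoded: EncodedMatrix) -> dict[str, float]:
    """Margin distance per patient (raw signed decision values)."""
    _validate_alignment(encoded, detector.feature_list)
    margins = _margins_for(detector, encoded.values)
    return dict(zip(encoded.patient_ids, margins.tolist()))


def calibrated_probabilities(detector: TrainedDetector, scores: dict[str, float]) -> dict[str, float]:
    """Map margin scores through the detector's Platt calibration."""
    pids = list(scores)
    m = np.asarray([scores[p] for p in pids]).reshape(-1, 1)
    probs = detector.calibration.predict_proba(m)[:, 1]
    return dict(zip(pids, probs.tolist()))


def precision_at_k(scores: dict[str, float], labels: LabelSet, k: int) -> float:
    """Fraction of the k top-scored patients labeled positive.

    Ties are broken by patient id so the metric is deterministic.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > len(scores):
        raise ValueError(f"k={k} exceeds the number of scored patients ({len(scores)})")
    top = sorted(scores, key=lambda pid: (-scores[pid], pid))[:k]
    return sum(labels.label_of(pid) for pid in top) / k


def ranking_metrics(
    scores: dict[str, float],
    labels: LabelSet,
    probabilities: dict[str, float] | None = None,
) -> tuple[float, float, float]:
    """(AUC, average precision, log loss) for a patient ranking.

    Log loss (natural log) needs probabilities; if none are supplied a
    logistic calibration is fitted to the scores themselves.
    """
    pids = list(scores)
    y = np.asarray([labels.label_of(p) for p in pids])
    if len(np.unique(y)) < 2:
        raise ValueError("ranking metrics require both label classes")
    s = np.asarray([scores[p] for p in pids])
    auc = float(roc_auc_score(y, s))
    ap = float(average_precision_score(y, s))
    if probabilities is None:
        probs = _fit_platt(s, y).predict_proba(s.reshape(-1, 1))[:, 1]
    else:
        probs = np.asarray([probabilities[p] for p in pids])
    ll = float(log_loss(y, probs, labels=[0, 1]))
    return auc, ap, ll


def cross_validate(encoded: EncodedMatrix, labels: LabelSet, config: DetectorConfig) -> CVResult:
    """Repeated stratified k-fold CV (defaults: 5 reps x 2 folds = 10
    fold-evaluations, repetition r seeded with seed + r).

    Within each fold-evaluation the model is fitted on the training half;
    test-half margins give AUC, average precision and precision@k with
    k = min(100, test size); log loss uses a Platt map fitted on the
    training half's margins.
    """
    y = np.asarray(labels.y(encoded.patient_ids))
    if int(y.sum()) < config.cv_folds or int((1 - y).sum()) < config.cv_folds:
        raise ValueError(
            f"each class needs >= cv_folds={config.cv_folds} members to stratify"
        )
    X = encoded.values
    pids = np.asarray(encoded.patient_ids)

    fold_auc, fold_ap, fold_p100, fold_ll = [], [], [], []
    for rep in range(config.cv_reps):
        skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed + rep)
        for tr, te in skf.split(X, y):
            m = _make_svc(config).fit(X[tr], y[tr])
            test_margins = m.decision_function(X[te])
            fold_auc.append(float(roc_auc_score(y[te], test_margins)))
            fold_ap.append(float(average_precision_score(y[te], test_margins)))
            test_scores = dict(zip(pids[te].tolist(), test_margins.tolist()))
            k = min(100, len(te))
            fold_p100.append(precision_at_k(test_scores, labels, k))
            platt = _fit_platt(m.decision_function(X[tr]), y[tr])
            probs = platt.predict_proba(test_margins.reshape(-1, 1))[:, 1]
            fold_ll.append(float(log_loss(y[te], probs, labels=[0, 1])))

    return CVResult(
        auc=float(np.mean(fold_auc)),
        average_precision=float(np.mean(fold_ap)),
        precision_at_100=float(np.mean(fold_p100)),
        log_loss=float(np.mean(fold_ll)),
        fold_auc=fold_auc,
        fold_average_precision=fold_ap,
        fold_precision_at_100=fold_p100,
        fold_log_loss=fold_ll,
    )


def write_scores(scores: dict[str, float], path: str | Path) -> Path:
    """TSV of (patient_id, margin_score, rank), rank 1 = highest score."""
    path = Path(path)
    ordered = sorted(scores, key=lambda pid: (-scores[pid], pid))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("patient_id\tmargin_score\trank\n")
        for rank, pid in enumerate(ordered, start=1):
            fh.write(f"{pid}\t{scores[pid]:.10g}\t{rank}\n")
    return path


def write_cv_result(result: CVResult, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("fold\tauc\taverage_precision\tprecision_at_100\tlog_loss\n")
        for i in range(result.n_fold_evaluations):
            fh.write(
                f"{i}\t{result.fold_auc[i]:.6g}\t{result.fold_average_precision[i]:.6g}\t"
                f"{result.fold_precision_at_100[i]:.6g}\t{result.fold_log_loss[i]:.6g}\n"
            )
        fh.write(
            f"aggregate\t{result.auc:.6g}\t{result.average_precision:.6g}\t"
            f"{result.precision_at_100:.6g}\t{result.log_loss:.6g}\n"
        )
    return path
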