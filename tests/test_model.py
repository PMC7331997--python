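"""Detector training, cross-validation and ranking metrics.

AUC is cross-checked against an exhaustive pairwise-comparison oracle;
planted-signal and permutation-null simulations bound the metrics from
both sides.
"""

import itertools

import numpy as np
import pytest
import scipy.sparse as sp

from raredetect.corpus import DocType
from raredetect.enrichment import LabelSet
from raredetect.features import EncodedMatrix, FeatureKey, build_matrix, encode
from raredetect.model import (
    DetectorConfig,
    cross_validate,
    precision_at_k,
    ranking_metrics,
    score,
    train,
)
from raredetect.pipeline import PipelineConfig, run_pipeline
from raredetect.simulate import SignalSpec, SimConfig, simulate_corpus


def make_encoded(X: np.ndarray) -> EncodedMatrix:
    pids = [f"p{i:03d}" for i in range(X.shape[0])]
    vocab = [FeatureKey(DocType.NOTES, "t", f"f{j}") for j in range(X.shape[1])]
    return EncodedMatrix(pids, vocab, sp.csr_matrix(X), "linear", np.ones(X.shape[1]))


def make_labels(y: np.ndarray, pids: list[str]) -> LabelSet:
    return LabelSet(
        positives={p for p, yy in zip(pids, y) if yy},
        negatives={p for p, yy in zip(pids, y) if not yy},
    )


def separable_data(n=20):
    rng = np.random.default_rng(0)
    y = np.array([1] * (n // 2) + [0] * (n // 2))
    X = np.column_stack([y + 0.05 * rng.normal(size=n), rng.uniform(size=n)])
    X = np.clip(X, 0, 1)
    enc = make_encoded(X)
    return enc, make_labels(y, enc.patient_ids), y


class TestTrain:
    def test_separable_fixture_training_auc_is_one(self):
        enc, labels, _ = separable_data()
        det = train(enc, labels, DetectorConfig(seed=1))
        auc, _, _ = ranking_metrics(score(det, enc), labels)
        assert auc == 1.0

    def test_identical_inputs_and_seed_identical_state_hash(self):
        enc, labels, _ = separable_data()
        h1 = train(enc, labels, DetectorConfig(seed=4)).state_hash()
        h2 = train(enc, labels, DetectorConfig(seed=4)).state_hash()
        assert h1 == h2

    def test_single_class_rejected(self):
        enc, _, y = separable_data()
        labels = LabelSet(positives=set(), negatives=set(enc.patient_ids))
        with pytest.raises(ValueError):
            train(enc, labels, DetectorConfig())

    @pytest.mark.parametrize("kernel", ["rbf", "linear", "poly2"])
    def test_all_kernels_fit_and_rank(self, kernel):
        enc, labels, _ = separable_data()
        det = train(enc, labels, DetectorConfig(kernel=kernel, seed=2))
        auc, _, _ = ranking_metrics(score(det, enc), labels)
        assert auc > 0.9


class TestScore:
    def test_one_score_per_patient(self):
        enc, labels, _ = separable_data()
        det = train(enc, labels, DetectorConfig(seed=1))
        s = score(det, enc)
        assert set(s) == set(enc.patient_ids)

    def test_duplicate_rows_identical_scores(self):
        enc, labels, _ = separable_data()
        det = train(enc, labels, DetectorConfig(seed=1))
        X = enc.values.toarray()
        X2 = np.vstack([X[:1], X[:1]])
        enc2 = EncodedMatrix(["a", "b"], list(enc.vocabulary), sp.csr_matrix(X2), "linear", enc.per_feature_max)
        s = score(det, enc2)
        assert s["a"] == s["b"]

    def test_vocabulary_mismatch_rejected(self):
        enc, labels, _ = separable_data()
        det = train(enc, labels, DetectorConfig(seed=1))
        bad = EncodedMatrix(
            enc.patient_ids,
            list(reversed(enc.vocabulary)),
            enc.values,
            "linear",
            enc.per_feature_max,
        )
        with pytest.raises(ValueError, match="aligned"):
            score(det, bad)

    def test_positives_outscore_negatives_on_planted_signal(self):
        corpus, truth = simulate_corpus(SimConfig(n_patients=600, prevalence=0.05, seed=8))
        matrix = build_matrix(corpus)
        labels = LabelSet(
            positives={pid for pid, c in truth.items() if c != "negative"},
            negatives={pid for pid, c in truth.items() if c == "negative"},
        )
        enc = encode(matrix, "log")
        det = train(enc, labels, DetectorConfig(seed=2))
        s = score(det, enc)
        mean_pos = np.mean([s[p] for p in labels.positives])
        mean_neg = np.mean([s[p] for p in labels.negatives])
        assert mean_pos > mean_neg


class TestCrossValidate:
    def test_defaults_give_ten_fold_evaluations(self):
        enc, labels, _ = separable_data(40)
        cv = cross_validate(enc, labels, DetectorConfig(seed=1))
        assert cv.n_fold_evaluations == 10

    def test_separable_data_auc_one_in_every_fold(self):
        enc, labels, _ = separable_data(40)
        cv = cross_validate(enc, labels, DetectorConfig(seed=1))
        assert all(a == 1.0 for a in cv.fold_auc)

    def test_too_few_positives_rejected(self):
        enc, _, y = separable_data(20)
        labels = make_labels(np.array([1] + [0] * 19), enc.patient_ids)
        with pytest.raises(ValueError, match="cv_folds"):
            cross_validate(enc, labels, DetectorConfig())

    def test_shuffled_labels_give_null_auc(self):
        """Labels independent of features -> AUC ~ 0.5 at n = 2000."""
        rng = np.random.default_rng(42)
        X = rng.uniform(0, 1, size=(2000, 10))
        y = np.zeros(2000, dtype=int)
        y[rng.choice(2000, 40, replace=False)] = 1
        enc = make_encoded(X)
        cv = cross_validate(enc, make_labels(y, enc.patient_ids), DetectorConfig(seed=0))
        assert 0.4 <= cv.auc <= 0.6


class TestPrecisionAtK:
    def test_hand_arithmetic(self):
        scores = {f"p{i:03d}": -float(i) for i in range(200)}
        labels = make_labels(
            np.array([1 if i in (3, 50, 99) else 0 for i in range(200)]),
            [f"p{i:03d}" for i in range(200)],
        )
        assert precision_at_k(scores, labels, 100) == pytest.approx(0.03)

    def test_all_positives_in_top_k(self):
        pids = [f"p{i}" for i in range(10)]
        scores = {p: 10.0 - i for i, p in enumerate(pids)}
        labels = make_labels(np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0]), pids)
        assert precision_at_k(scores, labels, 5) == pytest.approx(3 / 5)
        assert precision_at_k(scores, labels, 3) == 1.0

    def test_tie_broken_by_patient_id(self):
        scores = {"a": 1.0, "b": 1.0, "c": 0.0}
        labels = LabelSet(positives={"a"}, negatives={"b", "c"})
        assert precision_at_k(scores, labels, 1) == 1.0  # "a" before "b"

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            precision_at_k({"a": 1.0}, LabelSet(positives={"a"}, negatives=set()), 0)


def pairwise_auc(scores: dict, labels: LabelSet) -> float:
    """Exhaustive oracle: P(random positive outscores random negative),
    ties counting one half."""
    wins = 0.0
    pairs = 0
    for p in labels.positives:
        for n in labels.negatives:
            pairs += 1
            if scores[p] > scores[n]:
                wins += 1
            elif scores[p] == scores[n]:
                wins += 0.5
    return wins / pairs


class TestRankingMetrics:
    def test_perfect_ranking(self):
        pids = ["a", "b", "c", "d"]
        scores = dict(zip(pids, [4.0, 3.0, 2.0, 1.0]))
        labels = LabelSet(positives={"a", "b"}, negatives={"c", "d"})
        auc, ap, _ = ranking_metrics(scores, labels)
        assert auc == 1.0 and ap == 1.0

    def test_reversed_ranking_antisymmetry(self):
        pids = [f"p{i}" for i in range(10)]
        scores = {p: float(i) for i, p in enumerate(pids)}
        labels = LabelSet(positives=set(pids[:5]), negatives=set(pids[5:]))
        auc, _, _ = ranking_metrics(scores, labels)
        assert auc == 0.0

    def test_hand_value_075(self):
        scores = {"p1": 0.9, "p2": 0.4, "n1": 0.7, "n2": 0.1}
        labels = LabelSet(positives={"p1", "p2"}, negatives={"n1", "n2"})
        auc, _, _ = ranking_metrics(scores, labels)
        assert auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ranking_metrics({"a": 1.0}, LabelSet(positives={"a"}, negatives=set()))

    @pytest.mark.parametrize("seed", range(4))
    def test_auc_equals_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 100))
        pids = [f"p{i}" for i in range(n)]
        # quantized scores so ties occur
        scores = {p: float(rng.integers(0, 8)) for p in pids}
        y = np.zeros(n, dtype=int)
        y[rng.choice(n, max(1, n // 4), replace=False)] = 1
        labels = make_labels(y, pids)
        auc, _, _ = ranking_metrics(scores, labels)
        assert auc == pytest.approx(pairwise_auc(scores, labels), abs=1e-12)


def _cv_auc_for_rate_ratio(rate_ratio: float, seed: int) -> float:
    """Detector CV AUC on a label-independent (frequency-selected) note
    feature set, so the null case is a clean permutation null: with
    rate_ratio 1 the labels are independent of every retained feature."""
    cfg = PipelineConfig.from_dict(
        {
            "seed": seed,
            "sim": {
                "n_patients": 800,
                "prevalence": 0.02,
                "signal": {"rate_ratio": rate_ratio, "base_rate": 0.4},
            },
            "detector": {"cv_reps": 2},
        }
    )
    from raredetect.simulate import simulate_corpus
    from raredetect.enrichment import build_labels, list_candidates
    from raredetect.features import top_frequency_features
    from raredetect.veto import apply_veto, leakage_veto_rules

    corpus, truth = simulate_corpus(cfg.sim)
    candidates = list_candidates(corpus, cfg.sim.leakage.disease_code)
    labels = build_labels(
        corpus, candidates, {p for p in candidates if truth[p] == "diagnosed_positive"}
    )
    matrix = build_matrix(corpus)
    retained = apply_veto(matrix.vocabulary, leakage_veto_rules(cfg.sim.leakage)).retained
    feats = top_frequency_features(matrix, 150, doc_types=(DocType.NOTES,), features=retained)
    enc = encode(matrix.select(feats), "log")
    return cross_validate(enc, labels, cfg.detector).auc


def test_signal_strength_recovery_is_monotone():
    """Mean CV AUC is ~0.5 with no signal and increases with rate ratio."""
    ratios = (1.0, 4.0, 16.0)
    mean_auc = {
        r: np.mean([_cv_auc_for_rate_ratio(r, seed) for seed in range(3)]) for r in ratios
    }
    assert abs(mean_auc[1.0] - 0.5) < 0.15
    assert mean_auc[1.0] < mean_auc[4.0] <= mean_auc[16.0] + 0.02
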