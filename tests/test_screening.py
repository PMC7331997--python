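"""Odds-ratio statistics and the three-part screening filter.

The screening path is checked against an independent brute-force oracle
that enumerates every 2x2 table directly from the dense matrix and
applies the filter and tie rules from first principles.
"""

import numpy as np
import pytest
import scipy.stats

from raredetect.corpus import DocType
from raredetect.enrichment import LabelSet
from raredetect.features import FeatureKey, FeatureMatrix
from raredetect.screening import (
    ContingencyTable,
    ScreenParams,
    contingency,
    odds_ratio_test,
    screen_features,
)
from tests.conftest import random_feature_matrix, random_labels

import scipy.sparse as sp


class TestOddsRatio:
    def test_balanced_table_gives_unity(self):
        oratio, _ = odds_ratio_test(ContingencyTable(5, 5, 5, 5))
        assert oratio == 1.0

    def test_direct_formula(self):
        oratio, _ = odds_ratio_test(ContingencyTable(5, 25, 100, 199900))
        assert oratio == pytest.approx((5 * 199900) / (25 * 100))
        assert oratio == pytest.approx(399.8)

    def test_haldane_corrected_zero_cell(self):
        oratio, _ = odds_ratio_test(ContingencyTable(4, 26, 0, 1000))
        assert oratio == pytest.approx((4.5 * 1000.5) / (26.5 * 0.5), rel=1e-12)

    def test_all_zero_cells_undefined(self):
        with pytest.raises(ValueError):
            odds_ratio_test(ContingencyTable(0, 0, 0, 0))

    def test_p_value_is_exact_test_on_uncorrected_table(self):
        table = ContingencyTable(4, 26, 3, 967)
        _, p = odds_ratio_test(table)
        _, p_ref = scipy.stats.fisher_exact([[4, 26], [3, 967]])
        assert p == pytest.approx(p_ref, rel=1e-12)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)


class TestContingency:
    def matrix_and_labels(self):
        dense = np.array(
            [  # feat0 feat1 feat2
                [1, 0, 2],  # pos
                [0, 0, 1],  # pos
                [3, 0, 0],  # neg
                [0, 0, 0],  # neg
                [1, 0, 1],  # neg
            ]
        )
        vocab = [FeatureKey(DocType.NOTES, "t", f"f{j}") for j in range(3)]
        m = FeatureMatrix([f"p{i}" for i in range(5)], vocab, sp.csr_matrix(dense))
        labels = LabelSet(positives={"p0", "p1"}, negatives={"p2", "p3", "p4"})
        return m, vocab, labels

    def test_hand_placed_presences(self):
        m, vocab, labels = self.matrix_and_labels()
        t = contingency(m, vocab[0], labels)
        assert (t.a, t.b, t.c, t.d) == (1, 1, 2, 1)

    def test_feature_absent_everywhere(self):
        m, vocab, labels = self.matrix_and_labels()
        t = contingency(m, vocab[1], labels)
        assert (t.a, t.c) == (0, 0)

    def test_feature_present_everywhere(self):
        vocab = [FeatureKey(DocType.NOTES, "t", "f0")]
        m = FeatureMatrix(["p0", "p1"], vocab, sp.csr_matrix(np.array([[1], [4]])))
        labels = LabelSet(positives={"p0"}, negatives={"p1"})
        t = contingency(m, vocab[0], labels)
        assert (t.b, t.d) == (0, 0)

    def test_unknown_feature_raises(self):
        m, _, labels = self.matrix_and_labels()
        with pytest.raises(KeyError):
            contingency(m, FeatureKey(DocType.VITALS, "x", "nope"), labels)


def brute_force_screen(matrix: FeatureMatrix, labels: LabelSet, params: ScreenParams):
    """Independent oracle: per-feature 2x2 tables computed row by row,
    filter and tie rules applied from the definitions."""
    y = {pid: labels.label_of(pid) for pid in matrix.patient_ids}
    dense = matrix.counts.toarray()
    results = {}
    for j, fk in enumerate(matrix.vocabulary):
        a = b = c = d = 0
        for i, pid in enumerate(matrix.patient_ids):
            present = dense[i, j] > 0
            if y[pid] == 1:
                a, b = a + present, b + (not present)
            else:
                c, d = c + present, d + (not present)
        aa, bb, cc, dd = (a, b, c, d)
        if min(aa, bb, cc, dd) == 0:
            aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        oratio = aa * dd / (bb * cc)
        _, p = scipy.stats.fisher_exact([[a, b], [c, d]])
        results[fk] = (oratio, p, a)
    selected = set()
    for dt in {fk.doc_type for fk in results}:
        survivors = [
            fk
            for fk, (o, p, a) in results.items()
            if fk.doc_type == dt and p < params.alpha and a >= params.min_pos
        ]
        survivors.sort(key=lambda fk: (-results[fk][0], results[fk][1], fk.sort_key()))
        selected |= set(survivors[: params.per_type_k])
    return results, selected


class TestScreenFeatures:
    def test_min_pos_boundary(self):
        # one feature present in exactly 4 positives, one in exactly 3;
        # both perfectly associated with the label
        n_pos, n_neg = 5, 45
        dense = np.zeros((n_pos + n_neg, 2), dtype=int)
        dense[:4, 0] = 1
        dense[:3, 1] = 1
        vocab = [FeatureKey(DocType.NOTES, "t", "four"), FeatureKey(DocType.NOTES, "t", "three")]
        pids = [f"p{i}" for i in range(n_pos + n_neg)]
        m = FeatureMatrix(pids, vocab, sp.csr_matrix(dense))
        labels = LabelSet(positives=set(pids[:n_pos]), negatives=set(pids[n_pos:]))
        recs = {r.feature.token: r for r in screen_features(m, labels, ScreenParams())}
        assert recs["four"].passed_min_pos and recs["four"].selected
        assert not recs["three"].passed_min_pos and not recs["three"].selected
        assert recs["three"].passed_alpha  # fails only the occurrence filter

    def test_per_type_cap(self):
        """150 perfectly-label-aligned features in one doc type -> 100 selected."""
        rng = np.random.default_rng(1)
        n_pos, n_neg = 10, 40
        dense = np.zeros((50, 150), dtype=int)
        for j in range(150):
            dense[:n_pos, j] = 1  # in every positive
            # in j%3 negatives, so odds ratios (and ties) vary
            dense[n_pos : n_pos + j % 3, j] = 1
        vocab = [FeatureKey(DocType.LAB_RESULTS, "lab_name", f"t{j:03d}") for j in range(150)]
        pids = [f"p{i}" for i in range(50)]
        m = FeatureMatrix(pids, vocab, sp.csr_matrix(dense))
        labels = LabelSet(positives=set(pids[:n_pos]), negatives=set(pids[n_pos:]))
        params = ScreenParams(per_type_k=100)
        recs = screen_features(m, labels, params)
        assert sum(r.selected for r in recs) == 100
        assert all(r.passed_alpha and r.passed_min_pos for r in recs)

    def test_empty_class_rejected(self):
        m = random_feature_matrix(np.random.default_rng(0), 10, 5)
        labels = LabelSet(positives=set(), negatives=set(m.patient_ids))
        with pytest.raises(ValueError, match="empty label class"):
            screen_features(m, labels)

    def test_selected_implies_both_filters(self):
        rng = np.random.default_rng(3)
        m = random_feature_matrix(rng, 40, 80)
        labels = random_labels(rng, m.patient_ids, 8)
        for r in screen_features(m, labels, ScreenParams(min_pos=2)):
            if r.selected:
                assert r.passed_alpha and r.passed_min_pos

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, f = int(rng.integers(10, 50)), int(rng.integers(10, 200))
        m = random_feature_matrix(rng, n, f)
        labels = random_labels(rng, m.patient_ids, max(2, n // 5))
        params = ScreenParams(alpha=0.3, min_pos=1, per_type_k=10)
        recs = screen_features(m, labels, params)
        oracle_stats, oracle_selected = brute_force_screen(m, labels, params)
        for r in recs:
            o_or, o_p, o_a = oracle_stats[r.feature]
            assert r.odds_ratio == pytest.approx(o_or, rel=1e-12)
            assert r.p_value == pytest.approx(o_p, rel=1e-9)
            assert r.n_pos_patients == o_a
        assert {r.feature for r in recs if r.selected} == oracle_selected

    def test_invariant_to_patient_order(self):
        rng = np.random.default_rng(9)
        m = random_feature_matrix(rng, 30, 40)
        labels = random_labels(rng, m.patient_ids, 6)
        perm = rng.permutation(30)
        m2 = FeatureMatrix(
            [m.patient_ids[i] for i in perm], list(m.vocabulary), m.counts[perm]
        )
        sel1 = {r.feature for r in screen_features(m, labels, ScreenParams(alpha=0.5, min_pos=1)) if r.selected}
        sel2 = {r.feature for r in screen_features(m2, labels, ScreenParams(alpha=0.5, min_pos=1)) if r.selected}
        assert sel1 == sel2
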