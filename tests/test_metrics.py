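"""Evaluation metrics against brute-force oracles and independent references."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats
from sklearn import metrics as skm

from rpscore.exceptions import UndefinedMetricError, ValidationError
from rpscore.metrics import (
    auprc,
    auroc,
    chi_squared,
    mann_whitney_u,
    roc_points,
    youden_cutpoint,
)


def auroc_pairwise_oracle(scores, labels):
    """O(n^2) concordance count over all positive-negative pairs."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestAuroc:
    def test_separable_and_tied(self):
        assert auroc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
        assert auroc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_matches_pairwise_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(4, 20)
            s = rng.choice([0.1, 0.3, 0.5, 0.7], size=n)  # force ties
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            assert auroc(s, y) == pytest.approx(auroc_pairwise_oracle(s, y), abs=1e-12)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            s = rng.normal(size=60)
            y = rng.integers(0, 2, size=60)
            if y.min() == y.max():
                continue
            assert auroc(s, y) == pytest.approx(skm.roc_auc_score(y, s), abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_complement_and_monotone_invariance(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.permutation(np.arange(30, dtype=float))  # tie-free
        y = np.r_[np.zeros(15, int), np.ones(15, int)]
        a = auroc(s, y)
        assert a + auroc(-s, y) == pytest.approx(1.0, abs=1e-12)
        assert auroc(np.exp(s / 10), y) == pytest.approx(a, abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(UndefinedMetricError):
            auroc([1, 2, 3], [1, 1, 1])


class TestAuprc:
    def test_perfect_ranking(self):
        assert auprc([4, 3, 2, 1], [1, 1, 0, 0]) == 1.0

    def test_hand_enumerated_staircase(self):
        # thresholds desc: tp/called = 1/1, 1/2, 2/3, 3/4, 3/5, 3/6
        # AP = (1/3)(1) + (1/3)(2/3) + (1/3)(3/4) = 29/36
        s = [0.9, 0.8, 0.7, 0.6, 0.5, 0.4]
        y = [1, 0, 1, 1, 0, 0]
        assert auprc(s, y) == pytest.approx(29 / 36, abs=1e-12)

    def test_random_scores_approach_prevalence(self):
        rng = np.random.default_rng(7)
        n, p = 5000, 0.3
        y = (rng.uniform(size=n) < p).astype(int)
        s = rng.normal(size=n)
        assert auprc(s, y) == pytest.approx(y.mean(), abs=0.03)

    def test_matches_sklearn_average_precision(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            s = rng.choice([0.2, 0.4, 0.6, 0.8], size=40)
            y = rng.integers(0, 2, size=40)
            if y.sum() == 0:
                continue
            assert auprc(s, y) == pytest.approx(
                skm.average_precision_score(y, s), abs=1e-12
            )

    def test_no_positives_raises(self):
        with pytest.raises(UndefinedMetricError):
            auprc([1, 2], [0, 0])


class TestYouden:
    def test_separable(self):
        t, sens, spec = youden_cutpoint([1, 2, 10, 11], [0, 0, 1, 1])
        assert (sens, spec) == (1.0, 1.0)
        assert t == 10

    def test_all_tied_scores(self):
        t, sens, spec = youden_cutpoint([3, 3, 3, 3], [0, 1, 0, 1])
        assert sens + spec - 1 == pytest.approx(0.0)

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(5)
        s = rng.choice([1.0, 2.0, 3.0, 4.0, 5.0], size=10)
        y = np.array([0, 1, 0, 1, 1, 0, 1, 0, 0, 1])
        best_j = max(
            ((s >= t) & (y == 1)).sum() / (y == 1).sum()
            - ((s >= t) & (y == 0)).sum() / (y == 0).sum()
            for t in np.unique(s)
        )
        t, sens, spec = youden_cutpoint(s, y)
        assert sens + spec - 1 == pytest.approx(best_j, abs=1e-12)


class TestMannWhitney:
    def test_identical_samples_not_significant(self):
        _, p = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert p >= 0.9

    def test_extreme_configuration(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        # z = (|0 - 4.5| - 0.5) / sqrt(3*3*7/12)
        assert p == pytest.approx(2 * sstats.norm.sf(4.0 / np.sqrt(5.25)), abs=1e-12)

    def test_large_planted_shift(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 100)
        b = rng.normal(2, 1, 100)
        _, p = mann_whitney_u(a, b)
        assert p < 1e-6

    def test_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            a = rng.normal(size=25)
            b = rng.normal(0.3, 1.2, size=30)
            u, p = mann_whitney_u(a, b)
            ref = sstats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic", use_continuity=True
            )
            assert u == pytest.approx(ref.statistic, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-6)

    def test_empty_sample_raises(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1, 2])


class TestChiSquared:
    def test_independent_table(self):
        stat, p = chi_squared([[10, 10], [10, 10]])
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_hand_computed_diagonal(self):
        stat, _ = chi_squared([[20, 0], [0, 20]])
        assert stat == pytest.approx(40.0)

    def test_proportional_rows_unchanged_p(self):
        _, p1 = chi_squared([[5, 10, 15], [10, 20, 30]])
        assert p1 == pytest.approx(1.0)

    def test_matches_scipy(self):
        table = [[12, 5, 9], [7, 14, 3]]
        stat, p = chi_squared(table)
        ref = sstats.chi2_contingency(table, correction=False)
        assert stat == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_zero_margin_raises(self):
        with pytest.raises(ValidationError):
            chi_squared([[0, 0], [5, 5]])


class TestRocPoints:
    def test_confusion_identities_hold_pointwise(self):
        rng = np.random.default_rng(8)
        s = rng.choice([0.1, 0.5, 0.9], size=30)
        y = rng.integers(0, 2, size=30)
        pts = roc_points(s, y)
        n1, n0 = y.sum(), (y == 0).sum()
        for _, row in pts.iterrows():
            assert row.tp + row.fn == n1
            assert row.fp + row.tn == n0
            assert row.tpr == pytest.approx(row.tp / (row.tp + row.fn))
            assert row.fpr == pytest.approx(row.fp / (row.fp + row.tn))
            assert row.precision == pytest.approx(row.tp / (row.tp + row.fp))
            assert row.recall == row.tpr
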