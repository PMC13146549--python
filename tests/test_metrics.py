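import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from nabind import metrics


class TestConfusion:
    def test_perfect_and_inverted_counts(self):
        c = metrics.confusion([1, 0], [1, 0])
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 0, 0)
        c = metrics.confusion([0, 1], [1, 0])
        assert (c.tp, c.tn) == (0, 0)

    def test_counts_sum_to_n(self):
        rng = np.random.default_rng(0)
        pred, truth = rng.integers(0, 2, 50), rng.integers(0, 2, 50)
        c = metrics.confusion(pred, truth)
        assert c.total == 50

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            metrics.confusion([1], [1, 0])


class TestScalarMetrics:
    def test_perfect_classifier_scores_one(self):
        c = metrics.ConfusionCounts(tp=1, fp=0, tn=1, fn=0)
        assert metrics.precision(c) == metrics.recall(c) == metrics.f1(c) == 1.0
        assert metrics.mcc(c) == 1.0

    def test_mcc_hand_arithmetic(self):
        c = metrics.ConfusionCounts(tp=50, fp=10, tn=30, fn=10)
        expected = (50 * 30 - 10 * 10) / math.sqrt(60 * 60 * 40 * 40)
        assert metrics.mcc(c) == pytest.approx(expected, abs=1e-15)

    def test_mcc_sign_flips_under_class_swap(self):
        pred = np.array([1, 1, 0, 0, 1, 0])
        truth = np.array([1, 0, 0, 1, 1, 0])
        m = metrics.mcc(metrics.confusion(pred, truth))
        m_swapped = metrics.mcc(metrics.confusion(1 - pred, truth))
        assert m_swapped == pytest.approx(-m, abs=1e-12)

    def test_zero_denominator_returns_zero_with_warning(self):
        c = metrics.ConfusionCounts(tp=0, fp=0, tn=5, fn=0)
        with pytest.warns(UserWarning):
            assert metrics.precision(c) == 0.0

    @settings(deadline=None, max_examples=200)
    @given(st.tuples(*(st.integers(0, 200) for _ in range(4))))
    def test_formula_oracle_agreement(self, counts):
        """Implementations agree with naive per-formula arithmetic."""
        tp, fp, tn, fn = counts
        c = metrics.ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pre = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            f1 = 2 * rec * pre / (rec + pre) if rec + pre else 0.0
            den = math.sqrt(
                float(tp + fn) * (tp + fp) * (tn + fn) * (tn + fp)
            )
            mcc = (tp * tn - fn * fp) / den if den else 0.0
            assert metrics.precision(c) == pytest.approx(pre, abs=1e-12)
            assert metrics.recall(c) == pytest.approx(rec, abs=1e-12)
            assert metrics.f1(c) == pytest.approx(f1, abs=1e-12)
            assert metrics.mcc(c) == pytest.approx(mcc, abs=1e-12)


def _auroc_pair_counting(scores, labels):
    scores = np.asarray(scores, dtype=float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAuroc:
    def test_separated_scores_give_one(self):
        assert metrics.auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_constant_scores_give_half(self):
        assert metrics.auroc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            metrics.auroc([0.1, 0.2], [1, 1])

    @settings(deadline=None, max_examples=100)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_pairwise_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 20))
        scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
        labels = np.zeros(n, dtype=int)
        labels[: int(rng.integers(1, n))] = 1
        rng.shuffle(labels)
        if labels.sum() in (0, n):
            labels[0], labels[-1] = 1, 0
        assert metrics.auroc(scores, labels) == pytest.approx(
            _auroc_pair_counting(scores, labels), abs=1e-12
        )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        labels[0], labels[1] = 0, 1
        base = metrics.auroc(scores, labels)
        assert metrics.auroc(np.exp(3 * scores), labels) == pytest.approx(base, abs=1e-12)


class TestRelativeImprovement:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (0.889, 0.757, 17.44),
            (0.922, 0.881, 4.65),
            (0.990, 0.959, 3.23),
            (0.5, 0.5, 0.0),
        ],
    )
    def test_benchmark_percentages(self, a, b, expected):
        assert metrics.relative_improvement(a, b) == expected

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            metrics.relative_improvement(0.5, 0.0)


class TestMannWhitney:
    def test_extreme_small_sample_exact_p(self):
        u, p = metrics.mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(2 / 6, abs=1e-12)

    def test_identical_multisets_give_p_one(self):
        _, p = metrics.mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_symmetric_in_sample_order(self):
        x, y = [0.1, 0.9, 0.4], [0.5, 0.2]
        _, p_xy = metrics.mann_whitney_u(x, y)
        _, p_yx = metrics.mann_whitney_u(y, x)
        assert p_xy == pytest.approx(p_yx, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            metrics.mann_whitney_u([], [1.0])

    @settings(deadline=None, max_examples=40)
    @given(st.integers(0, 2**31 - 1))
    def test_exact_path_matches_scipy_exact(self, seed):
        """No-tie small samples: enumeration agrees with scipy's exact method."""
        rng = np.random.default_rng(seed)
        nx, ny = int(rng.integers(2, 6)), int(rng.integers(2, 6))
        vals = rng.permutation(np.arange(1.0, nx + ny + 1))
        x, y = vals[:nx], vals[nx:]
        u, p = metrics.mann_whitney_u(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert u == ref.statistic
        assert p == pytest.approx(ref.pvalue, abs=1e-9)


class TestBenjaminiHochberg:
    def test_hand_stepup_example(self):
        adjusted = metrics.bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adjusted, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(metrics.bh_adjust([0.2]), [0.2])

    def test_monotone_in_sorted_order_and_vs_hand_oracle(self):
        rng = np.random.default_rng(0)
        p = rng.random(25)
        adjusted = metrics.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adjusted[order]) >= -1e-12).all()
        # independent step-up computation
        n = len(p)
        ranked = p[order] * n / (np.arange(n) + 1)
        hand = np.minimum.accumulate(ranked[::-1])[::-1]
        hand = np.minimum(hand, 1.0)
        np.testing.assert_allclose(adjusted[order], hand, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            metrics.bh_adjust([0.5, 1.5])


class TestComparisonProtocol:
    def test_compare_models_report_structure(self):
        model = {"mcc": [0.80, 0.82, 0.81, 0.83], "auroc": [0.95, 0.96, 0.94, 0.95]}
        base = {"mcc": [0.60, 0.61, 0.62, 0.59], "auroc": [0.90, 0.91, 0.89, 0.90]}
        report = metrics.compare_models(model, base)
        assert report.metrics == ["mcc", "auroc"]
        assert all(i > 0 for i in report.improvement_pct)
        assert all(pa >= pr - 1e-15 for pa, pr in zip(report.p_adjusted, report.p_raw))
        assert report.significant == [p <= 0.05 for p in report.p_adjusted]

    def test_no_shared_metrics_rejected(self):
        with pytest.raises(ValueError):
            metrics.compare_models({"mcc": [1.0]}, {"auroc": [1.0]})
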