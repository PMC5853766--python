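"""Diagnostic-accuracy arithmetic and exact binomial intervals."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import heartsound as hs
from heartsound.evaluation import (ConfusionCounts, binarize_label, clopper_pearson,
                                   confusion, confusion_matrix_5class,
                                   diagnostic_metrics, evaluate_dataset,
                                   format_metrics_table)


def cp_bisect(k: int, n: int, level: float = 0.95, tol: float = 1e-9):
    """Independent oracle: invert the binomial CDF by bisection."""
    alpha = 1 - level

    def solve(f, lo, hi):
        for _ in range(100):
            mid = (lo + hi) / 2
            if f(mid):
                lo = mid
            else:
                hi = mid
            if hi - lo < tol:
                break
        return (lo + hi) / 2

    # lower: largest p with P(X >= k | p) <= alpha/2
    lower = 0.0 if k == 0 else solve(
        lambda p: stats.binom.sf(k - 1, n, p) <= alpha / 2, 0.0, 1.0)
    # upper: smallest p with P(X <= k | p) <= alpha/2
    upper = 1.0 if k == n else 1.0 - solve(
        lambda q: stats.binom.cdf(k, n, 1.0 - q) <= alpha / 2, 0.0, 1.0)
    return lower, upper


class TestClopperPearson:
    @pytest.mark.parametrize("k,n,lo_pct,hi_pct", [
        (27, 30, 73, 98),   # 90% accuracy cell
        (15, 16, 70, 100),  # 94% sensitivity cell
        (26, 30, 69, 96),   # 87% accuracy cell
        (12, 14, 57, 98),   # 86% specificity cell
        (13, 16, 54, 96),   # 81% sensitivity cell
        (11, 14, 49, 95),   # 79% specificity cell
        (15, 18, 59, 96),   # 83% PPV cell
        (14, 17, 57, 96),   # 82% NPV cell
    ], ids=lambda v: str(v))
    def test_matches_published_whole_percent_intervals(self, k, n, lo_pct, hi_pct):
        ci = clopper_pearson(k, n)
        assert round(100 * ci.lower) == lo_pct
        assert round(100 * ci.upper) == hi_pct

    def test_boundaries_are_exact(self):
        assert clopper_pearson(0, 10).lower == 0.0
        assert clopper_pearson(10, 10).upper == 1.0

    def test_agrees_with_binomial_cdf_bisection_small_n(self):
        for n in range(1, 21):
            for k in range(n + 1):
                ci = clopper_pearson(k, n)
                lo, hi = cp_bisect(k, n)
                assert ci.lower == pytest.approx(lo, abs=1e-6)
                assert ci.upper == pytest.approx(hi, abs=1e-6)

    @given(st.integers(0, 50), st.integers(1, 50))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_interval_contains_point_estimate(self, k, n):
        k = min(k, n)
        ci = clopper_pearson(k, n)
        assert 0.0 <= ci.lower <= k / n <= ci.upper <= 1.0

    def test_width_shrinks_with_n_at_fixed_ratio(self):
        widths = []
        for n in (10, 20, 40, 80, 160):
            ci = clopper_pearson(int(0.8 * n), n)
            widths.append(ci.upper - ci.lower)
        assert all(a > b for a, b in zip(widths, widths[1:]))

    def test_rejects_bad_inputs(self):
        with pytest.raises(hs.ConfigurationError):
            clopper_pearson(5, 4)
        with pytest.raises(hs.ConfigurationError):
            clopper_pearson(0, 0)


class TestDiagnosticMetrics:
    @pytest.mark.parametrize("counts,expected", [
        # (tp, fp, fn, tn) -> whole-percent (acc, sens, spec, ppv, npv)
        ((15, 2, 1, 12), (90, 94, 86, 88, 92)),
        ((15, 3, 1, 11), (87, 94, 79, 83, 92)),
        ((13, 0, 3, 14), (90, 81, 100, 100, 82)),
        ((10, 0, 0, 10), (100, 100, 100, 100, 100)),
    ], ids=["device-a", "device-b", "device-c", "perfect"])
    def test_whole_percent_metrics(self, counts, expected):
        m = diagnostic_metrics(ConfusionCounts(*counts))
        got = tuple(round(100 * est.value) for est in m)
        assert got == expected

    def test_undefined_metric_is_flagged_not_zero(self):
        m = diagnostic_metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=5))
        assert not m.sensitivity.defined and not m.ppv.defined
        assert m.sensitivity.value is None
        assert m.sensitivity.as_percent() == "—"
        assert m.specificity.value == 1.0

    def test_report_renders_whole_percent(self):
        text = format_metrics_table(diagnostic_metrics(ConfusionCounts(15, 2, 1, 12)))
        assert "90 (73-98)" in text and "94 (70-100)" in text


class TestConfusion:
    def test_binarize(self):
        assert binarize_label(hs.SoundClass.NORMAL) == "negative"
        for c in (hs.SoundClass.S3, hs.SoundClass.S4,
                  hs.SoundClass.SYSTOLIC_MURMUR, hs.SoundClass.DIASTOLIC_MURMUR):
            assert binarize_label(c) == "positive"
        with pytest.raises(ValueError):
            binarize_label("wheeze")

    def test_counts_and_symmetry(self):
        pos = [hs.SoundClass.SYSTOLIC_MURMUR] * 16
        neg = [hs.SoundClass.NORMAL] * 14
        truths = pos + neg
        perfect = confusion(truths, truths)
        assert (perfect.tp, perfect.fp, perfect.fn, perfect.tn) == (16, 0, 0, 14)
        all_pos = confusion([hs.SoundClass.S3] * 30, truths)
        assert (all_pos.tp, all_pos.fp, all_pos.fn, all_pos.tn) == (16, 14, 0, 0)
        all_neg = confusion([hs.SoundClass.NORMAL] * 30, truths)
        assert (all_neg.tp, all_neg.fp, all_neg.fn, all_neg.tn) == (0, 0, 16, 14)

    def test_length_mismatch_rejected(self):
        with pytest.raises(hs.ConfigurationError):
            confusion([hs.SoundClass.NORMAL], [])


class TestEvaluateDataset:
    def _data(self, rng):
        classes = list(hs.SoundClass)
        truths = [classes[rng.integers(5)] for _ in range(40)]
        preds = [t if rng.random() < 0.8 else classes[rng.integers(5)] for t in truths]
        return preds, truths

    def test_total_row_matches_hand_count(self):
        rng = np.random.default_rng(0)
        preds, truths = self._data(rng)
        table = evaluate_dataset(preds, truths)
        row = table[table.subgroup == "total"].iloc[0]
        # brute-force recount
        tp = sum(p != hs.SoundClass.NORMAL and t != hs.SoundClass.NORMAL
                 for p, t in zip(preds, truths))
        tn = sum(p == hs.SoundClass.NORMAL and t == hs.SoundClass.NORMAL
                 for p, t in zip(preds, truths))
        assert row.n == 40
        assert row.accuracy == pytest.approx((tp + tn) / 40)

    def test_disjoint_subgroups_partition_total(self):
        rng = np.random.default_rng(1)
        preds, truths = self._data(rng)
        half = np.zeros(40, dtype=bool)
        half[:23] = True
        table = evaluate_dataset(preds, truths,
                                 subgroups={"a": half, "b": ~half})
        ns = dict(zip(table.subgroup, table.n))
        assert ns["a"] + ns["b"] == ns["total"]

    def test_bad_subgroup_mask_rejected(self):
        with pytest.raises(hs.ConfigurationError):
            evaluate_dataset([hs.SoundClass.NORMAL], [hs.SoundClass.NORMAL],
                             subgroups={"x": np.ones(3, dtype=bool)})

    def test_five_class_matrix_totals(self):
        rng = np.random.default_rng(2)
        preds, truths = self._data(rng)
        mat = confusion_matrix_5class(preds, truths)
        assert mat.to_numpy().sum() == 40
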