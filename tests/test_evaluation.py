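import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from _oracles import rank_auc
from hrvrefine.evaluation import confusion_metrics, group_ttest, roc_sweep, summarize_run
from hrvrefine.refine import assign_subject_types


class TestConfusionMetrics:
    def test_perfect_separation(self):
        m = confusion_metrics([0.3, 0.4, 0.8, 0.9], ["CHF", "CHF", "NSR", "NSR"], c=0.6)
        assert (m.se, m.sp, m.acc) == (1.0, 1.0, 1.0)
        assert (m.tp, m.tn, m.fp, m.fn) == (2, 2, 0, 0)

    def test_threshold_above_max_predicts_all_positive(self, rng):
        values = rng.uniform(0, 1, 50)
        labels = ["CHF"] * 25 + ["NSR"] * 25
        m = confusion_metrics(values, labels, c=values.max())
        assert m.se == 1.0 and m.sp == 0.0

    def test_matches_direct_tally(self, rng):
        values = rng.uniform(0, 1, 200)
        labels = np.where(rng.random(200) < 0.4, "CHF", "NSR")
        c = 0.5
        m = confusion_metrics(values, labels, c)
        tp = sum(v <= c and l == "CHF" for v, l in zip(values, labels))
        tn = sum(v > c and l == "NSR" for v, l in zip(values, labels))
        fp = sum(v <= c and l == "NSR" for v, l in zip(values, labels))
        fn = sum(v > c and l == "CHF" for v, l in zip(values, labels))
        assert (m.tp, m.tn, m.fp, m.fn) == (tp, tn, fp, fn)
        assert m.se == pytest.approx(tp / (tp + fn))
        assert m.sp == pytest.approx(tn / (tn + fp))
        assert m.acc == pytest.approx((tp + tn) / 200)
        assert m.j == pytest.approx(m.se + m.sp - 1)

    def test_one_class_absent_is_an_error(self):
        with pytest.raises(ValueError, match="both NSR and CHF"):
            confusion_metrics([0.1, 0.2], ["NSR", "NSR"], c=0.15)


class TestRocSweep:
    def test_perfectly_separated_groups(self):
        values = np.r_[np.full(30, 0.3), np.full(40, 0.9)]
        labels = ["CHF"] * 30 + ["NSR"] * 40
        report = roc_sweep(values, labels)
        assert report.auc == pytest.approx(1.0)
        assert report.metrics_at_c_star.j == pytest.approx(1.0)
        assert 0.3 <= report.c_star < 0.9

    def test_101_thresholds_spanning_the_range(self, rng):
        values = rng.uniform(0, 2, 100)
        labels = np.where(rng.random(100) < 0.5, "CHF", "NSR")
        report = roc_sweep(values, labels)
        assert report.thresholds.size == 101
        assert report.thresholds[0] == values.min()
        assert report.thresholds[-1] == values.max()
        step = (values.max() - values.min()) / 100
        np.testing.assert_allclose(np.diff(report.thresholds), step, rtol=1e-9)

    def test_trapezoid_auc_close_to_rank_statistic(self, rng):
        for _ in range(30):
            n = int(rng.integers(40, 300))
            labels = np.where(rng.random(n) < 0.5, "CHF", "NSR")
            if len(set(labels)) < 2:
                continue
            shift = rng.uniform(0, 1.5)
            values = rng.normal(0, 1, n) - shift * (labels == "CHF")
            report = roc_sweep(values, labels)
            assert report.auc == pytest.approx(rank_auc(values, labels), abs=0.01)

    def test_shuffled_labels_give_chance_auc(self, rng):
        values = rng.normal(0, 1, 2000)
        labels = np.where(rng.random(2000) < 0.5, "CHF", "NSR")
        report = roc_sweep(values, labels)
        assert 0.45 <= report.auc <= 0.55

    def test_se_monotone_nondecreasing_sp_nonincreasing_in_c(self, rng):
        values = rng.normal(0, 1, 300)
        labels = np.where(rng.random(300) < 0.4, "CHF", "NSR")
        report = roc_sweep(values, labels)
        assert np.all(np.diff(report.se) >= 0)
        assert np.all(np.diff(report.sp) <= 0)
        assert report.j.max() == pytest.approx(report.metrics_at_c_star.j)

    def test_auc_invariant_under_monotone_transform(self, rng):
        values = rng.uniform(0.1, 2, 400)
        labels = np.where(rng.random(400) < 0.5, "CHF", "NSR")
        a1 = roc_sweep(values, labels).auc
        a2 = roc_sweep(np.log(values), labels).auc
        assert a2 == pytest.approx(a1, abs=0.01)  # sweep grid shifts slightly

    def test_constrained_cutpoints(self):
        rng = np.random.default_rng(0)
        values = np.r_[rng.uniform(0.0, 0.5, 200), rng.uniform(0.4, 1.0, 200)]
        labels = ["CHF"] * 200 + ["NSR"] * 200
        report = roc_sweep(values, labels)
        assert report.metrics_at_c_se99.se > 0.99
        assert report.metrics_at_c_sp99.sp > 0.99
        # among swept thresholds meeting the constraint, Sp (resp. Se) is maximal
        mask = report.se > 0.99
        assert report.metrics_at_c_se99.sp == pytest.approx(report.sp[mask].max())
        mask = report.sp > 0.99
        assert report.metrics_at_c_sp99.se == pytest.approx(report.se[mask].max())

    def test_empty_constraint_flagged_as_none(self):
        # tiny sample where no swept c reaches Se > 0.99 without Sp collapse is
        # impossible; instead check the degenerate constant-values path
        report = roc_sweep([0.5, 0.5, 0.5, 0.5], ["CHF", "CHF", "NSR", "NSR"])
        assert report.thresholds.size == 1
        assert report.c_sp99 is None
        assert report.metrics_at_c_sp99 is None


class TestGroupTTest:
    def test_identical_groups(self):
        t, p = group_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_closed_form_hand_computation(self):
        # pooled s^2 = 1, SE = sqrt(2/3), t = -1/sqrt(2/3)
        t, p = group_ttest([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert t == pytest.approx(-math.sqrt(1.5), abs=1e-4)
        assert t == pytest.approx(-1.2247, abs=1e-4)

    def test_matches_textbook_formula(self, rng):
        a = rng.normal(0.9, 0.2, 40)
        b = rng.normal(0.5, 0.25, 30)
        t, p = group_ttest(a, b)
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t_hand = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
        assert t == pytest.approx(t_hand)
        assert p == pytest.approx(2 * stats.t.sf(abs(t_hand), na + nb - 2))

    def test_degenerate_variance_is_an_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            group_ttest([1.0, 1.0], [2.0, 2.0])

    def test_welch_flag_changes_statistic(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.5, 3, 60)
        assert group_ttest(a, b) != group_ttest(a, b, welch=True)


def entropy_frame(rows):
    return pd.DataFrame(rows, columns=["subject_id", "group", "origin_start",
                                       "n_used", "r_used_ms", "sampen", "defined"])


class TestSummarizeRun:
    def test_two_subject_constant_entropies(self):
        rows = [("n1", "NSR", i * 300, 300, 12.0, 0.7 + 0.001 * i, True) for i in range(5)]
        rows += [("c1", "CHF", i * 300, 300, 12.0, 0.4 + 0.001 * i, True) for i in range(5)]
        summary = summarize_run(entropy_frame(rows), typing=None, scope="ALL")
        assert summary.mean_sampen["NSR"] == pytest.approx(0.702)
        assert summary.mean_sampen["CHF"] == pytest.approx(0.402)
        assert summary.report.auc == pytest.approx(1.0)

    def test_all_is_union_of_types_when_none_excluded(self, rng):
        rows = []
        for sid, group, level, n in [("n1", "NSR", 0.8, 100), ("n2", "NSR", 0.7, 30),
                                     ("c1", "CHF", 0.4, 95), ("c2", "CHF", 0.5, 20)]:
            rows += [(sid, group, i * 300, 300, 12.0, level + rng.normal(0, 0.02), True)
                     for i in range(n)]
        table = entropy_frame(rows)
        typing = assign_subject_types({"n1": 100, "n2": 30, "c1": 95, "c2": 20})
        s_all = summarize_run(table, typing, "ALL")
        s1 = summarize_run(table, typing, "TYPE_I")
        s2 = summarize_run(table, typing, "TYPE_II")
        for g in ("NSR", "CHF"):
            assert s_all.n_segments[g] == s1.n_segments[g] + s2.n_segments[g]

    def test_empty_scope_is_an_error(self):
        rows = [("n1", "NSR", 0, 300, 12.0, 0.7, True),
                ("c1", "CHF", 0, 300, 12.0, 0.4, True)]
        typing = assign_subject_types({"n1": 10, "c1": 10})  # nobody reaches 90
        with pytest.raises(ValueError, match="TYPE_I"):
            summarize_run(entropy_frame(rows), typing, "TYPE_I")
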