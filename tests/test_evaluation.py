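import numpy as np
import pytest
from scipy.stats import chi2 as chi2_dist

import ecsubtypes as ec


def brute_force_logrank_2group(t1, e1, t2, e2):
    """Observed-minus-expected log-rank statistic computed directly from the
    risk-set definition (independent of any survival library)."""
    event_times = sorted({t for t, e in list(zip(t1, e1)) + list(zip(t2, e2)) if e})
    O1 = E1 = V = 0.0
    for t in event_times:
        n1 = sum(x >= t for x in t1)
        n2 = sum(x >= t for x in t2)
        n = n1 + n2
        d1 = sum(x == t and e for x, e in zip(t1, e1))
        d2 = sum(x == t and e for x, e in zip(t2, e2))
        d = d1 + d2
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return (O1 - E1) ** 2 / V


class TestConfusionMatrix:
    def test_perfect_agreement_is_diagonal(self):
        labels = ["POLE", "MSI", "CN-low", "CN-high"] * 3
        m = ec.confusion_matrix(labels[:10], labels[:10])
        assert np.trace(m.counts) == 10
        assert m.counts.sum() == 10

    def test_published_matrix_margins(self, table1):
        np.testing.assert_array_equal(table1.row_sums(), [17, 65, 90, 60])
        np.testing.assert_array_equal(table1.col_sums(), [17, 58, 95, 62])

    def test_swapping_reference_and_prediction_transposes(self):
        rng = np.random.default_rng(4)
        ref = rng.choice(ec.SUBTYPES, size=60).tolist()
        pred = rng.choice(ec.SUBTYPES, size=60).tolist()
        a = ec.confusion_matrix(ref, pred)
        b = ec.confusion_matrix(pred, ref)
        np.testing.assert_array_equal(a.counts, b.counts.T)

    def test_foreign_label_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            ec.confusion_matrix(["POLE"], ["serous"])


class TestPerClassMetrics:
    def test_published_recalls(self, table1):
        prf = ec.per_class_prf(table1)
        assert prf.loc["POLE", "recall"] == pytest.approx(1.0)
        assert prf.loc["MSI", "recall"] == pytest.approx(58 / 65)
        assert prf.loc["CN-low", "recall"] == pytest.approx(80 / 90)
        assert prf.loc["CN-high", "recall"] == pytest.approx(51 / 60)

    def test_empty_predicted_column_precision_zero(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[0, 1] = 5  # POLE always predicted MSI; POLE column empty
        m = ec.ConfusionMatrix(ec.SUBTYPES, counts, 5)
        prf = ec.per_class_prf(m)
        assert prf.loc["POLE", "precision"] == 0.0
        assert prf.loc["POLE", "f1"] == 0.0

    def test_row_percentages_half_up(self, table1):
        pct = ec.row_percentages(table1)
        np.testing.assert_array_equal(pct[0], [100, 0, 0, 0])
        np.testing.assert_array_equal(pct[1], [0, 89, 9, 2])
        np.testing.assert_array_equal(pct[2], [0, 0, 89, 11])
        np.testing.assert_array_equal(pct[3], [0, 0, 15, 85])

    def test_unrounded_rows_sum_to_100(self, table1):
        np.testing.assert_allclose(
            ec.row_percentages(table1, rounded=False).sum(axis=1), 100.0
        )

    def test_column_percentages(self, table1):
        np.testing.assert_array_equal(ec.column_percentages(table1), [7, 25, 41, 27])


class TestAggregateMetrics:
    def test_published_matrix_accuracy_and_macro_recall(self, table1):
        rep = ec.aggregate_metrics(table1)
        assert rep.accuracy == pytest.approx(206 / 232)
        assert rep.macro["recall"] == pytest.approx(
            (17 / 17 + 58 / 65 + 80 / 90 + 51 / 60) / 4
        )

    def test_diagonal_matrix_scores_one(self):
        m = ec.ConfusionMatrix(ec.SUBTYPES, np.diag([5, 6, 7, 8]), 26)
        rep = ec.aggregate_metrics(m)
        assert rep.accuracy == 1.0
        assert rep.macro["f1"] == 1.0
        assert rep.weighted["precision"] == 1.0

    def test_weighted_recall_equals_accuracy(self):
        """Identity on complete matrices: recall weighted by reference-class
        sizes is trace/n."""
        rng = np.random.default_rng(9)
        for _ in range(10):
            counts = rng.integers(0, 30, size=(4, 4))
            counts[np.arange(4), np.arange(4)] += 1  # no empty rows
            m = ec.ConfusionMatrix(ec.SUBTYPES, counts, int(counts.sum()))
            rep = ec.aggregate_metrics(m)
            assert rep.weighted["recall"] == pytest.approx(rep.accuracy)


class TestChiSquare:
    def test_identical_distributions(self):
        res = ec.chi_square_homogeneity([10, 20, 30], [10, 20, 30])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_swap_invariance(self):
        a = ec.chi_square_homogeneity([17, 65, 90, 60], [17, 58, 95, 62])
        b = ec.chi_square_homogeneity([17, 58, 95, 62], [17, 65, 90, 60])
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_hand_computed_two_by_two(self):
        """[[10,20],[20,10]]: all expected counts are 15, Pearson statistic
        is 4 * 25/15 = 20/3 on 1 df."""
        res = ec.chi_square_homogeneity([10, 20], [20, 10])
        assert res.statistic == pytest.approx(20 / 3)
        assert res.degrees_of_freedom == 1
        assert res.p_value == pytest.approx(chi2_dist.sf(20 / 3, 1))

    def test_zero_expected_count_rejected(self):
        with pytest.raises(ValueError, match="expected"):
            ec.chi_square_homogeneity([10, 0], [20, 0])


class TestKaplanMeier:
    def test_all_censored_survival_is_one(self):
        curve = ec.km_estimator([5, 10, 15], [False, False, False])
        assert (curve.survival == 1.0).all()
        assert ec.survival_at(curve, 12) == 1.0

    def test_hand_computed_product_limit(self):
        """Events at 1 and 2, censored at 3: S(1) = 2/3, S(2) = 1/3."""
        curve = ec.km_estimator([1, 2, 3], [True, True, False])
        assert ec.survival_at(curve, 1) == pytest.approx(2 / 3)
        assert ec.survival_at(curve, 2) == pytest.approx(1 / 3)
        assert ec.survival_at(curve, 2.9) == pytest.approx(1 / 3)

    def test_survival_before_first_event(self):
        curve = ec.km_estimator([10, 20], [True, True])
        assert ec.survival_at(curve, 5) == 1.0

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(21)
        times = rng.exponential(30, size=50)
        curve = ec.km_estimator(times, np.ones(50, dtype=bool))
        for t in np.quantile(times, [0.2, 0.5, 0.8]):
            assert ec.survival_at(curve, t) == pytest.approx((times > t).mean())

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            ec.km_estimator([-1, 2], [True, True])

    def test_monotone_non_increasing(self):
        rng = np.random.default_rng(22)
        times = rng.exponential(30, size=80)
        events = rng.random(80) < 0.7
        curve = ec.km_estimator(times, events)
        assert (np.diff(curve.survival) <= 1e-12).all()
        assert (np.diff(curve.at_risk) <= 0).all()


class TestLogRank:
    def test_identical_groups_statistic_near_zero(self):
        t = [1, 2, 3, 4, 5]
        e = [True, True, False, True, False]
        res = ec.logrank_test({"a": (t, e), "b": (t, e)})
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)

    def test_two_group_matches_brute_force(self):
        rng = np.random.default_rng(33)
        for _ in range(5):
            t1 = rng.exponential(20, size=10).round(2)
            t2 = rng.exponential(40, size=10).round(2)
            e1 = rng.random(10) < 0.8
            e2 = rng.random(10) < 0.8
            if not (e1.any() or e2.any()):
                continue
            expected = brute_force_logrank_2group(t1, e1, t2, e2)
            res = ec.logrank_test({"a": (t1, e1), "b": (t2, e2)})
            assert res.statistic == pytest.approx(expected, rel=1e-10)
            assert res.degrees_of_freedom == 1

    def test_four_ordered_hazard_groups_significant(self):
        """Strongly ordered exponential hazards at the generator's defaults
        give a decisive omnibus test."""
        labels = {}
        for i, sub in enumerate(ec.SUBTYPES):
            for j in range(50):
                labels[f"{sub}_{j}"] = sub
        surv = ec.simulate_survival(labels, seed=5)
        groups = {}
        for sid, sub in labels.items():
            groups.setdefault(sub, ([], []))
            t, e = surv[sid]
            groups[sub][0].append(t)
            groups[sub][1].append(e)
        res = ec.logrank_test(groups)
        assert res.degrees_of_freedom == 3
        assert res.p_value < 0.01

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            ec.logrank_test({"a": ([1, 2], [False, False]), "b": ([3], [False])})


class TestEvaluateCohort:
    def test_end_to_end_report(self, small_cohort, fitted_cascade):
        calls = fitted_cascade.classify_cohort(
            small_cohort.variants, small_cohort.clinical, small_cohort.profiles
        )
        ev = ec.evaluate_cohort(calls, small_cohort.clinical)
        assert ev.confusion.n_total == len(calls)
        assert 0.0 <= ev.metrics.accuracy <= 1.0
        assert 0.0 <= ev.chi_square.p_value <= 1.0
        assert set(ev.km_curves) == {"reference", "predicted"}
        assert not ev.survival_36m.empty
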