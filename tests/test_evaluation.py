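"""Evaluation metrics against closed forms, brute-force oracles and
printed cohort statistics."""

import numpy as np
import pytest
from oracles import all_pairs_auc, cumulative_ap
from sklearn.metrics import average_precision_score, roc_auc_score

from ctgvision.evaluation import (CategoricalRow, CohortTable,
                                  ConfusionMatrix, ContinuousRow, MetricSet,
                                  aggregate_folds, cohort_compare,
                                  metrics_from_confusion, pr_ap,
                                  random_baseline_ap, roc_auc,
                                  staged_embeddings, stratified_kfold)


class TestConfusionMetrics:
    def test_perfect_classifier_scores_one_everywhere(self):
        m = metrics_from_confusion(ConfusionMatrix(tp=10, fp=0, fn=0, tn=20))
        assert (m.accuracy, m.sensitivity, m.specificity, m.precision,
                m.f1_macro) == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_enhanced_model_worked_example(self):
        # aggregated 5-fold matrix: 55 FN / 64 FP over 602 pos, 1020 neg
        m = metrics_from_confusion(ConfusionMatrix(tp=547, fp=64, fn=55,
                                                   tn=956))
        assert m.accuracy == pytest.approx(0.9266, abs=5e-5)
        assert m.specificity == pytest.approx(0.9373, abs=5e-5)
        assert m.sensitivity == pytest.approx(0.9086, abs=5e-5)

    def test_baseline_model_worked_example(self):
        m = metrics_from_confusion(ConfusionMatrix(tp=541, fp=68, fn=61,
                                                   tn=952))
        assert m.accuracy == pytest.approx(0.9205, abs=5e-5)
        assert m.specificity == pytest.approx(0.9333, abs=5e-5)

    def test_symmetric_matrix_macro_equals_positive_f1(self):
        m = metrics_from_confusion(ConfusionMatrix(tp=40, fp=10, fn=10,
                                                   tn=40))
        assert m.f1_macro == pytest.approx(m.f1_positive)

    def test_zero_denominator_flagged_as_nan(self):
        with pytest.warns(RuntimeWarning, match="precision"):
            m = metrics_from_confusion(ConfusionMatrix(tp=0, fp=0, fn=5,
                                                       tn=5))
        assert np.isnan(m.precision)


class TestRocAuc:
    def test_perfect_separation_gives_one(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9],
                       [False, False, True, True]) == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(4000)
        labels = rng.random(4000) < 0.4
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.03)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_all_pairs_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 6, size=20).astype(float)  # forces ties
        labels = rng.random(20) < 0.5
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        assert roc_auc(scores, labels) == pytest.approx(
            all_pairs_auc(scores, labels), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.random(50)
        labels = rng.random(50) < 0.4
        a = roc_auc(scores, labels)
        b = roc_auc(np.exp(5 * scores) + 3, labels)
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [True, True])

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(2)
        scores = rng.random(200)
        labels = rng.random(200) < 0.37
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)


class TestAveragePrecision:
    def test_all_positives_ranked_first_gives_one(self):
        assert pr_ap([0.9, 0.8, 0.2, 0.1],
                     [True, True, False, False]) == 1.0

    def test_random_baseline_is_prevalence(self):
        assert random_baseline_ap(602, 1020) == pytest.approx(0.37, abs=0.002)

    def test_random_ranking_converges_to_prevalence(self):
        rng = np.random.default_rng(3)
        labels = rng.random(10_000) < 0.37
        scores = rng.random(10_000)
        assert pr_ap(scores, labels) == pytest.approx(labels.mean(), abs=0.02)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_direct_summation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(10)
        labels = rng.random(10) < 0.5
        if not labels.any():
            labels[0] = True
        assert pr_ap(scores, labels) == pytest.approx(
            cumulative_ap(scores, labels), abs=1e-12)

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(4)
        scores = rng.random(300)
        labels = rng.random(300) < 0.3
        assert pr_ap(scores, labels) == pytest.approx(
            average_precision_score(labels, scores), abs=1e-12)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            pr_ap([0.5], [False])


class TestStratifiedKFold:
    def test_fold_sizes_and_stratification(self):
        labels = np.array([1] * 37 + [0] * 63)
        folds = stratified_kfold(labels, k=5, seed=0)
        for f in range(5):
            assert (folds == f).sum() == 20
            assert (labels[folds == f] == 1).sum() in (7, 8)

    def test_partition_property(self):
        labels = np.arange(40) % 2
        folds = stratified_kfold(labels, k=4, seed=1)
        assert sorted(np.unique(folds)) == [0, 1, 2, 3]
        assert len(folds) == 40

    def test_reproducible_by_seed(self):
        labels = np.arange(30) % 2
        assert np.array_equal(stratified_kfold(labels, 5, seed=9),
                              stratified_kfold(labels, 5, seed=9))

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_kfold(np.array([0] * 20 + [1] * 3), k=5, seed=0)


class TestAggregateFolds:
    def _ms(self, acc):
        return MetricSet(accuracy=acc, sensitivity=acc, specificity=acc,
                         precision=acc, f1_positive=acc, f1_macro=acc,
                         auc=acc, average_precision=acc)

    def test_identical_folds_have_zero_sd(self):
        cm = ConfusionMatrix(5, 1, 1, 13)
        report = aggregate_folds([(self._ms(0.9), cm)] * 3)
        assert report.sd.accuracy == 0.0
        assert report.aggregated_confusion.tp == 15

    def test_two_point_mean_and_sd(self):
        cm = ConfusionMatrix(1, 0, 0, 1)
        report = aggregate_folds([(self._ms(0.9), cm), (self._ms(1.0), cm)])
        assert report.mean.accuracy == pytest.approx(0.95)
        assert report.sd.accuracy == pytest.approx(0.070710678, abs=1e-8)

    def test_aggregated_counts_are_columnwise_sums(self):
        rng = np.random.default_rng(0)
        pairs = []
        for _ in range(4):
            tp, fp, fn, tn = rng.integers(0, 30, size=4)
            pairs.append((self._ms(0.5),
                          ConfusionMatrix(int(tp), int(fp), int(fn),
                                          int(tn))))
        report = aggregate_folds(pairs)
        for field in ("tp", "fp", "fn", "tn"):
            assert getattr(report.aggregated_confusion, field) == sum(
                getattr(cm, field) for _, cm in pairs)

    def test_weighted_fold_accuracy_matches_aggregate(self):
        # accuracy of the summed matrix = sample-weighted mean of folds
        rng = np.random.default_rng(1)
        pairs = []
        for _ in range(5):
            tp, fp, fn, tn = [int(v) for v in rng.integers(1, 40, size=4)]
            cm = ConfusionMatrix(tp, fp, fn, tn)
            pairs.append((metrics_from_confusion(cm), cm))
        report = aggregate_folds(pairs)
        agg = metrics_from_confusion(report.aggregated_confusion)
        weighted = sum(m.accuracy * cm.total for m, cm in pairs) / sum(
            cm.total for _, cm in pairs)
        assert agg.accuracy == pytest.approx(weighted, abs=1e-12)

    def test_single_fold_rejected(self):
        with pytest.raises(ValueError):
            aggregate_folds([(self._ms(1.0), ConfusionMatrix(1, 0, 0, 1))])


class TestCohortCompare:
    def test_printed_categorical_p_values(self):
        table = CohortTable(rows=[
            CategoricalRow("nulliparous", 1080, 1622, 376, 552),
            CategoricalRow("male_sex", 838, 1622, 286, 552),
            CategoricalRow("apgar_lt7", 36, 1622, 19, 552),
        ])
        p = cohort_compare(table)
        assert p["nulliparous"] == pytest.approx(0.543, abs=5e-4)
        assert p["male_sex"] == pytest.approx(0.992, abs=5e-4)
        assert p["apgar_lt7"] == pytest.approx(0.155, abs=5e-4)

    def test_identical_groups_give_p_one(self):
        p = cohort_compare(CohortTable(rows=[
            CategoricalRow("same", 50, 100, 50, 100)]))
        assert p["same"] == pytest.approx(1.0)

    def test_welch_t_from_summary_stats(self):
        from scipy.stats import ttest_ind
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 40), rng.normal(0.5, 2, 60)
        row = ContinuousRow("x", 40, a.mean(), a.std(ddof=1),
                            60, b.mean(), b.std(ddof=1))
        p = cohort_compare(CohortTable(rows=[row]))["x"]
        assert p == pytest.approx(ttest_ind(a, b, equal_var=False).pvalue,
                                  abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cohort_compare(CohortTable(rows=[
                ContinuousRow("flat", 10, 1.0, 0.0, 10, 1.0, 0.0)]))


class TestStagedEmbeddings:
    def test_four_taps_with_one_point_per_sample(self):
        from ctgvision.model import build_network
        net = build_network(width_mult=0.25, depth_mult=0.5, input_size=16,
                            dropout=0.0, seed=0)
        X = np.random.default_rng(0).normal(size=(12, 3, 16, 16))
        emb = staged_embeddings(net, X, seed=0)
        assert set(emb) == {"input", "stage3", "stage6", "pooled"}
        for pts in emb.values():
            assert pts.shape == (12, 2)

    def test_fixed_seed_reproducible(self):
        from ctgvision.model import build_network
        net = build_network(width_mult=0.25, depth_mult=0.5, input_size=16,
                            dropout=0.0, seed=0)
        X = np.random.default_rng(1).normal(size=(10, 3, 16, 16))
        a = staged_embeddings(net, X, seed=5)
        b = staged_embeddings(net, X, seed=5)
        for k in a:
            assert np.array_equal(a[k], b[k])

    def test_too_few_samples_rejected(self):
        from ctgvision.model import build_network
        net = build_network(width_mult=0.25, depth_mult=0.5, input_size=16,
                            seed=0)
        with pytest.raises(ValueError):
            staged_embeddings(net, np.zeros((3, 3, 16, 16)), seed=0)
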