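"""Split arithmetic, screening, tuning, ROC evaluation, stratified AUC."""

import numpy as np
import pandas as pd
import pytest

from hairdyn import (
    ConfusionMatrix,
    evaluate,
    screen_features,
    split,
    stratified_performance,
    tune_and_fit,
)


class TestSplit:
    def test_cohort_of_486_partitions_389_97(self):
        spec = split([f"S{i}" for i in range(486)], train_fraction=0.8, seed=0)
        assert len(spec.train_ids) == 389
        assert len(spec.holdout_ids) == 97

    def test_small_cohort_8_2(self):
        spec = split([f"S{i}" for i in range(10)], train_fraction=0.8, seed=1)
        assert (len(spec.train_ids), len(spec.holdout_ids)) == (8, 2)

    def test_deterministic_under_seed(self):
        ids = [f"S{i}" for i in range(50)]
        assert split(ids, seed=3) == split(ids, seed=3)
        assert split(ids, seed=3) != split(ids, seed=4)

    def test_partition_is_disjoint_and_complete(self):
        ids = [f"S{i}" for i in range(37)]
        spec = split(ids, train_fraction=0.8, seed=9)
        assert set(spec.train_ids) | set(spec.holdout_ids) == set(ids)
        assert not set(spec.train_ids) & set(spec.holdout_ids)

    @pytest.mark.parametrize("fraction", [0.0, 1.0])
    def test_empty_partition_rejected(self, fraction):
        with pytest.raises(ValueError):
            split([f"S{i}" for i in range(20)], train_fraction=fraction, seed=0)


@pytest.fixture(scope="module")
def train_data():
    from tests_helpers import make_labeled_table

    return make_labeled_table(n=80, n_signal=4, n_null=12, seed=5)


@pytest.fixture(scope="module")
def labeled_train():
    from tests_helpers import make_labeled_table

    table, subjects = make_labeled_table(n=60, n_signal=3, n_null=5, seed=6)
    labels = np.array([int(s.is_case) for s in subjects])
    return table, labels


class TestScreenFeatures:
    def test_k_equal_to_all_is_identity(self, train_data):
        table, subjects = train_data
        selected = screen_features(table, subjects, k=table.shape[1])
        assert set(selected) == set(table.columns)

    def test_signal_features_rank_first(self, train_data):
        table, subjects = train_data
        selected = screen_features(table, subjects, k=4)
        assert all(fid.startswith("sig") for fid in selected)

    def test_k_too_large_rejected(self, train_data):
        table, subjects = train_data
        with pytest.raises(ValueError, match="exceeds"):
            screen_features(table, subjects, k=999)


class TestTuneAndFit:
    def test_budget_one_yields_valid_model(self, labeled_train):
        table, labels = labeled_train
        model, cfg, history = tune_and_fit(table, labels, budget=1, seed=0)
        assert len(history) == 1
        scores = model.predict_proba(table.to_numpy())[:, 1]
        assert np.all((scores >= 0) & (scores <= 1))

    def test_surrogate_search_extends_history(self, labeled_train):
        table, labels = labeled_train
        _, best, history = tune_and_fit(table, labels, budget=6, seed=0)
        assert len(history) == 6
        assert best in [cfg for cfg, _ in history]

    def test_single_class_labels_rejected(self, labeled_train):
        table, _ = labeled_train
        with pytest.raises(ValueError, match="single-class"):
            tune_and_fit(table, np.ones(len(table), dtype=int), budget=1)


class TestEvaluate:
    def test_worked_confusion_matrix_arithmetic(self):
        # 28 positives / 69 negatives with operating point (tp=27, fn=1,
        # tn=52, fp=17): the Youden-optimal threshold must land there.
        scores = np.concatenate([
            np.full(27, 0.8), [0.1],          # positives
            np.full(17, 0.9), np.full(52, 0.2),  # negatives
        ])
        labels = np.concatenate([np.ones(28, int), np.zeros(69, int)])
        rep = evaluate(scores, labels)
        cm = rep.confusion
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (27, 1, 52, 17)
        assert round(100 * rep.sensitivity, 1) == 96.4
        assert round(100 * rep.specificity, 1) == 75.4
        assert round(100 * rep.accuracy, 1) == 81.4
        assert rep.j == pytest.approx(rep.sensitivity + rep.specificity - 1)

    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.7, 0.2, 0.1])
        labels = np.array([1, 1, 1, 0, 0])
        rep = evaluate(scores, labels)
        assert rep.auc == 1.0 and rep.j == pytest.approx(1.0)
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0

    def test_chance_scores_give_half_auc(self):
        rng = np.random.default_rng(12)
        scores = rng.uniform(size=2000)
        labels = rng.integers(0, 2, size=2000)
        rep = evaluate(scores, labels)
        assert abs(rep.auc - 0.5) < 0.03

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(13)
        labels = rng.integers(0, 2, size=200)
        scores = rng.normal(size=200) + labels
        a = evaluate(scores, labels)
        b = evaluate(np.exp(3 * scores), labels)
        assert a.auc == pytest.approx(b.auc)
        assert a.confusion == b.confusion

    def test_youden_tie_resolves_to_lowest_threshold(self):
        # Two thresholds achieve the same J; the lower one (favoring
        # sensitivity) must be reported.
        scores = np.array([0.1, 0.4, 0.6, 0.9])
        labels = np.array([0, 1, 0, 1])
        rep = evaluate(scores, labels)
        assert rep.youden_threshold == pytest.approx(0.4)

    def test_cis_contain_point_estimates(self):
        rng = np.random.default_rng(14)
        labels = rng.integers(0, 2, size=100)
        scores = rng.normal(size=100) + 0.8 * labels
        rep = evaluate(scores, labels)
        for est, (lo, hi) in [(rep.sensitivity, rep.sensitivity_ci),
                              (rep.specificity, rep.specificity_ci),
                              (rep.accuracy, rep.accuracy_ci)]:
            assert lo <= est <= hi

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            evaluate(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_nonfinite_scores_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            evaluate(np.array([0.1, np.nan, 0.5]), np.array([1, 0, 1]))


def test_confusion_matrix_hand_arithmetic():
    cm = ConfusionMatrix(tp=27, fn=1, tn=52, fp=17)
    assert cm.n == 97
    assert cm.sensitivity == pytest.approx(27 / 28)
    assert cm.specificity == pytest.approx(52 / 69)
    assert cm.accuracy == pytest.approx(79 / 97)
    with pytest.raises(ValueError):
        ConfusionMatrix(tp=-1, fn=0, tn=0, fp=0)


class TestStratifiedPerformance:
    def test_identical_strata_agree_with_overall(self):
        rng = np.random.default_rng(15)
        labels = np.tile(rng.integers(0, 2, size=60), 2)
        scores = np.tile(rng.normal(size=60) + labels[:60], 2)
        strata = np.array(["a"] * 60 + ["b"] * 60)
        reports = stratified_performance(scores, labels, strata)
        assert reports["a"]["auc"] == pytest.approx(reports["b"]["auc"])
        assert reports["a"]["p"] > 0.9 and reports["b"]["p"] > 0.9

    def test_whole_sample_stratum_p_is_one(self):
        rng = np.random.default_rng(16)
        labels = rng.integers(0, 2, size=80)
        scores = rng.normal(size=80) + labels
        reports = stratified_performance(scores, labels, np.array(["all"] * 80))
        assert reports["all"]["p"] == 1.0
        assert reports["all"]["auc"] == pytest.approx(reports["all"]["overall_auc"])

    def test_single_class_stratum_flagged(self):
        labels = np.array([1, 1, 0, 0, 1, 0])
        scores = np.array([0.9, 0.8, 0.2, 0.1, 0.7, 0.3])
        strata = np.array(["a", "a", "b", "b", "b", "b"])
        reports = stratified_performance(scores, labels, strata)
        assert reports["a"]["flagged"] == "single-class stratum"
        assert reports["a"]["auc"] is None
        assert reports["b"]["flagged"] == ""
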