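"""Cross-validation harness: folds, metrics, training loop, comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from scafkan import (CohortConfig, FusionConfig, TrainConfig, compare_models,
                     compute_metrics, cross_validate, generate_cohort,
                     make_folds, roc_auc)
from scafkan.baselines import ResNetClassifier, logistic_fn, reskan_fn
from scafkan.metrics import MetricSet
from scafkan.model import FusionModel, train_network
from scafkan.train_eval import EvalReport, holm_adjust


class TestFolds:
    def test_dev_cohort_five_fold_stratification(self):
        y = np.array([1] * 39 + [0] * 85)
        plan = make_folds(y, K=5, seed=0)
        sizes = sorted(len(v) for _, v in plan.folds)
        assert sizes == [24, 25, 25, 25, 25]
        pos = [y[v].sum() for _, v in plan.folds]
        assert all(p in (7, 8) for p in pos)

    def test_k_one_refused(self):
        with pytest.raises(ValueError):
            make_folds(np.array([0, 1] * 10), K=1)

    def test_seed_determinism(self):
        y = np.array([0, 1] * 30)
        a = make_folds(y, 5, seed=9)
        b = make_folds(y, 5, seed=9)
        for (t1, v1), (t2, v2) in zip(a.folds, b.folds):
            assert np.array_equal(v1, v2)


class TestMetrics:
    def test_perfect_separation(self):
        m = compute_metrics(np.array([0, 0, 1, 1]), np.array([.1, .2, .8, .9]))
        assert m.auc == 1.0 and m.f1 == 1.0

    def test_worked_pair_counting_example(self):
        # 3 of the 4 positive-negative pairs are ordered correctly
        assert roc_auc(np.array([1, 0, 1, 0]),
                       np.array([.9, .8, .4, .1])) == 0.75

    def test_constant_scores_give_half(self):
        assert roc_auc(np.array([1, 0, 1, 0]), np.full(4, 0.3)) == 0.5

    def test_no_predicted_positives_flagged(self):
        m = compute_metrics(np.array([0, 1]), np.array([0.1, 0.2]))
        assert m.precision == 0.0 and m.precision_undefined

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_auc_equals_brute_force_pair_count(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        p = np.round(rng.random(n), 2)    # coarse scores force ties
        wins = half = total = 0
        for i in np.flatnonzero(y == 1):
            for j in np.flatnonzero(y == 0):
                total += 1
                if p[i] > p[j]:
                    wins += 1
                elif p[i] == p[j]:
                    half += 1
        assert roc_auc(y, p) == pytest.approx((wins + 0.5 * half) / total)


def _report(aucs, plan):
    ms = [MetricSet(a, a, a, a, a, np.zeros((2, 2), int)) for a in aucs]
    return EvalReport("stub", plan, ms, [np.zeros(2)] * len(aucs),
                      [np.array([0, 1])] * len(aucs))


class TestComparison:
    @pytest.fixture()
    def plan(self):
        return make_folds(np.array([0, 1] * 30), 5, seed=0)

    def test_identical_reports_give_zero_effect(self, plan):
        r = _report([.8, .85, .8, .85, .9], plan)
        c = compare_models(r, r)
        assert c.cohens_d == 0.0 and c.t_statistic == 0.0

    def test_hand_computed_effect_size(self, plan):
        a = _report([.80, .85, .80, .85, .90], plan)
        b = _report([.70, .80, .70, .80, .80], plan)
        c = compare_models(a, b)
        # differences [.10,.05,.10,.05,.10]: mean .08, sample SD .027386
        assert c.cohens_d == pytest.approx(0.08 / 0.0273861, rel=1e-4)
        assert c.p_value < 0.05

    def test_constant_differences_yield_infinite_sentinel(self, plan):
        a = _report([.8, .8, .8, .8, .8], plan)
        b = _report([.7, .7, .7, .7, .7], plan)
        with pytest.warns(UserWarning):
            c = compare_models(a, b)
        assert np.isinf(c.cohens_d) and c.cohens_d > 0

    def test_holm_adjustment_matches_statsmodels(self, rng):
        p = rng.random(8) * 0.2
        ours = holm_adjust(p)
        ref = multipletests(p, method="holm")[1]
        assert np.allclose(ours, ref)


class TestTraining:
    def test_zero_learning_rate_changes_nothing_and_stops_early(self, rng):
        net = FusionModel(FusionConfig(n_features=4, d=8, n_heads=2,
                                       dropout=0.0, seed=0))
        before = [p.copy() for p in net.state_dict()]
        X = rng.normal(size=(30, 4))
        y = np.array([0, 1] * 15)
        hist = train_network(net, X, y, X, y,
                             TrainConfig(learning_rate=0.0, max_epochs=50,
                                         patience=1, seed=0))
        # constant validation metric never improves after epoch 1
        assert len(hist["train_loss"]) == 2
        for b, a in zip(before, net.state_dict()):
            assert np.array_equal(b, a)

    def test_separable_blobs_reach_perfect_training_auc(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-2, 0.5, (30, 2)), rng.normal(2, 0.5, (30, 2))])
        y = np.array([0] * 30 + [1] * 30)
        net = ResNetClassifier(2, d=16, depth=1, dropout=0.0, seed=0)
        train_network(net, X, y, X, y,
                      TrainConfig(max_epochs=200, patience=200, seed=0))
        assert roc_auc(y, net.predict_proba(X)) == 1.0

    def test_nonfinite_loss_aborts(self, rng):
        net = FusionModel(FusionConfig(n_features=3, d=8, n_heads=2, seed=0))
        net.head.weight.data[:] = np.nan
        X = rng.normal(size=(20, 3))
        y = np.array([0, 1] * 10)
        with pytest.raises(FloatingPointError):
            train_network(net, X, y, X, y, TrainConfig(max_epochs=3, seed=0))


class TestCrossValidate:
    def test_logistic_pipeline_end_to_end(self):
        cohort = generate_cohort(CohortConfig(n_patients=124, seed=17))
        report = cross_validate(logistic_fn(), cohort, K=5, seed=0,
                                model_name="logistic")
        assert len(report.fold_metrics) == 5
        agg = report.aggregate()
        assert 0.5 < agg["auc"][0] <= 1.0
        # aggregates recompute exactly from fold values
        assert agg["auc"][0] == pytest.approx(report.fold_aucs.mean())
        assert agg["auc"][1] == pytest.approx(report.fold_aucs.std(ddof=1))
        assert "5-fold" in report.summary()

    def test_roc_and_histogram_exports(self):
        cohort = generate_cohort(CohortConfig(n_patients=60, seed=18))
        report = cross_validate(logistic_fn(), cohort, K=3, seed=0)
        pts = report.roc_data(0)
        assert pts[0].tolist() == [0.0, 0.0]
        assert pts[-1].tolist() == [1.0, 1.0]
        h = report.histogram_data(0)
        assert h["positive"].sum() == report.fold_labels[0].sum()
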