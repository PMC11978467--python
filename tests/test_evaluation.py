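"""Tests for bootstrap splits, filtering, tuning, metrics and the harness."""

import math

import numpy as np
import pandas as pd
import pytest

from bmprog.evaluation import (
    HarnessConfig,
    HyperparamSpace,
    aggregate_importance,
    au_prc,
    baseline_auprc,
    bootstrap_split,
    correlation_filter,
    fit_forest,
    roc_auc,
    run_experiment,
    run_iteration,
    sensitivity_specificity,
    subgroup_pooled_metrics,
    training_operating_point,
    tune_hyperparameters,
)
from bmprog.evaluation.harness import iteration_seed
from _oracle import pairwise_auc


class TestBootstrap:
    @staticmethod
    def _groups(n_patients=20, lesions_per=2):
        return np.repeat([f"P{i}" for i in range(n_patients)], lesions_per)

    def test_partition_properties(self):
        g = self._groups()
        s = bootstrap_split(g, 3)
        support = set(s.train_rows.tolist())
        test = set(s.test_rows.tolist())
        assert support | test == set(range(len(g)))
        assert support & test == set()

    def test_patients_travel_together(self):
        g = self._groups()
        s = bootstrap_split(g, 7)
        test_patients = {g[i] for i in s.test_rows}
        train_patients = {g[i] for i in s.train_rows}
        assert test_patients & train_patients == set()

    def test_seed_determinism(self):
        g = self._groups()
        a, b = bootstrap_split(g, 5), bootstrap_split(g, 5)
        np.testing.assert_array_equal(a.train_rows, b.train_rows)
        np.testing.assert_array_equal(a.test_rows, b.test_rows)

    def test_oob_fraction_approaches_one_over_e(self):
        g = self._groups(n_patients=200, lesions_per=1)
        fracs = [len(bootstrap_split(g, s).test_rows) / 200 for s in range(300)]
        assert np.mean(fracs) == pytest.approx(math.exp(-1), abs=0.01)

    def test_lesion_unit_switch(self):
        g = self._groups()
        s = bootstrap_split(g, 11, unit="lesion")
        assert len(s.train_rows) == len(g)


class TestCorrelationFilter:
    def test_duplicate_column_dropped(self, rng):
        x = rng.normal(size=(100, 3))
        x[:, 1] = x[:, 0]
        kept = correlation_filter(x)
        assert 0 in kept and 1 not in kept and 2 in kept

    def test_independent_columns_kept(self, rng):
        x = rng.normal(size=(2000, 8))
        assert len(correlation_filter(x)) == 8

    def test_three_way_redundancy_keeps_exactly_first(self, rng):
        shared = rng.normal(size=(5000, 1))
        x = math.sqrt(0.9) * shared + math.sqrt(0.1) * rng.normal(size=(5000, 3))
        kept = correlation_filter(x)  # pairwise r ~ 0.9 > 0.8
        np.testing.assert_array_equal(kept, [0])

    def test_zero_variance_dropped(self, rng):
        x = rng.normal(size=(50, 3))
        x[:, 1] = 4.2
        kept = correlation_filter(x)
        assert 1 not in kept


class TestTuning:
    @staticmethod
    def _separable(n=40):
        rng = np.random.default_rng(0)
        y = np.arange(n) % 2
        x = np.column_stack([y * 10.0 + rng.normal(size=n) * 0.01, rng.normal(size=n)])
        return x, y

    def test_bounds_always_honored(self, rng):
        x = rng.normal(size=(30, 4))
        y = rng.integers(0, 2, size=30)
        if len(np.unique(y)) < 2:
            y[0] = 1 - y[0]
        n_trees, depth = tune_hyperparameters(x, y, budget=4, seed=1, inner_cv=3)
        assert 10 <= n_trees <= 1000
        assert 1 <= depth <= len(y)

    def test_budget_one_returns_single_point(self):
        x, y = self._separable()
        res = tune_hyperparameters(x, y, budget=1, seed=2, inner_cv=3, full_result=True)
        assert res.n_evaluations == 1

    def test_separable_data_reaches_perfect_inner_cv_auc(self):
        x, y = self._separable()
        res = tune_hyperparameters(x, y, budget=5, seed=3, inner_cv=3, full_result=True)
        assert res.best_score == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            tune_hyperparameters(np.zeros((10, 2)), np.zeros(10, dtype=int))


class TestForest:
    def test_memorization_and_determinism(self, rng):
        x = rng.normal(size=(60, 3))
        y = (x[:, 0] > 0).astype(int)
        a = fit_forest(x, y, (50, 10), seed=4)
        b = fit_forest(x, y, (50, 10), seed=4)
        pa, pb = a.predict_proba(x)[:, 1], b.predict_proba(x)[:, 1]
        np.testing.assert_array_equal(pa, pb)
        assert roc_auc(pa, y) == 1.0
        assert len(a.feature_importances_) == 3

    def test_nan_rejected(self):
        x = np.full((10, 2), np.nan)
        with pytest.raises(ValueError):
            fit_forest(x, np.arange(10) % 2, (10, 2), seed=0)


class TestMetrics:
    def test_auc_matches_pairwise_concordance(self, rng):
        for _ in range(5):
            scores = rng.normal(size=40)
            labels = rng.integers(0, 2, size=40)
            if len(np.unique(labels)) < 2:
                continue
            assert roc_auc(scores, labels) == pytest.approx(pairwise_auc(scores, labels))

    def test_auc_hand_example(self):
        # 3 of 4 pos/neg pairs correctly ordered
        assert roc_auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == 0.75

    def test_perfect_ranking(self):
        assert roc_auc([0.9, 0.8, 0.7, 0.3, 0.2, 0.1], [1, 1, 1, 0, 0, 0]) == 1.0

    def test_baseline_auprc_is_prevalence(self):
        labels = np.zeros(115, dtype=int)
        labels[:29] = 1
        assert baseline_auprc(labels) == pytest.approx(0.2522, abs=1e-4)
        assert baseline_auprc(np.ones(10)) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])
        with pytest.raises(ValueError):
            au_prc([0.1, 0.2], [0, 0])


class TestOperatingPoint:
    def test_perfect_separation(self):
        probs = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        thr = training_operating_point(probs, labels)
        sens, spec = sensitivity_specificity(probs, labels, thr)
        assert sens == 1.0 and spec == 1.0

    def test_four_point_fixture_traced_by_enumeration(self):
        # Thresholds between 0.6/0.7 and 0.8/0.9 both reach J = 0.5; the tie
        # breaks toward higher specificity, i.e. the higher threshold.
        probs = np.array([0.9, 0.8, 0.7, 0.6])
        labels = np.array([1, 0, 1, 0])
        thr = training_operating_point(probs, labels)
        assert 0.8 < thr <= 0.9
        sens, spec = sensitivity_specificity(probs, labels, thr)
        assert (sens, spec) == (0.5, 1.0)

    def test_uninformative_scores_give_near_zero_j(self, rng):
        probs = rng.uniform(size=4000)
        labels = rng.integers(0, 2, size=4000)
        thr = training_operating_point(probs, labels)
        sens, spec = sensitivity_specificity(probs, labels, thr)
        assert sens + spec - 1 < 0.08


class TestImportanceAggregation:
    def test_single_iteration_minmax(self):
        out = aggregate_importance([np.array([2.0, 4.0, 6.0])])
        np.testing.assert_allclose(out, [0.0, 0.5, 1.0])

    def test_always_filtered_feature_stays_zero(self):
        its = [np.array([0.0, 0.3, 1.0]), np.array([0.0, 1.0, 0.2])]
        assert aggregate_importance(its)[0] == 0.0

    def test_constant_aggregate_renormalizes_to_zeros(self):
        its = [np.array([0.0, 1.0]), np.array([1.0, 0.0])]
        np.testing.assert_allclose(aggregate_importance(its), [0.0, 0.0])

    def test_two_iteration_hand_computation(self):
        its = [np.array([0.0, 0.5, 1.0]), np.array([0.0, 1.0, 0.5])]
        # mean = (0, 0.75, 0.75) -> min-max -> (0, 1, 1)
        np.testing.assert_allclose(aggregate_importance(its), [0.0, 1.0, 1.0])


def _toy_problem(n_patients=40, lesions_per=2, d=2.0, seed=0, n_features=4):
    rng = np.random.default_rng(seed)
    n = n_patients * lesions_per
    groups = np.repeat([f"P{i}" for i in range(n_patients)], lesions_per)
    y = rng.integers(0, 2, size=n)
    x = rng.normal(size=(n, n_features))
    x[:, 0] += d * y
    return pd.DataFrame(x, columns=[f"f{i}" for i in range(n_features)]), y, groups


class TestHarness:
    CFG = dict(n_iterations=4, tune_budget=2, inner_cv=3)

    def test_experiment_reproducible_and_cis_bracket_mean(self):
        x, y, g = _toy_problem()
        cfg = HarnessConfig(**self.CFG)
        a = run_experiment(x, y, g, cfg, seed=9)
        b = run_experiment(x, y, g, cfg, seed=9)
        pd.testing.assert_frame_equal(a.iteration_table, b.iteration_table)
        for mean, lo, hi in a.metrics.values():
            assert lo <= mean <= hi
        assert a.mean_test_fraction_pct > 0
        np.testing.assert_array_equal(
            a.aggregated_importance, b.aggregated_importance
        )

    def test_importance_bounds_and_signal(self):
        x, y, g = _toy_problem(d=3.0)
        res = run_experiment(x, y, g, HarnessConfig(**self.CFG), seed=1)
        imp = res.aggregated_importance
        assert imp.min() == 0.0 and imp.max() == 1.0
        assert int(np.argmax(imp)) == 0  # the informative feature dominates
        assert res.metrics["auc"][0] > 0.9

    def test_single_class_experiment_rejected(self):
        x, y, g = _toy_problem()
        with pytest.raises(ValueError):
            run_experiment(x, np.zeros_like(y), g, HarnessConfig(**self.CFG), seed=0)

    def test_test_rows_never_influence_training_artifacts(self):
        """Permuting/overwriting the held-out rows' features leaves every
        training artifact (filter set, hyperparameters, operating point)
        and every training prediction unchanged."""
        x, y, g = _toy_problem(seed=3)
        cfg = HarnessConfig(**self.CFG)
        seed = iteration_seed(123, 0)
        split = bootstrap_split(g, seed)
        base = run_iteration(x.to_numpy(), y, split, seed, cfg)

        corrupted = x.to_numpy().copy()
        rng = np.random.default_rng(99)
        corrupted[split.test_rows] = rng.normal(size=(len(split.test_rows), x.shape[1]))
        alt = run_iteration(corrupted, y, split, seed, cfg)

        np.testing.assert_array_equal(base.retained, alt.retained)
        assert (base.n_trees, base.max_depth) == (alt.n_trees, alt.max_depth)
        assert base.threshold == alt.threshold

    def test_iteration_seed_is_stable_and_bounded(self):
        assert iteration_seed(5, 3) == iteration_seed(5, 3)
        assert iteration_seed(5, 3) != iteration_seed(5, 4)
        assert 0 <= iteration_seed(2**20, 249) < 2**31


class TestSubgroupPooling:
    @staticmethod
    def _records(rng, n=400):
        probs = rng.uniform(size=n)
        labels = (rng.uniform(size=n) < probs).astype(int)  # informative scores
        return pd.DataFrame(
            {
                "lesion_id": [f"L{i}" for i in range(n)],
                "prob": probs,
                "label": labels,
                "pred": (probs >= 0.5).astype(int),
                "site": rng.choice(["lung", "other"], size=n, p=[0.75, 0.25]),
            }
        )

    def test_whole_set_group_matches_direct_metrics(self, rng):
        rec = self._records(rng)
        rec["site"] = "all"
        out = subgroup_pooled_metrics(rec, "site")
        assert out.loc[0, "auc"] == pytest.approx(roc_auc(rec["prob"], rec["label"]))
        assert out.loc[0, "baseline_auprc"] == pytest.approx(rec["label"].mean())

    def test_identical_score_distributions_give_close_aucs(self, rng):
        rec = self._records(rng, n=4000)
        out = subgroup_pooled_metrics(rec, "site").set_index("site")
        assert out.loc["lung", "auc"] == pytest.approx(out.loc["other", "auc"], abs=0.05)

    def test_single_class_group_reports_nan_not_error(self, rng):
        rec = self._records(rng, n=50)
        rec.loc[rec["site"] == "other", "label"] = 1
        out = subgroup_pooled_metrics(rec, "site").set_index("site")
        assert math.isnan(out.loc["other", "auc"])
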