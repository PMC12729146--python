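"""Classifier protocol: grouped stratified splitting, CV-based tuning,
held-out evaluation and the emotion battery."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from hrvscreen.errors import (
    ConfigurationError,
    StratificationError,
    UndefinedMetricError,
)
from hrvscreen.features import FEATURE_NAMES
from hrvscreen.models import (
    ModelConfig,
    battery_table,
    evaluate,
    run_emotion_battery,
    split_train_test,
    tune_and_train,
)
from hrvscreen.stats import mann_whitney_u


def make_table(rng, n_hc=20, n_iwd=10, epochs=3, sep=0.0, condition="sadness"):
    """Epoch-level standardized feature table with a controllable class
    separation planted on two features."""
    rows = []
    for g, n in (("HC", n_hc), ("IWD", n_iwd)):
        for i in range(n):
            pid = f"{g}{i:03d}"
            for e in range(epochs):
                row = {
                    "participant_id": pid,
                    "condition": condition,
                    "epoch_index": e,
                    "group": g,
                }
                for k, name in enumerate(FEATURE_NAMES):
                    v = rng.normal()
                    if g == "IWD" and k < 2:
                        v += sep
                    row[f"{name}_std"] = v
                rows.append(row)
    return pd.DataFrame(rows)


class TestSplit:
    def test_split_is_stratified_and_participant_grouped(self):
        table = make_table(np.random.default_rng(0), n_hc=66, n_iwd=30, epochs=2)
        cfg = ModelConfig(seed=1)
        train, test = split_train_test(table, cfg)
        # no participant straddles the boundary
        assert not set(train.participant_id) & set(test.participant_id)
        # ~30% of each class's participants held out
        assert test[test.group == "HC"].participant_id.nunique() == 20
        assert test[test.group == "IWD"].participant_id.nunique() == 9
        assert test.participant_id.nunique() == 29

    def test_same_seed_same_split(self):
        table = make_table(np.random.default_rng(1))
        a = split_train_test(table, ModelConfig(seed=5))
        b = split_train_test(table, ModelConfig(seed=5))
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_single_class_rejected(self):
        table = make_table(np.random.default_rng(2), n_iwd=1)
        table = table[table.group == "HC"]
        with pytest.raises(StratificationError):
            split_train_test(table, ModelConfig(seed=0))


class TestTuneAndTrain:
    def test_separable_clusters_reach_high_cv_auc(self):
        table = make_table(np.random.default_rng(3), sep=6.0)
        cfg = ModelConfig(seed=0, search_budget=1, n_bootstrap=0)
        train, _ = split_train_test(table, cfg)
        model = tune_and_train(train, cfg)
        assert np.mean(model.cv_scores) >= 0.99

    def test_permuted_labels_give_chance_auc(self):
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            table = make_table(rng, sep=2.0, epochs=2)
            # permute group labels at the participant level
            pids = table.participant_id.unique()
            perm = dict(zip(pids, rng.permutation(
                [table[table.participant_id == p].group.iloc[0] for p in pids])))
            table["group"] = table.participant_id.map(perm)
            cfg = ModelConfig(seed=seed, search_budget=1, n_bootstrap=0)
            try:
                train, test = split_train_test(table, cfg)
                model = tune_and_train(train, cfg)
                aucs.append(evaluate(model, test).auc)
            except (StratificationError, UndefinedMetricError):
                continue
        assert 0.35 <= np.mean(aucs) <= 0.65

    def test_larger_budget_does_not_hurt_cv_auc(self):
        table = make_table(np.random.default_rng(4), sep=1.0)
        train, _ = split_train_test(table, ModelConfig(seed=2))
        cv_1 = np.mean(
            tune_and_train(train, ModelConfig(seed=2, search_budget=1)).cv_scores
        )
        cv_12 = np.mean(
            tune_and_train(train, ModelConfig(seed=2, search_budget=12)).cv_scores
        )
        assert cv_12 >= cv_1 - 1e-12

    def test_zero_budget_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(search_budget=0).validate()

    def test_random_strategy_flag_accepted(self):
        table = make_table(np.random.default_rng(5), sep=2.0)
        train, _ = split_train_test(table, ModelConfig(seed=0))
        model = tune_and_train(
            train, ModelConfig(seed=0, search_budget=4, search_strategy="random")
        )
        assert model.best_params


class TestEvaluate:
    def _fitted(self, sep, seed=0, algorithm="ertc"):
        table = make_table(np.random.default_rng(seed), sep=sep)
        cfg = ModelConfig(seed=seed, algorithm=algorithm, search_budget=1, n_bootstrap=50)
        train, test = split_train_test(table, cfg)
        return tune_and_train(train, cfg), test

    def test_perfect_separation_reaches_perfect_metrics(self):
        model, test = self._fitted(sep=8.0)
        rep = evaluate(model, test)
        assert rep.auc == 1.0
        assert rep.accuracy == 1.0
        assert (rep.roc.tpr.iloc[0], rep.roc.fpr.iloc[0]) == (0.0, 0.0)
        assert (rep.roc.tpr.iloc[-1], rep.roc.fpr.iloc[-1]) == (1.0, 1.0)
        assert rep.roc.tpr.is_monotonic_increasing

    def test_constant_predictor_majority_accuracy_and_half_auc(self):
        # a degenerate model scoring everyone identically: accuracy equals the
        # majority-class share (66/96) and rank-based AUC is exactly 1/2
        y = np.array([1] * 30 + [0] * 66)
        scores = np.full(96, 0.4)
        pred = scores >= 0.5
        acc = np.mean(pred == y)
        assert acc == pytest.approx(66 / 96)
        assert roc_auc_score(y, scores) == 0.5

    def test_auc_equals_normalized_mann_whitney_u(self):
        model, test = self._fitted(sep=1.0, seed=7)
        rep = evaluate(model, test)
        cols = model.feature_columns
        scores = model.estimator.predict_proba(test[cols].to_numpy())[:, 1]
        y = (test.group == "IWD").to_numpy()
        u, _ = mann_whitney_u(scores[y], scores[~y])
        assert rep.auc == pytest.approx(u / (y.sum() * (~y).sum()))

    def test_cis_bracket_point_estimates(self):
        model, test = self._fitted(sep=1.5, seed=3)
        rep = evaluate(model, test)
        for point, (lo, hi) in (
            (rep.accuracy, rep.accuracy_ci),
            (rep.auc, rep.auc_ci),
            (rep.precision, rep.precision_ci),
        ):
            assert lo <= point <= hi
            assert 0.0 <= lo and hi <= 1.0

    def test_one_class_test_set_rejected(self):
        model, test = self._fitted(sep=1.0)
        with pytest.raises(UndefinedMetricError):
            evaluate(model, test[test.group == "HC"])


class TestBattery:
    def test_battery_covers_five_conditions_and_two_algorithms(self, small_cohort):
        _, feats, std, groups = small_cohort
        cfg = ModelConfig(seed=0, search_budget=1, n_bootstrap=10)
        reports = run_emotion_battery(std, feats, groups, base_config=cfg)
        table = battery_table(reports)
        assert len(table) == 10  # 5 conditions x 2 algorithms
        assert set(table.algorithm) == {"ertc", "logreg"}
        assert set(table.condition) == {"calm", "happiness", "sadness", "fear", "anger"}

    def test_missing_condition_warns_and_skips(self, small_cohort):
        _, feats, std, groups = small_cohort
        cfg = ModelConfig(seed=0, search_budget=1, n_bootstrap=0)
        partial = std[std.condition != "fear"]
        with pytest.warns(UserWarning, match="fear"):
            reports = run_emotion_battery(partial, feats, groups, base_config=cfg,
                                          algorithms=("ertc",))
        assert ("fear", "ertc") not in reports

    def test_fixed_seed_reproduces_reports(self, small_cohort):
        _, feats, std, groups = small_cohort
        cfg = ModelConfig(seed=4, search_budget=1, n_bootstrap=20)
        a = battery_table(run_emotion_battery(std, feats, groups, base_config=cfg,
                                              algorithms=("ertc",)))
        b = battery_table(run_emotion_battery(std, feats, groups, base_config=cfg,
                                              algorithms=("ertc",)))
        pd.testing.assert_frame_equal(a, b)
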