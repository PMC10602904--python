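"""Classifier battery and leakage-free cross-validation harness."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import (AdaBoostClassifier, ExtraTreesClassifier,
                              GradientBoostingClassifier,
                              RandomForestClassifier)

from entrainflow.classify import (TaskSpec, chance_level, cross_validate,
                                  holdout_split, make_battery, make_task,
                                  run_tasks, summary_table)
from entrainflow.features import FeatureMatrix


def _toy_matrix(rng, n_a=12, n_b=10, n_noise=20, effect=3.0):
    """Participants x 2 conditions; group-a condition carried by column 0,
    group difference by column 1."""
    rows, labels = [], []
    for g, n in (("a", n_a), ("b", n_b)):
        for p in range(n):
            for cond in ("direct", "reversed"):
                x = rng.normal(size=n_noise + 2)
                if g == "a" and cond == "direct":
                    x[0] += effect
                if g == "b":
                    x[1] += effect
                rows.append(x)
                labels.append({"participant": f"{g}{p:02d}", "group": g,
                               "condition": cond})
    cols = ([f"amplitude|left|{i}.0" for i in range(2)]
            + [f"time|right|{i}.0" for i in range(n_noise)])
    return FeatureMatrix(pd.DataFrame(rows, columns=cols),
                         pd.DataFrame(labels))


class TestBattery:
    def test_default_roster_has_ten_algorithms(self):
        battery = make_battery()
        assert len(battery) == 10
        assert set(battery) == {"LR", "LDA", "KNN", "CART", "NB", "SVM",
                                "RF", "ET", "AB", "GBM"}

    @pytest.mark.parametrize("name,cls,count", [
        ("RF", RandomForestClassifier, 100),
        ("ET", ExtraTreesClassifier, 100),
        ("AB", AdaBoostClassifier, 50),
        ("GBM", GradientBoostingClassifier, 100),
    ])
    def test_ensemble_estimator_counts(self, name, cls, count):
        est = make_battery([name])[name]
        assert isinstance(est, cls)
        assert est.n_estimators == count

    def test_unknown_algorithm_error_lists_roster(self):
        with pytest.raises(ValueError, match="LR"):
            make_battery(["XGB"])


class TestTasks:
    def test_four_class_task_has_four_classes(self, rng):
        m = _toy_matrix(rng)
        task = make_task("four_class")
        assert task.n_classes() == 4
        assert len(set(task.class_labels(m.labels))) == 4

    def test_chance_level_of_four_class_is_quarter(self):
        assert chance_level(make_task("four_class")) == 0.25
        assert chance_level(make_task("group_a_condition")) == 0.5

    def test_direct_only_task_uses_half_the_rows(self, rng):
        m = _toy_matrix(rng)
        task = make_task("direct_only_group")
        assert task.row_mask(m.labels).sum() == m.shape[0] // 2

    def test_time_only_subset_selects_time_columns(self, rng):
        m = _toy_matrix(rng, n_noise=20)
        cols = m.columns_for_subset("time_only")
        assert len(cols) == 20
        assert all(c.startswith("time|") for c in cols)

    def test_unknown_task_rejected(self):
        with pytest.raises(ValueError):
            make_task("five_class")


class TestHoldout:
    def test_twenty_percent_of_each_group_held_out(self, rng):
        m = _toy_matrix(rng, n_a=20, n_b=10)
        train, hold = holdout_split(m, seed=1)
        held = hold.labels.groupby("group")["participant"].nunique()
        assert held["a"] == 4
        assert held["b"] == 2

    def test_condition_rows_travel_together(self, rng):
        m = _toy_matrix(rng)
        train, hold = holdout_split(m, seed=2)
        assert set(train.labels["participant"]) \
            .isdisjoint(hold.labels["participant"])
        assert (hold.labels.groupby("participant").size() == 2).all()

    def test_different_seeds_draw_different_sets_of_same_size(self, rng):
        m = _toy_matrix(rng)
        _, h1 = holdout_split(m, seed=1)
        _, h2 = holdout_split(m, seed=99)
        assert h1.shape == h2.shape
        assert set(h1.labels["participant"]) != set(h2.labels["participant"])

    def test_small_group_raises(self, rng):
        m = _toy_matrix(rng, n_a=4, n_b=10)
        with pytest.raises(ValueError, match="20%"):
            holdout_split(m)


class TestCrossValidate:
    def test_fold_scaling_depends_only_on_training_rows(self, rng):
        m = _toy_matrix(rng)
        task = make_task("group_a_condition")
        rep = cross_validate(m, task, battery=make_battery(["LDA"]),
                             folds=5, seed=3)
        sub = m.select_rows(task.row_mask(m.labels))
        for record in rep.scaling_records:
            fit = sub.values.loc[record["fit_rows"]]
            assert np.allclose(record["mean"], fit.mean(axis=0))
            assert np.allclose(record["sd"], fit.std(axis=0, ddof=0))

    def test_no_participant_straddles_folds(self, rng):
        m = _toy_matrix(rng)
        task = make_task("four_class")
        rep = cross_validate(m, task, battery=make_battery(["NB"]),
                             folds=5, seed=3)
        sub = m.select_rows(task.row_mask(m.labels))
        all_rows = set(sub.values.index)
        for record in rep.scaling_records:
            train = set(record["fit_rows"])
            val_participants = set(
                sub.labels.loc[sorted(all_rows - train), "participant"])
            train_participants = set(sub.labels.loc[sorted(train),
                                                    "participant"])
            assert val_participants.isdisjoint(train_participants)

    def test_missing_class_in_training_fold_raises(self, rng):
        # class carried by a single participant cannot stratify
        m = _toy_matrix(rng, n_a=6, n_b=1)
        with pytest.raises(ValueError, match="stratification"):
            cross_validate(m, make_task("four_class"),
                           battery=make_battery(["NB"]), folds=5, seed=0)

    def test_separable_toy_task_is_learned(self, rng):
        m = _toy_matrix(rng, n_a=16, n_noise=8, effect=5.0)
        rep = cross_validate(m, make_task("group_a_condition"),
                             battery=make_battery(["LDA", "NB"]), folds=5,
                             seed=4)
        assert np.mean(rep.fold_accuracies["NB"]) > 0.9
        assert np.mean(rep.fold_accuracies["LDA"]) > 0.8

    def test_report_bundle_is_deterministic(self, rng):
        m = _toy_matrix(rng)
        tasks = [make_task("group_a_condition"),
                 make_task("direct_only_group", "time_only")]
        r1 = run_tasks(m, tasks, battery_names=["LDA", "CART"], folds=5,
                       seed=11)
        r2 = run_tasks(m, tasks, battery_names=["LDA", "CART"], folds=5,
                       seed=11)
        t1, t2 = summary_table(r1), summary_table(r2)
        assert t1.equals(t2)

    def test_empty_task_list_rejected(self, rng):
        with pytest.raises(ValueError):
            run_tasks(_toy_matrix(rng), [], folds=5, seed=0)
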