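"""Brain-state classification battery with a leakage-free CV harness.

Ten classifiers — six base algorithms (logistic regression standing in for
"linear regression" in a classification battery, LDA, kNN, CART, Gaussian
naive Bayes, RBF-SVM) and four ensembles with fixed estimator counts
(random forest 100, extra trees 100, AdaBoost 50, gradient boosting 100) —
are evaluated with 10-fold cross-validation plus a per-group 20 %
participant-level hold-out.

Leakage prevention is structural and instrumented: feature scaling is fit
inside each training fold only (the fitted per-fold parameters and fit-row
ids are recorded in the report), folds are stratified by class and grouped
by participant so a participant's two condition rows never straddle a
split, and the hold-out is drawn by participant before anything is fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (AdaBoostClassifier, ExtraTreesClassifier,
                              GradientBoostingClassifier,
                              RandomForestClassifier)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureMatrix, apply_scaling, zscale

__all__ = [
    "TaskSpec",
    "ClassificationReport",
    "TASK_NAMES",
    "make_task",
    "make_battery",
    "holdout_split",
    "cross_validate",
    "run_tasks",
    "summary_table",
    "chance_level",
]

TASK_NAMES = ("group_a_condition", "group_b_condition", "four_class",
              "direct_only_group")

FEATURE_SUBSETS = ("amplitude_and_time", "time_only", "amplitude_only")


@dataclass(frozen=True)
class TaskSpec:
    """One classification problem over the feature matrix.

    ``name`` selects rows and the label definition:

    - ``group_a_condition`` / ``group_b_condition``: one group's rows,
      classes = stimulus condition (direct vs reversed);
    - ``four_class``: all rows, classes = group × condition;
    - ``direct_only_group``: direct-condition rows only, classes = group.

    ``feature_subset`` restricts columns to amplitude features, time
    features, or both.
    """

    name: str
    feature_subset: str = "amplitude_and_time"

    def __post_init__(self) -> None:
        if self.name not in TASK_NAMES:
            raise ValueError(f"unknown task {self.name!r}; "
                             f"choose from {TASK_NAMES}")
        if self.feature_subset not in FEATURE_SUBSETS:
            raise ValueError(f"unknown feature subset "
                             f"{self.feature_subset!r}")

    def row_mask(self, labels: pd.DataFrame) -> np.ndarray:
        if self.name == "group_a_condition":
            return (labels["group"] == "a").to_numpy()
        if self.name == "group_b_condition":
            return (labels["group"] == "b").to_numpy()
        if self.name == "direct_only_group":
            return (labels["condition"] == "direct").to_numpy()
        return np.ones(len(labels), dtype=bool)

    def class_labels(self, labels: pd.DataFrame) -> np.ndarray:
        if self.name in ("group_a_condition", "group_b_condition"):
            return labels["condition"].to_numpy()
        if self.name == "direct_only_group":
            return labels["group"].to_numpy()
        return (labels["group"] + "_" + labels["condition"]).to_numpy()

    def n_classes(self) -> int:
        return 4 if self.name == "four_class" else 2


def make_task(name: str, feature_subset: str = "amplitude_and_time"
              ) -> TaskSpec:
    return TaskSpec(name, feature_subset)


def chance_level(task: TaskSpec | int) -> float:
    """Expected accuracy of uniform random guessing (1/k)."""
    k = task if isinstance(task, int) else task.n_classes()
    return 1.0 / k


# Roster of (name, factory) pairs; factories take a seed and return a fresh
# estimator.  Estimator counts for the ensembles are fixed by design.
_ROSTER = {
    "LR": lambda seed: LogisticRegression(max_iter=2000),
    "LDA": lambda seed: LinearDiscriminantAnalysis(),
    "KNN": lambda seed: KNeighborsClassifier(),
    "CART": lambda seed: DecisionTreeClassifier(random_state=seed),
    "NB": lambda seed: GaussianNB(),
    "SVM": lambda seed: SVC(kernel="rbf", C=1.0, random_state=seed),
    "RF": lambda seed: RandomForestClassifier(n_estimators=100,
                                              random_state=seed),
    "ET": lambda seed: ExtraTreesClassifier(n_estimators=100,
                                            random_state=seed),
    "AB": lambda seed: AdaBoostClassifier(n_estimators=50,
                                          random_state=seed),
    "GBM": lambda seed: GradientBoostingClassifier(n_estimators=100,
                                                   random_state=seed),
}


def make_battery(names: list[str] | None = None, seed: int = 0) -> dict:
    """Instantiate the classifier battery (all ten by default)."""
    if names is None:
        names = list(_ROSTER)
    unknown = [n for n in names if n not in _ROSTER]
    if unknown:
        raise ValueError(f"unknown algorithm(s) {unknown}; roster is "
                         f"{list(_ROSTER)}")
    return {n: _ROSTER[n](seed) for n in names}


def holdout_split(m: FeatureMatrix, fraction: float = 0.2,
                  seed: int = 0) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Per-group participant-level hold-out.

    From each group, ``fraction`` of the *participants* (rounded, at least
    one) is held out; both condition rows of a held-out participant travel
    together.  Groups smaller than 5 participants cannot yield a 20 % split
    and raise.
    """
    rng = np.random.default_rng(seed)
    held = []
    for group, sub in m.labels.groupby("group"):
        participants = np.sort(sub["participant"].unique())
        if len(participants) < 5:
            raise ValueError(
                f"group {group!r} has {len(participants)} participants; "
                "need >= 5 for a 20% hold-out")
        n_hold = max(1, int(round(fraction * len(participants))))
        held.extend(rng.choice(participants, size=n_hold, replace=False))
    hold_mask = m.labels["participant"].isin(held).to_numpy()
    return m.select_rows(~hold_mask), m.select_rows(hold_mask)


@dataclass
class ClassificationReport:
    """Per-algorithm CV and hold-out accuracies for one task.

    ``fold_accuracies`` maps algorithm → array of per-fold accuracies;
    ``scaling_records`` holds, per fold, the training-row ids and fitted
    column means/SDs — the instrumentation proving fold-local scaling.
    """

    task: TaskSpec
    fold_accuracies: dict[str, np.ndarray]
    holdout_accuracy: dict[str, float]
    n_folds: int
    seed: int
    n_train_rows: int
    n_holdout_rows: int
    scaling_records: list[dict] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, acc in self.fold_accuracies.items():
            rows.append({"algorithm": name,
                         "cv_mean": float(np.mean(acc)),
                         "cv_sd": float(np.std(acc)),
                         "holdout": self.holdout_accuracy.get(name,
                                                              float("nan"))})
        return pd.DataFrame(rows)


def _check_classes(y_train: np.ndarray, y_all: np.ndarray,
                   fold: int) -> None:
    missing = set(np.unique(y_all)) - set(np.unique(y_train))
    if missing:
        raise ValueError(
            f"stratification failure: class(es) {sorted(missing)} absent "
            f"from training fold {fold}")


def cross_validate(train: FeatureMatrix, task: TaskSpec,
                   battery: dict | None = None, folds: int = 10,
                   seed: int = 0,
                   holdout: FeatureMatrix | None = None
                   ) -> ClassificationReport:
    """Grouped, stratified k-fold CV of the battery on one task.

    Scaling is fit on each fold's training rows only and applied to its
    validation rows (recorded in ``scaling_records``).  Folds are grouped
    by participant.  After CV each algorithm is refit on the full training
    set (scaled on itself) and scored once on the hold-out, transformed
    with the training statistics.
    """
    if battery is None:
        battery = make_battery(seed=seed)
    mask = task.row_mask(train.labels)
    sub = train.select_rows(mask)
    cols = sub.columns_for_subset(task.feature_subset)
    X = sub.values[cols]
    y = task.class_labels(sub.labels)
    groups = sub.labels["participant"].to_numpy()
    if len(np.unique(groups)) < folds:
        raise ValueError(f"{len(np.unique(groups))} participants cannot "
                         f"support {folds} grouped folds")

    sub_feat = FeatureMatrix(X, sub.labels)
    splitter = StratifiedGroupKFold(n_splits=folds, shuffle=True,
                                    random_state=seed)
    fold_acc = {name: np.empty(folds) for name in battery}
    scaling_records = []
    for k, (tr, va) in enumerate(splitter.split(X, y, groups)):
        _check_classes(y[tr], y, k)
        fit_rows = X.index[tr]
        scaled_tr = zscale(sub_feat.select_rows(X.index.isin(fit_rows)))
        scaled_va = apply_scaling(
            sub_feat.select_rows(X.index.isin(X.index[va])),
            scaled_tr.scaling)
        scaling_records.append({
            "fold": k,
            "fit_rows": list(map(int, fit_rows)),
            "mean": scaled_tr.scaling["mean"].to_numpy(),
            "sd": scaled_tr.scaling["sd"].to_numpy(),
        })
        for name, est in battery.items():
            model = clone(est)
            model.fit(scaled_tr.values.to_numpy(), y[tr])
            pred = model.predict(scaled_va.values.to_numpy())
            fold_acc[name][k] = np.mean(pred == y[va])

    holdout_acc = {}
    n_hold = 0
    if holdout is not None:
        hmask = task.row_mask(holdout.labels)
        hsub = holdout.select_rows(hmask)
        n_hold = hsub.shape[0]
        if n_hold:
            scaled_full = zscale(sub_feat)
            hX = FeatureMatrix(hsub.values[cols], hsub.labels)
            scaled_hold = apply_scaling(hX, scaled_full.scaling)
            hy = task.class_labels(hsub.labels)
            for name, est in battery.items():
                model = clone(est)
                model.fit(scaled_full.values.to_numpy(), y)
                pred = model.predict(scaled_hold.values.to_numpy())
                holdout_acc[name] = float(np.mean(pred == hy))

    return ClassificationReport(task, fold_acc, holdout_acc, folds, seed,
                                n_train_rows=sub.shape[0],
                                n_holdout_rows=n_hold,
                                scaling_records=scaling_records)


def run_tasks(m: FeatureMatrix, tasks: list[TaskSpec],
              battery_names: list[str] | None = None, folds: int = 10,
              seed: int = 0, holdout_fraction: float = 0.2
              ) -> dict[tuple[str, str], ClassificationReport]:
    """Hold-out split once, then CV every (task, feature subset).

    Returns a report per (task name, feature subset).  The full run is a
    deterministic function of (matrix, tasks, seed).
    """
    if not tasks:
        raise ValueError("empty task list")
    train, hold = holdout_split(m, fraction=holdout_fraction, seed=seed)
    battery = make_battery(battery_names, seed=seed)
    reports = {}
    for task in tasks:
        reports[(task.name, task.feature_subset)] = cross_validate(
            train, task, battery=battery, folds=folds, seed=seed,
            holdout=hold)
    return reports


def summary_table(reports: dict) -> pd.DataFrame:
    """Algorithm × accuracy summary across tasks (long format)."""
    frames = []
    for (name, subset), rep in reports.items():
        df = rep.summary()
        df.insert(0, "task", name)
        df.insert(1, "feature_subset", subset)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
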