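"""The activity-classification experiment grid.

Six feature-set cases (time domain, wavelet domain, their union, each with
and without CFS selection) crossed with five classifiers (multilayer
perceptron, naive Bayes, a C4.5-style pruned decision tree, a 100-tree
random forest and a RIPPER-style rule learner) under stratified 10-fold
cross-validation. Feature selection, when a case requests it, runs on each
fold's training split only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .ingest import TIME_FEATURES
from .profiles import ACTIVITIES
from .ripper import RipperClassifier
from .selection import best_first_select
from .wavelets import WAVELET_FEATURES

CLASSIFIER_NAMES: tuple[str, ...] = (
    "mlp",
    "naive_bayes",
    "c45_tree",
    "random_forest",
    "ripper_rules",
)

#: Time-domain features that survive into the wavelet case (the wavelet case
#: replaces the raw accelerometer/gyroscope features by subband energies).
NON_INERTIAL_TIME_FEATURES: tuple[str, ...] = (
    "distSpeed",
    "distPace",
    "distTotal",
    "hrRate",
    "tempSkin",
    "pedTotalSteps",
    "cal",
)

CASE_NAMES: tuple[str, ...] = (
    "time",
    "time+selection",
    "wavelet",
    "wavelet+selection",
    "time+wavelet",
    "time+wavelet+selection",
)


@dataclass(frozen=True)
class ExperimentCase:
    """One feature-set configuration of the experiment grid."""

    name: str
    feature_names: tuple[str, ...]
    select: bool = False


@dataclass
class ExperimentResult:
    """Cross-validated accuracy and pooled confusion matrix of one run."""

    case_name: str
    classifier_name: str
    accuracy: float  # percent correctly classified
    confusion: pd.DataFrame  # true x predicted counts over all ten activities
    fold_seed: int
    selected_features_per_fold: list[list[str]] = field(default_factory=list)


def build_cases(feature_table: pd.DataFrame) -> dict[str, ExperimentCase]:
    """Instantiate the six experiment cases against a 55-feature table."""
    required = [*TIME_FEATURES, *WAVELET_FEATURES]
    missing = [c for c in required if c not in feature_table.columns]
    if missing:
        raise ValueError(f"feature table is missing columns: {missing}")
    time_set = tuple(TIME_FEATURES)
    wavelet_set = (*NON_INERTIAL_TIME_FEATURES, *WAVELET_FEATURES)
    union_set = (*TIME_FEATURES, *WAVELET_FEATURES)
    cases = {
        "time": ExperimentCase("time", time_set),
        "time+selection": ExperimentCase("time+selection", time_set, select=True),
        "wavelet": ExperimentCase("wavelet", wavelet_set),
        "wavelet+selection": ExperimentCase("wavelet+selection", wavelet_set, select=True),
        "time+wavelet": ExperimentCase("time+wavelet", union_set),
        "time+wavelet+selection": ExperimentCase(
            "time+wavelet+selection", union_set, select=True
        ),
    }
    assert len(cases["time"].feature_names) == 19
    assert len(cases["wavelet"].feature_names) == 43
    assert len(cases["time+wavelet"].feature_names) == 55
    return cases


def make_classifier(name: str, n_features: int, n_classes: int, seed: int):
    """Instantiate one of the five classifiers with its conventional defaults."""
    if name == "mlp":
        hidden = max((n_features + n_classes) // 2, 2)
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "mlp",
                    MLPClassifier(
                        hidden_layer_sizes=(hidden,),
                        solver="sgd",
                        learning_rate_init=0.3,
                        momentum=0.2,
                        max_iter=500,
                        random_state=seed,
                    ),
                ),
            ]
        )
    if name == "naive_bayes":
        return GaussianNB()
    if name == "c45_tree":
        return DecisionTreeClassifier(
            criterion="entropy", min_samples_leaf=2, random_state=seed
        )
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    if name == "ripper_rules":
        return RipperClassifier(random_state=seed)
    raise ValueError(f"unknown classifier {name!r}")


def stratified_fold_assignment(
    labels: np.ndarray, folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Assign each instance to a fold, stratified by class.

    Classes with fewer members than ``folds`` are spread round-robin over
    randomly chosen folds, which degrades gracefully to leave-one-out for
    those instances.
    """
    assignment = np.empty(len(labels), dtype=int)
    for label in np.unique(labels):
        idx = np.nonzero(labels == label)[0]
        idx = rng.permutation(idx)
        start = int(rng.integers(folds))
        assignment[idx] = (start + np.arange(idx.size)) % folds
    return assignment


def run_cv(
    case: ExperimentCase,
    classifier: str,
    table: pd.DataFrame,
    folds: int = 10,
    seed: int = 0,
) -> ExperimentResult:
    """Stratified k-fold cross-validation of one (case, classifier) cell."""
    if len(table) < folds:
        raise ValueError(f"need at least {folds} instances, got {len(table)}")
    X_all = table[list(case.feature_names)]
    y_all = table["activity"].to_numpy()
    rng = np.random.default_rng(seed)
    fold_of = stratified_fold_assignment(y_all, folds, rng)

    labels = list(ACTIVITIES)
    confusion = pd.DataFrame(
        np.zeros((len(labels), len(labels)), dtype=int), index=labels, columns=labels
    )
    selected_per_fold: list[list[str]] = []
    for fold in range(folds):
        test = fold_of == fold
        train = ~test
        if test.sum() == 0:
            continue
        features = list(case.feature_names)
        if case.select:
            result = best_first_select(X_all.loc[train, features], y_all[train])
            if result.selected_feature_names:
                features = result.selected_feature_names
            selected_per_fold.append(features)
        model = make_classifier(
            classifier, len(features), np.unique(y_all[train]).size, seed + fold
        )
        model.fit(X_all.loc[train, features].to_numpy(), y_all[train])
        pred = model.predict(X_all.loc[test, features].to_numpy())
        for t, p in zip(y_all[test], pred):
            confusion.loc[t, p] += 1

    total = confusion.to_numpy().sum()
    accuracy = 100.0 * np.trace(confusion.to_numpy()) / total
    return ExperimentResult(
        case_name=case.name,
        classifier_name=classifier,
        accuracy=float(accuracy),
        confusion=confusion,
        fold_seed=seed,
        selected_features_per_fold=selected_per_fold,
    )


def run_grid(
    table: pd.DataFrame,
    cases: Sequence[str] | None = None,
    classifiers: Sequence[str] | None = None,
    folds: int = 10,
    seed: int = 0,
) -> list[ExperimentResult]:
    """Run (a sub-grid of) the full 6 x 5 experiment grid."""
    all_cases = build_cases(table)
    case_names = list(cases or CASE_NAMES)
    clf_names = list(classifiers or CLASSIFIER_NAMES)
    return [
        run_cv(all_cases[c], clf, table, folds=folds, seed=seed)
        for c in case_names
        for clf in clf_names
    ]


def confusion_report(results: Sequence[ExperimentResult]) -> dict:
    """Summary accuracy table (cases x classifiers) plus per-run matrices."""
    cases = []
    for r in results:
        if r.case_name not in cases:
            cases.append(r.case_name)
    clfs = []
    for r in results:
        if r.classifier_name not in clfs:
            clfs.append(r.classifier_name)
    summary = pd.DataFrame(index=cases, columns=clfs, dtype=float)
    matrices: dict[tuple[str, str], pd.DataFrame] = {}
    for r in results:
        summary.loc[r.case_name, r.classifier_name] = r.accuracy
        matrices[(r.case_name, r.classifier_name)] = r.confusion
    return {"summary": summary, "matrices": matrices}


def plot_confusion(confusion: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """Render one confusion matrix as a heatmap PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(confusion.to_numpy(), cmap="Blues")
    ax.set_xticks(range(len(confusion.columns)), confusion.columns, rotation=90)
    ax.set_yticks(range(len(confusion.index)), confusion.index)
    ax.set_xlabel("Predicted label")
    ax.set_ylabel("True label")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
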