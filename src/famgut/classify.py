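"""Individual discrimination with a bagged tree ensemble.

A random forest is trained to predict which family member a sample came
from, using OTU relative abundances as features.  Performance is measured
by the out-of-bag (OOB) error — each sample is voted on only by trees whose
bootstrap excluded it — and features are ranked by Gini importance (mean
decrease in node impurity).  A refit restricted to the top-k features
quantifies how much signal a handful of discriminating OTUs carries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .tables import CountTable, RelAbundTable

__all__ = ["ClassifierReport", "train_individual_classifier", "top_feature_refit"]


@dataclass
class ClassifierReport:
    """Out-of-bag performance and feature ranking of one forest fit."""

    oob_error: float
    confusion: pd.DataFrame  # rows: true class, columns: OOB-predicted class
    importances: pd.Series  # sorted descending, index = feature ids
    n_trees: int
    seed: int | None
    features: tuple[str, ...]
    per_subject_misclassified: pd.Series  # misclassified sample count per true class

    def __post_init__(self) -> None:
        if not (0.0 <= self.oob_error <= 1.0):
            raise ValueError("OOB error outside [0, 1]")
        if (self.importances < -1e-12).any():
            raise ValueError("importances must be non-negative")

    def top_features(self, k: int) -> list[str]:
        return list(self.importances.index[:k])


def _as_matrix(
    table: CountTable | RelAbundTable | pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    df = table if isinstance(table, pd.DataFrame) else table.data
    df = df.astype(float)
    return df, list(df.columns)


def train_individual_classifier(
    table: CountTable | RelAbundTable | pd.DataFrame,
    labels: pd.Series,
    n_trees: int = 10_000,
    seed: int | None = None,
) -> ClassifierReport:
    """Fit a random forest to discriminate subjects and report OOB metrics.

    ``labels`` maps sample id -> subject id and must cover every sample in
    the table; every class needs at least 2 samples for OOB voting to be
    meaningful.  Deterministic given ``seed``.
    """
    df, features = _as_matrix(table)
    missing = [s for s in df.index if s not in labels.index]
    if missing:
        raise ValueError(f"samples without labels: {missing}")
    y = labels.loc[df.index].astype(str)
    classes = sorted(y.unique())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train a classifier")
    class_counts = y.value_counts()
    if (class_counts < 2).any():
        small = sorted(class_counts.index[class_counts < 2])
        raise ValueError(f"classes with fewer than 2 samples: {small}")

    forest = RandomForestClassifier(
        n_estimators=n_trees,
        oob_score=True,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(df.to_numpy(), y.to_numpy())

    votes = forest.oob_decision_function_
    # a sample can miss OOB votes only with very few trees; break such ties to class 0
    predicted = np.asarray(forest.classes_)[np.nanargmax(np.nan_to_num(votes), axis=1)]
    wrong = predicted != y.to_numpy()
    oob_error = float(wrong.mean())

    confusion = pd.crosstab(
        pd.Series(y.to_numpy(), name="true"),
        pd.Series(predicted, name="predicted"),
    ).reindex(index=classes, columns=classes, fill_value=0)

    # sort by importance, breaking exact ties by feature id for determinism
    importances = pd.Series(forest.feature_importances_, index=features)
    order = sorted(features, key=lambda f: (-importances[f], f))
    importances = importances.loc[order]

    per_subject = pd.Series(wrong, index=df.index).groupby(y).sum().reindex(classes)
    return ClassifierReport(
        oob_error=oob_error,
        confusion=confusion,
        importances=importances,
        n_trees=n_trees,
        seed=seed,
        features=tuple(features),
        per_subject_misclassified=per_subject,
    )


def top_feature_refit(
    table: CountTable | RelAbundTable | pd.DataFrame,
    labels: pd.Series,
    report: ClassifierReport,
    k: int = 15,
    n_trees: int | None = None,
    seed: int | None = None,
) -> ClassifierReport:
    """Refit the forest restricted to the k highest-importance features."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(report.importances):
        raise ValueError(f"k={k} exceeds the {len(report.importances)} ranked features")
    top = report.top_features(k)
    df = table if isinstance(table, pd.DataFrame) else table.data
    return train_individual_classifier(
        df[top].copy(),
        labels,
        n_trees=n_trees if n_trees is not None else report.n_trees,
        seed=seed if seed is not None else report.seed,
    )
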