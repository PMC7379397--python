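"""Imputation effectiveness evaluation.

Whether imputation preserved the information content of the cohort is
measured downstream: a support-vector classifier separates the two
diagnostic groups under stratified 10-fold cross-validation, once on the
complete-case participants of the original data (the reference dataset)
and once on the imputed participants of the completed data, over the same
feature space (all item columns plus the 12 attention indices).  The two
per-fold accuracy vectors are compared with an independent two-sample
pooled-variance t-test; a non-significant difference is the success
criterion — imputation should neither degrade nor artificially inflate
group separability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .registry import CohortTable, ItemRegistry, extract_reference_subset

__all__ = ["ClassificationRun", "EvaluationReport", "classify_groups", "compare_runs", "evaluate_imputation"]

#: Fixed classifier settings, recorded in every run for reproducibility.
CLASSIFIER_DESCRIPTOR = "SVC(kernel='rbf', C=1.0, gamma='scale') on standardized features"


@dataclass
class ClassificationRun:
    fold_accuracies: list[float]
    mean_accuracy: float
    sd_accuracy: float
    classifier: str
    seed: int

    def summary(self) -> str:
        """Mean ± SD, e.g. '0.8931 ± 0.0215'."""
        return f"{self.mean_accuracy:.4f} ± {self.sd_accuracy:.4f}"


@dataclass
class EvaluationReport:
    imputed_run: ClassificationRun
    reference_run: ClassificationRun
    t_statistic: float
    p_value: float


def classify_groups(
    features: np.ndarray, labels: np.ndarray, n_folds: int = 10, seed: int = 0
) -> ClassificationRun:
    """Stratified k-fold CV accuracy of the two-group classifier.

    Feature standardization is fit inside each training fold only.
    Deterministic given ``seed``.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if np.isnan(X).any():
        raise ValueError("features contain missing entries")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both group labels must be present")
    if counts.min() < n_folds:
        raise ValueError(
            f"need at least {n_folds} participants per group for {n_folds}-fold CV "
            f"(smallest group has {counts.min()})"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**32))
    fold_acc: list[float] = []
    for train_idx, test_idx in skf.split(X, y):
        clf = make_pipeline(StandardScaler(), SVC(kernel="rbf", C=1.0, gamma="scale"))
        clf.fit(X[train_idx], y[train_idx])
        fold_acc.append(float(clf.score(X[test_idx], y[test_idx])))
    return ClassificationRun(
        fold_accuracies=fold_acc,
        mean_accuracy=float(np.mean(fold_acc)),
        sd_accuracy=float(np.std(fold_acc, ddof=1)),
        classifier=CLASSIFIER_DESCRIPTOR,
        seed=seed,
    )


def compare_runs(run_a: ClassificationRun, run_b: ClassificationRun) -> tuple[float, float]:
    """Two-sample pooled-variance (Student) t-test on fold accuracies.

    Returns (t, two-sided p).  Degenerate zero-variance samples with equal
    means give (0, 1) by definition rather than an error.
    """
    a = np.asarray(run_a.fold_accuracies, dtype=float)
    b = np.asarray(run_b.fold_accuracies, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each run needs at least 2 folds")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def _feature_matrix(cohort: CohortTable) -> np.ndarray:
    return np.column_stack([cohort.ccpt_matrix(), cohort.item_matrix()])


def evaluate_imputation(
    original_cohort: CohortTable,
    completed_cohort: CohortTable,
    registry: ItemRegistry,
    seed: int = 0,
    n_folds: int = 10,
) -> EvaluationReport:
    """Reference-vs-imputed classification comparison.

    The reference run classifies the complete-case participants of the
    original cohort; the imputed run classifies the remaining participants
    of the completed cohort (the rows that actually received imputed
    values).  The two participant sets are disjoint, hence the independent
    t-test.  Errors if either set is empty.
    """
    ref_ids = set(extract_reference_subset(original_cohort))
    if not ref_ids:
        raise ValueError("reference subset is empty: no complete-case participants")
    all_ids = original_cohort.participant_ids
    imputed_ids = [pid for pid in all_ids if pid not in ref_ids]
    if not imputed_ids:
        raise ValueError("no imputed participants: original cohort had no missing data")
    if completed_cohort.count_missing():
        raise ValueError("completed cohort still has missing item cells")

    is_ref = np.array([pid in ref_ids for pid in all_ids])
    comp_ids = completed_cohort.participant_ids
    if comp_ids != all_ids:
        raise ValueError("completed cohort participants must match the original cohort")

    # shared feature space: indices + the completed cohort's item set (which
    # may be a subset of the original's, e.g. in ODD-exclusion runs)
    item_cols = completed_cohort.item_ids
    if not set(item_cols) <= set(original_cohort.item_ids):
        raise ValueError("completed cohort items must be a subset of the original's")
    X_ref = np.column_stack(
        [original_cohort.ccpt_matrix(), original_cohort.frame[item_cols].to_numpy(float)]
    )[is_ref]
    y_ref = original_cohort.labels[is_ref]
    X_imp = _feature_matrix(completed_cohort)[~is_ref]
    y_imp = completed_cohort.labels[~is_ref]

    ss = np.random.SeedSequence(seed)
    seed_ref, seed_imp = [int(s >> 1) for s in ss.generate_state(2)]
    reference_run = classify_groups(X_ref, y_ref, n_folds=n_folds, seed=seed_ref)
    imputed_run = classify_groups(X_imp, y_imp, n_folds=n_folds, seed=seed_imp)
    t, p = compare_runs(imputed_run, reference_run)
    return EvaluationReport(
        imputed_run=imputed_run, reference_run=reference_run, t_statistic=t, p_value=p
    )
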