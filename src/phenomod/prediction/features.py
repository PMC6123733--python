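"""Feature influence on prediction performance.

Three complementary views:

- **Importance scores** scaled to [0, 100]: a model family's built-in
  measure (tree-ensemble impurity importance, |standardized coefficient|
  for regularized linear models) where one exists, otherwise a
  univariate filter (|Pearson r| with a numeric target; best
  one-vs-rest AUC for class labels).
- **Predictive power**: the mean cross-validated R² obtained when a
  single feature is used alone to predict a numeric target.
- **Greedy backward elimination** (classification): repeatedly drop the
  feature whose removal least decreases cross-validated accuracy, down
  to a single feature, recording the accuracy distribution at every
  subset size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ..exceptions import ValidationError
from .crossval import CVConfig, cv_splits, run_cross_validation, run_seeds
from .metrics import roc_auc
from .registry import SupervisedTable, get_model

__all__ = [
    "ImportanceResult",
    "EliminationPath",
    "feature_importance",
    "predictive_power",
    "greedy_backward_selection",
    "scale_importance",
]


@dataclass
class ImportanceResult:
    feature_names: list
    scores: np.ndarray          # scaled to [0, 100]
    raw: np.ndarray
    method: str                 # "builtin" | "filter"

    def as_dict(self):
        return dict(zip(self.feature_names, self.scores))


def scale_importance(raw) -> np.ndarray:
    """Min–max scale raw scores to [0, 100].

    Invariant under positive affine transforms of the raw scores.  When
    all raw scores are equal the scale is undefined: every feature gets
    100 if the common score is positive, else 0.
    """
    raw = np.asarray(raw, dtype=float)
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.full(raw.shape, 100.0 if hi > 0 else 0.0)
    return (raw - lo) / (hi - lo) * 100.0


def _builtin_raw(table, entry, model_id, seed):
    est, _ = get_model(model_id, table.task, seed)
    est.fit(table.features, table.target)
    final = est[-1] if hasattr(est, "steps") else est
    if entry.builtin_importance == "tree":
        return np.asarray(final.feature_importances_, dtype=float)
    coef = np.atleast_2d(final.coef_)
    return np.mean(np.abs(coef), axis=0)


def _filter_raw(table):
    y = table.target
    raw = np.empty(table.p)
    for j in range(table.p):
        x = table.features[:, j]
        if np.ptp(x) == 0:
            warnings.warn(f"feature {table.feature_names[j]!r} has zero variance;"
                          " raw importance set to 0", stacklevel=3)
            raw[j] = 0.0
            continue
        if table.task == "regression":
            raw[j] = abs(stats.pearsonr(x, y)[0])
        else:
            best = 0.0
            for cls in np.unique(y):
                lab = (y == cls).astype(int)
                if lab.min() == lab.max():
                    continue
                _, auc = roc_auc(lab, x)
                best = max(best, auc, 1.0 - auc)  # direction-free separation
            raw[j] = best
    return raw


def feature_importance(table: SupervisedTable, model_id, config: CVConfig) -> ImportanceResult:
    """Per-feature importance on the 0 (least) – 100 (most) scale."""
    _, entry = get_model(model_id, table.task, config.seed)
    if entry.builtin_importance is not None:
        raw = _builtin_raw(table, entry, model_id, config.seed)
        method = "builtin"
    else:
        raw = _filter_raw(table)
        method = "filter"
    return ImportanceResult(list(table.feature_names), scale_importance(raw),
                            raw, method)


def predictive_power(table: SupervisedTable, model_id, config: CVConfig) -> dict:
    """Mean cross-validated R² of each feature used alone (regression)."""
    if table.task != "regression":
        raise ValidationError("predictive power is defined for regression tasks")
    power = {}
    for name in table.feature_names:
        sub = table.subset_features([name])
        (res,) = run_cross_validation(sub, [model_id], config)
        power[name] = res.mean["r_squared"]
    return power


@dataclass
class EliminationPath:
    """Trace of greedy backward feature elimination.

    ``removal_order`` lists features first-removed to last-removed
    (length p-1; one feature always survives).  ``accuracy_by_size``
    maps each remaining-feature count in {p, ..., 1} to the vector of
    k×N per-fold cross-validation accuracies of the retained subset.
    """

    removal_order: list
    accuracy_by_size: dict

    @property
    def surviving_feature(self):
        removed = set(self.removal_order)
        (last,) = [f for f in self.all_features if f not in removed]
        return last

    @property
    def all_features(self):
        size = max(self.accuracy_by_size)
        # reconstruct original order: removal_order is a permutation minus one
        return self._features

    def mean_accuracy_by_size(self):
        return {s: float(np.mean(v)) for s, v in self.accuracy_by_size.items()}


def _fold_accuracies(table, model_id, config, seeds, splits_per_run):
    """k×N per-fold test accuracies of one feature subset."""
    y = table.target
    accs = []
    for run, seed in enumerate(seeds):
        for train, test in splits_per_run[run]:
            est, _ = get_model(model_id, table.task, seed)
            est.fit(table.features[train], y[train])
            accs.append(float(np.mean(est.predict(table.features[test]) == y[test])))
    return np.asarray(accs)


def greedy_backward_selection(table: SupervisedTable, model_id,
                              config: CVConfig) -> EliminationPath:
    """Greedy backward elimination on cross-validated accuracy.

    At each step the candidate subsets formed by dropping one remaining
    feature are each scored by k-fold × N cross-validation under the
    shared seed schedule; the feature whose removal yields the highest
    mean accuracy (least decrease) is removed, ties resolved in favor of
    the earliest input column.  Iterates until one feature remains.
    """
    if table.task != "classification":
        raise ValidationError("greedy elimination is defined for classification tasks")
    if table.p < 2:
        raise ValidationError("need at least 2 features")
    seeds = run_seeds(config)
    splits_per_run = [cv_splits(table, config, s) for s in seeds]

    def score(feature_subset):
        sub = table.subset_features(feature_subset)
        return _fold_accuracies(sub, model_id, config, seeds, splits_per_run)

    remaining = list(table.feature_names)
    removal_order = []
    accuracy_by_size = {len(remaining): score(remaining)}
    while len(remaining) > 1:
        best_feature, best_mean, best_vec = None, -np.inf, None
        for f in remaining:  # input column order => first max wins ties
            candidate = [g for g in remaining if g != f]
            vec = score(candidate)
            m = float(vec.mean())
            if m > best_mean:
                best_feature, best_mean, best_vec = f, m, vec
        removal_order.append(best_feature)
        remaining.remove(best_feature)
        accuracy_by_size[len(remaining)] = best_vec
    path = EliminationPath(removal_order, accuracy_by_size)
    path._features = list(table.feature_names)
    return path
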