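"""Repeated k-fold cross-validation with pooled per-run metrics.

Each of N randomizations partitions the samples into k folds
((k-1)/k train, 1/k test), collects out-of-fold predictions and scores
the pooled predictions once per run; means and standard deviations are
then taken across runs.  One master seed deterministically generates the
N run seeds, and the same partition schedule is reused across models so
model comparisons are paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from ..exceptions import ValidationError
from .metrics import classification_metrics, multiclass_auc, regression_metrics
from .registry import SupervisedTable, get_model

__all__ = ["CVConfig", "CVResult", "run_cross_validation", "run_seeds", "cv_splits"]


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation settings: k folds, N repeats, master seed."""

    k: int = 5
    repeats: int = 10
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        if self.k < 2:
            raise ValidationError("k must be >= 2")
        if self.repeats < 1:
            raise ValidationError("repeats must be >= 1")


def run_seeds(config: CVConfig) -> np.ndarray:
    """The deterministic per-run seed schedule derived from the master seed."""
    return np.random.SeedSequence(config.seed).generate_state(config.repeats) % (2**31)


def _validate(table: SupervisedTable, config: CVConfig):
    if table.n < 2 * config.k:
        raise ValidationError(f"need n >= 2k samples (n={table.n}, k={config.k})")
    if table.task == "classification" and config.stratified:
        _, counts = np.unique(table.target, return_counts=True)
        if counts.min() < config.k:
            raise ValidationError(
                f"stratified {config.k}-fold CV needs >= k members per class "
                f"(smallest class has {counts.min()})"
            )


def cv_splits(table: SupervisedTable, config: CVConfig, seed: int):
    """The k (train, test) index pairs of one randomization."""
    if table.task == "classification" and config.stratified:
        splitter = StratifiedKFold(n_splits=config.k, shuffle=True, random_state=int(seed))
    else:
        splitter = KFold(n_splits=config.k, shuffle=True, random_state=int(seed))
    return list(splitter.split(table.features, table.target))


@dataclass
class CVResult:
    """Cross-validation outcome for one model."""

    model_id: str
    task: str
    per_run: list                     # one metric dict per randomization
    mean: dict
    sd: dict
    out_of_fold_predictions: np.ndarray   # (N, n), aligned to table rows
    per_fold_accuracy: np.ndarray | None = None  # (N, k), classification only
    config: CVConfig | None = None
    extras: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"Cross-validation: model={self.model_id} task={self.task} "
                 f"k={self.config.k} N={self.config.repeats}"]
        for key in self.mean:
            lines.append(f"  {key:12s} {self.mean[key]: .4f} +/- {self.sd[key]:.4f}")
        return "\n".join(lines)


def _aggregate(per_run):
    keys = [k for k, v in per_run[0].items() if isinstance(v, (int, float))]
    mean = {k: float(np.mean([r[k] for r in per_run])) for k in keys}
    sd = {k: float(np.std([r[k] for r in per_run], ddof=1)) if len(per_run) > 1 else 0.0
          for k in keys}
    return mean, sd


def _one_model(table, model_id, config, seeds, splits_per_run):
    y = table.target
    classes = np.unique(y) if table.task == "classification" else None
    per_run, oof_all, fold_acc = [], [], []
    for run, seed in enumerate(seeds):
        splits = splits_per_run[run]
        oof = np.empty(table.n, dtype=object if table.task == "classification" else float)
        scores = (np.full((table.n, classes.size), np.nan)
                  if classes is not None else None)
        accs = []
        for train, test in splits:
            est, entry = get_model(model_id, table.task, seed)
            est.fit(table.features[train], y[train])
            pred = est.predict(table.features[test])
            oof[test] = pred
            if classes is not None:
                accs.append(float(np.mean(pred == y[test])))
                proba = _class_scores(est, table.features[test], classes)
                if proba is not None:
                    scores[test] = proba
        if table.task == "regression":
            m = regression_metrics(y, np.asarray(oof, dtype=float)).as_dict()
        else:
            cm = classification_metrics(y, np.asarray(list(oof)))
            m = {"accuracy": cm.accuracy}
            if scores is not None and np.all(np.isfinite(scores)):
                m["auc"] = multiclass_auc(y, scores, classes)
            fold_acc.append(accs)
        per_run.append(m)
        oof_all.append(np.asarray(oof))
    mean, sd = _aggregate(per_run)
    return CVResult(
        model_id, table.task, per_run, mean, sd,
        np.stack([o.astype(float) if table.task == "regression" else o
                  for o in oof_all]),
        np.array(fold_acc) if fold_acc else None, config,
    )


def _class_scores(est, X, classes):
    if hasattr(est, "predict_proba"):
        proba = est.predict_proba(X)
        fitted_classes = est.classes_ if hasattr(est, "classes_") else \
            est[-1].classes_
        out = np.zeros((X.shape[0], classes.size))
        lookup = {c: j for j, c in enumerate(fitted_classes)}
        for j, c in enumerate(classes):
            if c in lookup:
                out[:, j] = proba[:, lookup[c]]
        return out
    return None


def run_cross_validation(table, model_ids, config: CVConfig):
    """Evaluate one or more registered models under a shared fold schedule.

    Returns a list of :class:`CVResult`, one per model id, in input order.
    """
    if isinstance(model_ids, str):
        model_ids = [model_ids]
    _validate(table, config)
    seeds = run_seeds(config)
    splits_per_run = [cv_splits(table, config, s) for s in seeds]
    return [_one_model(table, mid, config, seeds, splits_per_run)
            for mid in model_ids]
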