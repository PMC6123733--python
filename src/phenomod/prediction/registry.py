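"""Learner registry: a uniform fit/predict surface over scikit-learn.

Every registered model id maps, per task, to an estimator factory taking
a seed.  Scale-sensitive families are wrapped in a pipeline that centers
and scales features using training-fold statistics only.  Additional
models can be registered through :func:`register_model`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import (
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.linear_model import (
    ElasticNet,
    Lasso,
    LinearRegression,
    LogisticRegression,
    Ridge,
)
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from ..exceptions import UnknownModelError, ValidationError

__all__ = [
    "SupervisedTable",
    "ModelEntry",
    "register_model",
    "get_model",
    "list_models",
]


@dataclass
class SupervisedTable:
    """Sample × feature matrix plus a prediction target.

    ``task`` is ``"regression"`` (numeric target) or ``"classification"``
    (categorical labels).  No missing values are allowed; ingestion drops
    incomplete rows before construction.
    """

    sample_ids: list
    features: np.ndarray
    feature_names: list
    target: np.ndarray
    task: str

    def __post_init__(self):
        X = np.asarray(self.features, dtype=float)
        if X.ndim != 2:
            raise ValidationError("features must be a 2-D matrix")
        n, p = X.shape
        if p < 1 or n < 2:
            raise ValidationError(f"need n >= 2 samples and p >= 1 features, got {X.shape}")
        if not np.all(np.isfinite(X)):
            raise ValidationError("features contain missing/non-finite values")
        if len(self.feature_names) != p or len(self.sample_ids) != n:
            raise ValidationError("name vectors inconsistent with matrix shape")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids")
        if self.task not in ("regression", "classification"):
            raise ValidationError(f"task must be regression|classification, got {self.task!r}")
        y = np.asarray(self.target)
        if y.shape != (n,):
            raise ValidationError("target length must match sample count")
        if self.task == "regression":
            y = y.astype(float)
            if not np.all(np.isfinite(y)):
                raise ValidationError("regression target contains non-finite values")
        self.features = X
        self.target = y

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def p(self) -> int:
        return self.features.shape[1]

    def subset_features(self, names) -> "SupervisedTable":
        idx = [self.feature_names.index(nm) for nm in names]
        return SupervisedTable(self.sample_ids, self.features[:, idx],
                               list(names), self.target, self.task)

    @classmethod
    def from_dataframe(cls, df, target, task=None, id_col=None) -> "SupervisedTable":
        """Build from a wide dataframe with a designated target column."""
        df = df.copy()
        ids = (df.pop(id_col).astype(str).tolist() if id_col
               else [str(i) for i in range(len(df))])
        y = df.pop(target)
        if task is None:
            task = "regression" if np.issubdtype(y.dtype, np.number) else "classification"
        feats = df.select_dtypes(include=[np.number])
        return cls(ids, feats.to_numpy(dtype=float), list(feats.columns),
                   y.to_numpy(), task)


@dataclass(frozen=True)
class ModelEntry:
    model_id: str
    regressor: Callable | None
    classifier: Callable | None
    scale_sensitive: bool = False
    builtin_importance: str | None = None  # "tree" | "coef" | None
    ignores_features: bool = False
    extra: dict = field(default_factory=dict)


def _svm_c(kernel):
    return lambda seed: SVC(kernel=kernel, probability=True, random_state=seed)


_REGISTRY: dict[str, ModelEntry] = {}


def register_model(entry: ModelEntry, overwrite: bool = False):
    """Plugin hook: add a model to the registry."""
    if entry.model_id in _REGISTRY and not overwrite:
        raise ValidationError(f"model id {entry.model_id!r} already registered")
    _REGISTRY[entry.model_id] = entry


for _e in [
    ModelEntry("ols", lambda s: LinearRegression(),
               lambda s: LogisticRegression(max_iter=2000, random_state=s),
               builtin_importance="coef", scale_sensitive=True),
    ModelEntry("ridge", lambda s: Ridge(random_state=s),
               None, scale_sensitive=True, builtin_importance="coef"),
    ModelEntry("lasso", lambda s: Lasso(random_state=s, max_iter=5000),
               None, scale_sensitive=True, builtin_importance="coef"),
    ModelEntry("enet", lambda s: ElasticNet(random_state=s, max_iter=5000),
               None, scale_sensitive=True, builtin_importance="coef"),
    ModelEntry("pls", lambda s: PLSRegression(n_components=2),
               None, scale_sensitive=True),
    ModelEntry("knn", lambda s: KNeighborsRegressor(),
               lambda s: KNeighborsClassifier(), scale_sensitive=True),
    ModelEntry("tree", lambda s: DecisionTreeRegressor(random_state=s),
               lambda s: DecisionTreeClassifier(random_state=s),
               builtin_importance="tree"),
    ModelEntry("rf", lambda s: RandomForestRegressor(n_estimators=200, random_state=s),
               lambda s: RandomForestClassifier(n_estimators=200, random_state=s),
               builtin_importance="tree"),
    ModelEntry("gbm", lambda s: GradientBoostingRegressor(random_state=s),
               lambda s: GradientBoostingClassifier(random_state=s),
               builtin_importance="tree"),
    ModelEntry("svm_linear", lambda s: SVR(kernel="linear"), _svm_c("linear"),
               scale_sensitive=True),
    ModelEntry("svm_rbf", lambda s: SVR(kernel="rbf"), _svm_c("rbf"),
               scale_sensitive=True),
    ModelEntry("mlp",
               lambda s: MLPRegressor(random_state=s, max_iter=1000),
               lambda s: MLPClassifier(random_state=s, max_iter=1000),
               scale_sensitive=True),
    ModelEntry("nb", None, lambda s: GaussianNB()),
    ModelEntry("lda", None, lambda s: LinearDiscriminantAnalysis()),
    ModelEntry("majority", None,
               lambda s: DummyClassifier(strategy="most_frequent"),
               ignores_features=True),
]:
    register_model(_e)


def list_models(task: str | None = None):
    if task is None:
        return sorted(_REGISTRY)
    attr = "regressor" if task == "regression" else "classifier"
    return sorted(m for m, e in _REGISTRY.items() if getattr(e, attr) is not None)


def get_model(model_id: str, task: str, seed: int = 0):
    """Instantiate the estimator for (model_id, task), scaler included."""
    try:
        entry = _REGISTRY[model_id]
    except KeyError:
        raise UnknownModelError(
            f"unknown model id {model_id!r}; registered: {sorted(_REGISTRY)}"
        ) from None
    factory = entry.regressor if task == "regression" else entry.classifier
    if factory is None:
        raise UnknownModelError(f"model {model_id!r} does not support task {task!r}")
    est = factory(int(seed) % (2**31))
    if entry.scale_sensitive:
        est = Pipeline([("scale", StandardScaler()), ("model", est)])
    return est, entry
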