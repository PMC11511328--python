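"""Grid-searched RF / MLP training and test-set evaluation.

The default grids bracket the published best operating points (RF: entropy
criterion, depth 10, 4 features per split, min leaf 1, min split 5, 250
trees; MLP: tanh, hidden layers (100, 25), 200 iterations, batch 200,
learning rate 0.001, Adam with cross-entropy loss).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import ParameterGrid, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "ModelConfig", "ModelReport", "default_rf_grid", "default_mlp_grid",
    "RF_BEST_PARAMS", "MLP_BEST_PARAMS", "grid_search", "train",
    "predict_proba", "evaluate",
]

RF_BEST_PARAMS: dict[str, Any] = {
    "criterion": "entropy",
    "max_depth": 10,
    "max_features": 4,
    "min_samples_leaf": 1,
    "min_samples_split": 5,
    "n_estimators": 250,
}

MLP_BEST_PARAMS: dict[str, Any] = {
    "activation": "tanh",
    "hidden_layer_sizes": (100, 25),
    "max_iter": 200,
    "batch_size": 200,
    "learning_rate_init": 0.001,
    "solver": "adam",
}


def default_rf_grid() -> dict[str, list]:
    """Bracket each published best RF value with a smaller and larger setting."""
    return {
        "criterion": ["gini", "entropy"],
        "max_depth": [5, 10, 20],
        "max_features": [2, 4, 8],
        "min_samples_leaf": [1, 2],
        "min_samples_split": [2, 5, 10],
        "n_estimators": [100, 250, 500],
    }


def default_mlp_grid() -> dict[str, list]:
    return {
        "activation": ["tanh", "relu"],
        "hidden_layer_sizes": [(50,), (100, 25), (200, 50)],
        "max_iter": [200],
        "batch_size": [200],
        "learning_rate_init": [0.0005, 0.001, 0.002],
        "solver": ["adam"],
    }


@dataclass
class ModelConfig:
    family: str  # "rf" or "mlp"
    grid: dict[str, list] = field(default_factory=dict)
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("rf", "mlp"):
            raise ValueError(f"family must be 'rf' or 'mlp', got {self.family!r}")
        if not self.grid:
            self.grid = default_rf_grid() if self.family == "rf" \
                else default_mlp_grid()


@dataclass
class ModelReport:
    """Test-set evaluation summary with bootstrap confidence intervals."""

    classes: list[str]
    confusion: np.ndarray  # (C, C) counts, rows = true class
    metrics: dict[str, float]
    ci: dict[str, tuple[float, float]]
    per_class: dict[str, dict[str, float]]
    best_params: dict[str, Any] | None = None

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "confusion_matrix": self.confusion.tolist(),
            "metrics": self.metrics,
            "ci95": {k: list(v) for k, v in self.ci.items()},
            "per_class": self.per_class,
            "best_params": _jsonable(self.best_params),
        }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _make_estimator(family: str, params: dict[str, Any], seed: int):
    if family == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    mlp = MLPClassifier(random_state=seed, early_stopping=False, **params)
    # MLPs need standardized inputs; scaling is fit inside each CV fold.
    return Pipeline([("scale", StandardScaler()), ("mlp", mlp)])


def grid_search(train_features: pd.DataFrame, y, config: ModelConfig
                ) -> dict[str, Any]:
    """Best grid point by mean stratified-CV accuracy; ties keep grid order."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes for grid search")
    if counts.min() < config.cv_folds:
        raise ValueError(
            f"class with {counts.min()} samples cannot fill {config.cv_folds} "
            "stratified folds")
    X = train_features.to_numpy(dtype=np.float64)
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                          random_state=config.seed)
    folds = list(skf.split(X, y))

    best_params: dict[str, Any] | None = None
    best_score = -np.inf
    for params in ParameterGrid(config.grid):
        scores = []
        for tr, va in folds:
            est = _make_estimator(config.family, params, config.seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                est.fit(X[tr], y[tr])
            scores.append((est.predict(X[va]) == y[va]).mean())
        score = float(np.mean(scores))
        if score > best_score:
            best_score = score
            best_params = dict(params)
    assert best_params is not None
    return best_params


def train(best_params: dict[str, Any], train_features: pd.DataFrame, y,
          family: str, seed: int = 0):
    """Fit the chosen estimator on the full training table.

    The fitted model remembers its feature names; prediction is keyed by
    column name, not position.
    """
    est = _make_estimator(family, best_params, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(train_features.to_numpy(dtype=np.float64), np.asarray(y))
    est.feature_names_ = list(train_features.columns)
    est.best_params_used_ = dict(best_params)
    return est


def _ordered(model, X: pd.DataFrame) -> np.ndarray:
    names = getattr(model, "feature_names_", None)
    if names is not None:
        missing = [n for n in names if n not in X.columns]
        if missing:
            raise KeyError(f"missing feature columns at predict time: {missing}")
        X = X[names]
    return X.to_numpy(dtype=np.float64)


def predict_proba(model, X: pd.DataFrame) -> np.ndarray:
    """Class-probability rows (aligned to ``model.classes_``)."""
    return model.predict_proba(_ordered(model, X))


def _point_metrics(y_true, y_pred, proba, classes) -> tuple[dict, dict]:
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    per_class: dict[str, dict[str, float]] = {}
    sens, spec, prec = [], [], []
    total = cm.sum()
    for i, cls in enumerate(classes):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        s = tp / (tp + fn) if tp + fn else 0.0
        sp = tn / (tn + fp) if tn + fp else 0.0
        p = tp / (tp + fp) if tp + fp else 0.0
        per_class[str(cls)] = {"sensitivity": s, "specificity": sp,
                               "precision": p, "support": int(tp + fn)}
        sens.append(s)
        spec.append(sp)
        prec.append(p)
    metrics = {
        "accuracy": float(np.trace(cm) / total),
        "sensitivity": float(np.mean(sens)),
        "specificity": float(np.mean(spec)),
        "precision": float(np.mean(prec)),
        "auc": float(roc_auc_score(y_true, proba, multi_class="ovr",
                                   average="macro", labels=classes)),
    }
    return metrics, per_class


def evaluate(model, test_features: pd.DataFrame, y_test, n_boot: int = 1000,
             seed: int = 0) -> ModelReport:
    """Confusion matrix and macro one-vs-rest metrics with 95% bootstrap CIs.

    CIs are percentile intervals over ``n_boot`` resamples of the test rows;
    resamples missing a class are redrawn (capped), keeping AUC defined.
    """
    y_test = np.asarray(y_test)
    if len(y_test) == 0:
        raise ValueError("test set is empty")
    classes = list(model.classes_)
    present = set(np.unique(y_test))
    if not present.issuperset(classes):
        raise ValueError("every model class must appear in the test set")
    proba = predict_proba(model, test_features)
    y_pred = np.asarray(classes)[np.argmax(proba, axis=1)]

    metrics, per_class = _point_metrics(y_test, y_pred, proba, classes)
    cm = confusion_matrix(y_test, y_pred, labels=classes)

    rng = np.random.default_rng(seed)
    n = len(y_test)
    boot: dict[str, list[float]] = {k: [] for k in metrics}
    for _ in range(n_boot):
        for _attempt in range(100):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y_test[idx])) == len(classes):
                break
        m, _ = _point_metrics(y_test[idx], y_pred[idx], proba[idx], classes)
        for k, v in m.items():
            boot[k].append(v)
    ci = {k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
          for k, v in boot.items()}
    # Percentile intervals can exclude the point estimate only by resampling
    # noise; clip so lower <= point <= upper.
    ci = {k: (min(ci[k][0], metrics[k]), max(ci[k][1], metrics[k]))
          for k in ci}

    return ModelReport(classes=[str(c) for c in classes], confusion=cm,
                       metrics=metrics, ci=ci, per_class=per_class,
                       best_params=getattr(model, "best_params_used_", None))
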