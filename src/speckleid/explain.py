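"""Model-agnostic Shapley-value attribution with marginal background replacement.

The coalition value of a feature subset S for a sample x is the expectation of
the model output when features in S keep the sample's values and the rest are
replaced by background rows (marginal expectation).  Exact enumeration over
all subsets is used automatically when the feature count is at most 8;
otherwise a Monte-Carlo permutation estimator is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd

__all__ = ["ShapMatrix", "shapley_values", "global_importance",
           "beeswarm_export"]

EXACT_MAX_FEATURES = 8


@dataclass
class ShapMatrix:
    """Per (sample, feature, class) attributions plus per-class base values."""

    values: np.ndarray          # (n_samples, n_features, n_classes)
    base_values: np.ndarray     # (n_classes,)
    feature_names: list[str]
    n_background: int

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_classes(self) -> int:
        return self.values.shape[2]


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=np.float64)
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])


def _call_predict(predict_fn, X: np.ndarray, sample_index: int | None = None
                  ) -> np.ndarray:
    try:
        out = np.asarray(predict_fn(X), dtype=np.float64)
    except Exception as exc:
        ctx = f" while explaining sample {sample_index}" if sample_index is not None else ""
        raise RuntimeError(f"predict_fn failed{ctx}: {exc}") from exc
    if out.ndim == 1:
        out = out[:, None]
    return out


def _coalition_value(predict_fn, x: np.ndarray, background: np.ndarray,
                     mask: np.ndarray, sample_index: int) -> np.ndarray:
    """E over background of f(x_S, b_notS) for one coalition mask."""
    grid = background.copy()
    grid[:, mask] = x[mask]
    return _call_predict(predict_fn, grid, sample_index).mean(axis=0)


def _exact_shapley(predict_fn, x, background, n_features, sample_index):
    # Cache coalition values by bitmask; weights are the classic
    # |S|!(d-|S|-1)!/d! Shapley kernel.
    cache: dict[int, np.ndarray] = {}

    def value(bits: int) -> np.ndarray:
        if bits not in cache:
            mask = np.array([(bits >> f) & 1 for f in range(n_features)],
                            dtype=bool)
            cache[bits] = _coalition_value(predict_fn, x, background, mask,
                                           sample_index)
        return cache[bits]

    d = n_features
    n_classes = value(0).shape[0]
    phi = np.zeros((d, n_classes))
    others = list(range(d))
    for f in range(d):
        rest = [g for g in others if g != f]
        for size in range(d):
            w = factorial(size) * factorial(d - size - 1) / factorial(d)
            for combo in combinations(rest, size):
                bits = sum(1 << g for g in combo)
                phi[f] += w * (value(bits | (1 << f)) - value(bits))
    return phi


def _sampled_shapley(predict_fn, x, background, n_features, n_permutations,
                     rng, sample_index):
    n_classes = _call_predict(predict_fn, background[:1], sample_index).shape[1]
    phi = np.zeros((n_features, n_classes))
    mask = np.zeros(n_features, dtype=bool)
    for _ in range(n_permutations):
        order = rng.permutation(n_features)
        mask[:] = False
        prev = _coalition_value(predict_fn, x, background, mask, sample_index)
        for f in order:
            mask[f] = True
            cur = _coalition_value(predict_fn, x, background, mask,
                                   sample_index)
            phi[f] += cur - prev
            prev = cur
    return phi / n_permutations


def shapley_values(predict_fn, background, samples, n_permutations: int = 100,
                   seed: int = 0, exact: bool | None = None) -> ShapMatrix:
    """Shapley attribution of ``predict_fn`` outputs for each sample row.

    ``predict_fn`` maps an (n, d) array to (n, n_classes) outputs (or (n,)
    for a scalar model).  ``exact=None`` selects exact enumeration when
    d <= 8, sampling otherwise.
    """
    bg = _as_frame(background)
    S = _as_frame(samples)
    if len(bg) == 0:
        raise ValueError("background must be non-empty")
    if list(bg.columns) != list(S.columns):
        raise ValueError("background and samples must share feature columns")
    d = bg.shape[1]
    if exact is None:
        exact = d <= EXACT_MAX_FEATURES
    bg_arr = bg.to_numpy(dtype=np.float64)
    s_arr = S.to_numpy(dtype=np.float64)
    rng = np.random.default_rng(seed)

    base = _call_predict(predict_fn, bg_arr).mean(axis=0)
    values = np.empty((len(S), d, base.shape[0]))
    for i, x in enumerate(s_arr):
        if exact:
            values[i] = _exact_shapley(predict_fn, x, bg_arr, d, i)
        else:
            values[i] = _sampled_shapley(predict_fn, x, bg_arr, d,
                                         n_permutations, rng, i)
    return ShapMatrix(values=values, base_values=base,
                      feature_names=list(bg.columns), n_background=len(bg))


def global_importance(shap: ShapMatrix) -> pd.Series:
    """Mean |phi| over samples and classes, sorted descending."""
    if shap.n_samples == 0:
        raise ValueError("empty attribution matrix")
    imp = np.abs(shap.values).mean(axis=(0, 2))
    return pd.Series(imp, index=shap.feature_names).sort_values(
        ascending=False, kind="stable")


def beeswarm_export(shap: ShapMatrix, X, class_index: int) -> pd.DataFrame:
    """Long-form per-class attribution table for beeswarm-style plotting.

    One row per (feature, sample) holding the attribution and the raw feature
    value; features are ordered by total |phi| for the class, descending.
    """
    if not (0 <= class_index < shap.n_classes):
        raise ValueError(f"class_index {class_index} out of range")
    Xf = _as_frame(X)
    phi = shap.values[:, :, class_index]
    order = np.argsort(-np.abs(phi).sum(axis=0), kind="stable")
    rows = []
    for f in order:
        name = shap.feature_names[f]
        for s in range(shap.n_samples):
            rows.append((name, s, phi[s, f], Xf.iloc[s, f]))
    return pd.DataFrame(rows, columns=["feature", "sample", "phi",
                                       "feature_value"])
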