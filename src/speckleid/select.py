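"""Training-set feature selection: LOF outlier removal and collinearity pruning.

LOF is implemented in its classic form (k-distance, reachability distance,
local reachability density, density ratio) with the standard tie rule: the
neighborhood contains every point within the k-th nearest distance, so it can
hold more than k members when distances tie.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = ["LofResult", "FeatureMask", "lof_scores", "remove_outliers",
           "collinearity_filter", "apply_mask"]

_LRD_CAP = 1e12  # duplicate clusters give zero reachability; cap the density


@dataclass
class LofResult:
    scores: np.ndarray  # classic LOF ratio per sample (> 1 = more anomalous)
    k: int
    metric: str = "euclidean"


@dataclass
class FeatureMask:
    kept: list[str]
    dropped_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    threshold: float = 0.9
    seed: int = 0


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=np.float64)
    return np.asarray(X, dtype=np.float64)


def lof_scores(X, k: int = 20) -> LofResult:
    """Classic local outlier factor for every row of ``X``.

    Scores near 1 mark interior points; scores well above 1 mark outliers.
    Uses full pairwise Euclidean distances (exact ties handling); memory is
    O(n^2), fine up to ~10^4 samples.
    """
    M = _as_matrix(X)
    n = M.shape[0]
    if n <= k:
        raise ValueError(f"need more samples ({n}) than neighbors k={k}")

    D = cdist(M, M)
    np.fill_diagonal(D, np.inf)
    # k-distance: distance to the k-th nearest neighbor (excluding self).
    kdist = np.partition(D, k - 1, axis=1)[:, k - 1]
    # Neighborhoods include every point within the k-distance (tie rule).
    neigh_mask = D <= kdist[:, None]

    lrd = np.empty(n)
    neighborhoods: list[np.ndarray] = []
    for p in range(n):
        nb = np.flatnonzero(neigh_mask[p])
        neighborhoods.append(nb)
        reach = np.maximum(kdist[nb], D[p, nb])
        mean_reach = reach.mean()
        lrd[p] = 1.0 / mean_reach if mean_reach > 0 else _LRD_CAP

    scores = np.empty(n)
    for p in range(n):
        nb = neighborhoods[p]
        scores[p] = (lrd[nb] / lrd[p]).mean()
    return LofResult(scores=scores, k=k)


def remove_outliers(X: pd.DataFrame, fraction: float = 0.10, k: int = 20,
                    convention: str = "high") -> pd.DataFrame:
    """Drop the floor(fraction * n) most anomalous rows by LOF.

    ``convention="high"`` (default) treats high LOF ratios as anomalous —
    the classic reading.  ``convention="low"`` removes the lowest scores
    instead, matching libraries that report negated LOF.  Ties are broken by
    row order (stable sort), so the result is deterministic.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must be in [0, 1)")
    if convention not in ("high", "low"):
        raise ValueError(f"unknown convention {convention!r}")
    n = len(X)
    n_drop = int(np.floor(fraction * n))
    if n_drop == 0:
        return X.copy()
    scores = lof_scores(X, k=k).scores
    key = -scores if convention == "high" else scores
    drop = np.argsort(key, kind="stable")[:n_drop]
    keep = np.setdiff1d(np.arange(n), drop)
    return X.iloc[keep]


def collinearity_filter(X: pd.DataFrame, threshold: float = 0.9,
                        seed: int = 0) -> FeatureMask:
    """Prune features until no pair has |Pearson r| >= ``threshold``.

    Constant features are dropped first with a warning.  Violating pairs are
    visited in lexicographic upper-triangle order; one member of each pair is
    removed uniformly at random (seeded) and violations are re-examined among
    the survivors.  The returned mask records every removal and its
    correlation.
    """
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    rng = np.random.default_rng(seed)
    names = list(X.columns)
    values = X.to_numpy(dtype=np.float64)

    stds = values.std(axis=0)
    constant = [names[i] for i in range(len(names)) if stds[i] == 0]
    if constant:
        warnings.warn(f"dropping {len(constant)} constant feature(s): "
                      f"{constant}", stacklevel=2)
    live = [i for i in range(len(names)) if stds[i] > 0]

    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(values[:, live], rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)

    alive = list(range(len(live)))
    dropped_pairs: list[tuple[str, str, float]] = []
    while True:
        violation = None
        for ai, a in enumerate(alive):
            for b in alive[ai + 1:]:
                if abs(corr[a, b]) >= threshold:
                    violation = (a, b)
                    break
            if violation:
                break
        if violation is None:
            break
        a, b = violation
        out = a if rng.random() < 0.5 else b
        keep_member = b if out == a else a
        dropped_pairs.append((names[live[out]], names[live[keep_member]],
                              float(corr[a, b])))
        alive.remove(out)

    kept = [names[live[a]] for a in alive]
    # Post-condition: no surviving pair violates the threshold.
    sub = np.abs(corr[np.ix_(alive, alive)])
    np.fill_diagonal(sub, 0.0)
    assert sub.max(initial=0.0) < threshold
    return FeatureMask(kept=kept, dropped_pairs=dropped_pairs,
                       threshold=threshold, seed=seed)


def apply_mask(X: pd.DataFrame, mask: FeatureMask) -> pd.DataFrame:
    return X[mask.kept]
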