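"""Per-drug gray-level distributions, one-way ANOVA, and Tukey HSD."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import studentized_range

__all__ = ["GrayLevelDistribution", "gray_level_distributions",
           "anova_oneway", "tukey_hsd"]


@dataclass
class GrayLevelDistribution:
    """Aligned empirical gray-level probabilities per drug."""

    bin_edges: np.ndarray
    probabilities: dict[str, np.ndarray]
    pixel_counts: dict[str, int]


def gray_level_distributions(images_by_drug: Mapping[str, Sequence[np.ndarray]],
                             n_bins: int = 256, standardize: bool = True
                             ) -> GrayLevelDistribution:
    """Pooled standardized pixel histograms per drug on a common support."""
    pooled: dict[str, np.ndarray] = {}
    for drug, images in images_by_drug.items():
        if len(images) == 0:
            raise ValueError(f"no images for drug {drug!r}")
        vals = np.concatenate([np.asarray(im, dtype=np.float64).ravel()
                               for im in images])
        if standardize:
            sd = vals.std()
            vals = (vals - vals.mean()) / sd if sd > 0 else vals - vals.mean()
        pooled[drug] = vals

    lo = min(v.min() for v in pooled.values())
    hi = max(v.max() for v in pooled.values())
    if hi == lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    probabilities = {}
    counts = {}
    for drug, vals in pooled.items():
        hist, _ = np.histogram(vals, bins=edges)
        probabilities[drug] = hist / hist.sum()
        counts[drug] = int(vals.size)
    return GrayLevelDistribution(bin_edges=edges, probabilities=probabilities,
                                 pixel_counts=counts)


def anova_oneway(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA: F = MS_between / MS_within, p from F(k-1, N-k).

    Zero within-group variance with unequal group means returns (inf, 0.0).
    """
    groups = [np.asarray(g, dtype=np.float64).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 values")
    k = len(groups)
    N = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = k - 1
    df_within = N - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        if ms_between == 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    F = ms_between / ms_within
    p = float(f_dist.sf(F, df_between, df_within))
    return float(F), p


def tukey_hsd(groups: Sequence[np.ndarray], alpha: float = 0.01,
              names: Sequence[str] | None = None) -> pd.DataFrame:
    """All-pairs studentized-range comparisons with pooled within variance.

    Returns a table with columns group_a, group_b, mean_diff, q, p, reject;
    reject is True iff p < alpha.  Unequal group sizes use the
    Tukey-Kramer harmonic form.
    """
    groups = [np.asarray(g, dtype=np.float64).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 values")
    k = len(groups)
    if names is None:
        names = [f"group{i}" for i in range(k)]
    N = sum(len(g) for g in groups)
    df_within = N - k
    ms_within = sum(((g - g.mean()) ** 2).sum() for g in groups) / df_within

    rows = []
    for a in range(k):
        for b in range(a + 1, k):
            diff = groups[a].mean() - groups[b].mean()
            if ms_within == 0:
                q = 0.0 if diff == 0 else float("inf")
                p = 1.0 if diff == 0 else 0.0
            else:
                se = np.sqrt(ms_within / 2.0 *
                             (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
                q = abs(diff) / se
                p = float(studentized_range.sf(q, k, df_within))
            rows.append((names[a], names[b], float(diff), float(q), p,
                         bool(p < alpha)))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "mean_diff",
                                       "q", "p", "reject"])
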