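"""129-feature statistical texture descriptor for 8-bit images.

The descriptor concatenates 5 first-order statistics with 20 co-occurrence
(GLCM) statistics and 11 run-length (GLRLM) statistics per direction
theta in {0, 45, 90, 135} degrees: 5 + 4 * (20 + 11) = 129 values.

Conventions
-----------
* The GLCM is asymmetric (single offset per direction, no transpose
  symmetrization) over the full 256 gray levels at displacement d = 1.
* Angles map to (delta_row, delta_col) offsets with rows increasing downward:
  0 -> (0, +1), 45 -> (-1, +1), 90 -> (-1, 0), 135 -> (-1, -1).
* Entropies use the natural logarithm with 0 * ln 0 = 0.
* The GLRLM quantizes gray levels to 32 bins by default (full 8-bit runs on
  speckle are almost all of length 1); run-emphasis formulas index gray
  levels from 1.
* Kurtosis is excess (Fisher); skewness/kurtosis of a constant image are 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GLCM", "GLRLM", "THETAS", "GLCM_STAT_NAMES", "GLRLM_STAT_NAMES",
    "FIRST_ORDER_NAMES", "FEATURE_NAMES", "first_order_stats", "compute_glcm",
    "glcm_stats", "compute_glrlm", "glrlm_stats", "extract_features",
]

THETAS = (0, 45, 90, 135)

# (delta_row, delta_col) for each direction; rows increase downward.
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

FIRST_ORDER_NAMES = (
    "intensity", "standard_deviation", "variance", "kurtosis", "skewness",
)

GLCM_STAT_NAMES = (
    "energy", "contrast", "correlation", "sum_of_squares_variance",
    "homogeneity", "sum_average", "sum_variance", "sum_entropy", "entropy",
    "difference_variance", "difference_entropy", "imc1", "imc2",
    "dissimilarity", "autocorrelation", "cluster_shade", "cluster_prominence",
    "maximum_probability", "inverse_difference",
    "inverse_difference_moment_normalized",
)

GLRLM_STAT_NAMES = (
    "sre", "lre", "gln", "rln", "rp",
    "lgre", "hgre", "srlge", "srhge", "lrlge", "lrhge",
)

FEATURE_NAMES: tuple[str, ...] = tuple(
    list(FIRST_ORDER_NAMES)
    + [f"{stat}_{t}" for t in THETAS for stat in GLCM_STAT_NAMES]
    + [f"{stat}_{t}" for t in THETAS for stat in GLRLM_STAT_NAMES]
)
assert len(FEATURE_NAMES) == 129


@dataclass
class GLCM:
    """Directional gray-level co-occurrence counts and probabilities."""

    counts: np.ndarray  # (K, K) int64
    d: int
    theta: int

    @property
    def normalized(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / total


@dataclass
class GLRLM:
    """Directional gray-level run-length counts.

    ``counts[i, j]`` is the number of maximal runs of quantized level i
    (0-based) and length j + 1.
    """

    counts: np.ndarray  # (n_levels, max_run_length) int64
    theta: int
    n_levels: int
    n_pixels: int


def first_order_stats(image: np.ndarray) -> dict[str, float]:
    """Mean, population SD/variance, Fisher kurtosis, and skewness."""
    x = np.asarray(image, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("image must be non-empty")
    mean = x.mean()
    var = x.var()
    sd = np.sqrt(var)
    if sd == 0:
        skew = kurt = 0.0
    else:
        z = (x - mean) / sd
        skew = float(np.mean(z ** 3))
        kurt = float(np.mean(z ** 4) - 3.0)
    return {
        "intensity": float(mean),
        "standard_deviation": float(sd),
        "variance": float(var),
        "kurtosis": kurt,
        "skewness": skew,
    }


def compute_glcm(image: np.ndarray, d: int = 1, theta: int = 0,
                 n_levels: int = 256) -> GLCM:
    """Single-offset co-occurrence counts for direction ``theta``."""
    if theta not in _OFFSETS:
        raise ValueError(f"theta must be one of {sorted(_OFFSETS)}, got {theta}")
    if d < 1:
        raise ValueError("d must be >= 1")
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    dr, dc = _OFFSETS[theta]
    dr, dc = dr * d, dc * d
    h, w = img.shape

    r0 = slice(max(0, -dr), min(h, h - dr))
    c0 = slice(max(0, -dc), min(w, w - dc))
    src = img[r0, c0].ravel().astype(np.int64)
    dst = img[r0.start + dr:r0.stop + dr,
              c0.start + dc:c0.stop + dc].ravel().astype(np.int64)
    counts = np.bincount(src * n_levels + dst,
                         minlength=n_levels * n_levels).reshape(n_levels,
                                                                n_levels)
    return GLCM(counts=counts, d=d, theta=theta)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def glcm_stats(glcm: GLCM) -> dict[str, float]:
    """The 20 co-occurrence statistics from the normalized matrix."""
    counts = glcm.counts
    total = counts.sum()
    if total == 0:
        raise ValueError("GLCM has no pixel pairs")
    K = counts.shape[0]

    # Sparse evaluation: operate on nonzero entries only.
    ii, jj = np.nonzero(counts)
    p = counts[ii, jj] / total
    i = ii.astype(np.float64)
    j = jj.astype(np.float64)

    px = np.bincount(ii, weights=p, minlength=K)
    py = np.bincount(jj, weights=p, minlength=K)
    p_sum = np.bincount(ii + jj, weights=p, minlength=2 * K - 1)
    p_diff = np.bincount(np.abs(ii - jj), weights=p, minlength=K)

    mu_x = float((np.arange(K) * px).sum())
    mu_y = float((np.arange(K) * py).sum())
    sd_x = float(np.sqrt(((np.arange(K) - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((np.arange(K) - mu_y) ** 2 * py).sum()))

    diff = i - j
    adiff = np.abs(diff)

    energy = float((p ** 2).sum())
    contrast = float((diff ** 2 * p).sum())
    autocorr = float((i * j * p).sum())
    if sd_x > 0 and sd_y > 0:
        correlation = (autocorr - mu_x * mu_y) / (sd_x * sd_y)
    else:
        correlation = 0.0
    ssq_variance = float(((i - mu_x) ** 2 * p).sum())
    homogeneity = float((p / (1.0 + diff ** 2)).sum())
    inv_diff = float((p / (1.0 + adiff)).sum())
    idmn = float((p / (1.0 + (diff / K) ** 2)).sum())
    dissimilarity = float((adiff * p).sum())
    max_prob = float(p.max())

    k_sum = np.arange(2 * K - 1, dtype=np.float64)
    sum_avg = float((k_sum * p_sum).sum())
    sum_var = float(((k_sum - sum_avg) ** 2 * p_sum).sum())
    sum_ent = _entropy(p_sum)

    k_diff = np.arange(K, dtype=np.float64)
    mu_diff = float((k_diff * p_diff).sum())
    diff_var = float(((k_diff - mu_diff) ** 2 * p_diff).sum())
    diff_ent = _entropy(p_diff)

    hxy = _entropy(p)
    hx = _entropy(px)
    hy = _entropy(py)
    # HXY1 over nonzero joint entries; HXY2 over the product marginal support.
    pxpy_at = px[ii] * py[jj]
    pos = pxpy_at > 0
    hxy1 = float(-(p[pos] * np.log(pxpy_at[pos])).sum())
    nx = np.nonzero(px)[0]
    ny = np.nonzero(py)[0]
    outer = np.outer(px[nx], py[ny])
    hxy2 = float(-(outer * np.log(outer)).sum())
    denom = max(hx, hy)
    imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    shade_base = i + j - mu_x - mu_y
    cluster_shade = float((shade_base ** 3 * p).sum())
    cluster_prominence = float((shade_base ** 4 * p).sum())

    return {
        "energy": energy,
        "contrast": contrast,
        "correlation": float(correlation),
        "sum_of_squares_variance": ssq_variance,
        "homogeneity": homogeneity,
        "sum_average": sum_avg,
        "sum_variance": sum_var,
        "sum_entropy": sum_ent,
        "entropy": hxy,
        "difference_variance": diff_var,
        "difference_entropy": diff_ent,
        "imc1": float(imc1),
        "imc2": imc2,
        "dissimilarity": dissimilarity,
        "autocorrelation": autocorr,
        "cluster_shade": cluster_shade,
        "cluster_prominence": cluster_prominence,
        "maximum_probability": max_prob,
        "inverse_difference": inv_diff,
        "inverse_difference_moment_normalized": idmn,
    }


def _direction_lines(img: np.ndarray, theta: int) -> list[np.ndarray]:
    h, w = img.shape
    if theta == 0:
        return [img[r] for r in range(h)]
    if theta == 90:
        return [img[:, c] for c in range(w)]
    if theta == 135:  # main diagonals (down-right == up-left reversed)
        return [np.diagonal(img, k) for k in range(-(h - 1), w)]
    if theta == 45:  # anti-diagonals
        flipped = img[::-1]
        return [np.diagonal(flipped, k) for k in range(-(h - 1), w)]
    raise ValueError(f"theta must be one of {THETAS}, got {theta}")


def compute_glrlm(image: np.ndarray, theta: int = 0,
                  n_levels: int = 32) -> GLRLM:
    """Maximal-run counts by quantized gray level and run length."""
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    if theta not in THETAS:
        raise ValueError(f"theta must be one of {THETAS}, got {theta}")
    if not (2 <= n_levels <= 256):
        raise ValueError("n_levels must be in [2, 256]")
    q = (img.astype(np.int64) * n_levels) // 256 if n_levels != 256 \
        else img.astype(np.int64)
    q = np.clip(q, 0, n_levels - 1)

    lines = _direction_lines(q, theta)
    # Concatenate all lines with a sentinel separator, then find run breaks
    # in one vectorized pass.
    sep = -1
    parts: list[np.ndarray] = []
    for ln in lines:
        parts.append(np.asarray(ln, dtype=np.int64))
        parts.append(np.array([sep], dtype=np.int64))
    flat = np.concatenate(parts)
    change = np.flatnonzero(np.diff(flat) != 0) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [flat.size]))
    levels = flat[starts]
    lengths = ends - starts
    keep = levels != sep
    levels = levels[keep]
    lengths = lengths[keep]

    max_len = int(lengths.max()) if lengths.size else 1
    counts = np.zeros((n_levels, max_len), dtype=np.int64)
    np.add.at(counts, (levels, lengths - 1), 1)
    return GLRLM(counts=counts, theta=theta, n_levels=n_levels,
                 n_pixels=int(img.size))


def glrlm_stats(glrlm: GLRLM) -> dict[str, float]:
    """The 11 run-emphasis statistics (gray levels indexed from 1)."""
    counts = glrlm.counts
    n_runs = counts.sum()
    if n_runs == 0:
        raise ValueError("GLRLM has no runs")
    gl = np.arange(1, counts.shape[0] + 1, dtype=np.float64)[:, None]
    rl = np.arange(1, counts.shape[1] + 1, dtype=np.float64)[None, :]
    c = counts.astype(np.float64)
    g_marg = c.sum(axis=1)
    r_marg = c.sum(axis=0)
    rl1 = rl.ravel()
    gl1 = gl.ravel()

    return {
        "sre": float((r_marg / rl1 ** 2).sum() / n_runs),
        "lre": float((r_marg * rl1 ** 2).sum() / n_runs),
        "gln": float((g_marg ** 2).sum() / n_runs),
        "rln": float((r_marg ** 2).sum() / n_runs),
        "rp": float(n_runs / glrlm.n_pixels),
        "lgre": float((g_marg / gl1 ** 2).sum() / n_runs),
        "hgre": float((g_marg * gl1 ** 2).sum() / n_runs),
        "srlge": float((c / (gl ** 2 * rl ** 2)).sum() / n_runs),
        "srhge": float((c * gl ** 2 / rl ** 2).sum() / n_runs),
        "lrlge": float((c * rl ** 2 / gl ** 2).sum() / n_runs),
        "lrhge": float((c * gl ** 2 * rl ** 2).sum() / n_runs),
    }


def extract_features(image: np.ndarray, glrlm_levels: int = 32) -> dict[str, float]:
    """Full 129-value named descriptor of one 8-bit image."""
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("image must be a 2-D gray-level array")
    out = first_order_stats(img)
    for theta in THETAS:
        stats = glcm_stats(compute_glcm(img, d=1, theta=theta))
        for name, value in stats.items():
            out[f"{name}_{theta}"] = value
    for theta in THETAS:
        stats = glrlm_stats(compute_glrlm(img, theta=theta,
                                          n_levels=glrlm_levels))
        for name, value in stats.items():
            out[f"{name}_{theta}"] = value
    assert len(out) == 129
    return out
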