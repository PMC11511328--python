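"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately written in the most literal way possible
(pure-Python loops, direct definitions), sharing no code with the package.
"""

from __future__ import annotations

import math
from itertools import permutations

import numpy as np

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def brute_glcm_counts(image, theta: int, d: int = 1) -> dict[tuple[int, int], int]:
    """Pair counts by direct double loop over pixels."""
    img = np.asarray(image)
    h, w = img.shape
    dr, dc = OFFSETS[theta]
    dr, dc = dr * d, dc * d
    counts: dict[tuple[int, int], int] = {}
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                key = (int(img[r, c]), int(img[r2, c2]))
                counts[key] = counts.get(key, 0) + 1
    return counts


def brute_glcm_stats(counts: dict[tuple[int, int], int]) -> dict[str, float]:
    """The 20 co-occurrence statistics from a pair-count dict, by definition."""
    total = sum(counts.values())
    p = {k: v / total for k, v in counts.items()}
    px: dict[int, float] = {}
    py: dict[int, float] = {}
    for (i, j), v in p.items():
        px[i] = px.get(i, 0.0) + v
        py[j] = py.get(j, 0.0) + v

    mu_x = sum(i * v for i, v in px.items())
    mu_y = sum(j * v for j, v in py.items())
    sd_x = math.sqrt(sum((i - mu_x) ** 2 * v for i, v in px.items()))
    sd_y = math.sqrt(sum((j - mu_y) ** 2 * v for j, v in py.items()))

    p_sum: dict[int, float] = {}
    p_diff: dict[int, float] = {}
    for (i, j), v in p.items():
        p_sum[i + j] = p_sum.get(i + j, 0.0) + v
        p_diff[abs(i - j)] = p_diff.get(abs(i - j), 0.0) + v

    energy = sum(v ** 2 for v in p.values())
    contrast = sum((i - j) ** 2 * v for (i, j), v in p.items())
    autocorr = sum(i * j * v for (i, j), v in p.items())
    correlation = ((autocorr - mu_x * mu_y) / (sd_x * sd_y)
                   if sd_x > 0 and sd_y > 0 else 0.0)
    ssq = sum((i - mu_x) ** 2 * v for (i, _), v in p.items())
    homogeneity = sum(v / (1 + (i - j) ** 2) for (i, j), v in p.items())
    inv_diff = sum(v / (1 + abs(i - j)) for (i, j), v in p.items())
    K = 256
    idmn = sum(v / (1 + ((i - j) / K) ** 2) for (i, j), v in p.items())
    dissimilarity = sum(abs(i - j) * v for (i, j), v in p.items())
    max_prob = max(p.values())

    sum_avg = sum(k * v for k, v in p_sum.items())
    sum_var = sum((k - sum_avg) ** 2 * v for k, v in p_sum.items())
    sum_ent = -sum(v * math.log(v) for v in p_sum.values() if v > 0)
    mu_d = sum(k * v for k, v in p_diff.items())
    diff_var = sum((k - mu_d) ** 2 * v for k, v in p_diff.items())
    diff_ent = -sum(v * math.log(v) for v in p_diff.values() if v > 0)

    hxy = -sum(v * math.log(v) for v in p.values() if v > 0)
    hx = -sum(v * math.log(v) for v in px.values() if v > 0)
    hy = -sum(v * math.log(v) for v in py.values() if v > 0)
    hxy1 = -sum(v * math.log(px[i] * py[j]) for (i, j), v in p.items()
                if px[i] * py[j] > 0)
    hxy2 = -sum(a * b * math.log(a * b) for a in px.values()
                for b in py.values() if a * b > 0)
    denom = max(hx, hy)
    imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))

    shade = sum((i + j - mu_x - mu_y) ** 3 * v for (i, j), v in p.items())
    prominence = sum((i + j - mu_x - mu_y) ** 4 * v for (i, j), v in p.items())

    return {
        "energy": energy, "contrast": contrast, "correlation": correlation,
        "sum_of_squares_variance": ssq, "homogeneity": homogeneity,
        "sum_average": sum_avg, "sum_variance": sum_var,
        "sum_entropy": sum_ent, "entropy": hxy,
        "difference_variance": diff_var, "difference_entropy": diff_ent,
        "imc1": imc1, "imc2": imc2, "dissimilarity": dissimilarity,
        "autocorrelation": autocorr, "cluster_shade": shade,
        "cluster_prominence": prominence, "maximum_probability": max_prob,
        "inverse_difference": inv_diff,
        "inverse_difference_moment_normalized": idmn,
    }


def brute_glrlm_runs(image, theta: int, n_levels: int = 32
                     ) -> list[tuple[int, int]]:
    """All maximal (level, length) runs along direction ``theta``."""
    img = np.asarray(image).astype(int)
    q = img * n_levels // 256 if n_levels != 256 else img
    h, w = q.shape
    if theta == 0:
        lines = [list(q[r]) for r in range(h)]
    elif theta == 90:
        lines = [list(q[:, c]) for c in range(w)]
    elif theta == 45:
        lines = []
        for s in range(h + w - 1):
            # anti-diagonal r + c = s, walked up-right (row down to 0)
            line = [q[r, s - r] for r in range(h - 1, -1, -1)
                    if 0 <= s - r < w]
            lines.append(line)
    elif theta == 135:
        lines = []
        for s in range(-(h - 1), w):
            line = [q[r, r + s] for r in range(h) if 0 <= r + s < w]
            lines.append(line)
    else:
        raise ValueError(theta)
    runs: list[tuple[int, int]] = []
    for line in lines:
        if not line:
            continue
        cur = line[0]
        length = 1
        for v in line[1:]:
            if v == cur:
                length += 1
            else:
                runs.append((int(cur), length))
                cur, length = v, 1
        runs.append((int(cur), length))
    return runs


def brute_glrlm_stats(runs: list[tuple[int, int]], n_pixels: int
                      ) -> dict[str, float]:
    """Run-emphasis statistics straight from the run list (levels from 1)."""
    n = len(runs)
    gl = [lvl + 1 for lvl, _ in runs]
    rl = [length for _, length in runs]
    return {
        "sre": sum(1 / j ** 2 for j in rl) / n,
        "lre": sum(j ** 2 for j in rl) / n,
        "gln": sum(sum(1 for g in gl if g == lvl) ** 2
                   for lvl in set(gl)) / n,
        "rln": sum(sum(1 for j in rl if j == length) ** 2
                   for length in set(rl)) / n,
        "rp": n / n_pixels,
        "lgre": sum(1 / g ** 2 for g in gl) / n,
        "hgre": sum(g ** 2 for g in gl) / n,
        "srlge": sum(1 / (g ** 2 * j ** 2) for g, j in zip(gl, rl)) / n,
        "srhge": sum(g ** 2 / j ** 2 for g, j in zip(gl, rl)) / n,
        "lrlge": sum(j ** 2 / g ** 2 for g, j in zip(gl, rl)) / n,
        "lrhge": sum(g ** 2 * j ** 2 for g, j in zip(gl, rl)) / n,
    }


def brute_lof(X: np.ndarray, k: int) -> np.ndarray:
    """Classic LOF by direct O(n^2) definition with the inclusive tie rule."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    D = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            D[a, b] = math.dist(X[a], X[b])
    kdist = np.zeros(n)
    neighbors: list[list[int]] = []
    for a in range(n):
        ds = sorted((D[a, b], b) for b in range(n) if b != a)
        kdist[a] = ds[k - 1][0]
        neighbors.append([b for dist, b in ds if dist <= kdist[a]])
    lrd = np.zeros(n)
    for a in range(n):
        reach = [max(kdist[b], D[a, b]) for b in neighbors[a]]
        m = sum(reach) / len(reach)
        lrd[a] = 1.0 / m if m > 0 else 1e12
    lof = np.zeros(n)
    for a in range(n):
        lof[a] = sum(lrd[b] / lrd[a] for b in neighbors[a]) / len(neighbors[a])
    return lof


def brute_shapley(predict_fn, x: np.ndarray, background: np.ndarray
                  ) -> np.ndarray:
    """Exact Shapley values by averaging over all feature permutations."""
    d = len(x)
    phi = None
    count = 0
    for order in permutations(range(d)):
        mask = np.zeros(d, dtype=bool)
        prev = _mean_out(predict_fn, x, background, mask)
        contrib = np.zeros((d,) + prev.shape)
        for f in order:
            mask[f] = True
            cur = _mean_out(predict_fn, x, background, mask)
            contrib[f] = cur - prev
            prev = cur
        phi = contrib if phi is None else phi + contrib
        count += 1
    return phi / count


def _mean_out(predict_fn, x, background, mask):
    grid = np.array(background, dtype=float)
    grid[:, mask] = x[mask]
    out = np.asarray(predict_fn(grid), dtype=float)
    if out.ndim == 1:
        out = out[:, None]
    return out.mean(axis=0)
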