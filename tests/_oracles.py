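"""Brute-force oracles for the texture families.

Everything here is deliberately naive: plain Python loops over voxels,
neighbor pairs, runs, zones and dependencies, with feature formulas
written out longhand over matrix entries.  No code is shared with the
package's vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np

ANGLES_13 = [
    (dk, dr, dc)
    for dk in (-1, 0, 1)
    for dr in (-1, 0, 1)
    for dc in (-1, 0, 1)
    if (dk, dr, dc) > (0, 0, 0)
]
ANGLES_26 = ANGLES_13 + [(-a, -b, -c) for a, b, c in ANGLES_13]


def _inside(shape, k, r, c):
    return 0 <= k < shape[0] and 0 <= r < shape[1] and 0 <= c < shape[2]


def _log2(x):
    return math.log2(x)


# ---------------------------------------------------------------------------
# GLCM


def glcm_counts(lg, mask, angle, ng):
    m = [[0.0] * ng for _ in range(ng)]
    dk, dr, dc = angle
    for k in range(lg.shape[0]):
        for r in range(lg.shape[1]):
            for c in range(lg.shape[2]):
                if not mask[k, r, c]:
                    continue
                k2, r2, c2 = k + dk, r + dr, c + dc
                if _inside(lg.shape, k2, r2, c2) and mask[k2, r2, c2]:
                    i, j = lg[k, r, c] - 1, lg[k2, r2, c2] - 1
                    m[i][j] += 1
                    m[j][i] += 1
    return np.array(m)


def glcm_features_from_counts(counts):
    ng = counts.shape[0]
    total = float(counts.sum())
    p = [[counts[i][j] / total for j in range(ng)] for i in range(ng)]
    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i][j] for i in range(ng)) for j in range(ng)]
    mu_x = sum((i + 1) * px[i] for i in range(ng))
    mu_y = sum((j + 1) * py[j] for j in range(ng))
    sig_x = math.sqrt(sum(px[i] * (i + 1 - mu_x) ** 2 for i in range(ng)))
    sig_y = math.sqrt(sum(py[j] * (j + 1 - mu_y) ** 2 for j in range(ng)))
    p_diff = [0.0] * ng
    p_sum = [0.0] * (2 * ng - 1)
    for i in range(ng):
        for j in range(ng):
            p_diff[abs(i - j)] += p[i][j]
            p_sum[i + j] += p[i][j]
    da = sum(k * p_diff[k] for k in range(ng))
    hxy = -sum(v * _log2(v) for row in p for v in row if v > 0)
    hx = -sum(v * _log2(v) for v in px if v > 0)
    hy = -sum(v * _log2(v) for v in py if v > 0)
    hxy1 = -sum(
        p[i][j] * _log2(px[i] * py[j])
        for i in range(ng)
        for j in range(ng)
        if p[i][j] > 0 and px[i] * py[j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * _log2(px[i] * py[j])
        for i in range(ng)
        for j in range(ng)
        if px[i] * py[j] > 0
    )
    if sig_x > 0 and sig_y > 0:
        corr = (
            sum((i + 1) * (j + 1) * p[i][j] for i in range(ng) for j in range(ng))
            - mu_x * mu_y
        ) / (sig_x * sig_y)
    else:
        corr = 1.0
    mx = max(hx, hy)
    out = {
        "Autocorrelation": sum((i + 1) * (j + 1) * p[i][j] for i in range(ng) for j in range(ng)),
        "Joint Average": mu_x,
        "Cluster Prominence": sum(
            p[i][j] * (i + j + 2 - mu_x - mu_y) ** 4 for i in range(ng) for j in range(ng)
        ),
        "Cluster Shade": sum(
            p[i][j] * (i + j + 2 - mu_x - mu_y) ** 3 for i in range(ng) for j in range(ng)
        ),
        "Cluster Tendency": sum(
            p[i][j] * (i + j + 2 - mu_x - mu_y) ** 2 for i in range(ng) for j in range(ng)
        ),
        "Contrast": sum(p[i][j] * (i - j) ** 2 for i in range(ng) for j in range(ng)),
        "Correlation": corr,
        "Difference Average": da,
        "Difference Entropy": -sum(v * _log2(v) for v in p_diff if v > 0),
        "Difference Variance": sum(p_diff[k] * (k - da) ** 2 for k in range(ng)),
        "Joint Energy": sum(v * v for row in p for v in row),
        "Joint Entropy": hxy,
        "Informational Measure of Correlation 1": (hxy - hxy1) / mx if mx > 0 else 0.0,
        "Informational Measure of Correlation 2": math.sqrt(
            max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))
        ),
        "Inverse Difference Moment": sum(
            p[i][j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng)
        ),
        "Inverse Difference Moment Normalized": sum(
            p[i][j] / (1 + (i - j) ** 2 / ng**2) for i in range(ng) for j in range(ng)
        ),
        "Inverse Difference": sum(
            p[i][j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng)
        ),
        "Inverse Difference Normalized": sum(
            p[i][j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng)
        ),
        "Inverse Variance": sum(
            p[i][j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j
        ),
        "Maximum Probability": max(v for row in p for v in row),
        "Sum Entropy": -sum(v * _log2(v) for v in p_sum if v > 0),
        "Sum of Squares": sum(
            p[i][j] * (i + 1 - mu_x) ** 2 for i in range(ng) for j in range(ng)
        ),
    }
    return out


def glcm_features(lg, mask, ng):
    per_dir = []
    for angle in ANGLES_13:
        counts = glcm_counts(lg, mask, angle, ng)
        if counts.sum() > 0:
            per_dir.append(glcm_features_from_counts(counts))
    keys = per_dir[0].keys()
    return {k: sum(f[k] for f in per_dir) / len(per_dir) for k in keys}


# ---------------------------------------------------------------------------
# runs / zones / dependence enumerations


def run_list(lg, mask, angle):
    """All maximal (level, length) runs along one direction."""
    dk, dr, dc = angle
    runs = []
    for k in range(lg.shape[0]):
        for r in range(lg.shape[1]):
            for c in range(lg.shape[2]):
                if not mask[k, r, c]:
                    continue
                pk, pr, pc = k - dk, r - dr, c - dc
                if (
                    _inside(lg.shape, pk, pr, pc)
                    and mask[pk, pr, pc]
                    and lg[pk, pr, pc] == lg[k, r, c]
                ):
                    continue  # not a run start
                length = 1
                nk, nr, nc = k + dk, r + dr, c + dc
                while (
                    _inside(lg.shape, nk, nr, nc)
                    and mask[nk, nr, nc]
                    and lg[nk, nr, nc] == lg[k, r, c]
                ):
                    length += 1
                    nk, nr, nc = nk + dk, nr + dr, nc + dc
                runs.append((int(lg[k, r, c]), length))
    return runs


def zone_list(lg, mask):
    """(level, size) of every 26-connected equal-level component."""
    seen = np.zeros(lg.shape, dtype=bool)
    zones = []
    for k in range(lg.shape[0]):
        for r in range(lg.shape[1]):
            for c in range(lg.shape[2]):
                if not mask[k, r, c] or seen[k, r, c]:
                    continue
                level = lg[k, r, c]
                stack, size = [(k, r, c)], 0
                seen[k, r, c] = True
                while stack:
                    x = stack.pop()
                    size += 1
                    for dk, dr, dc in ANGLES_26:
                        y = (x[0] + dk, x[1] + dr, x[2] + dc)
                        if (
                            _inside(lg.shape, *y)
                            and mask[y]
                            and not seen[y]
                            and lg[y] == level
                        ):
                            seen[y] = True
                            stack.append(y)
                zones.append((int(level), size))
    return zones


def dependence_list(lg, mask, alpha=0):
    """(level, dependence count) per masked voxel."""
    out = []
    for k in range(lg.shape[0]):
        for r in range(lg.shape[1]):
            for c in range(lg.shape[2]):
                if not mask[k, r, c]:
                    continue
                dep = 0
                for dk, dr, dc in ANGLES_26:
                    y = (k + dk, r + dr, c + dc)
                    if _inside(lg.shape, *y) and mask[y] and abs(int(lg[y]) - int(lg[k, r, c])) <= alpha:
                        dep += 1
                out.append((int(lg[k, r, c]), dep))
    return out


def ngtdm_table(lg, mask, ng):
    """Rows 1..ng of (n_i, p_i, s_i); voxels without neighbors excluded."""
    n = [0.0] * ng
    s = [0.0] * ng
    total = 0
    for k in range(lg.shape[0]):
        for r in range(lg.shape[1]):
            for c in range(lg.shape[2]):
                if not mask[k, r, c]:
                    continue
                nb = [
                    int(lg[k + dk, r + dr, c + dc])
                    for dk, dr, dc in ANGLES_26
                    if _inside(lg.shape, k + dk, r + dr, c + dc) and mask[k + dk, r + dr, c + dc]
                ]
                if not nb:
                    continue
                lvl = int(lg[k, r, c])
                n[lvl - 1] += 1
                s[lvl - 1] += abs(lvl - sum(nb) / len(nb))
                total += 1
    p = [ni / total if total else 0.0 for ni in n]
    return n, p, s, total


# ---------------------------------------------------------------------------
# feature formulas over enumerations


def size_matrix_features(pairs, n_voxels, ng):
    """The 16 run-length/size-zone formulas from (level, size) pairs."""
    ns = len(pairs)
    smax = max(sz for _, sz in pairs)
    counts = [[0.0] * smax for _ in range(ng)]
    for lvl, sz in pairs:
        counts[lvl - 1][sz - 1] += 1
    row = [sum(counts[i]) for i in range(ng)]
    col = [sum(counts[i][j] for i in range(ng)) for j in range(smax)]
    mu_i = sum((i + 1) * row[i] for i in range(ng)) / ns
    mu_j = sum((j + 1) * col[j] for j in range(smax)) / ns
    ent = -sum(
        counts[i][j] / ns * _log2(counts[i][j] / ns)
        for i in range(ng)
        for j in range(smax)
        if counts[i][j] > 0
    )
    return {
        "small": sum(counts[i][j] / (j + 1) ** 2 for i in range(ng) for j in range(smax)) / ns,
        "large": sum(counts[i][j] * (j + 1) ** 2 for i in range(ng) for j in range(smax)) / ns,
        "gln": sum(v * v for v in row) / ns,
        "glnn": sum(v * v for v in row) / ns**2,
        "sn": sum(v * v for v in col) / ns,
        "snn": sum(v * v for v in col) / ns**2,
        "pct": ns / n_voxels,
        "glv": sum(row[i] / ns * (i + 1 - mu_i) ** 2 for i in range(ng)),
        "sv": sum(col[j] / ns * (j + 1 - mu_j) ** 2 for j in range(smax)),
        "entropy": ent,
        "lgl": sum(counts[i][j] / (i + 1) ** 2 for i in range(ng) for j in range(smax)) / ns,
        "hgl": sum(counts[i][j] * (i + 1) ** 2 for i in range(ng) for j in range(smax)) / ns,
        "small_lgl": sum(
            counts[i][j] / ((i + 1) ** 2 * (j + 1) ** 2) for i in range(ng) for j in range(smax)
        ) / ns,
        "small_hgl": sum(
            counts[i][j] * (i + 1) ** 2 / (j + 1) ** 2 for i in range(ng) for j in range(smax)
        ) / ns,
        "large_lgl": sum(
            counts[i][j] * (j + 1) ** 2 / (i + 1) ** 2 for i in range(ng) for j in range(smax)
        ) / ns,
        "large_hgl": sum(
            counts[i][j] * (i + 1) ** 2 * (j + 1) ** 2 for i in range(ng) for j in range(smax)
        ) / ns,
    }


def glrlm_features(lg, mask, ng, n_voxels):
    per_dir = [size_matrix_features(run_list(lg, mask, a), n_voxels, ng) for a in ANGLES_13]
    keys = per_dir[0].keys()
    return {k: sum(f[k] for f in per_dir) / len(per_dir) for k in keys}


def glszm_features(lg, mask, ng, n_voxels):
    return size_matrix_features(zone_list(lg, mask), n_voxels, ng)


def gldm_features(lg, mask, ng, alpha=0):
    deps = dependence_list(lg, mask, alpha)
    pairs = [(lvl, dep + 1) for lvl, dep in deps]  # column = dependence + 1
    nz = len(pairs)
    dmax = max(d for _, d in pairs)
    counts = [[0.0] * dmax for _ in range(ng)]
    for lvl, d in pairs:
        counts[lvl - 1][d - 1] += 1
    row = [sum(counts[i]) for i in range(ng)]
    col = [sum(counts[i][j] for i in range(ng)) for j in range(dmax)]
    mu_i = sum((i + 1) * row[i] for i in range(ng)) / nz
    mu_j = sum((j + 1) * col[j] for j in range(dmax)) / nz
    ent = -sum(
        counts[i][j] / nz * _log2(counts[i][j] / nz)
        for i in range(ng)
        for j in range(dmax)
        if counts[i][j] > 0
    )
    return {
        "Small Dependence Emphasis": sum(
            counts[i][j] / (j + 1) ** 2 for i in range(ng) for j in range(dmax)
        ) / nz,
        "Large Dependence Emphasis": sum(
            counts[i][j] * (j + 1) ** 2 for i in range(ng) for j in range(dmax)
        ) / nz,
        "Gray Level Non-Uniformity": sum(v * v for v in row) / nz,
        "Dependence Non-Uniformity": sum(v * v for v in col) / nz,
        "Dependence Non-Uniformity Normalized": sum(v * v for v in col) / nz**2,
        "Gray Level Variance": sum(row[i] / nz * (i + 1 - mu_i) ** 2 for i in range(ng)),
        "Dependence Variance": sum(col[j] / nz * (j + 1 - mu_j) ** 2 for j in range(dmax)),
        "Dependence Entropy": ent,
        "Low Gray Level Emphasis": sum(
            counts[i][j] / (i + 1) ** 2 for i in range(ng) for j in range(dmax)
        ) / nz,
        "High Gray Level Emphasis": sum(
            counts[i][j] * (i + 1) ** 2 for i in range(ng) for j in range(dmax)
        ) / nz,
        "Small Dependence Low Gray Level Emphasis": sum(
            counts[i][j] / ((i + 1) ** 2 * (j + 1) ** 2) for i in range(ng) for j in range(dmax)
        ) / nz,
        "Small Dependence High Gray Level Emphasis": sum(
            counts[i][j] * (i + 1) ** 2 / (j + 1) ** 2 for i in range(ng) for j in range(dmax)
        ) / nz,
        "Large Dependence Low Gray Level Emphasis": sum(
            counts[i][j] * (j + 1) ** 2 / (i + 1) ** 2 for i in range(ng) for j in range(dmax)
        ) / nz,
        "Large Dependence High Gray Level Emphasis": sum(
            counts[i][j] * (i + 1) ** 2 * (j + 1) ** 2 for i in range(ng) for j in range(dmax)
        ) / nz,
    }


def ngtdm_features(lg, mask, ng):
    EPS = 1e-6
    n, p, s, nvp = ngtdm_table(lg, mask, ng)
    act = [i for i in range(ng) if p[i] > 0]
    ngp = len(act)
    ps = sum(p[i] * s[i] for i in range(ng))
    coarseness = min(1.0 / max(ps, EPS), 1.0 / EPS)
    if ngp > 1:
        contrast = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in act for j in act)
            / (ngp * (ngp - 1))
            * (sum(s) / nvp)
        )
        busy_den = sum(abs((i + 1) * p[i] - (j + 1) * p[j]) for i in act for j in act)
        busyness = ps / busy_den if busy_den > EPS else 0.0
    else:
        contrast, busyness = 0.0, 0.0
    complexity = sum(
        abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j]) for i in act for j in act
    ) / nvp
    st = sum(s)
    strength = (
        sum((p[i] + p[j]) * (i - j) ** 2 for i in act for j in act) / st if st > EPS else 0.0
    )
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


def random_region(rng, max_side=5, max_levels=4):
    """A random level grid + mask for oracle-equivalence checks."""
    shape = tuple(int(rng.integers(2, max_side + 1)) for _ in range(3))
    mask = rng.random(shape) > 0.2
    mask[0, 0, 0] = mask[0, 0, 1] = True  # guarantee at least one neighbor pair
    lg = np.zeros(shape, dtype=np.int64)
    lg[mask] = rng.integers(1, max_levels + 1, size=int(mask.sum()))
    # renumber so levels are 1..ng with no gaps above the max used level
    ng = int(lg.max())
    return lg, mask, ng
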