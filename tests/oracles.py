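"""Independent brute-force oracles for texture features and ReliefF.

Everything here is written with explicit Python loops over voxel pairs,
runs, zones, and instances — deliberately unvectorized and independent of
the implementation under test. Only usable on tiny inputs.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def _in(shape, p):
    return all(0 <= c < n for c, n in zip(p, shape))


def _log2(v):
    return math.log(v, 2)


# ------------------------------------------------------------------ GLCM

def glcm_matrix(levels, mask, offset, ng):
    shape = levels.shape
    counts = [[0.0] * ng for _ in range(ng)]
    total = 0.0
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                q = (x + offset[0], y + offset[1], z + offset[2])
                if _in(shape, q) and mask[q]:
                    i, j = levels[x, y, z] - 1, levels[q] - 1
                    counts[i][j] += 1
                    counts[j][i] += 1
                    total += 2
    if total == 0:
        return None
    return [[c / total for c in row] for row in counts]


def glcm_features(p):
    ng = len(p)
    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    mu = sum((i + 1) * p[i][j] for i in range(ng) for j in range(ng))
    var = sum((i + 1 - mu) ** 2 * p[i][j] for i in range(ng) for j in range(ng))
    pdiff = [0.0] * ng
    psum = [0.0] * (2 * ng + 1)
    for i in range(ng):
        for j in range(ng):
            pdiff[abs(i - j)] += p[i][j]
            psum[i + j + 2] += p[i][j]
    da = sum(k * pdiff[k] for k in range(ng))
    sa = sum(k * psum[k] for k in range(2 * ng + 1))
    hxy = -sum(v * _log2(v) for row in p for v in row if v > 0)
    hx = -sum(v * _log2(v) for v in px if v > 0)
    hxy1 = -sum(
        p[i][j] * _log2(px[i] * px[j])
        for i in range(ng) for j in range(ng)
        if p[i][j] > 0 and px[i] * px[j] > 0
    )
    hxy2 = -sum(
        px[i] * px[j] * _log2(px[i] * px[j])
        for i in range(ng) for j in range(ng)
        if px[i] * px[j] > 0
    )
    corr = 1.0
    if var > 0:
        corr = sum(
            (i + 1 - mu) * (j + 1 - mu) * p[i][j]
            for i in range(ng) for j in range(ng)
        ) / var
    out = {
        "joint_maximum": max(max(row) for row in p),
        "joint_average": mu,
        "joint_variance": var,
        "joint_entropy": hxy,
        "difference_average": da,
        "difference_variance": sum(
            (k - da) ** 2 * pdiff[k] for k in range(ng)
        ),
        "difference_entropy": -sum(v * _log2(v) for v in pdiff if v > 0),
        "sum_average": sa,
        "sum_variance": sum(
            (k - sa) ** 2 * psum[k] for k in range(2 * ng + 1)
        ),
        "sum_entropy": -sum(v * _log2(v) for v in psum if v > 0),
        "angular_second_moment": sum(v**2 for row in p for v in row),
        "contrast": sum(
            (i - j) ** 2 * p[i][j] for i in range(ng) for j in range(ng)
        ),
        "dissimilarity": sum(
            abs(i - j) * p[i][j] for i in range(ng) for j in range(ng)
        ),
        "inverse_difference": sum(
            p[i][j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng)
        ),
        "inverse_difference_normalized": sum(
            p[i][j] / (1 + abs(i - j) / ng)
            for i in range(ng) for j in range(ng)
        ),
        "inverse_difference_moment": sum(
            p[i][j] / (1 + (i - j) ** 2)
            for i in range(ng) for j in range(ng)
        ),
        "inverse_difference_moment_normalized": sum(
            p[i][j] / (1 + (i - j) ** 2 / ng**2)
            for i in range(ng) for j in range(ng)
        ),
        "inverse_variance": sum(
            p[i][j] / (i - j) ** 2
            for i in range(ng) for j in range(ng) if i != j
        ),
        "correlation": corr,
        "autocorrelation": sum(
            (i + 1) * (j + 1) * p[i][j] for i in range(ng) for j in range(ng)
        ),
        "cluster_tendency": sum(
            (i + j + 2 - 2 * mu) ** 2 * p[i][j]
            for i in range(ng) for j in range(ng)
        ),
        "cluster_shade": sum(
            (i + j + 2 - 2 * mu) ** 3 * p[i][j]
            for i in range(ng) for j in range(ng)
        ),
        "cluster_prominence": sum(
            (i + j + 2 - 2 * mu) ** 4 * p[i][j]
            for i in range(ng) for j in range(ng)
        ),
        "information_correlation_1": 0.0 if hx == 0 else (hxy - hxy1) / hx,
        "information_correlation_2": math.sqrt(
            max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))
        ),
    }
    return out


# ----------------------------------------------------------------- GLRLM

def glrlm_runs(levels, mask, offset):
    """All (level, length) runs along one direction."""
    shape = levels.shape
    runs = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                prev = (x - offset[0], y - offset[1], z - offset[2])
                if (
                    _in(shape, prev)
                    and mask[prev]
                    and levels[prev] == levels[x, y, z]
                ):
                    continue  # not a run start
                length = 1
                cur = (x, y, z)
                while True:
                    nxt = tuple(c + o for c, o in zip(cur, offset))
                    if (
                        _in(shape, nxt)
                        and mask[nxt]
                        and levels[nxt] == levels[x, y, z]
                    ):
                        length += 1
                        cur = nxt
                    else:
                        break
                runs.append((int(levels[x, y, z]), length))
    return runs


def rl_matrix_from_pairs(pairs, ng, max2):
    m = [[0.0] * max2 for _ in range(ng)]
    for g, l in pairs:
        m[g - 1][l - 1] += 1
    return m


def run_zone_features(m, n_voxels, names):
    """Loop-based gray-level x second-axis matrix features.

    ``names`` is the 16-tuple of output names in the canonical order
    (small/short emphasis first, entropy last).
    """
    ng = len(m)
    nl = len(m[0])
    ns = sum(sum(row) for row in m)
    p = [[v / ns for v in row] for row in m]
    pg = [sum(p[g]) for g in range(ng)]
    pl = [sum(p[g][l] for g in range(ng)) for l in range(nl)]
    mu_g = sum((g + 1) * pg[g] for g in range(ng))
    mu_l = sum((l + 1) * pl[l] for l in range(nl))
    vals = [
        sum(pl[l] / (l + 1) ** 2 for l in range(nl)),
        sum(pl[l] * (l + 1) ** 2 for l in range(nl)),
        sum(pg[g] / (g + 1) ** 2 for g in range(ng)),
        sum(pg[g] * (g + 1) ** 2 for g in range(ng)),
        sum(
            p[g][l] / ((g + 1) ** 2 * (l + 1) ** 2)
            for g in range(ng) for l in range(nl)
        ),
        sum(
            p[g][l] * (g + 1) ** 2 / (l + 1) ** 2
            for g in range(ng) for l in range(nl)
        ),
        sum(
            p[g][l] * (l + 1) ** 2 / (g + 1) ** 2
            for g in range(ng) for l in range(nl)
        ),
        sum(
            p[g][l] * (g + 1) ** 2 * (l + 1) ** 2
            for g in range(ng) for l in range(nl)
        ),
        sum(sum(m[g]) ** 2 for g in range(ng)) / ns,
        sum(pg[g] ** 2 for g in range(ng)),
        sum(sum(m[g][l] for g in range(ng)) ** 2 for l in range(nl)) / ns,
        sum(pl[l] ** 2 for l in range(nl)),
        ns / n_voxels,
        sum((g + 1 - mu_g) ** 2 * pg[g] for g in range(ng)),
        sum((l + 1 - mu_l) ** 2 * pl[l] for l in range(nl)),
        -sum(v * _log2(v) for row in p for v in row if v > 0),
    ]
    return dict(zip(names, vals))


# ----------------------------------------------------------------- zones

_NEIGH26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def zones_26(levels, mask):
    """(level, size, min taxicab border distance) per 26-connected zone."""
    shape = levels.shape
    dist = border_distance(mask)
    seen = np.zeros(shape, bool)
    out = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z] or seen[x, y, z]:
                    continue
                g = levels[x, y, z]
                q = deque([(x, y, z)])
                seen[x, y, z] = True
                members = []
                while q:
                    cur = q.popleft()
                    members.append(cur)
                    for d in _NEIGH26:
                        nb = tuple(c + o for c, o in zip(cur, d))
                        if (
                            _in(shape, nb)
                            and mask[nb]
                            and not seen[nb]
                            and levels[nb] == g
                        ):
                            seen[nb] = True
                            q.append(nb)
                out.append(
                    (int(g), len(members), min(int(dist[m]) for m in members))
                )
    return out


def border_distance(mask):
    """Taxicab distance to the nearest voxel outside the mask; the region
    beyond the image edge counts as outside."""
    shape = mask.shape
    dist = np.where(mask, 10**9, 0).astype(np.int64)
    changed = True
    while changed:
        changed = False
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    if not mask[x, y, z]:
                        continue
                    best = dist[x, y, z]
                    for d in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                              (0, 0, 1), (0, 0, -1)]:
                        nb = (x + d[0], y + d[1], z + d[2])
                        cand = dist[nb] + 1 if _in(shape, nb) else 1
                        if cand < best:
                            best = cand
                    if best < dist[x, y, z]:
                        dist[x, y, z] = best
                        changed = True
    return dist


# ----------------------------------------------------------------- NGTDM

def ngtdm_table(levels, mask, ng):
    shape = levels.shape
    n = [0.0] * ng
    s = [0.0] * ng
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                nb_vals = []
                for d in _NEIGH26:
                    nb = (x + d[0], y + d[1], z + d[2])
                    if _in(shape, nb) and mask[nb]:
                        nb_vals.append(levels[nb])
                if not nb_vals:
                    continue
                g = int(levels[x, y, z])
                n[g - 1] += 1
                s[g - 1] += abs(g - sum(nb_vals) / len(nb_vals))
    return n, s


def ngtdm_features(levels, mask, ng):
    n, s = ngtdm_table(levels, mask, ng)
    nvc = sum(n)
    p = [v / nvc for v in n]
    present = [g for g in range(ng) if p[g] > 0]
    ngp = len(present)
    denom = sum(p[g] * s[g] for g in present)
    coarseness = 1.0 / denom if denom > 0 else 1e6
    if ngp > 1:
        contrast = (
            sum(
                p[i] * p[j] * (i - j) ** 2
                for i in present for j in present if i != j
            )
            / (ngp * (ngp - 1))
            * sum(s)
            / nvc
        )
        busy_den = sum(
            abs((i + 1) * p[i] - (j + 1) * p[j])
            for i in present for j in present if i != j
        )
        busyness = denom / busy_den if busy_den > 0 else 0.0
        complexity = sum(
            abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
            for i in present for j in present if i != j
        ) / nvc
        stot = sum(s)
        strength = (
            sum(
                (p[i] + p[j]) * (i - j) ** 2
                for i in present for j in present if i != j
            )
            / stot
            if stot > 0
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }


# ------------------------------------------------------------------ GLDM

def gldm_matrix(levels, mask, ng):
    shape = levels.shape
    rows = {}
    max_k = 0
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                k = 1
                for d in _NEIGH26:
                    nb = (x + d[0], y + d[1], z + d[2])
                    if (
                        _in(shape, nb)
                        and mask[nb]
                        and levels[nb] == levels[x, y, z]
                    ):
                        k += 1
                rows.setdefault((int(levels[x, y, z]), k), 0)
                rows[(int(levels[x, y, z]), k)] += 1
                max_k = max(max_k, k)
    m = [[0.0] * max_k for _ in range(ng)]
    for (g, k), c in rows.items():
        m[g - 1][k - 1] = c
    return m


def gldm_features(levels, mask, ng):
    m = gldm_matrix(levels, mask, ng)
    ns = sum(sum(row) for row in m)
    nk = len(m[0])
    p = [[v / ns for v in row] for row in m]
    pk = [sum(p[g][k] for g in range(ng)) for k in range(nk)]
    mu_k = sum((k + 1) * pk[k] for k in range(nk))
    return {
        "small_dependence_emphasis": sum(
            pk[k] / (k + 1) ** 2 for k in range(nk)
        ),
        "large_dependence_emphasis": sum(
            pk[k] * (k + 1) ** 2 for k in range(nk)
        ),
        "dependence_non_uniformity": sum(
            sum(m[g][k] for g in range(ng)) ** 2 for k in range(nk)
        )
        / ns,
        "dependence_variance": sum(
            (k + 1 - mu_k) ** 2 * pk[k] for k in range(nk)
        ),
        "dependence_entropy": -sum(
            v * _log2(v) for row in p for v in row if v > 0
        ),
    }


# --------------------------------------------------------------- ReliefF

def relieff(x, y, k):
    """Exhaustive full-pass multi-class ReliefF with Kononenko priors."""
    x = np.asarray(x, float)
    n, nf = x.shape
    lo = x.min(axis=0)
    rng = x.max(axis=0) - lo
    rng[rng == 0] = 1.0
    xs = (x - lo) / rng
    classes = sorted(set(y))
    priors = {c: sum(1 for v in y if v == c) / n for c in classes}
    w = [0.0] * nf
    for i in range(n):
        dists = [
            sum(abs(xs[i][f] - xs[j][f]) for f in range(nf)) for j in range(n)
        ]
        same = [j for j in range(n) if j != i and y[j] == y[i]]
        same.sort(key=lambda j: dists[j])
        k_hit = min(k, len(same))
        for j in same[:k_hit]:
            for f in range(nf):
                w[f] -= abs(xs[i][f] - xs[j][f]) / (n * k_hit)
        for c in classes:
            if c == y[i]:
                continue
            other = [j for j in range(n) if y[j] == c]
            other.sort(key=lambda j: dists[j])
            k_miss = min(k, len(other))
            if k_miss == 0:
                continue
            wc = priors[c] / (1.0 - priors[y[i]])
            for j in other[:k_miss]:
                for f in range(nf):
                    w[f] += wc * abs(xs[i][f] - xs[j][f]) / (n * k_miss)
    return np.asarray(w)


# --------------------------------------------------------- Lin's CCC

def lin_ccc(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    vx = sum((v - mx) ** 2 for v in x) / n
    vy = sum((v - my) ** 2 for v in y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    return 2 * cov / (vx + vy + (mx - my) ** 2)
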