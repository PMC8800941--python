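"""Higher-order texture features on the quantized grid.

All families follow the IBSI matrix definitions. Co-occurrence and
run-length matrices are built per offset over the 13 unique 3D directions
at distance 1, features are computed per direction and then averaged;
zone, distance-zone, neighbourhood tone-difference, and dependence
features are direction-free. Out-of-mask voxels never contribute.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .preprocess import QuantizedImage

#: The 13 unique direction offsets of a 3D 26-neighbourhood (one per
#: antiparallel pair).
DIRECTIONS_13 = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p, dtype=float)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def _entropy_bits(p: np.ndarray) -> float:
    return float(-_xlog2(p).sum())


def _shifted_pairs(levels: np.ndarray, mask: np.ndarray, offset):
    """Level pairs (a, b) for voxels a and a+offset, both in-mask."""
    sl_a, sl_b = [], []
    for o, n in zip(offset, levels.shape):
        if o >= 0:
            sl_a.append(slice(0, n - o))
            sl_b.append(slice(o, n))
        else:
            sl_a.append(slice(-o, n))
            sl_b.append(slice(0, n + o))
    sl_a, sl_b = tuple(sl_a), tuple(sl_b)
    valid = mask[sl_a] & mask[sl_b]
    return levels[sl_a][valid], levels[sl_b][valid]


# ---------------------------------------------------------------- GLCM

def glcm_matrix(q: QuantizedImage, offset) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix for one offset."""
    a, b = _shifted_pairs(q.levels, q.mask, offset)
    if a.size == 0:
        raise ValueError(f"no voxel pairs along offset {offset}")
    ng = q.n_levels
    counts = np.zeros((ng, ng), dtype=np.float64)
    np.add.at(counts, (a - 1, b - 1), 1.0)
    counts += counts.T  # symmetric: count both orders
    return counts / counts.sum()


def glcm_features_single(p: np.ndarray) -> dict[str, float]:
    """The 25 GLCM features of one normalized symmetric matrix."""
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # marginal (symmetric: px == py)
    mu = float((ii * p).sum())
    var = float(((ii - mu) ** 2 * p).sum())

    absdiff = np.abs(ii - jj)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, absdiff.ravel(), p.ravel())
    k_diff = np.arange(ng)
    da = float((k_diff * p_diff).sum())

    s = ii + jj
    p_sum = np.zeros(2 * ng + 1)
    np.add.at(p_sum, s.ravel(), p.ravel())
    k_sum = np.arange(2 * ng + 1)
    sa = float((k_sum * p_sum).sum())

    hxy = _entropy_bits(p)
    hx = _entropy_bits(px)
    outer = np.outer(px, px)
    pos = outer > 0
    hxy1 = float(-(p[pos] * np.log2(outer[pos])).sum())
    hxy2 = float(-_xlog2(outer).sum())

    corr = 1.0
    if var > 0:
        corr = float(((ii - mu) * (jj - mu) * p).sum() / var)
    ic1 = 0.0 if hx == 0 else (hxy - hxy1) / hx
    ic2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    offdiag = absdiff > 0
    inv_var = float((p[offdiag] / absdiff[offdiag] ** 2).sum())

    dev = s - 2.0 * mu
    return {
        "joint_maximum": float(p.max()),
        "joint_average": mu,
        "joint_variance": var,
        "joint_entropy": hxy,
        "difference_average": da,
        "difference_variance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "difference_entropy": _entropy_bits(p_diff),
        "sum_average": sa,
        "sum_variance": float(((k_sum - sa) ** 2 * p_sum).sum()),
        "sum_entropy": _entropy_bits(p_sum),
        "angular_second_moment": float((p**2).sum()),
        "contrast": float((absdiff**2 * p).sum()),
        "dissimilarity": float((absdiff * p).sum()),
        "inverse_difference": float((p / (1.0 + absdiff)).sum()),
        "inverse_difference_normalized": float((p / (1.0 + absdiff / ng)).sum()),
        "inverse_difference_moment": float((p / (1.0 + absdiff**2)).sum()),
        "inverse_difference_moment_normalized": float(
            (p / (1.0 + absdiff**2 / ng**2)).sum()
        ),
        "inverse_variance": inv_var,
        "correlation": corr,
        "autocorrelation": float((ii * jj * p).sum()),
        "cluster_tendency": float((dev**2 * p).sum()),
        "cluster_shade": float((dev**3 * p).sum()),
        "cluster_prominence": float((dev**4 * p).sum()),
        "information_correlation_1": ic1,
        "information_correlation_2": ic2,
    }


def glcm_features(q: QuantizedImage) -> dict[str, float]:
    """25 GLCM features averaged over the 13 directions."""
    if int(q.mask.sum()) < 2:
        raise ValueError("GLCM undefined for a single-voxel mask")
    acc: dict[str, float] = {}
    n_dir = 0
    for off in DIRECTIONS_13:
        try:
            feats = glcm_features_single(glcm_matrix(q, off))
        except ValueError:
            continue  # no pairs along this direction
        n_dir += 1
        for k, v in feats.items():
            acc[k] = acc.get(k, 0.0) + v
    if n_dir == 0:
        raise ValueError("no co-occurring voxel pairs in any direction")
    return {f"glcm_{k}": v / n_dir for k, v in acc.items()}


# --------------------------------------------------------------- GLRLM

def glrlm_matrix(q: QuantizedImage, offset) -> np.ndarray:
    """Run-length matrix R[level, run_length] for one direction."""
    coords = np.argwhere(q.mask)
    lv = q.levels[q.mask]
    shape = q.levels.shape
    # steps from the line's entry point into the grid
    t = np.full(coords.shape[0], np.iinfo(np.int64).max, dtype=np.int64)
    for ax, o in enumerate(offset):
        if o > 0:
            t = np.minimum(t, coords[:, ax])
        elif o < 0:
            t = np.minimum(t, shape[ax] - 1 - coords[:, ax])
    origin = coords - t[:, None] * np.asarray(offset)
    key = (origin[:, 0] * shape[1] + origin[:, 1]) * shape[2] + origin[:, 2]
    order = np.lexsort((t, key))
    key, t, lv = key[order], t[order], lv[order]
    # a new run starts at a new line, a gap in t, or a level change
    new_run = np.ones(lv.size, dtype=bool)
    if lv.size > 1:
        same = (
            (key[1:] == key[:-1]) & (t[1:] == t[:-1] + 1) & (lv[1:] == lv[:-1])
        )
        new_run[1:] = ~same
    run_id = np.cumsum(new_run) - 1
    run_len = np.bincount(run_id)
    run_lv = lv[new_run]
    rl = np.zeros((q.n_levels, int(run_len.max())), dtype=np.float64)
    np.add.at(rl, (run_lv - 1, run_len - 1), 1.0)
    return rl


def _run_zone_features(mat: np.ndarray, n_voxels: int, axis_name: str) -> dict[str, float]:
    """Shared gray-level x (length | size | distance) matrix features.

    ``axis_name`` selects the naming of the second-axis features.
    """
    ns = mat.sum()
    if ns == 0:
        raise ValueError("empty matrix")
    p = mat / ns
    g = np.arange(1, mat.shape[0] + 1, dtype=float)
    l = np.arange(1, mat.shape[1] + 1, dtype=float)
    pg = p.sum(axis=1)
    pl = p.sum(axis=0)
    gg, ll = np.meshgrid(g, l, indexing="ij")
    mu_g = float((g * pg).sum())
    mu_l = float((l * pl).sum())
    names = {
        "length": (
            "short_run_emphasis", "long_run_emphasis",
            "low_gray_level_run_emphasis", "high_gray_level_run_emphasis",
            "short_run_low_gray_level_emphasis", "short_run_high_gray_level_emphasis",
            "long_run_low_gray_level_emphasis", "long_run_high_gray_level_emphasis",
            "gray_level_non_uniformity", "gray_level_non_uniformity_normalized",
            "run_length_non_uniformity", "run_length_non_uniformity_normalized",
            "run_percentage", "gray_level_variance", "run_length_variance",
            "run_entropy",
        ),
        "size": (
            "small_zone_emphasis", "large_zone_emphasis",
            "low_gray_level_zone_emphasis", "high_gray_level_zone_emphasis",
            "small_zone_low_gray_level_emphasis", "small_zone_high_gray_level_emphasis",
            "large_zone_low_gray_level_emphasis", "large_zone_high_gray_level_emphasis",
            "gray_level_non_uniformity", "gray_level_non_uniformity_normalized",
            "zone_size_non_uniformity", "zone_size_non_uniformity_normalized",
            "zone_percentage", "gray_level_variance", "zone_size_variance",
            "zone_size_entropy",
        ),
        "distance": (
            "small_distance_emphasis", "large_distance_emphasis",
            "low_gray_level_zone_emphasis", "high_gray_level_zone_emphasis",
            "small_distance_low_gray_level_emphasis",
            "small_distance_high_gray_level_emphasis",
            "large_distance_low_gray_level_emphasis",
            "large_distance_high_gray_level_emphasis",
            "gray_level_non_uniformity", "gray_level_non_uniformity_normalized",
            "zone_distance_non_uniformity", "zone_distance_non_uniformity_normalized",
            "zone_percentage", "gray_level_variance", "zone_distance_variance",
            "zone_distance_entropy",
        ),
    }[axis_name]
    vals = (
        float((pl / l**2).sum()),
        float((pl * l**2).sum()),
        float((pg / g**2).sum()),
        float((pg * g**2).sum()),
        float((p / (gg**2 * ll**2)).sum()),
        float((p * gg**2 / ll**2).sum()),
        float((p * ll**2 / gg**2).sum()),
        float((p * gg**2 * ll**2).sum()),
        float((mat.sum(axis=1) ** 2).sum() / ns),
        float((pg**2).sum()),
        float((mat.sum(axis=0) ** 2).sum() / ns),
        float((pl**2).sum()),
        float(ns / n_voxels),
        float(((g - mu_g) ** 2 * pg).sum()),
        float(((l - mu_l) ** 2 * pl).sum()),
        _entropy_bits(p),
    )
    return dict(zip(names, vals))


def glrlm_features(q: QuantizedImage) -> dict[str, float]:
    """16 run-length features averaged over the 13 directions."""
    n_vox = int(q.mask.sum())
    acc: dict[str, float] = {}
    for off in DIRECTIONS_13:
        feats = _run_zone_features(glrlm_matrix(q, off), n_vox, "length")
        for k, v in feats.items():
            acc[k] = acc.get(k, 0.0) + v
    return {f"glrlm_{k}": v / len(DIRECTIONS_13) for k, v in acc.items()}


# --------------------------------------------------------------- zones

def _zones(q: QuantizedImage):
    """(level, size, min border distance) of each 26-connected zone.

    Border distance is the taxicab distance to the nearest voxel outside the
    ROI; the region outside the image counts as outside the ROI.
    """
    dist_map = ndimage.distance_transform_cdt(
        np.pad(q.mask, 1), metric="taxicab"
    )[1:-1, 1:-1, 1:-1]
    zones = []
    for g in np.unique(q.levels[q.mask]):
        lab, n = ndimage.label(q.levels == g, structure=_STRUCT_26)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        mind = ndimage.minimum(dist_map, labels=lab, index=np.arange(1, n + 1))
        mind = np.atleast_1d(mind)
        for s, d in zip(sizes, mind):
            zones.append((int(g), int(s), int(d)))
    return zones


def glszm_matrix(q: QuantizedImage) -> np.ndarray:
    zones = _zones(q)
    max_s = max(z[1] for z in zones)
    m = np.zeros((q.n_levels, max_s), dtype=np.float64)
    for g, s, _ in zones:
        m[g - 1, s - 1] += 1.0
    return m


def gldzm_matrix(q: QuantizedImage) -> np.ndarray:
    zones = _zones(q)
    max_d = max(z[2] for z in zones)
    m = np.zeros((q.n_levels, max_d), dtype=np.float64)
    for g, _, d in zones:
        m[g - 1, d - 1] += 1.0
    return m


def glszm_features(q: QuantizedImage) -> dict[str, float]:
    feats = _run_zone_features(glszm_matrix(q), int(q.mask.sum()), "size")
    return {f"glszm_{k}": v for k, v in feats.items()}


def gldzm_features(q: QuantizedImage) -> dict[str, float]:
    feats = _run_zone_features(gldzm_matrix(q), int(q.mask.sum()), "distance")
    return {f"gldzm_{k}": v for k, v in feats.items()}


# --------------------------------------------------------------- NGTDM

def _neighbor_sums(levels: np.ndarray, mask: np.ndarray):
    """Sum and count of in-mask 26-neighbour levels at every voxel."""
    total = np.zeros(levels.shape, dtype=np.float64)
    count = np.zeros(levels.shape, dtype=np.float64)
    vals = np.where(mask, levels, 0).astype(np.float64)
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                a, b = _shift_slices(levels.shape, (dx, dy, dz))
                total[a] += vals[b]
                count[a] += mask[b]
    return total, count


def _shift_slices(shape, offset):
    sl_a, sl_b = [], []
    for o, n in zip(offset, shape):
        if o >= 0:
            sl_a.append(slice(0, n - o))
            sl_b.append(slice(o, n))
        else:
            sl_a.append(slice(-o, n))
            sl_b.append(slice(0, n + o))
    return tuple(sl_a), tuple(sl_b)


def ngtdm_table(q: QuantizedImage):
    """Per-level occupancy n_g, probability p_g and tone-difference sum s_g."""
    total, count = _neighbor_sums(q.levels, q.mask)
    valid = q.mask & (count > 0)
    lv = q.levels[valid]
    diff = np.abs(lv - total[valid] / count[valid])
    ng = q.n_levels
    n_g = np.bincount(lv - 1, minlength=ng).astype(float)
    s_g = np.bincount(lv - 1, weights=diff, minlength=ng)
    nvc = n_g.sum()
    if nvc == 0:
        raise ValueError("no voxel has an in-mask neighbour")
    return n_g, n_g / nvc, s_g


def ngtdm_features(q: QuantizedImage) -> dict[str, float]:
    n_g, p, s = ngtdm_table(q)
    nvc = n_g.sum()
    g = np.arange(1, q.n_levels + 1, dtype=float)
    present = p > 0
    n_gp = int(present.sum())
    gp, pp, sp = g[present], p[present], s[present]

    denom = float((pp * sp).sum())
    coarseness = 1.0 / denom if denom > 0 else 1e6

    if n_gp > 1:
        gi, gj = np.meshgrid(gp, gp, indexing="ij")
        pi, pj = np.meshgrid(pp, pp, indexing="ij")
        si, sj = np.meshgrid(sp, sp, indexing="ij")
        off = ~np.eye(n_gp, dtype=bool)
        contrast = (
            float((pi * pj * (gi - gj) ** 2)[off].sum())
            / (n_gp * (n_gp - 1))
            * float(sp.sum())
            / nvc
        )
        busy_den = float(np.abs(gi * pi - gj * pj)[off].sum())
        busyness = denom / busy_den if busy_den > 0 else 0.0
        complexity = float(
            (np.abs(gi - gj) * (pi * si + pj * sj) / (pi + pj))[off].sum()
        ) / nvc
        s_tot = float(sp.sum())
        strength = (
            float(((pi + pj) * (gi - gj) ** 2)[off].sum()) / s_tot
            if s_tot > 0
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "ngtdm_coarseness": coarseness,
        "ngtdm_contrast": contrast,
        "ngtdm_busyness": busyness,
        "ngtdm_complexity": complexity,
        "ngtdm_strength": strength,
    }


# ---------------------------------------------------------------- GLDM

def gldm_matrix(q: QuantizedImage) -> np.ndarray:
    """Dependence matrix D[level, k]: k = 1 + number of 26-neighbours in
    the mask with the same quantized level."""
    dep = np.zeros(q.levels.shape, dtype=np.int64)
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                a, b = _shift_slices(q.levels.shape, (dx, dy, dz))
                dep[a] += (
                    q.mask[a] & q.mask[b] & (q.levels[a] == q.levels[b])
                )
    k = dep[q.mask] + 1
    lv = q.levels[q.mask]
    m = np.zeros((q.n_levels, int(k.max())), dtype=np.float64)
    np.add.at(m, (lv - 1, k - 1), 1.0)
    return m


def gldm_features(q: QuantizedImage) -> dict[str, float]:
    m = gldm_matrix(q)
    ns = m.sum()
    p = m / ns
    k = np.arange(1, m.shape[1] + 1, dtype=float)
    pk = p.sum(axis=0)
    mu_k = float((k * pk).sum())
    return {
        "gldm_small_dependence_emphasis": float((pk / k**2).sum()),
        "gldm_large_dependence_emphasis": float((pk * k**2).sum()),
        "gldm_dependence_non_uniformity": float((m.sum(axis=0) ** 2).sum() / ns),
        "gldm_dependence_variance": float(((k - mu_k) ** 2 * pk).sum()),
        "gldm_dependence_entropy": _entropy_bits(p),
    }
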