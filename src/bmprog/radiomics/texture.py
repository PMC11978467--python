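"""Gray-level texture matrices and their derived features.

Gray levels are discretized with a fixed bin COUNT over the ROI intensity
range (level indices 1..n_bins). Pairwise matrices (GLCM, GLRLM) are built for
the 13 unique 3D directions at distance 1 and their feature values averaged
over directions; GLSZM/GLDM/NGTDM use the full 26-connected neighborhood.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

EPS = np.spacing(1.0)

GLCM_FEATURES = (
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MCC",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
)

GLRLM_FEATURES = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "GrayLevelVariance",
    "RunVariance",
    "RunEntropy",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)

GLSZM_FEATURES = (
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)

GLDM_FEATURES = (
    "SmallDependenceEmphasis",
    "LargeDependenceEmphasis",
    "GrayLevelNonUniformity",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "GrayLevelVariance",
    "DependenceVariance",
    "DependenceEntropy",
    "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

NGTDM_FEATURES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

# 13 unique direction offsets at infinity-norm distance 1 (half of the 26)
ANGLES = [
    np.array(off)
    for off in (
        (0, 0, 1),
        (0, 1, -1),
        (0, 1, 0),
        (0, 1, 1),
        (1, -1, -1),
        (1, -1, 0),
        (1, -1, 1),
        (1, 0, -1),
        (1, 0, 0),
        (1, 0, 1),
        (1, 1, -1),
        (1, 1, 0),
        (1, 1, 1),
    )
]


def discretize(values: np.ndarray, bin_count: int = 64) -> np.ndarray:
    """Map ROI intensities to integer gray levels 1..bin_count (fixed count)."""
    values = np.asarray(values, dtype=float)
    vmin, vmax = values.min(), values.max()
    if vmax == vmin:
        return np.ones(values.shape, dtype=np.int64)
    edges = np.linspace(vmin, vmax, bin_count + 1)
    return (np.digitize(values, edges[1:-1], right=False) + 1).astype(np.int64)


def gray_level_volume(
    image: np.ndarray, mask: np.ndarray, bin_count: int = 64
) -> np.ndarray:
    """Full-size integer volume: gray level inside the mask, 0 outside."""
    gl = np.zeros(mask.shape, dtype=np.int64)
    gl[mask] = discretize(image[mask], bin_count)
    return gl


def _shifted_pairs(gl: np.ndarray, offset: np.ndarray):
    """Gray-level pairs (a, b) for voxels separated by `offset`, both in-mask."""
    sl_a, sl_b = [], []
    for d, n in zip(offset, gl.shape):
        if d == 0:
            sl_a.append(slice(None))
            sl_b.append(slice(None))
        elif d > 0:
            sl_a.append(slice(0, n - d))
            sl_b.append(slice(d, n))
        else:
            sl_a.append(slice(-d, n))
            sl_b.append(slice(0, n + d))
    a = gl[tuple(sl_a)].ravel()
    b = gl[tuple(sl_b)].ravel()
    valid = (a > 0) & (b > 0)
    return a[valid], b[valid]


# ---------------------------------------------------------------------- GLCM


def _glcm_single(a: np.ndarray, b: np.ndarray, ng: int) -> np.ndarray:
    p = np.zeros((ng, ng))
    np.add.at(p, (a - 1, b - 1), 1.0)
    p = p + p.T  # symmetric co-occurrence
    total = p.sum()
    return p / total if total > 0 else p


def _glcm_features_one(p: np.ndarray, ng: int) -> dict[str, float]:
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu_x = float((i * px).sum())
    sig_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))

    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.zeros(len(k_sum))
    np.add.at(p_sum, (ii + jj).ravel() - 2, p.ravel())
    k_diff = np.arange(0, ng)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).ravel(), p.ravel())

    hx = float(-np.sum(px * np.log2(px + EPS)))
    hxy = float(-np.sum(p * np.log2(p + EPS)))
    pxpy = np.outer(px, px)
    hxy1 = float(-np.sum(p * np.log2(pxpy + EPS)))
    hxy2 = float(-np.sum(pxpy * np.log2(pxpy + EPS)))

    diff_avg = float((k_diff * p_diff).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    autocorr = float((ii * jj * p).sum())
    if sig_x > 0:
        correlation = (autocorr - mu_x * mu_x) / (sig_x * sig_x)
    else:
        correlation = 1.0

    # MCC: sqrt of second-largest eigenvalue of Q
    nz = px > 0
    if nz.sum() > 1:
        psub = p[np.ix_(nz, nz)]
        pxs = px[nz]
        q = (psub @ (psub / pxs[None, :]).T) / pxs[:, None]
        eig = np.sort(np.real(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(np.clip(eig[-2], 0.0, 1.0)))
    else:
        mcc = 1.0

    off_diag = ii != jj
    inv_var = float((p[off_diag] / (ii - jj)[off_diag] ** 2).sum()) if ng > 1 else 0.0

    if hx > 0:
        imc1 = (hxy - hxy1) / hx
    else:
        imc1 = 0.0
    imc2 = float(np.sqrt(np.clip(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0, None)))

    return {
        "Autocorrelation": autocorr,
        "ClusterProminence": float(((ii + jj - 2 * mu_x) ** 4 * p).sum()),
        "ClusterShade": float(((ii + jj - 2 * mu_x) ** 3 * p).sum()),
        "ClusterTendency": float(((ii + jj - 2 * mu_x) ** 2 * p).sum()),
        "Contrast": contrast,
        "Correlation": float(correlation),
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": float(-np.sum(p_diff * np.log2(p_diff + EPS))),
        "DifferenceVariance": float(((k_diff - diff_avg) ** 2 * p_diff).sum()),
        "Id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((p / (1.0 + ((ii - jj) / ng) ** 2)).sum()),
        "Idn": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointAverage": mu_x,
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": float(-np.sum(p_sum * np.log2(p_sum + EPS))),
        "SumSquares": float(((ii - mu_x) ** 2 * p).sum()),
    }


def glcm_features(gl: np.ndarray) -> dict[str, float]:
    ng = int(gl.max())
    per_angle = []
    for off in ANGLES:
        a, b = _shifted_pairs(gl, off)
        if len(a) == 0:
            continue
        per_angle.append(_glcm_features_one(_glcm_single(a, b, ng), ng))
    if not per_angle:  # single isolated voxel
        per_angle = [_glcm_features_one(np.ones((1, 1)), 1)]
    return {k: float(np.mean([f[k] for f in per_angle])) for k in GLCM_FEATURES}


# --------------------------------------------------------------------- GLRLM


def _runs_for_angle(gl: np.ndarray, offset: np.ndarray):
    """(gray level, run length) of every maximal run along one direction."""
    coords = np.argwhere(gl > 0)
    levels = gl[gl > 0]
    axis = int(np.flatnonzero(offset)[0])
    t = coords[:, axis] * int(offset[axis])  # increments by 1 per step
    key = coords - t[:, None] * offset[None, :]
    order = np.lexsort((t, key[:, 2], key[:, 1], key[:, 0]))
    key, t, levels = key[order], t[order], levels[order]
    same_line = np.all(key[1:] == key[:-1], axis=1) & (np.diff(t) == 1)
    new_run = ~(same_line & (levels[1:] == levels[:-1]))
    starts = np.flatnonzero(np.concatenate(([True], new_run)))
    lengths = np.diff(np.concatenate((starts, [len(levels)])))
    return levels[starts], lengths


def _rlm_style_features(
    p: np.ndarray, n_voxels: int, prefix: dict[str, str]
) -> dict[str, float]:
    """Shared formulas for run-length / size-zone style matrices.

    ``p[i-1, j-1]`` counts runs (zones) of gray level i and length (size) j.
    """
    ns = p.sum()
    i = np.arange(1, p.shape[0] + 1, dtype=float)
    j = np.arange(1, p.shape[1] + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    pg = p.sum(axis=1)  # per gray level
    pr = p.sum(axis=0)  # per length/size
    pn = p / ns
    mu_i = float((ii * pn).sum())
    mu_j = float((jj * pn).sum())
    return {
        prefix["small"]: float((p / jj**2).sum() / ns),
        prefix["large"]: float((p * jj**2).sum() / ns),
        "GrayLevelNonUniformity": float((pg**2).sum() / ns),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum() / ns**2),
        prefix["nonuniformity"]: float((pr**2).sum() / ns),
        prefix["nonuniformity_norm"]: float((pr**2).sum() / ns**2),
        prefix["percentage"]: float(ns / n_voxels),
        "GrayLevelVariance": float(((ii - mu_i) ** 2 * pn).sum()),
        prefix["variance"]: float(((jj - mu_j) ** 2 * pn).sum()),
        prefix["entropy"]: float(-np.sum(pn * np.log2(pn + EPS))),
        prefix["low"]: float((p / ii**2).sum() / ns),
        prefix["high"]: float((p * ii**2).sum() / ns),
        prefix["small_low"]: float((p / (ii**2 * jj**2)).sum() / ns),
        prefix["small_high"]: float((p * ii**2 / jj**2).sum() / ns),
        prefix["large_low"]: float((p * jj**2 / ii**2).sum() / ns),
        prefix["large_high"]: float((p * ii**2 * jj**2).sum() / ns),
    }


_GLRLM_PREFIX = {
    "small": "ShortRunEmphasis",
    "large": "LongRunEmphasis",
    "nonuniformity": "RunLengthNonUniformity",
    "nonuniformity_norm": "RunLengthNonUniformityNormalized",
    "percentage": "RunPercentage",
    "variance": "RunVariance",
    "entropy": "RunEntropy",
    "low": "LowGrayLevelRunEmphasis",
    "high": "HighGrayLevelRunEmphasis",
    "small_low": "ShortRunLowGrayLevelEmphasis",
    "small_high": "ShortRunHighGrayLevelEmphasis",
    "large_low": "LongRunLowGrayLevelEmphasis",
    "large_high": "LongRunHighGrayLevelEmphasis",
}

_GLSZM_PREFIX = {
    "small": "SmallAreaEmphasis",
    "large": "LargeAreaEmphasis",
    "nonuniformity": "SizeZoneNonUniformity",
    "nonuniformity_norm": "SizeZoneNonUniformityNormalized",
    "percentage": "ZonePercentage",
    "variance": "ZoneVariance",
    "entropy": "ZoneEntropy",
    "low": "LowGrayLevelZoneEmphasis",
    "high": "HighGrayLevelZoneEmphasis",
    "small_low": "SmallAreaLowGrayLevelEmphasis",
    "small_high": "SmallAreaHighGrayLevelEmphasis",
    "large_low": "LargeAreaLowGrayLevelEmphasis",
    "large_high": "LargeAreaHighGrayLevelEmphasis",
}


def glrlm_features(gl: np.ndarray) -> dict[str, float]:
    ng = int(gl.max())
    n_voxels = int((gl > 0).sum())
    per_angle = []
    for off in ANGLES:
        levels, lengths = _runs_for_angle(gl, off)
        p = np.zeros((ng, int(lengths.max())))
        np.add.at(p, (levels - 1, lengths - 1), 1.0)
        per_angle.append(_rlm_style_features(p, n_voxels, _GLRLM_PREFIX))
    return {k: float(np.mean([f[k] for f in per_angle])) for k in GLRLM_FEATURES}


# --------------------------------------------------------------------- GLSZM


def glszm_features(gl: np.ndarray) -> dict[str, float]:
    ng = int(gl.max())
    n_voxels = int((gl > 0).sum())
    structure = np.ones((3, 3, 3), dtype=int)
    zones: list[tuple[int, int]] = []
    for level in np.unique(gl[gl > 0]):
        labeled, n_zones = ndimage.label(gl == level, structure=structure)
        if n_zones == 0:
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        zones.extend((int(level), int(s)) for s in sizes)
    max_size = max(s for _, s in zones)
    p = np.zeros((ng, max_size))
    for level, size in zones:
        p[level - 1, size - 1] += 1.0
    return {k: v for k, v in _rlm_style_features(p, n_voxels, _GLSZM_PREFIX).items()}


# ---------------------------------------------------------------------- GLDM


def _neighbor_stats(gl: np.ndarray):
    """Per in-mask voxel: neighbor count, neighbor gray sum, same-level count."""
    mask = gl > 0
    count = np.zeros(gl.shape, dtype=np.int64)
    gray_sum = np.zeros(gl.shape, dtype=np.float64)
    same = np.zeros(gl.shape, dtype=np.int64)
    offsets = [a for a in ANGLES] + [-a for a in ANGLES]
    for off in offsets:
        sl_a, sl_b = [], []
        for d, n in zip(off, gl.shape):
            if d == 0:
                sl_a.append(slice(None))
                sl_b.append(slice(None))
            elif d > 0:
                sl_a.append(slice(0, n - d))
                sl_b.append(slice(d, n))
            else:
                sl_a.append(slice(-d, n))
                sl_b.append(slice(0, n + d))
        sl_a, sl_b = tuple(sl_a), tuple(sl_b)
        nb_mask = mask[sl_b]
        count[sl_a] += nb_mask
        gray_sum[sl_a] += gl[sl_b] * nb_mask
        same[sl_a] += nb_mask & (gl[sl_a] == gl[sl_b])
    return count[mask], gray_sum[mask], same[mask]


def gldm_features(gl: np.ndarray, alpha: float = 0.0) -> dict[str, float]:
    mask = gl > 0
    levels = gl[mask]
    _, _, same = _neighbor_stats(gl)
    dependence = same + 1  # the center voxel depends on itself
    ng = int(levels.max())
    nd = int(dependence.max())
    p = np.zeros((ng, nd))
    np.add.at(p, (levels - 1, dependence - 1), 1.0)

    nz = p.sum()  # equals the voxel count: one entry per voxel
    i = np.arange(1, ng + 1, dtype=float)
    j = np.arange(1, nd + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    pg = p.sum(axis=1)
    pd_ = p.sum(axis=0)
    pn = p / nz
    mu_i = float((ii * pn).sum())
    mu_j = float((jj * pn).sum())
    return {
        "SmallDependenceEmphasis": float((p / jj**2).sum() / nz),
        "LargeDependenceEmphasis": float((p * jj**2).sum() / nz),
        "GrayLevelNonUniformity": float((pg**2).sum() / nz),
        "DependenceNonUniformity": float((pd_**2).sum() / nz),
        "DependenceNonUniformityNormalized": float((pd_**2).sum() / nz**2),
        "GrayLevelVariance": float(((ii - mu_i) ** 2 * pn).sum()),
        "DependenceVariance": float(((jj - mu_j) ** 2 * pn).sum()),
        "DependenceEntropy": float(-np.sum(pn * np.log2(pn + EPS))),
        "LowGrayLevelEmphasis": float((p / ii**2).sum() / nz),
        "HighGrayLevelEmphasis": float((p * ii**2).sum() / nz),
        "SmallDependenceLowGrayLevelEmphasis": float((p / (ii**2 * jj**2)).sum() / nz),
        "SmallDependenceHighGrayLevelEmphasis": float((p * ii**2 / jj**2).sum() / nz),
        "LargeDependenceLowGrayLevelEmphasis": float((p * jj**2 / ii**2).sum() / nz),
        "LargeDependenceHighGrayLevelEmphasis": float((p * ii**2 * jj**2).sum() / nz),
    }


# --------------------------------------------------------------------- NGTDM


def ngtdm_features(gl: np.ndarray) -> dict[str, float]:
    mask = gl > 0
    levels = gl[mask].astype(float)
    count, gray_sum, _ = _neighbor_stats(gl)
    has_nb = count > 0
    diff = np.zeros(levels.shape)
    diff[has_nb] = np.abs(levels[has_nb] - gray_sum[has_nb] / count[has_nb])

    n_vox = levels.size
    ng = int(levels.max())
    n_i = np.bincount(gl[mask], minlength=ng + 1)[1:].astype(float)
    s_i = np.zeros(ng)
    np.add.at(s_i, gl[mask] - 1, diff)
    p_i = n_i / n_vox
    present = p_i > 0
    ngp = int(present.sum())
    i = np.arange(1, ng + 1, dtype=float)

    coarse_den = float((p_i * s_i).sum())
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6

    if ngp > 1:
        ip, pp, sp = i[present], p_i[present], s_i[present]
        pij = np.subtract.outer(ip, ip) ** 2
        contrast = (
            float((np.outer(pp, pp) * pij).sum()) / (ngp * (ngp - 1))
        ) * (s_i.sum() / n_vox)
        busy_den = float(np.abs(np.subtract.outer(ip * pp, ip * pp)).sum())
        busyness = coarse_den / busy_den if busy_den > 0 else 0.0
        num = np.abs(np.subtract.outer(ip, ip)) * (
            np.add.outer(pp * sp, pp * sp) / np.add.outer(pp, pp)
        )
        complexity = float(num.sum()) / n_vox
        strength_num = float((np.add.outer(pp, pp) * pij).sum())
        strength = strength_num / s_i.sum() if s_i.sum() > 0 else 0.0
    else:
        contrast, busyness, complexity, strength = 0.0, 0.0, 0.0, 0.0

    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }
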