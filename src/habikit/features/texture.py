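"""The 73 gray-level texture features: GLCM 22, GLRLM 16, GLSZM 16, GLDM 14, NGTDM 5.

All matrices are built from a discretized integer volume (levels 1..Ng
inside the region, 0 outside) with unit voxel distance and a 26-connected
3-D neighbourhood.  GLCM and GLRLM use the 13 unique direction pairs and
average each feature over directions (no distance weighting); GLSZM zones
use 26-connectivity; GLDM uses dependence threshold alpha = 0 (equal
levels), with the dependence size counting the center voxel; NGTDM uses the
mean level of the in-region 26-neighbours.

Degenerate regions (a single gray level) return defined values: matrix
concentrations give e.g. GLCM contrast 0, correlation 1, a single GLSZM
zone, NGTDM contrast 0.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

EPS = np.finfo(float).eps

# 13 unique 3-D direction pairs (first non-zero component positive)
DIRECTIONS_13 = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1),
    (1, 0, 1), (1, 0, -1),
    (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

# GLCM 22-set: the modern 24-feature list minus SumAverage (redundant with
# JointAverage for symmetric matrices) and MCC; config-visible in FeatureConfig.
GLCM_NAMES = [
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumEntropy", "SumSquares",
]
GLRLM_NAMES = [
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
]
GLSZM_NAMES = [
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
]
GLDM_NAMES = [
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
]
NGTDM_NAMES = ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"]

TEXTURE_FAMILIES = {
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "gldm": GLDM_NAMES,
    "ngtdm": NGTDM_NAMES,
}


def _pair_slices(offset):
    """Slices (sa, sb) so that arr[sa] and arr[sb] are offset-separated pairs."""
    sa, sb = [], []
    for d in offset:
        if d == 0:
            sa.append(slice(None)); sb.append(slice(None))
        elif d > 0:
            sa.append(slice(None, -d)); sb.append(slice(d, None))
        else:
            sa.append(slice(-d, None)); sb.append(slice(None, d))
    return tuple(sa), tuple(sb)


# ---------------------------------------------------------------------------
# GLCM

def glcm_matrix(vol: np.ndarray, offset, n_levels: int) -> np.ndarray:
    """Symmetric co-occurrence counts for one direction (unnormalized)."""
    sa, sb = _pair_slices(offset)
    a, b = vol[sa].ravel(), vol[sb].ravel()
    valid = (a > 0) & (b > 0)
    a, b = a[valid] - 1, b[valid] - 1
    counts = np.bincount(a * n_levels + b, minlength=n_levels * n_levels)
    mat = counts.reshape(n_levels, n_levels).astype(float)
    return mat + mat.T


def _glcm_features(P: np.ndarray) -> dict[str, float]:
    Ng = P.shape[0]
    total = P.sum()
    if total == 0:
        return {name: 0.0 for name in GLCM_NAMES}
    p = P / total
    i = np.arange(1, Ng + 1)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    ux = float((i * px).sum())
    uy = float((i * py).sum())
    sx = np.sqrt(((i - ux) ** 2 * px).sum())
    sy = np.sqrt(((i - uy) ** 2 * py).sum())

    k_diff = np.arange(Ng)
    p_diff = np.array([p[np.abs(I - J) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * Ng + 1)
    p_sum = np.array([p[I + J == k].sum() for k in k_sum])

    da = float((k_diff * p_diff).sum())
    nz_d = p_diff > 0
    nz_s = p_sum > 0
    nz = p > 0

    hxy = float(-(p[nz] * np.log2(p[nz])).sum())
    hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())
    hy = float(-(py[py > 0] * np.log2(py[py > 0])).sum())
    pxpy = np.outer(px, py)
    m = nz & (pxpy > 0)
    hxy1 = float(-(p[m] * np.log2(pxpy[m])).sum())
    m2 = pxpy > 0
    hxy2 = float(-(pxpy[m2] * np.log2(pxpy[m2])).sum())

    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    corr = (
        float(((I * J * p).sum() - ux * uy) / (sx * sy)) if sx > 0 and sy > 0 else 1.0
    )
    off_diag = I != J
    inv_var = float((p[off_diag] / (I - J)[off_diag] ** 2).sum()) if off_diag.any() else 0.0

    return {
        "Autocorrelation": float((I * J * p).sum()),
        "JointAverage": ux,
        "ClusterProminence": float((((I + J - ux - uy) ** 4) * p).sum()),
        "ClusterShade": float((((I + J - ux - uy) ** 3) * p).sum()),
        "ClusterTendency": float((((I + J - ux - uy) ** 2) * p).sum()),
        "Contrast": float((((I - J) ** 2) * p).sum()),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-(p_diff[nz_d] * np.log2(p_diff[nz_d])).sum()),
        "DifferenceVariance": float((((k_diff - da) ** 2) * p_diff).sum()),
        "JointEnergy": float((p ** 2).sum()),
        "JointEntropy": hxy,
        "Imc1": imc1,
        "Imc2": imc2,
        "Idm": float((p / (1.0 + (I - J) ** 2)).sum()),
        "Idmn": float((p / (1.0 + ((I - J) / Ng) ** 2)).sum()),
        "Id": float((p / (1.0 + np.abs(I - J))).sum()),
        "Idn": float((p / (1.0 + np.abs(I - J) / Ng)).sum()),
        "InverseVariance": inv_var,
        "MaximumProbability": float(p.max()),
        "SumEntropy": float(-(p_sum[nz_s] * np.log2(p_sum[nz_s])).sum()),
        "SumSquares": float((((I - ux) ** 2) * p).sum()),
    }


def glcm_features(vol: np.ndarray, n_levels: int) -> dict[str, float]:
    """22 GLCM features averaged over the 13 unique 3-D directions."""
    per_dir = []
    for off in DIRECTIONS_13:
        M = glcm_matrix(vol, off, n_levels)
        if M.sum() > 0:
            per_dir.append(_glcm_features(M))
    if not per_dir:  # isolated voxels only
        return {name: 0.0 for name in GLCM_NAMES}
    return {name: float(np.mean([f[name] for f in per_dir])) for name in GLCM_NAMES}


# ---------------------------------------------------------------------------
# GLRLM

def glrlm_matrix(vol: np.ndarray, offset, n_levels: int) -> np.ndarray:
    """Run-length counts R[level, run_length] for one direction."""
    coords = np.column_stack(np.nonzero(vol))
    if coords.size == 0:
        return np.zeros((n_levels, 1))
    levels = vol[tuple(coords.T)]
    d = np.asarray(offset)
    m = int(d @ d)  # scaled-position increment per step along the direction
    t = coords @ d
    line = m * coords - t[:, None] * d[None, :]  # constant per line
    order = np.lexsort((t, line[:, 2], line[:, 1], line[:, 0]))
    t_s, lv_s, ln_s = t[order], levels[order], line[order]
    same_line = np.all(ln_s[1:] == ln_s[:-1], axis=1)
    contiguous = t_s[1:] == t_s[:-1] + m
    same_run = same_line & contiguous & (lv_s[1:] == lv_s[:-1])
    # run boundaries
    breaks = np.flatnonzero(~same_run)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(t_s) - 1]])
    run_len = ends - starts + 1
    run_lvl = lv_s[starts]
    max_len = int(run_len.max())
    R = np.zeros((n_levels, max_len))
    np.add.at(R, (run_lvl - 1, run_len - 1), 1.0)
    return R


def _rlm_style_features(M: np.ndarray, n_voxels: int, names) -> dict[str, float]:
    """Shared formula family for GLRLM (runs) / GLSZM (zones) style matrices."""
    Ng, Ns = M.shape
    Nr = M.sum()
    if Nr == 0:
        return {name: 0.0 for name in names}
    i = np.arange(1, Ng + 1)[:, None].astype(float)
    s = np.arange(1, Ns + 1)[None, :].astype(float)
    p = M / Nr
    mu_i = (p * i).sum()
    mu_s = (p * s).sum()
    g_marg = M.sum(axis=1)
    s_marg = M.sum(axis=0)
    nz = p > 0
    out = {}
    out[names[0]] = float((M / s ** 2).sum() / Nr)            # SRE / SAE
    out[names[1]] = float((M * s ** 2).sum() / Nr)            # LRE / LAE
    out[names[2]] = float((g_marg ** 2).sum() / Nr)           # GLN
    out[names[3]] = float((g_marg ** 2).sum() / Nr ** 2)      # GLNN
    out[names[4]] = float((s_marg ** 2).sum() / Nr)           # RLN / SZN
    out[names[5]] = float((s_marg ** 2).sum() / Nr ** 2)      # RLNN / SZNN
    out[names[6]] = float(Nr / n_voxels)                      # RP / ZP
    out[names[7]] = float((p * (i - mu_i) ** 2).sum())        # GLV
    out[names[8]] = float((p * (s - mu_s) ** 2).sum())        # RV / ZV
    out[names[9]] = float(-(p[nz] * np.log2(p[nz])).sum())    # entropy
    out[names[10]] = float((M / i ** 2).sum() / Nr)           # LGL
    out[names[11]] = float((M * i ** 2).sum() / Nr)           # HGL
    out[names[12]] = float((M / (i ** 2 * s ** 2)).sum() / Nr)
    out[names[13]] = float((M * i ** 2 / s ** 2).sum() / Nr)
    out[names[14]] = float((M * s ** 2 / i ** 2).sum() / Nr)
    out[names[15]] = float((M * i ** 2 * s ** 2).sum() / Nr)
    return out


def glrlm_features(vol: np.ndarray, n_levels: int) -> dict[str, float]:
    """16 GLRLM features averaged over the 13 unique 3-D directions."""
    n_voxels = int((vol > 0).sum())
    per_dir = []
    for off in DIRECTIONS_13:
        R = glrlm_matrix(vol, off, n_levels)
        per_dir.append(_rlm_style_features(R, n_voxels, GLRLM_NAMES))
    return {name: float(np.mean([f[name] for f in per_dir])) for name in GLRLM_NAMES}


# ---------------------------------------------------------------------------
# GLSZM

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(vol: np.ndarray, n_levels: int) -> np.ndarray:
    """Zone counts Z[level, zone_size] with 26-connected zones."""
    zones: list[tuple[int, int]] = []
    for lvl in range(1, n_levels + 1):
        lab, n_zone = ndimage.label(vol == lvl, structure=_STRUCT_26)
        if n_zone == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        zones.extend((lvl, int(sz)) for sz in sizes)
    if not zones:
        return np.zeros((n_levels, 1))
    max_size = max(sz for _, sz in zones)
    Z = np.zeros((n_levels, max_size))
    for lvl, sz in zones:
        Z[lvl - 1, sz - 1] += 1.0
    return Z


def glszm_features(vol: np.ndarray, n_levels: int) -> dict[str, float]:
    n_voxels = int((vol > 0).sum())
    Z = glszm_matrix(vol, n_levels)
    return _rlm_style_features(Z, n_voxels, GLSZM_NAMES)


# ---------------------------------------------------------------------------
# GLDM / NGTDM shared neighbour machinery

def _neighbor_stats(vol: np.ndarray):
    """Per in-region voxel: count of equal-level 26-neighbours, neighbour sum
    and neighbour count (in-region only)."""
    region = vol > 0
    eq = np.zeros(vol.shape, dtype=np.int32)
    nsum = np.zeros(vol.shape, dtype=np.float64)
    ncnt = np.zeros(vol.shape, dtype=np.int32)
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    for off in offsets:
        sa, sb = _pair_slices(off)
        nb_in = region[sb]
        eq[sa] += (nb_in & (vol[sa] == vol[sb])).astype(np.int32)
        nsum[sa] += np.where(nb_in, vol[sb], 0)
        ncnt[sa] += nb_in.astype(np.int32)
    return region, eq, nsum, ncnt


def gldm_matrix(vol: np.ndarray, n_levels: int) -> np.ndarray:
    """Dependence counts D[level, dependence]; dependence counts the center
    voxel plus its equal-level in-region 26-neighbours (alpha = 0)."""
    region, eq, _, _ = _neighbor_stats(vol)
    dep = eq[region] + 1  # include center -> 1..27
    lvl = vol[region]
    D = np.zeros((n_levels, 27))
    np.add.at(D, (lvl - 1, dep - 1), 1.0)
    return D[:, : int(dep.max())]


def gldm_features(vol: np.ndarray, n_levels: int) -> dict[str, float]:
    D = gldm_matrix(vol, n_levels)
    Ng, Nd = D.shape
    Nz = D.sum()
    i = np.arange(1, Ng + 1)[:, None].astype(float)
    j = np.arange(1, Nd + 1)[None, :].astype(float)
    p = D / Nz
    mu_i = (p * i).sum()
    mu_j = (p * j).sum()
    nz = p > 0
    return {
        "SmallDependenceEmphasis": float((D / j ** 2).sum() / Nz),
        "LargeDependenceEmphasis": float((D * j ** 2).sum() / Nz),
        "GrayLevelNonUniformity": float((D.sum(axis=1) ** 2).sum() / Nz),
        "DependenceNonUniformity": float((D.sum(axis=0) ** 2).sum() / Nz),
        "DependenceNonUniformityNormalized": float((D.sum(axis=0) ** 2).sum() / Nz ** 2),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "DependenceVariance": float((p * (j - mu_j) ** 2).sum()),
        "DependenceEntropy": float(-(p[nz] * np.log2(p[nz])).sum()),
        "LowGrayLevelEmphasis": float((D / i ** 2).sum() / Nz),
        "HighGrayLevelEmphasis": float((D * i ** 2).sum() / Nz),
        "SmallDependenceLowGrayLevelEmphasis": float((D / (i ** 2 * j ** 2)).sum() / Nz),
        "SmallDependenceHighGrayLevelEmphasis": float((D * i ** 2 / j ** 2).sum() / Nz),
        "LargeDependenceLowGrayLevelEmphasis": float((D * j ** 2 / i ** 2).sum() / Nz),
        "LargeDependenceHighGrayLevelEmphasis": float((D * i ** 2 * j ** 2).sum() / Nz),
    }


def ngtdm_features(vol: np.ndarray, n_levels: int) -> dict[str, float]:
    """The 5 neighbourhood gray-tone difference features."""
    region, _, nsum, ncnt = _neighbor_stats(vol)
    valid = region & (ncnt > 0)
    lvl = vol[valid].astype(float)
    avg = nsum[valid] / ncnt[valid]
    Nvp = lvl.size
    if Nvp == 0:
        return {name: 0.0 for name in NGTDM_NAMES}
    n_i = np.bincount(vol[valid] - 1, minlength=n_levels).astype(float)
    s_i = np.zeros(n_levels)
    np.add.at(s_i, vol[valid] - 1, np.abs(lvl - avg))
    p_i = n_i / Nvp
    present = p_i > 0
    Ngp = int(present.sum())
    i = np.arange(1, n_levels + 1, dtype=float)

    coarse_den = float((p_i * s_i).sum())
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6

    if Ngp > 1:
        ii, jj = np.meshgrid(i[present], i[present], indexing="ij")
        pp_i, pp_j = np.meshgrid(p_i[present], p_i[present], indexing="ij")
        ss_i, ss_j = np.meshgrid(s_i[present], s_i[present], indexing="ij")
        contrast = float(
            (pp_i * pp_j * (ii - jj) ** 2).sum() / (Ngp * (Ngp - 1)) * s_i.sum() / Nvp
        )
        busy_den = float(np.abs(ii * pp_i - jj * pp_j).sum())
        busyness = coarse_den / busy_den if busy_den > 0 else 0.0
        complexity = float(
            (np.abs(ii - jj) * (pp_i * ss_i + pp_j * ss_j) / (pp_i + pp_j)).sum() / Nvp
        )
        s_total = float(s_i.sum())
        strength = (
            float(((pp_i + pp_j) * (ii - jj) ** 2).sum()) / s_total if s_total > 0 else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Coarseness": float(coarseness),
        "Contrast": contrast,
        "Busyness": float(busyness),
        "Complexity": complexity,
        "Strength": float(strength),
    }


def texture(vol: np.ndarray, n_levels: int, families=None) -> dict[str, dict[str, float]]:
    """Compute the texture families for a discretized region volume.

    ``vol``: integer volume, 0 outside the region, 1..n_levels inside.
    Returns ``{family: {feature: value}}`` for the requested families
    (default: all five, 73 features).
    """
    vol = np.asarray(vol)
    if (vol > 0).sum() == 0:
        raise ValueError("empty region")
    if families is None:
        families = list(TEXTURE_FAMILIES)
    dispatch = {
        "glcm": glcm_features,
        "glrlm": glrlm_features,
        "glszm": glszm_features,
        "gldm": gldm_features,
        "ngtdm": ngtdm_features,
    }
    return {fam: dispatch[fam](vol, n_levels) for fam in families}
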