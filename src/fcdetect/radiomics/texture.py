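"""3D texture-matrix feature families on discretized ROIs.

Matrix conventions:

* GLCM - symmetric co-occurrence over the 13 unique distance-1 offsets of
  the 26-neighborhood; the 24 features are computed per offset and averaged.
* GLRLM - run lengths along the same 13 directions, features averaged.
* GLSZM - 26-connected iso-level zones, one matrix.
* NGTDM - per-level sums of |level - mean of valid 26-neighbors|.
* GLDM - dependence = 1 + number of 26-neighbors with an identical level
  (alpha = 0); one matrix.

Degenerate ROIs (single voxel, single gray level) follow the limiting
conventions: undefined ratios become 0, single-level normalizing features
take their boundary value.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

TEXTURE_FAMILIES = ("glcm", "glrlm", "glszm", "ngtdm", "gldm")

GLCM_NAMES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares", "Mcc",
)
GLRLM_NAMES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)
GLSZM_NAMES = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)
NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")
GLDM_NAMES = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)
TEXTURE_NAMES = {
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "ngtdm": NGTDM_NAMES,
    "gldm": GLDM_NAMES,
}

#: the 13 unique directions of the 3D 26-neighborhood (one per +/- pair)
OFFSETS_13 = tuple(
    (a, b, c)
    for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
    if (a, b, c) > (0, 0, 0)
)

_NEIGHBORS_26 = tuple(
    (a, b, c)
    for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
    if (a, b, c) != (0, 0, 0)
)


def _shifted_views(arr: np.ndarray, off: tuple[int, int, int]) -> tuple[tuple[slice, ...], tuple[slice, ...]]:
    """Index tuples (base, shifted) so arr[base] pairs with arr[shifted]."""
    base, shifted = [], []
    for o, n in zip(off, arr.shape):
        if o >= 0:
            base.append(slice(0, n - o))
            shifted.append(slice(o, n))
        else:
            base.append(slice(-o, n))
            shifted.append(slice(0, n + o))
    return tuple(base), tuple(shifted)


# ---------------------------------------------------------------- matrices

def glcm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int, offset: tuple[int, int, int]) -> np.ndarray:
    """Symmetric gray-level co-occurrence counts for one offset."""
    base, shifted = _shifted_views(levels, offset)
    valid = mask[base] & mask[shifted]
    i = levels[base][valid] - 1
    j = levels[shifted][valid] - 1
    mat = np.zeros((n_levels, n_levels), dtype=np.int64)
    np.add.at(mat, (i, j), 1)
    np.add.at(mat, (j, i), 1)
    return mat


def glrlm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int, direction: tuple[int, int, int]) -> np.ndarray:
    """Run-length counts along one direction; columns are run lengths 1..max."""
    max_run = int(np.ceil(np.sqrt(sum((d * s) ** 2 for d, s in zip(direction, levels.shape))))) + 1
    mat = np.zeros((n_levels, max_run), dtype=np.int64)

    back = tuple(-d for d in direction)
    base, shifted = _shifted_views(levels, back)
    # a run starts where the predecessor along -direction is absent or differs
    same_as_prev = np.zeros(levels.shape, dtype=bool)
    same_as_prev[base] = mask[base] & mask[shifted] & (levels[base] == levels[shifted])
    starts = np.argwhere(mask & ~same_as_prev)
    if len(starts) == 0:
        return mat[:, :1]
    lev = levels[tuple(starts.T)]
    pos = starts
    length = np.ones(len(starts), dtype=np.int64)
    alive = np.ones(len(starts), dtype=bool)
    d = np.asarray(direction)
    while alive.any():
        nxt = pos + d
        inb = np.all((nxt >= 0) & (nxt < np.asarray(levels.shape)), axis=1) & alive
        cont = np.zeros(len(starts), dtype=bool)
        if inb.any():
            idx = tuple(nxt[inb].T)
            cont[inb] = mask[idx] & (levels[idx] == lev[inb])
        length[cont] += 1
        pos = np.where(cont[:, None], nxt, pos)
        alive = cont
    np.add.at(mat, (lev - 1, length - 1), 1)
    return mat[:, : length.max()]


def glszm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone counts from 26-connected iso-level zones."""
    structure = np.ones((3, 3, 3), dtype=bool)
    sizes_per_level: list[np.ndarray] = []
    max_size = 1
    for lev in range(1, n_levels + 1):
        sel = mask & (levels == lev)
        if not sel.any():
            sizes_per_level.append(np.array([], dtype=np.int64))
            continue
        lab, n_zones = ndimage.label(sel, structure=structure)
        sizes = np.bincount(lab.ravel())[1:]
        sizes_per_level.append(sizes)
        max_size = max(max_size, int(sizes.max()))
    mat = np.zeros((n_levels, max_size), dtype=np.int64)
    for lev_idx, sizes in enumerate(sizes_per_level):
        for s in sizes:
            mat[lev_idx, s - 1] += 1
    return mat


def _neighbor_level_stats(levels: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel sum and count of in-mask 26-neighbor gray levels."""
    nsum = np.zeros(levels.shape, dtype=np.float64)
    ncnt = np.zeros(levels.shape, dtype=np.int64)
    for off in _NEIGHBORS_26:
        base, shifted = _shifted_views(levels, off)
        contrib = mask[shifted]
        nsum[base] += np.where(contrib, levels[shifted], 0)
        ncnt[base] += contrib
    return nsum, ncnt


def ngtdm_table(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray, int]:
    """(n_i, s_i, N_vp): per-level voxel counts, absolute-difference sums and
    the number of voxels with at least one valid neighbor."""
    nsum, ncnt = _neighbor_level_stats(levels, mask)
    valid = mask & (ncnt > 0)
    n_i = np.zeros(n_levels, dtype=np.int64)
    s_i = np.zeros(n_levels, dtype=np.float64)
    lev = levels[valid]
    diff = np.abs(lev - nsum[valid] / ncnt[valid])
    np.add.at(n_i, lev - 1, 1)
    np.add.at(s_i, lev - 1, diff)
    return n_i, s_i, int(valid.sum())


def gldm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int, alpha: int = 0) -> np.ndarray:
    """Dependence counts: j = 1 + number of 26-neighbors within alpha levels."""
    dep = np.zeros(levels.shape, dtype=np.int64)
    for off in _NEIGHBORS_26:
        base, shifted = _shifted_views(levels, off)
        dep[base] += mask[base] & mask[shifted] & (np.abs(levels[base] - levels[shifted]) <= alpha)
    j = dep[mask]  # dependence size - 1
    i = levels[mask] - 1
    mat = np.zeros((n_levels, int(j.max()) + 1), dtype=np.int64)
    np.add.at(mat, (i, j), 1)
    return mat


# ---------------------------------------------------------------- features

def _xlogx(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def _glcm_features_single(mat: np.ndarray) -> dict[str, float]:
    total = mat.sum()
    p = mat / total
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sig_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sig_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))

    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.zeros(k_sum.size)
    np.add.at(p_sum, (ii + jj).ravel() - 2, p.ravel())
    k_diff = np.arange(0, ng)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).ravel(), p.ravel())

    hx = float(-_xlogx(px).sum())
    hy = float(-_xlogx(py).sum())
    hxy = float(-_xlogx(p).sum())
    pxpy = np.outer(px, py)
    nz = (p > 0) & (pxpy > 0)
    hxy1 = float(-(p[nz] * np.log2(pxpy[nz])).sum())
    nz2 = pxpy > 0
    hxy2 = float(-_xlogx(pxpy[nz2]).sum())

    da = float((k_diff * p_diff).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    autoc = float((ii * jj * p).sum())
    corr = (autoc - mu_x * mu_y) / (sig_x * sig_y) if sig_x > 0 and sig_y > 0 else 1.0

    denom = max(hx, hy)
    imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))) if hxy2 >= hxy else 0.0

    off_diag = ii != jj
    inv_var = float((p[off_diag] / (ii - jj)[off_diag] ** 2).sum()) if off_diag.any() else 0.0

    # MCC: second-largest eigenvalue of Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k))
    present = px > 0
    if present.sum() > 1:
        psub = p[np.ix_(present, present)]
        pxs = px[present]
        pys = py[present]
        q = (psub / pxs[:, None]) @ (psub / pys[:, None]).T
        eig = np.sort(np.real(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(max(0.0, eig[-2])))
    else:
        mcc = 1.0

    return {
        "Autocorrelation": autoc,
        "JointAverage": mu_x,
        "ClusterProminence": float(((ii + jj - mu_x - mu_y) ** 4 * p).sum()),
        "ClusterShade": float(((ii + jj - mu_x - mu_y) ** 3 * p).sum()),
        "ClusterTendency": float(((ii + jj - mu_x - mu_y) ** 2 * p).sum()),
        "Contrast": contrast,
        "Correlation": float(corr),
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-_xlogx(p_diff).sum()),
        "DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "Imc1": float(imc1),
        "Imc2": imc2,
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((p / (1.0 + ((ii - jj) / ng) ** 2)).sum()),
        "Id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Idn": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "InverseVariance": inv_var,
        "MaximumProbability": float(p.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": float(-_xlogx(p_sum).sum()),
        "SumSquares": float(((ii - mu_x) ** 2 * p).sum()),
        "Mcc": mcc,
    }


def _run_style_features(mat: np.ndarray, n_voxels: int, names: tuple[str, ...], kind: str) -> dict[str, float]:
    """Shared feature formulas for the GLRLM / GLSZM / GLDM matrix shape
    (gray level x run-length / zone-size / dependence-size)."""
    nr = mat.sum()
    if nr == 0:
        return {k: 0.0 for k in names}
    p = mat / nr
    ng, nj = mat.shape
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, nj + 1)[None, :]
    pg = mat.sum(axis=1)
    pj = mat.sum(axis=0)
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())

    short = float((mat / j**2).sum() / nr)
    long_ = float((mat * j**2).sum() / nr)
    vals = {
        "short": short,
        "long": long_,
        "gln": float((pg**2).sum() / nr),
        "glnn": float((pg**2).sum() / nr**2),
        "jn": float((pj**2).sum() / nr),
        "jnn": float((pj**2).sum() / nr**2),
        "pct": float(nr / n_voxels),
        "glv": float((p * (i - mu_i) ** 2).sum()),
        "jv": float((p * (j - mu_j) ** 2).sum()),
        "ent": float(-_xlogx(p).sum()),
        "lgl": float((mat / i**2).sum() / nr),
        "hgl": float((mat * i**2).sum() / nr),
        "slgl": float((mat / (i**2 * j**2)).sum() / nr),
        "shgl": float((mat * i**2 / j**2).sum() / nr),
        "llgl": float((mat * j**2 / i**2).sum() / nr),
        "lhgl": float((mat * i**2 * j**2).sum() / nr),
    }
    if kind == "glrlm":
        order = ("short", "long", "gln", "glnn", "jn", "jnn", "pct", "glv", "jv", "ent",
                 "lgl", "hgl", "slgl", "shgl", "llgl", "lhgl")
    elif kind == "glszm":
        order = ("short", "long", "gln", "glnn", "jn", "jnn", "pct", "glv", "jv", "ent",
                 "lgl", "hgl", "slgl", "shgl", "llgl", "lhgl")
    else:  # gldm: no percentage/normalized-gln pair, dependence entropy included
        order = ("short", "long", "gln", "jn", "jnn", "glv", "jv", "ent",
                 "lgl", "hgl", "slgl", "shgl", "llgl", "lhgl")
    return dict(zip(names, (vals[k] for k in order)))


def _ngtdm_features(n_i: np.ndarray, s_i: np.ndarray, nvp: int) -> dict[str, float]:
    if nvp == 0:
        return {k: 0.0 for k in NGTDM_NAMES}
    p_i = n_i / nvp
    present = p_i > 0
    ngp = int(present.sum())
    i = np.arange(1, len(n_i) + 1, dtype=float)
    ps = float((p_i * s_i).sum())

    coarseness = 1.0 / ps if ps > 0 else 1e6
    if ngp > 1:
        ii = i[present]
        pi = p_i[present]
        si = s_i[present]
        diff2 = (ii[:, None] - ii[None, :]) ** 2
        contrast = float((pi[:, None] * pi[None, :] * diff2).sum() / (ngp * (ngp - 1)) * s_i.sum() / nvp)
        denom_b = float(np.abs(ii[:, None] * pi[:, None] - ii[None, :] * pi[None, :]).sum())
        busyness = ps / denom_b if denom_b > 0 else 0.0
        num_c = np.abs(ii[:, None] - ii[None, :]) * (
            (pi[:, None] * si[:, None] + pi[None, :] * si[None, :])
            / (pi[:, None] + pi[None, :])
        )
        complexity = float(num_c.sum() / nvp)
        s_tot = float(s_i.sum())
        strength = float(((pi[:, None] + pi[None, :]) * diff2).sum() / s_tot) if s_tot > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness": float(coarseness),
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


def texture_features(disc, family: str) -> dict[str, float]:
    """Compute one texture family's features from a DiscretizedROI."""
    if family not in TEXTURE_FAMILIES:
        raise ValueError(f"unknown texture family {family!r}")
    levels, mask, ng = disc.levels, disc.mask, disc.n_levels
    n_voxels = int(mask.sum())

    if family == "glcm":
        per_offset = []
        for off in OFFSETS_13:
            mat = glcm_matrix(levels, mask, ng, off)
            if mat.sum() > 0:
                per_offset.append(_glcm_features_single(mat))
        if not per_offset:
            return {k: 0.0 for k in GLCM_NAMES}
        return {k: float(np.mean([f[k] for f in per_offset])) for k in GLCM_NAMES}

    if family == "glrlm":
        per_dir = [
            _run_style_features(glrlm_matrix(levels, mask, ng, off), n_voxels, GLRLM_NAMES, "glrlm")
            for off in OFFSETS_13
        ]
        return {k: float(np.mean([f[k] for f in per_dir])) for k in GLRLM_NAMES}

    if family == "glszm":
        return _run_style_features(glszm_matrix(levels, mask, ng), n_voxels, GLSZM_NAMES, "glszm")

    if family == "ngtdm":
        n_i, s_i, nvp = ngtdm_table(levels, mask, ng)
        return _ngtdm_features(n_i, s_i, nvp)

    return _run_style_features(gldm_matrix(levels, mask, ng), n_voxels, GLDM_NAMES, "gldm")
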