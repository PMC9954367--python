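"""Gray-level texture matrices and their feature sets (2D).

Conventions, shared by every matrix:

* the input is a discretized image (integer levels 1..Ng, see
  :func:`discretize`) and a boolean mask; only masked pixels contribute;
* GLCM: symmetric co-occurrence at distance 1 over 4 angles, features
  averaged over angles (24 features);
* GLRLM: runs of equal level along 4 directions, mask gaps break runs,
  features averaged over directions (16 features);
* GLSZM: 8-connected constant-level zones (16 features);
* GLDM: a neighbour within Chebyshev distance δ is dependent if its level
  differs from the centre by at most α; the dependence of a pixel is
  1 + its number of dependent neighbours (14 features);
* NGTDM: per-level probability p_i and summed absolute difference s_i
  between each pixel and the mean of its masked neighbours within δ;
  pixels without masked neighbours are excluded (5 features).

Entropies use log2; sums over empty index sets are 0.  The formulas are the
field-standard (IBSI-style) definitions.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "discretize",
    "glcm_matrix",
    "glrlm_matrix",
    "glszm_matrix",
    "gldm_matrix",
    "ngtdm_matrix",
    "compute_glcm_features",
    "compute_glrlm_features",
    "compute_glszm_features",
    "compute_gldm_features",
    "compute_ngtdm_features",
]

_ANGLES = ((0, 1), (1, 0), (1, 1), (1, -1))
_EIGHT = tuple(
    (dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)
)


def discretize(image: np.ndarray, mask: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width binning of masked intensities into levels 1..n_bins.

    Bins are half-open ``[edge_k, edge_{k+1})`` except the last, which is
    closed so the maximum lands in the top bin.  Pixels outside the mask get
    level 0.  A constant region maps entirely to level 1.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    img = np.asarray(image, float)
    lo, hi = img[mask].min(), img[mask].max()
    out = np.zeros(img.shape, dtype=np.int64)
    if hi == lo:
        out[mask] = 1
        return out
    width = (hi - lo) / n_bins
    lev = np.floor((img - lo) / width).astype(np.int64) + 1
    out[mask] = np.clip(lev[mask], 1, n_bins)
    return out


# ---------------------------------------------------------------------------
# matrix builders

def _shift_pairs(lev, mask, off):
    """Index pairs (centre level, neighbour level) for one 2D offset."""
    dy, dx = off
    h, w = lev.shape
    ys = slice(max(dy, 0), h + min(dy, 0))
    xs = slice(max(dx, 0), w + min(dx, 0))
    ys2 = slice(max(-dy, 0), h + min(-dy, 0))
    xs2 = slice(max(-dx, 0), w + min(-dx, 0))
    ok = mask[ys, xs] & mask[ys2, xs2]
    return lev[ys, xs][ok], lev[ys2, xs2][ok]


def glcm_matrix(
    lev: np.ndarray,
    mask: np.ndarray,
    n_levels: int,
    distance: int = 1,
    angles=_ANGLES,
) -> np.ndarray:
    """Normalized symmetric GLCMs, shape (n_angles, Ng, Ng)."""
    mask = np.asarray(mask, bool)
    mats = np.zeros((len(angles), n_levels, n_levels))
    for a, (dy, dx) in enumerate(angles):
        li, lj = _shift_pairs(lev, mask, (dy * distance, dx * distance))
        if li.size:
            np.add.at(mats[a], (li - 1, lj - 1), 1.0)
            np.add.at(mats[a], (lj - 1, li - 1), 1.0)
            mats[a] /= mats[a].sum()
    return mats


def _lines(arr: np.ndarray, direction) -> list[np.ndarray]:
    if direction == (0, 1):
        return list(arr)
    if direction == (1, 0):
        return list(arr.T)
    if direction == (1, 1):
        return [arr[::-1].diagonal(k).copy() for k in range(-arr.shape[0] + 1, arr.shape[1])]
    if direction == (1, -1):
        a = arr[:, ::-1]
        return [a[::-1].diagonal(k).copy() for k in range(-a.shape[0] + 1, a.shape[1])]
    raise ValueError(f"unsupported direction {direction}")


def glrlm_matrix(
    lev: np.ndarray, mask: np.ndarray, n_levels: int, directions=_ANGLES
) -> np.ndarray:
    """Run-length matrices, shape (n_directions, Ng, max_run)."""
    mask = np.asarray(mask, bool)
    max_run = max(lev.shape)
    mats = np.zeros((len(directions), n_levels, max_run))
    for d, direction in enumerate(directions):
        for line, mline in zip(_lines(lev, direction), _lines(mask, direction)):
            run_level, run_len = 0, 0
            for v, ok in zip(line, mline):
                if ok and v == run_level:
                    run_len += 1
                else:
                    if run_len:
                        mats[d, run_level - 1, run_len - 1] += 1
                    run_level, run_len = (int(v), 1) if ok else (0, 0)
            if run_len:
                mats[d, run_level - 1, run_len - 1] += 1
    return mats


def glszm_matrix(lev: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone matrix over 8-connected constant-level zones, (Ng, max_zone)."""
    mask = np.asarray(mask, bool)
    np_pix = int(mask.sum())
    mat = np.zeros((n_levels, max(np_pix, 1)))
    structure = np.ones((3, 3), dtype=bool)
    for i in np.unique(lev[mask]):
        comp, n = ndimage.label((lev == i) & mask, structure=structure)
        if n:
            sizes = ndimage.sum_labels(np.ones(comp.shape), comp, np.arange(1, n + 1))
            for s in sizes.astype(int):
                mat[i - 1, s - 1] += 1
    return mat


def gldm_matrix(
    lev: np.ndarray, mask: np.ndarray, n_levels: int, delta: int = 1, alpha: int = 0
) -> np.ndarray:
    """Dependence matrix, shape (Ng, max_dependence); dependence >= 1.

    The dependence of a masked pixel is one (itself) plus the number of
    masked neighbours within Chebyshev distance ``delta`` whose level
    differs by at most ``alpha``.
    """
    mask = np.asarray(mask, bool)
    offsets = [
        (dy, dx)
        for dy in range(-delta, delta + 1)
        for dx in range(-delta, delta + 1)
        if (dy, dx) != (0, 0)
    ]
    dep = np.zeros(lev.shape, dtype=np.int64)
    h, w = lev.shape
    for dy, dx in offsets:
        ys = slice(max(dy, 0), h + min(dy, 0))
        xs = slice(max(dx, 0), w + min(dx, 0))
        ys2 = slice(max(-dy, 0), h + min(-dy, 0))
        xs2 = slice(max(-dx, 0), w + min(-dx, 0))
        ok = mask[ys, xs] & mask[ys2, xs2] & (
            np.abs(lev[ys, xs] - lev[ys2, xs2]) <= alpha
        )
        sub = dep[ys, xs]
        sub[ok] += 1
        dep[ys, xs] = sub
    dep = dep + 1
    max_dep = len(offsets) + 1
    mat = np.zeros((n_levels, max_dep))
    np.add.at(mat, (lev[mask] - 1, dep[mask] - 1), 1.0)
    return mat


def ngtdm_matrix(
    lev: np.ndarray, mask: np.ndarray, n_levels: int, delta: int = 1
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-level probabilities p_i, summed differences s_i, and valid count.

    Returns ``(p, s, n_valid)`` where ``p[i-1]`` is the fraction of valid
    masked pixels at level i and ``s[i-1]`` sums, over those pixels, the
    absolute difference between the pixel level and the mean level of its
    masked neighbours within Chebyshev distance ``delta``.
    """
    mask = np.asarray(mask, bool)
    offsets = [
        (dy, dx)
        for dy in range(-delta, delta + 1)
        for dx in range(-delta, delta + 1)
        if (dy, dx) != (0, 0)
    ]
    h, w = lev.shape
    nb_sum = np.zeros(lev.shape)
    nb_cnt = np.zeros(lev.shape)
    for dy, dx in offsets:
        ys = slice(max(dy, 0), h + min(dy, 0))
        xs = slice(max(dx, 0), w + min(dx, 0))
        ys2 = slice(max(-dy, 0), h + min(-dy, 0))
        xs2 = slice(max(-dx, 0), w + min(-dx, 0))
        ok = mask[ys2, xs2]
        add = np.where(ok, lev[ys2, xs2], 0)
        nb_sum[ys, xs] += add
        nb_cnt[ys, xs] += ok
    valid = mask & (nb_cnt > 0)
    n_valid = int(valid.sum())
    p = np.zeros(n_levels)
    s = np.zeros(n_levels)
    if n_valid:
        avg = nb_sum[valid] / nb_cnt[valid]
        lv = lev[valid]
        diffs = np.abs(lv - avg)
        for i in range(1, n_levels + 1):
            sel = lv == i
            p[i - 1] = sel.sum() / n_valid
            s[i - 1] = diffs[sel].sum()
    return p, s, n_valid


# ---------------------------------------------------------------------------
# feature calculators

def _entropy2(p: np.ndarray) -> float:
    nz = p > 0
    return float(-np.sum(p[nz] * np.log2(p[nz])))


def _glcm_one(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1).reshape(-1, 1)
    j = np.arange(1, ng + 1).reshape(1, -1)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(np.sum(px * np.arange(1, ng + 1)))
    mu_y = float(np.sum(py * np.arange(1, ng + 1)))
    sig_x = float(np.sqrt(np.sum(px * (np.arange(1, ng + 1) - mu_x) ** 2)))
    sig_y = float(np.sqrt(np.sum(py * (np.arange(1, ng + 1) - mu_y) ** 2)))
    # diagonal (difference) and cross (sum) distributions
    k_diff = np.arange(0, ng)
    p_diff = np.array([np.sum(p[np.abs(i - j) == k]) for k in k_diff])
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([np.sum(p[(i + j) == k]) for k in k_sum])

    hx, hy, hxy = _entropy2(px), _entropy2(py), _entropy2(p)
    outer = px.reshape(-1, 1) * py.reshape(1, -1)
    nz = (p > 0) & (outer > 0)
    hxy1 = float(-np.sum(p[nz] * np.log2(outer[nz])))
    nz2 = outer > 0
    hxy2 = float(-np.sum(outer[nz2] * np.log2(outer[nz2])))

    da = float(np.sum(k_diff * p_diff))
    out = {
        "Autocorrelation": float(np.sum(p * i * j)),
        "JointAverage": mu_x,
        "ClusterProminence": float(np.sum(p * (i + j - mu_x - mu_y) ** 4)),
        "ClusterShade": float(np.sum(p * (i + j - mu_x - mu_y) ** 3)),
        "ClusterTendency": float(np.sum(p * (i + j - mu_x - mu_y) ** 2)),
        "Contrast": float(np.sum(p * (i - j) ** 2)),
        "Correlation": (
            float((np.sum(p * i * j) - mu_x * mu_y) / (sig_x * sig_y))
            if sig_x * sig_y > 0
            else 1.0
        ),
        "DifferenceAverage": da,
        "DifferenceEntropy": _entropy2(p_diff),
        "DifferenceVariance": float(np.sum((k_diff - da) ** 2 * p_diff)),
        "JointEnergy": float(np.sum(p**2)),
        "JointEntropy": hxy,
        "Imc1": float((hxy - hxy1) / max(hx, hy)) if max(hx, hy) > 0 else 0.0,
        "Imc2": float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))),
        "Idm": float(np.sum(p_diff / (1.0 + k_diff**2))),
        "Idmn": float(np.sum(p_diff / (1.0 + (k_diff / ng) ** 2))),
        "Id": float(np.sum(p_diff / (1.0 + k_diff))),
        "Idn": float(np.sum(p_diff / (1.0 + k_diff / ng))),
        "InverseVariance": float(np.sum(p_diff[1:] / k_diff[1:] ** 2)),
        "MaximumProbability": float(p.max()),
        "SumAverage": float(np.sum(k_sum * p_sum)),
        "SumEntropy": _entropy2(p_sum),
        "SumSquares": float(np.sum(p * (i - mu_x) ** 2)),
        "MCC": _mcc(p, px, py),
    }
    return out


def _mcc(p: np.ndarray, px: np.ndarray, py: np.ndarray) -> float:
    keep = px > 0
    if keep.sum() < 2:
        return 1.0
    sub = p[np.ix_(keep, keep)]
    pxs = px[keep]
    pys = py[keep]
    q = np.einsum("ik,jk->ij", sub, sub / (pys.reshape(1, -1))) / pxs.reshape(-1, 1)
    ev = np.sort(np.real(np.linalg.eigvals(q)))
    second = float(ev[-2])
    # eigenvalues at round-off scale are genuine zeros; without the floor
    # the square root amplifies ~1e-16 noise into the output
    if second < 1e-12:
        second = 0.0
    return float(np.sqrt(second))


def compute_glcm_features(mats: np.ndarray, prefix: str = "glcm_") -> dict[str, float]:
    """24 co-occurrence features, averaged over the matrix stack (angles)."""
    if mats.size == 0 or not np.any(mats.sum(axis=(1, 2)) > 0):
        raise ValueError("empty GLCM")
    per = [_glcm_one(m) for m in mats if m.sum() > 0]
    return {prefix + k: float(np.mean([d[k] for d in per])) for k in per[0]}


def _run_zone_family(mat: np.ndarray, n_pixels: int) -> dict[str, float]:
    """Shared statistics of the run-length / size-zone / dependence family.

    ``mat[i-1, j-1]`` counts runs/zones/pixels at gray level i with
    length/size/dependence j; ``n_pixels`` is Np of the region.
    """
    ns = mat.sum()
    if ns == 0:
        raise ValueError("empty matrix")
    ng, nj = mat.shape
    i = np.arange(1, ng + 1).reshape(-1, 1)
    j = np.arange(1, nj + 1).reshape(1, -1)
    pg = mat.sum(axis=1)
    pr = mat.sum(axis=0)
    pnorm = mat / ns
    mu_i = float(np.sum(pnorm * i))
    mu_j = float(np.sum(pnorm * j))
    return {
        "ShortEmphasis": float(np.sum(pr / j.ravel() ** 2) / ns),
        "LongEmphasis": float(np.sum(pr * j.ravel() ** 2) / ns),
        "GrayLevelNonUniformity": float(np.sum(pg**2) / ns),
        "GrayLevelNonUniformityNormalized": float(np.sum(pg**2) / ns**2),
        "SizeNonUniformity": float(np.sum(pr**2) / ns),
        "SizeNonUniformityNormalized": float(np.sum(pr**2) / ns**2),
        "Percentage": float(ns / n_pixels),
        "GrayLevelVariance": float(np.sum(pnorm * (i - mu_i) ** 2)),
        "SizeVariance": float(np.sum(pnorm * (j - mu_j) ** 2)),
        "Entropy": _entropy2(pnorm[pnorm > 0]),
        "LowGrayLevelEmphasis": float(np.sum(pg / i.ravel() ** 2) / ns),
        "HighGrayLevelEmphasis": float(np.sum(pg * i.ravel() ** 2) / ns),
        "ShortLowGrayLevelEmphasis": float(np.sum(mat / (i**2 * j**2)) / ns),
        "ShortHighGrayLevelEmphasis": float(np.sum(mat * i**2 / j**2) / ns),
        "LongLowGrayLevelEmphasis": float(np.sum(mat * j**2 / i**2) / ns),
        "LongHighGrayLevelEmphasis": float(np.sum(mat * i**2 * j**2) / ns),
    }


_GLRLM_NAMES = {
    "ShortEmphasis": "ShortRunEmphasis",
    "LongEmphasis": "LongRunEmphasis",
    "SizeNonUniformity": "RunLengthNonUniformity",
    "SizeNonUniformityNormalized": "RunLengthNonUniformityNormalized",
    "Percentage": "RunPercentage",
    "SizeVariance": "RunVariance",
    "Entropy": "RunEntropy",
    "LowGrayLevelEmphasis": "LowGrayLevelRunEmphasis",
    "HighGrayLevelEmphasis": "HighGrayLevelRunEmphasis",
    "ShortLowGrayLevelEmphasis": "ShortRunLowGrayLevelEmphasis",
    "ShortHighGrayLevelEmphasis": "ShortRunHighGrayLevelEmphasis",
    "LongLowGrayLevelEmphasis": "LongRunLowGrayLevelEmphasis",
    "LongHighGrayLevelEmphasis": "LongRunHighGrayLevelEmphasis",
}

_GLSZM_NAMES = {
    "ShortEmphasis": "SmallAreaEmphasis",
    "LongEmphasis": "LargeAreaEmphasis",
    "SizeNonUniformity": "SizeZoneNonUniformity",
    "SizeNonUniformityNormalized": "SizeZoneNonUniformityNormalized",
    "Percentage": "ZonePercentage",
    "SizeVariance": "ZoneVariance",
    "Entropy": "ZoneEntropy",
    "LowGrayLevelEmphasis": "LowGrayLevelZoneEmphasis",
    "HighGrayLevelEmphasis": "HighGrayLevelZoneEmphasis",
    "ShortLowGrayLevelEmphasis": "SmallAreaLowGrayLevelEmphasis",
    "ShortHighGrayLevelEmphasis": "SmallAreaHighGrayLevelEmphasis",
    "LongLowGrayLevelEmphasis": "LargeAreaLowGrayLevelEmphasis",
    "LongHighGrayLevelEmphasis": "LargeAreaHighGrayLevelEmphasis",
}


def compute_glrlm_features(
    mats: np.ndarray, n_pixels: int, prefix: str = "glrlm_"
) -> dict[str, float]:
    """16 run-length features, averaged over directions."""
    per = []
    for m in mats:
        d = _run_zone_family(m, n_pixels)
        per.append({_GLRLM_NAMES.get(k, k): v for k, v in d.items()})
    return {prefix + k: float(np.mean([d[k] for d in per])) for k in per[0]}


def compute_glszm_features(
    mat: np.ndarray, n_pixels: int, prefix: str = "glszm_"
) -> dict[str, float]:
    """16 size-zone features."""
    d = _run_zone_family(mat, n_pixels)
    return {prefix + _GLSZM_NAMES.get(k, k): v for k, v in d.items()}


def compute_gldm_features(mat: np.ndarray, prefix: str = "gldm_") -> dict[str, float]:
    """14 dependence features; Nz equals the pixel count of the region."""
    d = _run_zone_family(mat, int(mat.sum()))
    names = {
        "ShortEmphasis": "SmallDependenceEmphasis",
        "LongEmphasis": "LargeDependenceEmphasis",
        "SizeNonUniformity": "DependenceNonUniformity",
        "SizeNonUniformityNormalized": "DependenceNonUniformityNormalized",
        "SizeVariance": "DependenceVariance",
        "Entropy": "DependenceEntropy",
        "LowGrayLevelEmphasis": "LowGrayLevelEmphasis",
        "HighGrayLevelEmphasis": "HighGrayLevelEmphasis",
        "ShortLowGrayLevelEmphasis": "SmallDependenceLowGrayLevelEmphasis",
        "ShortHighGrayLevelEmphasis": "SmallDependenceHighGrayLevelEmphasis",
        "LongLowGrayLevelEmphasis": "LargeDependenceLowGrayLevelEmphasis",
        "LongHighGrayLevelEmphasis": "LargeDependenceHighGrayLevelEmphasis",
    }
    out = {}
    for k, v in d.items():
        if k in ("GrayLevelNonUniformityNormalized", "Percentage"):
            continue  # not part of the 14-feature dependence set
        out[prefix + names.get(k, k)] = v
    return out


def compute_ngtdm_features(
    p: np.ndarray, s: np.ndarray, n_valid: int, prefix: str = "ngtdm_", eps: float = 1e-6
) -> dict[str, float]:
    """Coarseness, contrast, busyness, complexity, strength."""
    if n_valid == 0:
        raise ValueError("NGTDM has no valid pixels")
    idx = np.arange(1, p.size + 1)
    act = p > 0
    ngp = int(act.sum())
    ia, pa, sa = idx[act], p[act], s[act]
    coarseness = 1.0 / (eps + float(np.sum(p * s)))
    if ngp > 1:
        diff2 = (ia.reshape(-1, 1) - ia.reshape(1, -1)) ** 2
        pij = pa.reshape(-1, 1) * pa.reshape(1, -1)
        contrast = float(np.sum(pij * diff2) / (ngp * (ngp - 1)) * (s.sum() / n_valid))
        absdiff = np.abs(
            (ia * pa).reshape(-1, 1) - (ia * pa).reshape(1, -1)
        )
        denom = float(absdiff.sum())
        busyness = float(np.sum(p * s) / denom) if denom > 0 else 0.0
        num = np.abs(ia.reshape(-1, 1) - ia.reshape(1, -1)) * (
            (pa * sa).reshape(-1, 1) + (pa * sa).reshape(1, -1)
        ) / (pa.reshape(-1, 1) + pa.reshape(1, -1))
        complexity = float(num.sum() / n_valid)
        strength_num = float(
            np.sum((pa.reshape(-1, 1) + pa.reshape(1, -1)) * diff2)
        )
        strength = strength_num / (eps + float(s.sum()))
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        prefix + "Coarseness": coarseness,
        prefix + "Contrast": contrast,
        prefix + "Busyness": busyness,
        prefix + "Complexity": complexity,
        prefix + "Strength": strength,
    }
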