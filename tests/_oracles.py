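"""Brute-force texture oracles: direct pair/run/zone/neighbourhood
enumeration in pure Python, independent of the package's vectorized
implementations.  Formulas are written as explicit sums over matrix entries.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np

ANGLES = ((0, 1), (1, 0), (1, 1), (1, -1))
EIGHT = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]


def _log2(x):
    return math.log2(x)


# ---------------------------------------------------------------------------
# GLCM

def glcm_dict(lev, mask, offset):
    h, w = lev.shape
    dy, dx = offset
    counts: dict = defaultdict(float)
    for y in range(h):
        for x in range(w):
            y2, x2 = y + dy, x + dx
            if 0 <= y2 < h and 0 <= x2 < w and mask[y, x] and mask[y2, x2]:
                counts[(int(lev[y, x]), int(lev[y2, x2]))] += 1
                counts[(int(lev[y2, x2]), int(lev[y, x]))] += 1
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()} if total else {}


def glcm_features_oracle(lev, mask, n_levels, offsets=ANGLES):
    per = []
    for off in offsets:
        p = glcm_dict(lev, mask, off)
        if p:
            per.append(_glcm_feats(p, n_levels))
    return {k: float(np.mean([d[k] for d in per])) for k in per[0]}


def _glcm_feats(p, ng):
    px = defaultdict(float)
    py = defaultdict(float)
    for (i, j), v in p.items():
        px[i] += v
        py[j] += v
    mu_x = sum(i * v for i, v in px.items())
    mu_y = sum(j * v for j, v in py.items())
    sig_x = math.sqrt(sum(v * (i - mu_x) ** 2 for i, v in px.items()))
    sig_y = math.sqrt(sum(v * (j - mu_y) ** 2 for j, v in py.items()))
    pdiff = defaultdict(float)
    psum = defaultdict(float)
    for (i, j), v in p.items():
        pdiff[abs(i - j)] += v
        psum[i + j] += v
    hx = -sum(v * _log2(v) for v in px.values() if v > 0)
    hy = -sum(v * _log2(v) for v in py.values() if v > 0)
    hxy = -sum(v * _log2(v) for v in p.values() if v > 0)
    hxy1 = -sum(v * _log2(px[i] * py[j]) for (i, j), v in p.items() if px[i] * py[j] > 0)
    hxy2 = -sum(
        px[i] * py[j] * _log2(px[i] * py[j])
        for i in px
        for j in py
        if px[i] * py[j] > 0
    )
    da = sum(k * v for k, v in pdiff.items())
    corr = 1.0
    if sig_x * sig_y > 0:
        corr = (sum(i * j * v for (i, j), v in p.items()) - mu_x * mu_y) / (sig_x * sig_y)
    # MCC via the Q matrix on occupied levels
    occ = sorted(px)
    if len(occ) < 2:
        mcc = 1.0
    else:
        q = np.zeros((len(occ), len(occ)))
        for a, i in enumerate(occ):
            for b, j in enumerate(occ):
                q[a, b] = sum(
                    p.get((i, k), 0.0) * p.get((j, k), 0.0) / (px[i] * py[k])
                    for k in py
                    if py[k] > 0
                )
        ev = sorted(np.real(np.linalg.eigvals(q)))
        second = ev[-2] if ev[-2] >= 1e-12 else 0.0  # same round-off floor
        mcc = math.sqrt(second)
    return {
        "Autocorrelation": sum(i * j * v for (i, j), v in p.items()),
        "JointAverage": mu_x,
        "ClusterProminence": sum(v * (i + j - mu_x - mu_y) ** 4 for (i, j), v in p.items()),
        "ClusterShade": sum(v * (i + j - mu_x - mu_y) ** 3 for (i, j), v in p.items()),
        "ClusterTendency": sum(v * (i + j - mu_x - mu_y) ** 2 for (i, j), v in p.items()),
        "Contrast": sum(v * (i - j) ** 2 for (i, j), v in p.items()),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": -sum(v * _log2(v) for v in pdiff.values() if v > 0),
        "DifferenceVariance": sum((k - da) ** 2 * v for k, v in pdiff.items()),
        "JointEnergy": sum(v * v for v in p.values()),
        "JointEntropy": hxy,
        "Imc1": (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0,
        "Imc2": math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))),
        "Idm": sum(v / (1.0 + k * k) for k, v in pdiff.items()),
        "Idmn": sum(v / (1.0 + (k / ng) ** 2) for k, v in pdiff.items()),
        "Id": sum(v / (1.0 + k) for k, v in pdiff.items()),
        "Idn": sum(v / (1.0 + k / ng) for k, v in pdiff.items()),
        "InverseVariance": sum(v / (k * k) for k, v in pdiff.items() if k > 0),
        "MaximumProbability": max(p.values()),
        "SumAverage": sum(k * v for k, v in psum.items()),
        "SumEntropy": -sum(v * _log2(v) for v in psum.values() if v > 0),
        "SumSquares": sum(v * (i - mu_x) ** 2 for (i, j), v in p.items()),
        "MCC": mcc,
    }


# ---------------------------------------------------------------------------
# run/zone/dependence family, from (i, j) -> count dictionaries

def family_feats(counts, n_pixels, ng):
    ns = sum(counts.values())
    pg = defaultdict(float)
    pr = defaultdict(float)
    for (i, j), v in counts.items():
        pg[i] += v
        pr[j] += v
    mu_i = sum(i * v / ns for (i, j), v in counts.items())
    mu_j = sum(j * v / ns for (i, j), v in counts.items())
    return {
        "ShortEmphasis": sum(v / (j * j) for (i, j), v in counts.items()) / ns,
        "LongEmphasis": sum(v * j * j for (i, j), v in counts.items()) / ns,
        "GrayLevelNonUniformity": sum(v * v for v in pg.values()) / ns,
        "GrayLevelNonUniformityNormalized": sum(v * v for v in pg.values()) / ns**2,
        "SizeNonUniformity": sum(v * v for v in pr.values()) / ns,
        "SizeNonUniformityNormalized": sum(v * v for v in pr.values()) / ns**2,
        "Percentage": ns / n_pixels,
        "GrayLevelVariance": sum(v / ns * (i - mu_i) ** 2 for (i, j), v in counts.items()),
        "SizeVariance": sum(v / ns * (j - mu_j) ** 2 for (i, j), v in counts.items()),
        "Entropy": -sum(v / ns * _log2(v / ns) for v in counts.values() if v > 0),
        "LowGrayLevelEmphasis": sum(v / (i * i) for (i, j), v in counts.items()) / ns,
        "HighGrayLevelEmphasis": sum(v * i * i for (i, j), v in counts.items()) / ns,
        "ShortLowGrayLevelEmphasis": sum(v / (i * i * j * j) for (i, j), v in counts.items()) / ns,
        "ShortHighGrayLevelEmphasis": sum(v * i * i / (j * j) for (i, j), v in counts.items()) / ns,
        "LongLowGrayLevelEmphasis": sum(v * j * j / (i * i) for (i, j), v in counts.items()) / ns,
        "LongHighGrayLevelEmphasis": sum(v * i * i * j * j for (i, j), v in counts.items()) / ns,
    }


def glrlm_counts(lev, mask, direction):
    h, w = lev.shape
    dy, dx = direction
    counts: dict = defaultdict(float)
    starts = []
    for y in range(h):
        for x in range(w):
            py, px_ = y - dy, x - dx
            if not (0 <= py < h and 0 <= px_ < w):
                starts.append((y, x))
    for y0, x0 in starts:
        y, x = y0, x0
        run_level, run_len = None, 0
        while 0 <= y < h and 0 <= x < w:
            if mask[y, x] and lev[y, x] == run_level:
                run_len += 1
            else:
                if run_len:
                    counts[(int(run_level), run_len)] += 1
                run_level, run_len = (int(lev[y, x]), 1) if mask[y, x] else (None, 0)
            y, x = y + dy, x + dx
        if run_len:
            counts[(int(run_level), run_len)] += 1
    return counts


def glrlm_features_oracle(lev, mask, n_levels, directions=ANGLES):
    npix = int(mask.sum())
    per = [family_feats(glrlm_counts(lev, mask, d), npix, n_levels) for d in directions]
    return {k: float(np.mean([d[k] for d in per])) for k in per[0]}


def glszm_counts(lev, mask):
    h, w = lev.shape
    seen = np.zeros_like(mask, dtype=bool)
    counts: dict = defaultdict(float)
    for y in range(h):
        for x in range(w):
            if mask[y, x] and not seen[y, x]:
                level = int(lev[y, x])
                stack, size = [(y, x)], 0
                seen[y, x] = True
                while stack:
                    cy, cx = stack.pop()
                    size += 1
                    for dy, dx in EIGHT:
                        ny, nx = cy + dy, cx + dx
                        if (
                            0 <= ny < h and 0 <= nx < w
                            and mask[ny, nx] and not seen[ny, nx]
                            and int(lev[ny, nx]) == level
                        ):
                            seen[ny, nx] = True
                            stack.append((ny, nx))
                counts[(level, size)] += 1
    return counts


def glszm_features_oracle(lev, mask, n_levels):
    return family_feats(glszm_counts(lev, mask), int(mask.sum()), n_levels)


def gldm_counts(lev, mask, delta=1, alpha=0):
    h, w = lev.shape
    counts: dict = defaultdict(float)
    offs = [
        (dy, dx)
        for dy in range(-delta, delta + 1)
        for dx in range(-delta, delta + 1)
        if (dy, dx) != (0, 0)
    ]
    for y in range(h):
        for x in range(w):
            if not mask[y, x]:
                continue
            dep = 1
            for dy, dx in offs:
                ny, nx = y + dy, x + dx
                if (
                    0 <= ny < h and 0 <= nx < w and mask[ny, nx]
                    and abs(int(lev[ny, nx]) - int(lev[y, x])) <= alpha
                ):
                    dep += 1
            counts[(int(lev[y, x]), dep)] += 1
    return counts


def gldm_features_oracle(lev, mask, n_levels):
    counts = gldm_counts(lev, mask)
    feats = family_feats(counts, int(mask.sum()), n_levels)
    del feats["GrayLevelNonUniformityNormalized"], feats["Percentage"]
    return feats


def ngtdm_oracle(lev, mask, n_levels, delta=1, eps=1e-6):
    h, w = lev.shape
    offs = [
        (dy, dx)
        for dy in range(-delta, delta + 1)
        for dx in range(-delta, delta + 1)
        if (dy, dx) != (0, 0)
    ]
    p = np.zeros(n_levels)
    s = np.zeros(n_levels)
    nvc = 0
    for y in range(h):
        for x in range(w):
            if not mask[y, x]:
                continue
            nb = [
                int(lev[y + dy, x + dx])
                for dy, dx in offs
                if 0 <= y + dy < h and 0 <= x + dx < w and mask[y + dy, x + dx]
            ]
            if not nb:
                continue
            nvc += 1
            i = int(lev[y, x])
            p[i - 1] += 1
            s[i - 1] += abs(i - sum(nb) / len(nb))
    if nvc:
        p = p / nvc
    idx = np.arange(1, n_levels + 1)
    act = [a for a in range(n_levels) if p[a] > 0]
    ngp = len(act)
    coarse = 1.0 / (eps + float(sum(p[a] * s[a] for a in range(n_levels))))
    if ngp > 1:
        contrast = (
            sum(p[a] * p[b] * (idx[a] - idx[b]) ** 2 for a in act for b in act)
            / (ngp * (ngp - 1))
        ) * (s.sum() / nvc)
        denom = sum(abs(idx[a] * p[a] - idx[b] * p[b]) for a in act for b in act)
        busy = float(sum(p[a] * s[a] for a in act) / denom) if denom > 0 else 0.0
        cplx = sum(
            abs(idx[a] - idx[b]) * (p[a] * s[a] + p[b] * s[b]) / (p[a] + p[b])
            for a in act
            for b in act
        ) / nvc
        strength = sum(
            (p[a] + p[b]) * (idx[a] - idx[b]) ** 2 for a in act for b in act
        ) / (eps + s.sum())
    else:
        contrast = busy = cplx = strength = 0.0
    return {
        "Coarseness": coarse,
        "Contrast": float(contrast),
        "Busyness": busy,
        "Complexity": float(cplx),
        "Strength": float(strength),
    }, nvc
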