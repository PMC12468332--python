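"""Independent brute-force oracles used by the test suite.

Everything here is written as plain loops over voxels, pairs and neighbors,
deliberately avoiding the vectorized code paths of the package so the two
routes can disagree when either is wrong.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def ray_march_split(source, target, inside_fn, step_mm=0.1):
    """d_out/d_in by marching the ray in small steps."""
    source = np.asarray(source, float)
    target = np.asarray(target, float)
    d = np.linalg.norm(target - source)
    n = int(np.ceil(d / step_mm))
    ts = np.linspace(0.0, 1.0, n + 1)
    pts = source[None, :] + ts[:, None] * (target - source)[None, :]
    ins = inside_fn(pts)
    d_in = float(np.sum(ins) / len(ts) * d)
    return d - d_in, d_in


# ---------------------------------------------------------------------------
# First-order statistics
# ---------------------------------------------------------------------------

def first_order(vals, n_bins=64):
    vals = np.asarray(vals, float).ravel()
    n = len(vals)
    mean = sum(vals) / n
    var = sum((v - mean) ** 2 for v in vals) / n
    med = float(np.median(vals))
    lo, hi = min(vals), max(vals)
    counts = [0] * n_bins
    for v in vals:
        if hi == lo:
            lev = 1
        else:
            lev = int(np.floor((v - lo) / (hi - lo) * n_bins)) + 1
            lev = min(max(lev, 1), n_bins)
        counts[lev - 1] += 1
    ent = 0.0
    uni = 0.0
    for c in counts:
        if c > 0:
            p = c / n
            ent -= p * np.log2(p)
            uni += p * p
    if var > 0:
        m3 = sum((v - mean) ** 3 for v in vals) / n
        m4 = sum((v - mean) ** 4 for v in vals) / n
        skew = m3 / var ** 1.5
        kurt = m4 / var ** 2
    else:
        skew = kurt = np.nan
    return {"Mean": mean, "Median": med, "Variance": var, "Entropy": ent,
            "Uniformity": uni, "Skewness": skew, "Kurtosis": kurt}


# ---------------------------------------------------------------------------
# GLCM by explicit pair enumeration
# ---------------------------------------------------------------------------

_OFFSETS = [(1, 0, 0), (0, 1, 0), (0, 0, 1),
            (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
            (0, 1, 1), (0, 1, -1),
            (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1)]


def glcm(levels, mask, n_bins=64):
    shape = mask.shape
    per_dir = []
    for off in _OFFSETS:
        P = np.zeros((n_bins, n_bins))
        found = False
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    if not mask[x, y, z]:
                        continue
                    xx, yy, zz = x + off[0], y + off[1], z + off[2]
                    if not (0 <= xx < shape[0] and 0 <= yy < shape[1]
                            and 0 <= zz < shape[2]):
                        continue
                    if not mask[xx, yy, zz]:
                        continue
                    i, j = levels[x, y, z] - 1, levels[xx, yy, zz] - 1
                    P[i, j] += 1
                    P[j, i] += 1
                    found = True
        if not found:
            continue
        P = P / P.sum()
        per_dir.append(_glcm_feats(P))
    keys = per_dir[0].keys()
    return {k: float(np.mean([d[k] for d in per_dir])) for k in keys}


def _glcm_feats(P):
    n = P.shape[0]
    mu = 0.0
    for i in range(n):
        for j in range(n):
            mu += (i + 1) * P[i, j]
    sig2 = 0.0
    for i in range(n):
        for j in range(n):
            sig2 += (i + 1 - mu) ** 2 * P[i, j]
    out = {"Autocorrelation": 0.0, "Contrast": 0.0, "Correlation": 0.0,
           "Difference Average": 0.0, "Inverse Difference": 0.0,
           "Joint Average": mu, "Joint Energy": 0.0, "Joint Entropy": 0.0,
           "Sum of Squares": sig2}
    corr_num = 0.0
    for i in range(n):
        for j in range(n):
            p = P[i, j]
            gi, gj = i + 1, j + 1
            out["Autocorrelation"] += gi * gj * p
            out["Contrast"] += (gi - gj) ** 2 * p
            corr_num += (gi - mu) * (gj - mu) * p
            out["Difference Average"] += abs(gi - gj) * p
            out["Inverse Difference"] += p / (1 + abs(gi - gj))
            out["Joint Energy"] += p * p
            if p > 0:
                out["Joint Entropy"] -= p * np.log2(p)
    out["Correlation"] = corr_num / sig2 if sig2 > 0 else 1.0
    return out


# ---------------------------------------------------------------------------
# NGTDM by explicit neighbor enumeration
# ---------------------------------------------------------------------------

def ngtdm(levels, mask, n_bins=64, eps=1e-6):
    shape = mask.shape
    s = {}
    n = {}
    n_vc = 0
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                nb = []
                for dx in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dz in (-1, 0, 1):
                            if dx == dy == dz == 0:
                                continue
                            xx, yy, zz = x + dx, y + dy, z + dz
                            if (0 <= xx < shape[0] and 0 <= yy < shape[1]
                                    and 0 <= zz < shape[2] and mask[xx, yy, zz]):
                                nb.append(levels[xx, yy, zz])
                if not nb:
                    continue
                n_vc += 1
                g = int(levels[x, y, z])
                s[g] = s.get(g, 0.0) + abs(g - sum(nb) / len(nb))
                n[g] = n.get(g, 0) + 1
    present = sorted(n)
    p = {g: n[g] / n_vc for g in present}
    ngp = len(present)
    coars = 1.0 / (eps + sum(p[g] * s[g] for g in present))
    if ngp > 1:
        contrast = (sum(p[i] * p[j] * (i - j) ** 2 for i in present for j in present)
                    / (ngp * (ngp - 1)) * sum(s.values()) / n_vc)
        denom = sum(abs(i * p[i] - j * p[j]) for i in present for j in present if i != j)
        busy = sum(p[g] * s[g] for g in present) / denom if denom > 0 else 0.0
        compl = sum(abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
                    for i in present for j in present) / n_vc
        strength = (sum((p[i] + p[j]) * (i - j) ** 2
                        for i in present for j in present if i != j)
                    / (eps + sum(s.values())))
    else:
        contrast = busy = compl = strength = 0.0
    return {"Coarseness": coars, "Contrast": contrast, "Busyness": busy,
            "Complexity": compl, "Strength": strength}


# ---------------------------------------------------------------------------
# Shape
# ---------------------------------------------------------------------------

def hull_voxel_count(idx, shape):
    """Lattice points inside the convex hull, facet test per point."""
    from scipy.spatial import ConvexHull
    hull = ConvexHull(np.asarray(idx, float))
    count = 0
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                pt = np.array([x, y, z], float)
                ok = True
                for eq in hull.equations:
                    if eq[:3] @ pt + eq[3] > 1e-9:
                        ok = False
                        break
                count += ok
    return count


def solidity(mask):
    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    sub = np.asarray(mask)[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    return sub.sum() / hull_voxel_count(np.argwhere(sub), sub.shape)


def mesh_area(verts, faces):
    """Triangle-by-triangle cross-product area sum."""
    total = 0.0
    for f in faces:
        a, b, c = verts[f[0]], verts[f[1]], verts[f[2]]
        total += 0.5 * np.linalg.norm(np.cross(b - a, c - a))
    return total


def sphericity(mask, spacing=2.0):
    from skimage.measure import marching_cubes
    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    sub = np.asarray(mask)[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    verts, faces, _, _ = marching_cubes(np.pad(sub, 1).astype(float), 0.5,
                                        spacing=(spacing,) * 3)
    v = mask.sum() * spacing ** 3
    return (36 * np.pi * v ** 2) ** (1 / 3) / mesh_area(verts, faces)


def axis_ratios(mask, spacing=2.0):
    pts = np.argwhere(mask) * spacing
    mean = pts.mean(axis=0)
    cov = np.zeros((3, 3))
    for p in pts:
        d = p - mean
        cov += np.outer(d, d)
    cov /= len(pts)
    lam = sorted(np.linalg.eigvalsh(cov), reverse=True)
    elong = np.sqrt(lam[1] / lam[0])
    flat = np.sqrt(lam[2] / lam[0]) if lam[2] > 1e-12 * lam[0] else np.nan
    return elong, flat


def max_pairwise_distance(points):
    pts = np.asarray(points, float)
    best = 0.0
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            best = max(best, float(np.linalg.norm(pts[i] - pts[j])))
    return best


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def anova_f_by_hand(groups):
    all_vals = [v for g in groups for v in g]
    grand = sum(all_vals) / len(all_vals)
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum(sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups)
    df1 = len(groups) - 1
    df2 = len(all_vals) - len(groups)
    return (ssb / df1) / (ssw / df2)


def random_blob_mask(rng, shape=(8, 8, 8), p=0.5):
    """Connected random mask: a dilated random walk inside ``shape``."""
    mask = np.zeros(shape, bool)
    pos = np.array([s // 2 for s in shape])
    mask[tuple(pos)] = True
    for _ in range(int(np.prod(shape) * p)):
        step = rng.integers(-1, 2, 3)
        pos = np.clip(pos + step, 0, np.array(shape) - 1)
        mask[tuple(pos)] = True
    return mask
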