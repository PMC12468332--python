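"""The 25-feature radiomic vector computed per ROI.

Four shape descriptors, seven first-order intensity statistics, nine
gray-level co-occurrence (GLCM) features and five neighborhood gray-tone
difference (NGTDM) features, following the standard radiomics (IBSI-style)
definitions. Intensities are quantized with a fixed bin number of 64 over
the ROI min-max range, which makes every texture feature invariant to global
affine intensity rescaling.

Conventions fixed here: GLCM distance 1 voxel over the 13 unique 3D
directions, symmetrized and normalized per direction with features averaged
across directions; NGTDM neighborhoods are the in-mask 26-neighbors;
kurtosis is uncorrected (normal -> 3).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

N_BINS = 64
EPS = 1e-6

#: Report order of the feature vector: (category, name).
FEATURE_ORDER = [
    ("Shape", "Solidity"), ("Shape", "Sphericity"),
    ("Shape", "Elongation"), ("Shape", "Flatness"),
    ("First-order", "Mean"), ("First-order", "Median"),
    ("First-order", "Variance"), ("First-order", "Entropy"),
    ("First-order", "Skewness"), ("First-order", "Kurtosis"),
    ("First-order", "Uniformity"),
    ("GLCM", "Autocorrelation"), ("GLCM", "Contrast"),
    ("GLCM", "Correlation"), ("GLCM", "Difference Average"),
    ("GLCM", "Inverse Difference"), ("GLCM", "Joint Average"),
    ("GLCM", "Joint Energy"), ("GLCM", "Joint Entropy"),
    ("GLCM", "Sum of Squares"),
    ("NGTDM", "Coarseness"), ("NGTDM", "Contrast"), ("NGTDM", "Busyness"),
    ("NGTDM", "Complexity"), ("NGTDM", "Strength"),
]

#: 13 unique 3D direction offsets at distance 1 (half of the 26 neighbors).
GLCM_OFFSETS = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
    (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]


# ---------------------------------------------------------------------------
# Quantization
# ---------------------------------------------------------------------------

def quantize(intensities: np.ndarray, n_bins: int = N_BINS) -> np.ndarray:
    """Map ROI intensities to gray levels 1..n_bins (fixed bin number).

    Bins are equal-width over [min, max] of the ROI intensities; a constant
    ROI maps entirely to level 1.
    """
    x = np.asarray(intensities, float)
    if x.size == 0:
        raise ValueError("empty ROI")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite ROI intensities")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.ones(x.shape, np.int64)
    lev = np.floor((x - lo) / (hi - lo) * n_bins).astype(np.int64) + 1
    return np.clip(lev, 1, n_bins)


# ---------------------------------------------------------------------------
# First-order
# ---------------------------------------------------------------------------

def first_order_features(intensities: np.ndarray, n_bins: int = N_BINS) -> dict:
    """Mean, median, variance on raw intensities; entropy/uniformity on the
    64-bin histogram; standardized skewness and (uncorrected) kurtosis.

    A single-voxel ROI gets variance 0 and NaN skewness/kurtosis.
    """
    x = np.asarray(intensities, float).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")
    out = {"Mean": float(x.mean()), "Median": float(np.median(x)),
           "Variance": float(x.var())}
    lev = quantize(x, n_bins)
    p = np.bincount(lev, minlength=n_bins + 1)[1:].astype(float)
    p /= p.sum()
    nz = p > 0
    out["Entropy"] = float(-np.sum(p[nz] * np.log2(p[nz])) + 0.0)
    out["Uniformity"] = float(np.sum(p ** 2))
    m2 = np.mean((x - x.mean()) ** 2)
    if m2 <= 0:
        out["Skewness"] = np.nan if x.size < 2 else 0.0
        out["Kurtosis"] = np.nan if x.size < 2 else 0.0
        if x.size >= 2:  # constant multi-voxel ROI: moments degenerate
            out["Skewness"] = np.nan
            out["Kurtosis"] = np.nan
    else:
        m3 = np.mean((x - x.mean()) ** 3)
        m4 = np.mean((x - x.mean()) ** 4)
        out["Skewness"] = float(m3 / m2 ** 1.5)
        out["Kurtosis"] = float(m4 / m2 ** 2)
    return out


# ---------------------------------------------------------------------------
# Shape
# ---------------------------------------------------------------------------

def _hull_voxel_count(idx: np.ndarray, shape) -> int:
    """Lattice voxels whose centers lie in the convex hull of ``idx``."""
    from scipy.spatial import ConvexHull, QhullError
    try:
        hull = ConvexHull(idx.astype(float))
    except QhullError:
        return len(np.unique(idx, axis=0))  # degenerate: flat mask
    grid = np.argwhere(np.ones(shape, bool)).astype(float)
    ok = np.all(grid @ hull.equations[:, :3].T
                + hull.equations[:, 3] <= 1e-9, axis=1)
    return int(ok.sum())


def shape_features(mask: np.ndarray, spacing_mm: float = 2.0) -> dict:
    """Solidity, sphericity, elongation and flatness of a voxel mask.

    solidity = voxel count / convex-hull voxel count; sphericity =
    (36 pi V^2)^(1/3) / A with A the marching-cubes mesh area; elongation =
    sqrt(l2/l1) and flatness = sqrt(l3/l1) from the ordered eigenvalues of
    the voxel-center covariance. Coplanar masks get NaN flatness.
    """
    mask = np.asarray(mask, bool)
    idx = np.argwhere(mask)
    if len(idx) == 0:
        raise ValueError("empty mask")
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    sub = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    sub_idx = np.argwhere(sub)

    sol = float(sub.sum()) / max(_hull_voxel_count(sub_idx, sub.shape), 1)

    from skimage.measure import marching_cubes, mesh_surface_area
    padded = np.pad(sub, 1).astype(float)
    verts, faces, _, _ = marching_cubes(padded, level=0.5,
                                        spacing=(spacing_mm,) * 3)
    area = float(mesh_surface_area(verts, faces))
    volume = float(mask.sum()) * spacing_mm ** 3
    spher = float((36.0 * np.pi * volume ** 2) ** (1.0 / 3.0) / area)

    pts = idx * spacing_mm
    if len(pts) < 2:
        elong, flat = np.nan, np.nan
    else:
        cov = np.cov(pts.T, bias=True)
        lam = np.sort(np.linalg.eigvalsh(cov))[::-1]
        lam = np.clip(lam, 0.0, None)
        if lam[0] <= 0:
            elong, flat = np.nan, np.nan
        else:
            elong = float(np.sqrt(lam[1] / lam[0]))
            flat = (float(np.sqrt(lam[2] / lam[0]))
                    if lam[2] > 1e-12 * lam[0] else np.nan)
    return {"Solidity": sol, "Sphericity": spher,
            "Elongation": elong, "Flatness": flat}


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def _glcm_matrix(levels: np.ndarray, mask: np.ndarray, offset,
                 n_bins: int) -> np.ndarray | None:
    """Symmetrized, normalized co-occurrence matrix for one direction."""
    dz = np.array(offset)
    sl_a = tuple(slice(max(0, -d), levels.shape[k] - max(0, d))
                 for k, d in enumerate(dz))
    sl_b = tuple(slice(max(0, d), levels.shape[k] + min(0, d) or None)
                 for k, d in enumerate(dz))
    a = levels[sl_a]
    b = levels[sl_b]
    valid = mask[sl_a] & mask[sl_b]
    if not valid.any():
        return None
    i = a[valid] - 1
    j = b[valid] - 1
    P = np.zeros((n_bins, n_bins))
    np.add.at(P, (i, j), 1.0)
    P = P + P.T
    return P / P.sum()


def _glcm_direction_features(P: np.ndarray) -> dict:
    n = P.shape[0]
    i = np.arange(1, n + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu = float(np.sum(i * px))
    sig = np.sqrt(np.sum((i - mu) ** 2 * px))
    nz = P > 0
    diff = np.abs(ii - jj)
    pd = np.array([P[diff == k].sum() for k in range(n)])
    if sig > 0:
        corr = float(np.sum((ii - mu) * (jj - mu) * P) / sig ** 2)
    else:
        corr = 1.0
    return {
        "Autocorrelation": float(np.sum(ii * jj * P)),
        "Contrast": float(np.sum((ii - jj) ** 2 * P)),
        "Correlation": corr,
        "Difference Average": float(np.sum(np.arange(n) * pd)),
        "Inverse Difference": float(np.sum(P / (1.0 + diff))),
        "Joint Average": mu,
        "Joint Energy": float(np.sum(P ** 2)),
        "Joint Entropy": float(-np.sum(P[nz] * np.log2(P[nz]))),
        "Sum of Squares": float(np.sum((ii - mu) ** 2 * P)),
    }


def glcm_features(levels: np.ndarray, mask: np.ndarray,
                  n_bins: int = N_BINS) -> dict:
    """Nine GLCM features, averaged over the 13 symmetric 3D directions."""
    per_dir = []
    for off in GLCM_OFFSETS:
        P = _glcm_matrix(levels, mask, off, n_bins)
        if P is not None:
            per_dir.append(_glcm_direction_features(P))
    keys = ["Autocorrelation", "Contrast", "Correlation", "Difference Average",
            "Inverse Difference", "Joint Average", "Joint Energy",
            "Joint Entropy", "Sum of Squares"]
    if not per_dir:
        return {k: np.nan for k in keys}
    return {k: float(np.mean([d[k] for d in per_dir])) for k in keys}


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def ngtdm_features(levels: np.ndarray, mask: np.ndarray,
                   n_bins: int = N_BINS, eps: float = EPS) -> dict:
    """Coarseness, contrast, busyness, complexity, strength.

    For each voxel with at least one in-mask 26-neighbor, the absolute
    difference between its level and the mean level of those neighbors
    accumulates into the per-level sums s_i; the five summary statistics
    follow the standard neighborhood gray-tone difference definitions with
    an epsilon guard of 1e-6 on the coarseness and strength denominators.
    """
    keys = ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"]
    mask = np.asarray(mask, bool)
    if mask.sum() < 2:
        return {k: np.nan for k in keys}
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    lv = np.where(mask, levels, 0).astype(float)
    nb_sum = ndimage.convolve(lv, kernel, mode="constant")
    nb_cnt = ndimage.convolve(mask.astype(float), kernel, mode="constant")
    valid = mask & (nb_cnt > 0)
    if not valid.any():
        return {k: np.nan for k in keys}
    diffs = np.abs(levels[valid] - nb_sum[valid] / nb_cnt[valid])
    lv_valid = levels[valid]
    n_vc = int(valid.sum())
    present = np.unique(lv_valid)
    n_i = np.array([(lv_valid == g).sum() for g in present], float)
    s_i = np.array([diffs[lv_valid == g].sum() for g in present])
    p_i = n_i / n_vc
    g = present.astype(float)
    ngp = len(present)

    coarseness = 1.0 / (eps + float(np.sum(p_i * s_i)))
    if ngp > 1:
        gi, gj = np.meshgrid(g, g, indexing="ij")
        pi_, pj_ = np.meshgrid(p_i, p_i, indexing="ij")
        si_, sj_ = np.meshgrid(s_i, s_i, indexing="ij")
        contrast = (float(np.sum(pi_ * pj_ * (gi - gj) ** 2))
                    / (ngp * (ngp - 1)) * float(np.sum(s_i)) / n_vc)
        denom_b = float(np.sum(np.abs(gi * pi_ - gj * pj_)
                               * (1 - np.eye(ngp))))
        busyness = float(np.sum(p_i * s_i)) / denom_b if denom_b > 0 else 0.0
        complexity = float(np.sum(np.abs(gi - gj) * (pi_ * si_ + pj_ * sj_)
                                  / (pi_ + pj_))) / n_vc
        strength = (float(np.sum((pi_ + pj_) * (gi - gj) ** 2
                                 * (1 - np.eye(ngp))))
                    / (eps + float(np.sum(s_i))))
    else:
        contrast = busyness = complexity = strength = 0.0
    return {"Coarseness": coarseness, "Contrast": contrast,
            "Busyness": busyness, "Complexity": complexity,
            "Strength": strength}


# ---------------------------------------------------------------------------
# Full vector
# ---------------------------------------------------------------------------

def feature_vector(data: np.ndarray, mask: np.ndarray,
                   spacing_mm: float = 2.0, n_bins: int = N_BINS) -> dict:
    """All 25 features of an ROI, keyed '<Category> <Name>' in report order."""
    mask = np.asarray(mask, bool)
    vals = np.asarray(data, float)[mask]
    levels_roi = quantize(vals, n_bins)
    levels = np.zeros(mask.shape, np.int64)
    levels[mask] = levels_roi
    out = {}
    shp = shape_features(mask, spacing_mm)
    fo = first_order_features(vals, n_bins)
    gl = glcm_features(levels, mask, n_bins)
    ng = ngtdm_features(levels, mask, n_bins)
    for cat, name in FEATURE_ORDER:
        src = {"Shape": shp, "First-order": fo, "GLCM": gl, "NGTDM": ng}[cat]
        out[f"{cat} {name}"] = src[name]
    return out
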