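"""Region-of-interest extraction and validation from reconstructed volumes.

Candidate blobs are segmented by Otsu thresholding over in-breast voxels and
light morphology, then validated by persistence across the pc_fib range
volumes, structural (volume and solidity) filters and an intensity-contrast
filter. SNR, CNR, volume and maximal linear dimension are computed per
validated ROI.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import ball

from .imaging import VolumeImage

VOXEL_ML = 0.008  # 2 mm isotropic voxel in mL

MIN_VOLUME_ML = 0.25
MIN_SOLIDITY = 0.3
MIN_CNR = 2.0
PERSISTENCE_RADIUS_MM = 5.0
PERSISTENCE_QUORUM = 6


class ROILabel(enum.Enum):
    CLINICAL = "clinical"
    SCAR = "scar"
    ARTIFACT_1 = "artifact_1"
    ARTIFACT_2 = "artifact_2"
    ARTIFACT_3 = "artifact_3"
    ARTIFACT_4 = "artifact_4"
    UNSPECIFIED = "unspecified"


@dataclass
class Candidate:
    mask: np.ndarray            # boolean, volume shape
    centroid_mm: np.ndarray
    n_voxels: int


@dataclass
class ROIRecord:
    mask: np.ndarray
    centroid_mm: np.ndarray
    volume_ml: float
    max_linear_dimension_mm: float
    snr: float
    cnr: float
    mean_intensity: float
    median_intensity: float
    label: ROILabel = ROILabel.UNSPECIFIED
    persistence: int = 0
    meta: dict = field(default_factory=dict)


def _centroid_mm(mask: np.ndarray, vol: VolumeImage) -> np.ndarray:
    idx = np.argwhere(mask)
    return np.array([vol.grid_x[idx[:, 0]].mean(),
                     vol.grid_y[idx[:, 1]].mean(),
                     vol.z_planes[idx[:, 2]].mean()])


def segment_candidates(vol: VolumeImage,
                       threshold_quantile: float | None = None) -> list[Candidate]:
    """Threshold + morphology + 26-connected components.

    The threshold is the Otsu level of the in-breast (below-cut-out) voxel
    intensities; ``threshold_quantile`` overrides it with a fixed quantile.
    Morphological opening then closing with a 1-voxel ball removes speckle
    and heals pinholes.
    """
    region = vol.mask & ~vol.excluded_z[None, None, :]
    vals = vol.data[region]
    if vals.size == 0 or vals.max() <= 0:
        warnings.warn("empty in-breast region; no candidates")
        return []
    if threshold_quantile is not None:
        thr = float(np.quantile(vals, threshold_quantile))
    else:
        try:
            thr = float(threshold_otsu(vals))
        except ValueError:  # constant image
            warnings.warn("constant in-breast intensity; no candidates")
            return []
    binary = (vol.data > thr) & region
    se = ball(1)
    if vol.data.shape[2] < 3:  # too thin for 3D opening: in-plane disk
        se = ball(1)[:, :, 1:2]
    binary = ndimage.binary_opening(binary, se)
    binary = ndimage.binary_closing(binary, se)
    labels = cc_label(binary, connectivity=3)
    out = []
    for lb in range(1, labels.max() + 1):
        m = labels == lb
        out.append(Candidate(mask=m, centroid_mm=_centroid_mm(m, vol),
                             n_voxels=int(m.sum())))
    out.sort(key=lambda c: -c.n_voxels)
    return out


def persistence_filter(analysis_candidates: list[Candidate],
                       per_range_candidates: list[list[Candidate]],
                       r_match_mm: float = PERSISTENCE_RADIUS_MM,
                       quorum: int = PERSISTENCE_QUORUM) -> list[tuple[Candidate, int]]:
    """Keep analysis-volume candidates persistent across the range volumes.

    A candidate is persistent when a candidate with centroid within
    ``r_match_mm`` exists in at least ``quorum`` of the range-volume
    candidate sets; returns (candidate, persistence count) pairs.
    """
    kept = []
    for cand in analysis_candidates:
        count = 0
        for cands in per_range_candidates:
            if any(np.linalg.norm(c.centroid_mm - cand.centroid_mm) <= r_match_mm
                   for c in cands):
                count += 1
        if count >= quorum:
            kept.append((cand, count))
    return kept


def solidity(mask: np.ndarray) -> float:
    """Voxel count over convex-hull voxel count (voxel centers in the hull)."""
    from .radiomics import _hull_voxel_count
    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    sub = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    return float(sub.sum()) / max(_hull_voxel_count(np.argwhere(sub), sub.shape), 1)


def roi_metrics(mask: np.ndarray, vol: VolumeImage,
                other_masks: list[np.ndarray] = (),
                dilate_voxels: int = 2):
    """SNR, CNR, maximal linear dimension (mm) and volume (mL) of an ROI.

    Background = in-breast voxels outside every ROI mask dilated by
    ``dilate_voxels``; SNR = mean(ROI)/std(bg); CNR = (mean(ROI) -
    mean(bg))/std(bg); max linear dimension is the center-to-center max
    pairwise voxel distance.
    """
    region = vol.mask & ~vol.excluded_z[None, None, :]
    excl = mask.copy()
    for m in other_masks:
        excl |= m
    excl = ndimage.binary_dilation(excl, ball(1), iterations=dilate_voxels)
    bg = region & ~excl
    if not bg.any():
        raise ValueError("empty background region for SNR/CNR")
    bg_vals = vol.data[bg]
    roi_vals = vol.data[mask]
    std = float(bg_vals.std())
    if std <= 0:
        raise ValueError("degenerate background (zero variance)")
    snr = float(roi_vals.mean() / std)
    cnr = float((roi_vals.mean() - bg_vals.mean()) / std)
    idx = np.argwhere(mask)
    pts = np.column_stack([vol.grid_x[idx[:, 0]], vol.grid_y[idx[:, 1]],
                           vol.z_planes[idx[:, 2]]])
    if len(pts) == 1:
        mld = 0.0
    else:
        try:
            from scipy.spatial import ConvexHull
            hp = pts[ConvexHull(pts).vertices] if len(pts) > 4 else pts
        except Exception:
            hp = pts
        d2 = np.sum((hp[:, None, :] - hp[None, :, :]) ** 2, axis=-1)
        mld = float(np.sqrt(d2.max()))
    return snr, cnr, mld, float(mask.sum()) * VOXEL_ML


def structural_filter(candidates: list[tuple[Candidate, int]],
                      vol: VolumeImage,
                      min_volume_ml: float = MIN_VOLUME_ML,
                      min_solidity: float = MIN_SOLIDITY,
                      min_cnr: float = MIN_CNR,
                      reject_log: list | None = None) -> list[ROIRecord]:
    """Validate persistent candidates by volume, solidity and CNR thresholds."""
    all_masks = [c.mask for c, _ in candidates]
    out = []
    for k, (cand, persistence) in enumerate(candidates):
        others = [m for i, m in enumerate(all_masks) if i != k]
        vol_ml = cand.n_voxels * VOXEL_ML
        if vol_ml < min_volume_ml:
            if reject_log is not None:
                reject_log.append({"centroid": cand.centroid_mm.tolist(),
                                   "reason": "volume", "value": vol_ml})
            continue
        sol = solidity(cand.mask)
        if sol < min_solidity:
            if reject_log is not None:
                reject_log.append({"centroid": cand.centroid_mm.tolist(),
                                   "reason": "solidity", "value": sol})
            continue
        snr, cnr, mld, vml = roi_metrics(cand.mask, vol, others)
        if cnr < min_cnr:
            if reject_log is not None:
                reject_log.append({"centroid": cand.centroid_mm.tolist(),
                                   "reason": "contrast", "value": cnr})
            continue
        roi_vals = vol.data[cand.mask]
        out.append(ROIRecord(mask=cand.mask, centroid_mm=cand.centroid_mm,
                             volume_ml=vml, max_linear_dimension_mm=mld,
                             snr=snr, cnr=cnr,
                             mean_intensity=float(roi_vals.mean()),
                             median_intensity=float(np.median(roi_vals)),
                             persistence=persistence,
                             meta={"solidity": sol}))
    return out


def extract_rois(analysis_volume: VolumeImage,
                 range_volumes: dict | None = None,
                 min_volume_ml: float = MIN_VOLUME_ML,
                 min_solidity: float = MIN_SOLIDITY,
                 min_cnr: float = MIN_CNR,
                 r_match_mm: float = PERSISTENCE_RADIUS_MM,
                 quorum: int | None = None,
                 threshold_quantile: float | None = None,
                 reject_log: list | None = None) -> list[ROIRecord]:
    """Full ROI chain on the designated analysis volume (default GLOBAL).

    When ``range_volumes`` is given, persistence across them is required;
    the quorum defaults to ceil(6/11 of the range count).
    """
    cands = segment_candidates(analysis_volume, threshold_quantile)
    if range_volumes:
        per_range = [segment_candidates(v, threshold_quantile)
                     for v in range_volumes.values()]
        if quorum is None:
            quorum = max(1, int(np.ceil(len(per_range) * PERSISTENCE_QUORUM / 11)))
        pairs = persistence_filter(cands, per_range, r_match_mm, quorum)
    else:
        pairs = [(c, 0) for c in cands]
    return structural_filter(pairs, analysis_volume, min_volume_ml,
                             min_solidity, min_cnr, reject_log)


def label_volume(rois: list[ROIRecord], vol: VolumeImage) -> VolumeImage:
    """Integer label map of the validated ROIs on the volume lattice."""
    lab = np.zeros(vol.data.shape, np.int16)
    for i, roi in enumerate(rois, 1):
        lab[roi.mask] = i
    return VolumeImage(data=lab, grid_x=vol.grid_x, grid_y=vol.grid_y,
                       z_planes=vol.z_planes, mask=vol.mask,
                       excluded_z=vol.excluded_z.copy(),
                       provenance={"kind": "roi_labels"})
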