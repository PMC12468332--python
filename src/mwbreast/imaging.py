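"""Sectorized wideband TR-MUSIC reconstruction under parametric pc_fib.

Per coronal slice, 8-probe sub-arrays are slid around the 21-probe ring (21
sectors); each sector's multistatic matrix is decomposed per frequency by
SVD, and the MUSIC pseudospectrum is evaluated on the slice lattice with
two-media straight-ray steering vectors parameterized by the assumed
fibroglandular fraction pc_fib. The best pc_fib within a search range is
picked per sector by a focus-quality score, the 21 partial images are
stitched with a raised-cosine angular taper, slices are stacked into a 3D
volume, and the 11-range volume set is averaged into GLOBAL / LOW / HIGH
composite images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import (MediumModel, ProbeArray, RadialEnvelope,
                       BreastEnvelope, GeometryError, lattice_centers,
                       ray_path_split_many)
from .forward import ScanData, complex_wavenumber
from .preprocess import (Mode, SectorPreprocessResult, preprocess_sector,
                         subarray_probes)

#: The 11 pc_fib search ranges (percent), as scanned clinically.
PCFIB_RANGES: tuple[tuple[int, int], ...] = (
    (10, 30), (20, 40), (30, 50), (40, 60), (50, 70), (60, 80), (70, 90),
    (20, 50), (50, 80), (10, 60), (40, 90),
)

PCFIB_STEP = 5  # percentage points between candidate assumptions in a range

SECTOR_MARGIN_DEG = 10.0


class ImagingConfigError(ValueError):
    pass


def low_ranges(ranges=PCFIB_RANGES):
    """Ranges lying entirely at pc_fib <= 50%."""
    return tuple(r for r in ranges if r[1] <= 50)


def high_ranges(ranges=PCFIB_RANGES):
    """Ranges lying entirely at pc_fib >= 50%."""
    return tuple(r for r in ranges if r[0] >= 50)


def pcfib_candidates(rng: tuple[int, int], step: int = PCFIB_STEP) -> np.ndarray:
    lo, hi = rng
    if not (0 <= lo < hi <= 100):
        raise ImagingConfigError(f"bad pc_fib range {rng}")
    return np.arange(lo, hi + 1, step)


def form_subarray(array: ProbeArray, center_index: int) -> np.ndarray:
    """8 contiguous probe indices centered at ``center_index`` (wrap mod 21)."""
    if not 0 <= center_index < array.n_probes:
        raise ImagingConfigError("center index out of range")
    return subarray_probes(center_index, array.n_probes)


# ---------------------------------------------------------------------------
# Sector images
# ---------------------------------------------------------------------------

@dataclass
class SectorImage:
    """Nonnegative pseudospectrum restricted to one sector wedge."""

    values: np.ndarray          # (ny, nx), zero outside wedge & mask
    weight: np.ndarray          # (ny, nx) angular taper weight in [0, 1]
    pc_fib: float
    score: float = 0.0


def sector_taper(grid_x: np.ndarray, grid_y: np.ndarray, center_index: int,
                 n_probes: int = 21,
                 margin_deg: float = SECTOR_MARGIN_DEG) -> np.ndarray:
    """Raised-cosine angular weight of the sector wedge on the slice grid.

    The wedge spans the 8-probe arc (weight 1) plus a ``margin_deg`` cosine
    taper on each side.
    """
    theta_c = 2 * np.pi / n_probes * (center_index + 0.5)
    half_arc = 3.5 * 2 * np.pi / n_probes
    margin = np.deg2rad(margin_deg)
    xx, yy = np.meshgrid(grid_x, grid_y, indexing="xy")
    dtheta = np.abs(np.angle(np.exp(1j * (np.arctan2(yy, xx) - theta_c))))
    w = np.zeros_like(dtheta)
    w[dtheta <= half_arc] = 1.0
    tr = (dtheta > half_arc) & (dtheta <= half_arc + margin)
    w[tr] = 0.5 * (1 + np.cos(np.pi * (dtheta[tr] - half_arc) / margin))
    return w


def signal_rank(s: np.ndarray, max_rank: int = 4) -> int:
    """Signal-subspace rank from the largest relative singular-value gap."""
    s = np.asarray(s, float)
    if s[0] <= 0:
        return 0
    ratios = s[:-1] / np.maximum(s[1:], 1e-300)
    k = int(np.argmax(ratios[: max_rank])) + 1
    return min(k, max_rank)


def music_pseudospectrum(matrices: np.ndarray, steering: np.ndarray,
                         max_rank: int = 4) -> np.ndarray:
    """Wideband MUSIC image from per-frequency matrices and steering vectors.

    Parameters
    ----------
    matrices : (n_freq, m, m) complex
        Multistatic data matrix per frequency.
    steering : (n_freq, m, n_pix) complex
        Steering vectors; normalized to unit norm internally.

    Returns
    -------
    (n_pix,) image: mean over frequencies of per-frequency unit-max
    pseudospectra ``P(r) = 1 / sum_noise |<u_k, g(r)>|^2``, computed through
    the signal-subspace complement.
    """
    n_f, m, n_pix = steering.shape
    if np.allclose(matrices, 0):
        warnings.warn("all-zero data matrix; returning uniform image")
        return np.ones(n_pix)
    out = np.zeros(n_pix)
    n_used = 0
    for fi in range(n_f):
        M = matrices[fi]
        if not np.any(M):
            continue
        u, s, _ = np.linalg.svd(M)
        r = signal_rank(s, max_rank)
        if r == 0:
            continue
        A = steering[fi]
        A = A / np.linalg.norm(A, axis=0, keepdims=True)
        proj = u[:, :r].conj().T @ A             # (r, n_pix)
        noise_power = 1.0 - np.sum(np.abs(proj) ** 2, axis=0)
        p = 1.0 / np.clip(noise_power, 1e-12, None)
        out += p / p.max()
        n_used += 1
    return out / max(n_used, 1)


@dataclass
class SliceGeometry:
    """Precomputed lattice, mask and two-media path splits for one slice."""

    z: float
    grid_x: np.ndarray
    grid_y: np.ndarray
    mask: np.ndarray            # (ny, nx) in-breast mask
    d_out: np.ndarray           # (n_probes, n_pix) mm, transition-liquid leg
    d_in: np.ndarray            # (n_probes, n_pix) mm, in-breast leg
    pix_index: np.ndarray       # flat indices of mask pixels into (ny, nx)

    @classmethod
    def build(cls, envelope: BreastEnvelope, array: ProbeArray, z: float,
              grid_n: int = 64) -> "SliceGeometry":
        gx = lattice_centers(grid_n)
        gy = lattice_centers(grid_n)
        xx, yy = np.meshgrid(gx, gy, indexing="xy")
        pts = np.column_stack([xx.ravel(), yy.ravel(),
                               np.full(xx.size, z)])
        mask = envelope.inside(pts).reshape(grid_n, grid_n)
        pix = np.nonzero(mask.ravel())[0]
        tgts = pts[pix]
        probe_xy = array.probe_xy()
        n_p = array.n_probes
        d_out = np.empty((n_p, len(pix)))
        d_in = np.empty((n_p, len(pix)))
        for p in range(n_p):
            src = np.array([probe_xy[p, 0], probe_xy[p, 1], z])
            d_out[p], d_in[p] = ray_path_split_many(src, tgts, envelope)
        return cls(z=z, grid_x=gx, grid_y=gy, mask=mask,
                   d_out=d_out, d_in=d_in, pix_index=pix)

    def steering(self, pc_fib: float, freqs: np.ndarray,
                 media: MediumModel) -> np.ndarray:
        """(n_freq, n_probes, n_pix) two-media steering vectors (unnormalized).

        Amplitude = exp(-alpha * d) / d (matching the forward Green factor),
        phase from the per-medium propagation constants.
        """
        g_t = complex_wavenumber(freqs, media.transition)
        g_in = complex_wavenumber(freqs, media.interior(pc_fib))
        d_tot = np.clip(self.d_out + self.d_in, 1e-6, None) / 1000.0
        phase = (g_t[:, None, None] * self.d_out[None] / 1000.0
                 + g_in[:, None, None] * self.d_in[None] / 1000.0)
        return np.exp(-phase) / d_tot[None]


def trmusic_sector(cleaned: np.ndarray, freqs: np.ndarray,
                   geom: SliceGeometry, center_index: int,
                   probes: np.ndarray, pc_fib: float,
                   media: MediumModel, max_rank: int = 4,
                   steering_cache: dict | None = None) -> SectorImage:
    """TR-MUSIC partial image of one azimuthal sector.

    ``cleaned`` is the preprocessed (8, 8, n_freq) sub-array matrix (zero
    monostatic diagonal); ``pc_fib`` parameterizes the in-breast leg of the
    steering model. The result is restricted to the sector wedge.
    """
    if not 0.0 <= pc_fib <= 1.0:
        raise GeometryError("pc_fib must be in [0,1]")
    if steering_cache is not None and pc_fib in steering_cache:
        A_full = steering_cache[pc_fib]
    else:
        A_full = geom.steering(pc_fib, freqs, media)
        if steering_cache is not None:
            steering_cache[pc_fib] = A_full
    ny, nx = geom.mask.shape
    taper = sector_taper(geom.grid_x, geom.grid_y, center_index)
    wedge = (taper.ravel()[geom.pix_index] > 0)
    img = np.zeros(ny * nx)
    if wedge.any():
        A = A_full[:, probes][:, :, wedge]
        M = np.moveaxis(cleaned, 2, 0)  # (n_freq, 8, 8)
        vals = music_pseudospectrum(M, A, max_rank)
        img[geom.pix_index[wedge]] = vals
    si = SectorImage(values=img.reshape(ny, nx), weight=taper * geom.mask,
                     pc_fib=pc_fib)
    si.score = focus_quality(si)
    return si


def focus_quality(image: SectorImage | np.ndarray) -> float:
    """Peak-to-mean sharpness of a nonnegative sector image.

    Invariant to global intensity scaling; 1 for a uniform image, 0 for an
    all-zero image; maximal for a single-pixel impulse on fixed support.
    """
    vals = image.values if isinstance(image, SectorImage) else np.asarray(image)
    support = vals > 0
    if isinstance(image, SectorImage):
        support = image.weight > 0
    if not support.any():
        return 0.0
    v = vals[support]
    m = v.mean()
    if m <= 0:
        return 0.0
    return float(v.max() / m)


def select_pcfib(candidates: list[SectorImage],
                 rng: tuple[float, float] | None = None) -> SectorImage:
    """Best-focused candidate assumption; ties broken toward the range midpoint."""
    if not candidates:
        raise ImagingConfigError("empty candidate list")
    if rng is None:
        pcs = [c.pc_fib for c in candidates]
        rng = (min(pcs), max(pcs))
    mid = 0.5 * (rng[0] + rng[1]) / (100.0 if rng[1] > 1 else 1.0)
    best_score = max(c.score for c in candidates)
    contenders = [c for c in candidates if c.score >= best_score * (1 - 1e-12)]
    return min(contenders, key=lambda c: abs(c.pc_fib - mid))


def stitch_sectors(sectors: list[SectorImage],
                   mask: np.ndarray | None = None) -> np.ndarray:
    """Combine sector images into one slice by taper-weighted averaging.

    Each sector is normalized to unit max before averaging; weights are
    renormalized to sum to 1 at every covered pixel (all-zero sectors are
    excluded). Raises when covered-mask pixels are reached by no sector.
    """
    num = None
    den = None
    for s in sectors:
        vmax = s.values.max()
        if vmax <= 0:
            continue
        v = s.values / vmax
        if num is None:
            num = np.zeros_like(v)
            den = np.zeros_like(v)
        num += s.weight * v
        den += s.weight
    if num is None:
        return np.zeros_like(sectors[0].values)
    if mask is not None:
        uncovered = mask & (den <= 0)
        if uncovered.any():
            pix = np.argwhere(uncovered)[:5]
            raise ImagingConfigError(
                f"sector coverage gap at pixels {pix.tolist()} (and possibly more)")
    out = np.zeros_like(num)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

@dataclass
class VolumeImage:
    """Nonnegative 3D intensity grid on the 2 mm lattice.

    ``data`` is indexed (x, y, z); ``z_planes`` ascending. Slices flagged by
    the cut-out rule are zeroed and marked in ``excluded_z``.
    """

    data: np.ndarray
    grid_x: np.ndarray
    grid_y: np.ndarray
    z_planes: np.ndarray
    mask: np.ndarray
    excluded_z: np.ndarray = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.excluded_z is None:
            self.excluded_z = np.zeros(len(self.z_planes), bool)

    @property
    def voxel_volume_ml(self) -> float:
        return 0.008

    def affine(self) -> np.ndarray:
        aff = np.diag([2.0, 2.0, 2.0, 1.0])
        aff[:3, 3] = [self.grid_x[0], self.grid_y[0], self.z_planes[0]]
        return aff

    def to_nifti(self):
        import nibabel as nib
        return nib.Nifti1Image(self.data.astype(np.float32), self.affine())

    def save(self, path) -> None:
        import nibabel as nib
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path, mask_threshold: float = 0.0) -> "VolumeImage":
        """Read an externally produced volume (2 mm lattice expected).

        The breast mask defaults to strictly positive voxels; the affine's
        translation recovers the lattice coordinates.
        """
        import nibabel as nib
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, float)
        aff = img.affine
        if not np.allclose(np.abs(np.diag(aff)[:3]), 2.0):
            raise ImagingConfigError("expected a 2 mm isotropic lattice")
        gx = aff[0, 3] + 2.0 * np.arange(data.shape[0])
        gy = aff[1, 3] + 2.0 * np.arange(data.shape[1])
        gz = aff[2, 3] + 2.0 * np.arange(data.shape[2])
        return cls(data=data, grid_x=gx, grid_y=gy, z_planes=gz,
                   mask=data > mask_threshold,
                   provenance={"source": str(path)})


def stack_slices(slice_images: dict[float, np.ndarray], mask_2d_by_z: dict,
                 grid_x: np.ndarray, grid_y: np.ndarray,
                 cutout_index: int | None = None,
                 z_ordered: np.ndarray | None = None,
                 provenance: dict | None = None) -> VolumeImage:
    """Stack +/-2 mm coronal slabs into a volume with triangular z-weights.

    Volume planes sit on the odd-mm lattice between/around the even-mm scan
    heights; each plane is the triangular-weighted average of the slabs
    covering it. Slices at or above the cut-out index are zeroed and flagged.
    """
    zs = np.array(sorted(slice_images)) if z_ordered is None else np.asarray(z_ordered, float)
    half = 2.0
    z_planes = np.arange(np.floor(zs.min() / 2) * 2 - 1, zs.max() + half, 2.0)
    z_planes = z_planes[(z_planes >= zs.min() - half) & (z_planes <= zs.max() + half)]
    nx, ny = len(grid_x), len(grid_y)
    data = np.zeros((nx, ny, len(z_planes)))
    mask3 = np.zeros((nx, ny, len(z_planes)), bool)
    excluded_z = np.zeros(len(z_planes), bool)
    cut_z = None
    if cutout_index is not None:
        scan_desc = np.sort(zs)[::-1]
        if cutout_index < len(scan_desc):
            cut_z = scan_desc[cutout_index]  # uppermost trusted height
    for k, zp in enumerate(z_planes):
        w = np.clip(1.0 - np.abs(zs - zp) / half, 0.0, None)
        if w.sum() <= 0:
            continue
        w = w / w.sum()
        plane = np.zeros((ny, nx))
        pmask = np.zeros((ny, nx), bool)
        for wi, z in zip(w, zs):
            if wi <= 0:
                continue
            plane += wi * slice_images[z]
            pmask |= mask_2d_by_z[z]
        if cut_z is not None and zp > cut_z:
            plane[:] = 0.0
            excluded_z[k] = True
        data[:, :, k] = plane.T  # (ny, nx) -> (x, y)
        mask3[:, :, k] = pmask.T
    return VolumeImage(data=data, grid_x=grid_x, grid_y=grid_y,
                       z_planes=z_planes, mask=mask3, excluded_z=excluded_z,
                       provenance=provenance or {})


def composite_images(volumes: dict[tuple[int, int], VolumeImage],
                     ranges=PCFIB_RANGES) -> dict[str, VolumeImage]:
    """GLOBAL / LOW / HIGH voxelwise-mean composites of the range volumes."""
    if set(volumes) != set(ranges):
        raise ImagingConfigError(
            f"expected volumes for ranges {ranges}, got {sorted(volumes)}")

    def mean_of(members, kind):
        ref = volumes[members[0]]
        data = np.mean([volumes[m].data for m in members], axis=0)
        return VolumeImage(data=data, grid_x=ref.grid_x, grid_y=ref.grid_y,
                           z_planes=ref.z_planes, mask=ref.mask,
                           excluded_z=ref.excluded_z.copy(),
                           provenance={"composite": kind,
                                       "members": list(members)})

    out = {"GLOBAL": mean_of(list(ranges), "GLOBAL")}
    lo = low_ranges(ranges)
    hi = high_ranges(ranges)
    if lo:
        out["LOW"] = mean_of(list(lo), "LOW")
    if hi:
        out["HIGH"] = mean_of(list(hi), "HIGH")
    return out


# ---------------------------------------------------------------------------
# Full reconstruction driver
# ---------------------------------------------------------------------------

@dataclass
class ReconstructionResult:
    range_volumes: dict[tuple[int, int], VolumeImage]
    composites: dict[str, VolumeImage]
    selections: dict  # (range, z, sector) -> selected pc_fib (percent)
    cutout_index: int | None


def reconstruct(scan: ScanData, envelope: RadialEnvelope, media: MediumModel,
                mode: Mode = Mode.DEFAULT,
                ranges=PCFIB_RANGES, step: int = PCFIB_STEP,
                grid_n: int = 64, max_rank: int = 4,
                pc_fib_ref: float = 0.5,
                calibration_ref: float | str | None = None,
                emd: bool = True,
                pca: bool = True,
                cutout_index: int | None = None,
                sectors: np.ndarray | None = None) -> ReconstructionResult:
    """Run the sectorized TR-MUSIC chain for every pc_fib search range.

    Per slice, sector data are preprocessed once, subspaces are shared across
    candidate assumptions, and sector images are cached per unique pc_fib
    value so overlapping ranges cost nothing extra.
    """
    array = scan.array
    n_probes = array.n_probes
    sector_centers = np.arange(n_probes) if sectors is None else np.asarray(sectors)
    probe_xy = array.probe_xy()
    cand_by_range = {r: pcfib_candidates(r, step) for r in ranges}
    for r, c in cand_by_range.items():
        if len(c) < 2:
            raise ImagingConfigError(f"range {r} yields fewer than 2 candidates")
    unique_pc = sorted({int(p) for c in cand_by_range.values() for p in c})

    slice_images: dict[tuple[int, int], dict[float, np.ndarray]] = {
        r: {} for r in ranges}
    mask_by_z: dict[float, np.ndarray] = {}
    selections: dict = {}

    for si, z in enumerate(array.z_positions):
        z = float(z)
        geom = SliceGeometry.build(envelope, array, z, grid_n)
        mask_by_z[z] = geom.mask
        steering_cache: dict = {}
        sector_imgs: dict[tuple[int, int], SectorImage] = {}
        pre: dict[int, SectorPreprocessResult] = {}
        for c in sector_centers:
            pre[c] = preprocess_sector(
                scan.data[si], scan.freqs, int(c), mode, envelope, probe_xy,
                z, media, pc_fib_ref=pc_fib_ref,
                calibration_ref=calibration_ref, emd=emd, pca=pca)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for c in sector_centers:
                for p in unique_pc:
                    sector_imgs[(int(c), p)] = trmusic_sector(
                        pre[c].cleaned, scan.freqs, geom, int(c),
                        pre[c].probes, p / 100.0, media, max_rank,
                        steering_cache)
        for r in ranges:
            chosen = []
            for c in sector_centers:
                cands = [sector_imgs[(int(c), int(p))] for p in cand_by_range[r]]
                best = select_pcfib(cands, r)
                selections[(r, z, int(c))] = int(round(best.pc_fib * 100))
                chosen.append(best)
            slice_images[r][z] = stitch_sectors(chosen)

    range_volumes = {}
    for r in ranges:
        range_volumes[r] = stack_slices(
            slice_images[r], mask_by_z,
            grid_x=lattice_centers(grid_n), grid_y=lattice_centers(grid_n),
            cutout_index=cutout_index,
            provenance={"pc_fib_range": r, "mode": mode.value})
    comps = composite_images(range_volumes, ranges)
    return ReconstructionResult(range_volumes=range_volumes, composites=comps,
                                selections=selections,
                                cutout_index=cutout_index)
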