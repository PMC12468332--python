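"""Scanner geometry, dispersive media, breast envelope and lesion ground truth.

The scanner is a ring of 21 wideband probes outside a cylindrical container
filled with a lossy transition liquid; the pendulous breast hangs through a
table aperture into the liquid and the ring steps vertically in 2 mm
increments, the uppermost scan plane sitting 24 mm below the table.

Coordinate convention (used everywhere in this package): right-handed, z
vertical with z = 0 at the table plane and negative downward; all lengths in
millimetres; the reconstruction lattice is 2 mm isotropic with in-plane voxel
centers at odd-millimetre coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

C0_MM_NS = 299.792458  # speed of light, mm/ns
C0_M_S = 299792458.0

N_PROBES = 21
Z_STEP_MM = 2.0
TOP_OFFSET_MM = 24.0


class GeometryError(ValueError):
    """Invalid scanner/phantom geometry."""


# ---------------------------------------------------------------------------
# Probe array
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeArray:
    """Circular multistatic probe ring scanned vertically in 2 mm steps."""

    ring_radius: float
    z_positions: np.ndarray  # descending, top slice first
    n_probes: int = N_PROBES
    top_offset: float = TOP_OFFSET_MM

    @property
    def angles(self) -> np.ndarray:
        """Probe azimuths in radians, equally spaced on the ring."""
        return 2.0 * np.pi * np.arange(self.n_probes) / self.n_probes

    def probe_xy(self) -> np.ndarray:
        """(n_probes, 2) probe positions in the scan plane."""
        a = self.angles
        return self.ring_radius * np.column_stack([np.cos(a), np.sin(a)])

    @property
    def n_slices(self) -> int:
        return len(self.z_positions)


def build_probe_array(ring_radius: float, z_min: float, z_max: float) -> ProbeArray:
    """Build the 21-probe ring with a 2 mm vertical scan grid.

    Parameters
    ----------
    ring_radius : float
        Radius of the probe circle in mm; must exceed the phantom radius.
    z_min, z_max : float
        Vertical scan extent in mm (negative, below the table plane).
        The topmost usable position is 24 mm below the table.
    """
    if ring_radius <= 0:
        raise GeometryError(f"ring radius must be positive, got {ring_radius}")
    if z_max <= z_min:
        raise GeometryError("z_max must exceed z_min")
    z_top = min(z_max, -TOP_OFFSET_MM)
    n = int(np.floor((z_top - z_min) / Z_STEP_MM)) + 1
    z = z_top - Z_STEP_MM * np.arange(n)
    return ProbeArray(ring_radius=float(ring_radius), z_positions=z)


# ---------------------------------------------------------------------------
# Dispersive media
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Medium:
    """Relative permittivity and loss tangent over the scan band.

    Scalars denote non-dispersive media; arrays must match the scan
    frequency grid.
    """

    eps_r: float | np.ndarray
    tan_delta: float | np.ndarray

    def __post_init__(self):
        if np.any(np.asarray(self.eps_r) < 1):
            raise GeometryError("relative permittivity must be >= 1")
        if np.any(np.asarray(self.tan_delta) < 0):
            raise GeometryError("loss tangent must be >= 0")


@dataclass(frozen=True)
class MediumModel:
    """Dielectric table for the transition liquid and breast tissues.

    Defaults are plausible wideband values for the 0.8-4.1 GHz window:
    the transition liquid is matched close to skin, fibroglandular tissue is
    both higher-permittivity and lossier than adipose tissue.
    """

    transition: Medium = field(default_factory=lambda: Medium(38.0, 0.18))
    adipose: Medium = field(default_factory=lambda: Medium(9.0, 0.13))
    fibroglandular: Medium = field(default_factory=lambda: Medium(42.0, 0.25))
    skin: Medium = field(default_factory=lambda: Medium(38.0, 0.25))

    def __post_init__(self):
        if np.any(np.asarray(self.fibroglandular.eps_r) < np.asarray(self.adipose.eps_r)):
            raise GeometryError("fibroglandular permittivity must dominate adipose")

    def interior(self, pc_fib: float) -> Medium:
        """Effective interior medium: pc_fib-weighted adipose/fibroglandular mix."""
        if not 0.0 <= pc_fib <= 1.0:
            raise GeometryError(f"pc_fib must be in [0,1], got {pc_fib}")
        eps = (pc_fib * np.asarray(self.fibroglandular.eps_r)
               + (1 - pc_fib) * np.asarray(self.adipose.eps_r))
        td = (pc_fib * np.asarray(self.fibroglandular.tan_delta)
              + (1 - pc_fib) * np.asarray(self.adipose.tan_delta))
        return Medium(eps if eps.ndim else float(eps), td if td.ndim else float(td))


# ---------------------------------------------------------------------------
# Breast envelope
# ---------------------------------------------------------------------------

class BreastEnvelope:
    """Closed surface with an inside/outside predicate.

    Subclasses implement :meth:`inside`; first-intersection queries are
    resolved by bisection along the ray, which is exact for any envelope that
    a ray crosses once on entry (true for star-shaped pendulous surfaces and
    for convex test shapes).
    """

    def inside(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def entry_fraction(self, source: np.ndarray, targets: np.ndarray,
                       n_iter: int = 60) -> np.ndarray:
        """Fraction u in [0,1] along source->target at which the ray enters.

        ``targets`` must be inside (or on) the envelope and ``source``
        outside; vectorized over targets.
        """
        source = np.asarray(source, float)
        targets = np.atleast_2d(np.asarray(targets, float))
        lo = np.zeros(len(targets))
        hi = np.ones(len(targets))
        for _ in range(n_iter):
            mid = 0.5 * (lo + hi)
            pts = source[None, :] + mid[:, None] * (targets - source[None, :])
            ins = self.inside(pts)
            hi = np.where(ins, mid, hi)
            lo = np.where(ins, lo, mid)
        return 0.5 * (lo + hi)


class RadialEnvelope(BreastEnvelope):
    """Pendulous breast surface as a radius function rho(theta, z).

    The surface is sampled on a regular (theta, z) grid and evaluated with
    bilinear interpolation (periodic in theta); it is watertight by
    construction, closing at the table plane (z = z_top) and at the tip
    (z = z_top - length, where rho -> 0).
    """

    def __init__(self, rho_grid: np.ndarray, z_grid: np.ndarray):
        rho_grid = np.asarray(rho_grid, float)
        z_grid = np.asarray(z_grid, float)
        if rho_grid.ndim != 2 or rho_grid.shape[1] != len(z_grid):
            raise GeometryError("rho_grid must be (n_theta, n_z)")
        if np.any(rho_grid < 0):
            raise GeometryError("negative envelope radius")
        self.rho_grid = rho_grid
        self.z_grid = z_grid  # ascending
        self.theta_grid = 2 * np.pi * np.arange(rho_grid.shape[0]) / rho_grid.shape[0]

    @classmethod
    def pendulous(cls, base_radius: float, length: float,
                  azimuthal_ripple: float = 0.0, n_theta: int = 72,
                  n_z: int = 64, z_top: float = 0.0) -> "RadialEnvelope":
        """Semi-ellipsoidal pendulous envelope hanging from the table plane."""
        z = np.linspace(z_top - length, z_top, n_z)
        s = np.clip((z_top - z) / length, 0.0, 1.0)  # 0 at top, 1 at tip
        profile = base_radius * np.sqrt(np.clip(1.0 - s ** 2, 0.0, None))
        theta = 2 * np.pi * np.arange(n_theta) / n_theta
        mod = 1.0 + azimuthal_ripple * np.cos(2 * theta)
        return cls(np.outer(mod, profile), z)

    def radius(self, theta: np.ndarray, z: np.ndarray) -> np.ndarray:
        theta = np.mod(np.asarray(theta, float), 2 * np.pi)
        z = np.asarray(z, float)
        n_t = len(self.theta_grid)
        dt = 2 * np.pi / n_t
        it = theta / dt
        i0 = np.floor(it).astype(int) % n_t
        i1 = (i0 + 1) % n_t
        ft = it - np.floor(it)
        jz = np.interp(z, self.z_grid, np.arange(len(self.z_grid)))
        j0 = np.clip(np.floor(jz).astype(int), 0, len(self.z_grid) - 2)
        fz = jz - j0
        r = ((1 - ft) * (1 - fz) * self.rho_grid[i0, j0]
             + ft * (1 - fz) * self.rho_grid[i1, j0]
             + (1 - ft) * fz * self.rho_grid[i0, j0 + 1]
             + ft * fz * self.rho_grid[i1, j0 + 1])
        return r

    def inside(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, float))
        x, y, z = points[:, 0], points[:, 1], points[:, 2]
        in_z = (z >= self.z_grid[0]) & (z <= self.z_grid[-1])
        rho = np.hypot(x, y)
        theta = np.arctan2(y, x)
        return in_z & (rho <= self.radius(theta, z))

    def cross_section_area(self, z: float) -> float:
        """Area of the horizontal envelope cross-section at height z."""
        if z < self.z_grid[0] or z > self.z_grid[-1]:
            return 0.0
        r = self.radius(self.theta_grid, np.full_like(self.theta_grid, z))
        return float(0.5 * np.sum(r ** 2) * (2 * np.pi / len(self.theta_grid)))


class EllipsoidEnvelope(BreastEnvelope):
    """Axis-aligned ellipsoid; used for closed-form checks."""

    def __init__(self, center, semi_axes):
        self.center = np.asarray(center, float)
        self.semi_axes = np.asarray(semi_axes, float)
        if np.any(self.semi_axes <= 0):
            raise GeometryError("semi-axes must be positive")

    def inside(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, float))
        q = (points - self.center) / self.semi_axes
        return np.sum(q ** 2, axis=1) <= 1.0


# ---------------------------------------------------------------------------
# Ray-path splitting
# ---------------------------------------------------------------------------

def ray_path_split(source, target, envelope: BreastEnvelope):
    """Split a straight probe->voxel ray into out-of-breast and in-breast legs.

    Returns ``(d_out, d_in)`` in mm with ``d_out + d_in`` equal to the
    Euclidean source-target distance by construction.
    """
    source = np.asarray(source, float)
    target = np.asarray(target, float)
    if envelope.inside(source[None, :])[0]:
        raise GeometryError("ray source must lie outside the envelope")
    if not envelope.inside(target[None, :])[0]:
        raise GeometryError("ray target must lie inside the envelope")
    d = float(np.linalg.norm(target - source))
    u = float(envelope.entry_fraction(source, target[None, :])[0])
    return u * d, (1.0 - u) * d


def ray_path_split_many(source, targets, envelope: BreastEnvelope):
    """Vectorized :func:`ray_path_split` for many in-envelope targets."""
    source = np.asarray(source, float)
    targets = np.atleast_2d(np.asarray(targets, float))
    d = np.linalg.norm(targets - source[None, :], axis=1)
    u = envelope.entry_fraction(source, targets)
    return u * d, (1.0 - u) * d


# ---------------------------------------------------------------------------
# Phantom and lesions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LesionSpec:
    """Ground-truth lesion: dielectric contrast blob with optional irregularity.

    ``contrast`` multiplies the interior background contrast; ``spiculation``
    and ``roughness_mm`` deform the ellipsoid surface; ``heterogeneity``
    is the relative sigma of voxelwise contrast noise.
    """

    center: tuple[float, float, float]
    axes: tuple[float, float, float] = (8.0, 8.0, 8.0)
    contrast: float = 2.0
    spiculation: int = 0
    roughness_mm: float = 0.0
    heterogeneity: float = 0.0
    heterogeneity_corr_mm: float = 7.0

    def __post_init__(self):
        if min(self.axes) <= 0 or self.contrast <= 0:
            raise GeometryError("lesion axes and contrast must be positive")
        if self.heterogeneity < 0 or self.roughness_mm < 0:
            raise GeometryError("lesion noise amplitudes must be >= 0")
        if self.heterogeneity_corr_mm < 0:
            raise GeometryError("heterogeneity correlation length must be >= 0")


def malignant_like(center, axes=(9.0, 7.0, 7.0), contrast=2.5) -> LesionSpec:
    """Spiculated, rough, heterogeneous lesion preset."""
    return LesionSpec(center, axes, contrast, spiculation=8,
                      roughness_mm=3.0, heterogeneity=0.35)


def benign_like(center, axes=(8.0, 8.0, 8.0), contrast=2.5) -> LesionSpec:
    """Smooth homogeneous ellipsoid preset."""
    return LesionSpec(center, axes, contrast)


@dataclass(frozen=True)
class PhantomSpec:
    base_radius: float = 55.0
    length: float = 90.0
    azimuthal_ripple: float = 0.0
    pc_fib: float = 0.35
    lesions: tuple[LesionSpec, ...] = ()
    fold_present: bool = False
    fold_angle_deg: float = 0.0
    chest_intrusion_mm: float = 0.0
    breast_volume_ml: float | None = None


@dataclass(frozen=True)
class Lesion:
    """Rasterized lesion: voxel centers (mm) with voxelwise contrasts."""

    spec: LesionSpec
    voxels: np.ndarray      # (n, 3) voxel centers, mm
    contrasts: np.ndarray   # (n,) dielectric contrast per voxel


@dataclass(frozen=True)
class Phantom:
    spec: PhantomSpec
    envelope: RadialEnvelope
    lesions: tuple[Lesion, ...]
    seed: int
    media: MediumModel = field(default_factory=MediumModel)

    @property
    def pc_fib_true(self) -> float:
        return self.spec.pc_fib

    @property
    def volume_ml(self) -> float:
        if self.spec.breast_volume_ml is not None:
            return self.spec.breast_volume_ml
        # semi-ellipsoid of revolution: (2/3) pi R^2 L, mm^3 -> mL
        return (2.0 / 3.0) * np.pi * self.spec.base_radius ** 2 * self.spec.length / 1000.0


def lattice_centers(n: int, step: float = 2.0) -> np.ndarray:
    """1D lattice of n voxel centers straddling the origin (odd mm for step 2)."""
    return step * (np.arange(n) - n / 2 + 0.5)


def _rasterize_lesion(spec: LesionSpec, rng: np.random.Generator) -> Lesion:
    c = np.asarray(spec.center, float)
    ax = np.asarray(spec.axes, float)
    pad = spec.roughness_mm + 2.0
    n = int(np.ceil((ax.max() + pad) / 1.0))
    g = np.arange(-n, n + 1, 2.0)  # 2 mm lattice relative to center snap
    # snap the lattice so voxel centers sit at odd-mm global coordinates
    snap = (np.round((c - 1.0) / 2.0) * 2.0 + 1.0) - c
    xs, ys, zs = np.meshgrid(g + snap[0], g + snap[1], g + snap[2], indexing="ij")
    pts = np.column_stack([xs.ravel(), ys.ravel(), zs.ravel()])
    q = pts / ax
    r = np.linalg.norm(q, axis=1)
    theta = np.arctan2(q[:, 1], q[:, 0])
    with np.errstate(invalid="ignore"):
        cosp = np.divide(q[:, 2], r, out=np.zeros_like(r), where=r > 0)
        polar = np.arccos(np.clip(cosp, -1, 1))
    mean_ax = float(ax.mean())
    mod = np.ones_like(r)
    if spec.spiculation > 0 and spec.roughness_mm > 0:
        phase = rng.uniform(0, 2 * np.pi, size=2)
        amp = spec.roughness_mm / mean_ax
        mod += amp * np.cos(spec.spiculation * theta + phase[0]) * np.sin(polar) ** 2
        mod += 0.5 * amp * np.cos(3 * polar + phase[1])
    inside = r <= mod
    voxels = pts[inside] + c
    base = spec.contrast
    n_vox = int(inside.sum())
    if spec.heterogeneity > 0 and n_vox > 1:
        # spatially correlated Gaussian field: intratumoral heterogeneity has
        # a macroscopic correlation length (necrotic cores, lobulation), not
        # white voxel noise the imaging resolution could never carry
        z = rng.standard_normal(n_vox)
        ell = max(spec.heterogeneity_corr_mm, 1e-6)
        pv = pts[inside]
        d2 = np.sum((pv[:, None, :] - pv[None, :, :]) ** 2, axis=-1)
        cov = np.exp(-0.5 * d2 / ell ** 2) + 1e-8 * np.eye(n_vox)
        field = np.linalg.cholesky(cov) @ z
        field /= max(field.std(), 1e-12)
        contrasts = np.clip(base * (1.0 + spec.heterogeneity * field),
                            0.1 * base, None)
    elif spec.heterogeneity > 0:
        contrasts = np.clip(base * (1.0 + spec.heterogeneity
                                    * rng.standard_normal(n_vox)),
                            0.1 * base, None)
    else:
        contrasts = np.full(n_vox, base)
    return Lesion(spec=spec, voxels=voxels, contrasts=contrasts)


def make_phantom(spec: PhantomSpec, seed: int,
                 media: MediumModel | None = None) -> Phantom:
    """Deterministically realize a phantom from its specification.

    The same (spec, seed) pair always yields a bitwise-identical phantom.
    Raises if a lesion centroid falls outside the envelope.
    """
    if not 0.0 <= spec.pc_fib <= 1.0:
        raise GeometryError("pc_fib must be in [0,1]")
    rng = np.random.default_rng(seed)
    envelope = RadialEnvelope.pendulous(spec.base_radius, spec.length,
                                        spec.azimuthal_ripple)
    lesions = []
    for ls in spec.lesions:
        if not envelope.inside(np.asarray(ls.center, float)[None, :])[0]:
            raise GeometryError(f"lesion centroid {ls.center} outside envelope")
        lesions.append(_rasterize_lesion(ls, rng))
    return Phantom(spec=spec, envelope=envelope, lesions=tuple(lesions),
                   seed=seed, media=media or MediumModel())


# ---------------------------------------------------------------------------
# Cut-out detection
# ---------------------------------------------------------------------------

def detect_cutout_slice(envelope: RadialEnvelope, array: ProbeArray,
                        chest_intrusion: float = 0.0,
                        area_fraction: float = 0.9):
    """Uppermost trusted scan-slice index, or None when the whole scan is valid.

    A slice is distrusted when (a) the envelope cross-section exceeds
    ``area_fraction`` of the ring aperture (breast too large for the
    aperture) or (b) it lies within the chest-wall intrusion depth below the
    table. Slices above the returned index are excluded from imaging.
    """
    ring_area = np.pi * array.ring_radius ** 2
    bad = np.zeros(array.n_slices, bool)
    for i, z in enumerate(array.z_positions):
        if envelope.cross_section_area(float(z)) > area_fraction * ring_area:
            bad[i] = True
        if chest_intrusion > 0 and z > -(array.top_offset + chest_intrusion):
            bad[i] = True
    if not bad.any():
        return None
    good = np.nonzero(~bad)[0]
    if len(good) == 0:
        return array.n_slices  # nothing trusted
    return int(good[0])
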