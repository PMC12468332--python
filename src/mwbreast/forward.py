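"""Born-approximation multistatic scan synthesis.

Each probe in turn illuminates the breast while the remaining probes receive,
giving a 21x21 complex S21 matrix per frequency and per vertical scan
position (the monostatic diagonal is not measured). Propagation is modeled
per coronal slab as straight rays split into a transition-liquid leg and an
in-breast leg, each with the lossy transmission-line propagation constant and
1/d spherical spreading. Antenna coupling, skin reflection, a localized
skin-fold echo and circular Gaussian noise are injectable on top of the
lesion scattering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (C0_M_S, Medium, Phantom, ProbeArray,
                       GeometryError, ray_path_split_many)

DEFAULT_BAND_HZ = (0.8e9, 4.1e9)
DEFAULT_N_FREQ = 34


class ScanConfigError(ValueError):
    pass


def complex_wavenumber(f, medium: Medium):
    """Lossy propagation constant gamma = alpha + i*beta in 1/m.

    alpha = (2 pi f / c0) sqrt((eps_r/2)(sqrt(1+tan^2 d) - 1))  [Np/m]
    beta  = (2 pi f / c0) sqrt((eps_r/2)(sqrt(1+tan^2 d) + 1))  [rad/m]

    In the lossless limit alpha = 0 and beta = (2 pi f / c0) sqrt(eps_r).
    """
    f = np.asarray(f, float)
    if np.any(f <= 0):
        raise GeometryError("frequency must be positive")
    eps = np.asarray(medium.eps_r, float)
    td = np.asarray(medium.tan_delta, float)
    if np.any(td < 0):
        raise GeometryError("loss tangent must be >= 0")
    k0 = 2.0 * np.pi * f / C0_M_S
    root = np.sqrt(1.0 + td ** 2)
    alpha = k0 * np.sqrt(eps / 2.0 * (root - 1.0))
    beta = k0 * np.sqrt(eps / 2.0 * (root + 1.0))
    return alpha + 1j * beta


@dataclass
class ArtifactConfig:
    """Injectable artifact terms, all off by default.

    ``coupling_db`` sets the coupling amplitude in dB above the strongest
    lesion echo of the slice (the dominant common mode the PCA stage must
    remove); ``skin_amplitude`` scales the envelope first-reflection term;
    ``fold_amplitude`` adds a localized strong echo visible only to probes
    within ``fold_halfwidth_deg`` of the phantom's fold azimuth.
    """

    coupling: bool = False
    coupling_db: float = 30.0
    coupling_delay_ns: float = 0.15
    skin: bool = False
    skin_amplitude: float = 0.3
    fold_amplitude: float = 0.0
    fold_halfwidth_deg: float = 35.0


@dataclass
class ScanData:
    """Complex multistatic S21 tensor, (n_slices, n_probes, n_probes, n_freq).

    Reciprocity S21[i,j] = S21[j,i] holds before noise injection; the
    monostatic diagonal is not measured and stored as zero with
    ``diag_valid = False``.
    """

    data: np.ndarray
    freqs: np.ndarray
    array: ProbeArray
    seed: int | None = None
    diag_valid: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def n_freq(self) -> int:
        return len(self.freqs)

    def save(self, path) -> None:
        np.savez(path, data=self.data, freqs=self.freqs,
                 ring_radius=self.array.ring_radius,
                 z_positions=self.array.z_positions,
                 seed=-1 if self.seed is None else self.seed,
                 diag_valid=self.diag_valid)

    @classmethod
    def load(cls, path) -> "ScanData":
        with np.load(path) as z:
            arr = ProbeArray(ring_radius=float(z["ring_radius"]),
                             z_positions=z["z_positions"])
            seed = int(z["seed"])
            sd = cls(data=z["data"], freqs=z["freqs"], array=arr,
                     seed=None if seed < 0 else seed,
                     diag_valid=bool(z["diag_valid"]))
        pre = sd.data
        if not np.allclose(pre, np.swapaxes(pre, 1, 2), equal_nan=True):
            sd.meta["reciprocity"] = "broken (noisy scan)"
        else:
            sd.meta["reciprocity"] = "ok"
        return sd


def frequency_grid(band_hz=DEFAULT_BAND_HZ, n_freq=DEFAULT_N_FREQ) -> np.ndarray:
    if n_freq < 1:
        raise ScanConfigError("empty frequency grid")
    return np.linspace(band_hz[0], band_hz[1], n_freq)


def _slab_voxels(phantom: Phantom, z: float, half_width: float = 2.0):
    """Lesion voxels and contrasts falling in the +/- half_width slab at z."""
    vox, con = [], []
    for les in phantom.lesions:
        m = np.abs(les.voxels[:, 2] - z) <= half_width
        if m.any():
            vox.append(les.voxels[m])
            con.append(les.contrasts[m])
    if not vox:
        return np.empty((0, 3)), np.empty(0)
    return np.vstack(vox), np.concatenate(con)


def _greens(probe_xy, z, voxels, freqs, phantom: Phantom):
    """Per-probe two-media Green factors, shape (n_probes, n_vox, n_freq)."""
    media = phantom.media
    g_trans = complex_wavenumber(freqs, media.transition)
    g_in = complex_wavenumber(freqs, media.interior(phantom.pc_fib_true))
    n_p = len(probe_xy)
    out = np.empty((n_p, len(voxels), len(freqs)), complex)
    # in-plane propagation: voxels projected to the slab mid-plane
    tgt = voxels.copy()
    tgt[:, 2] = z
    for p in range(n_p):
        src = np.array([probe_xy[p, 0], probe_xy[p, 1], z])
        d_out, d_in = ray_path_split_many(src, tgt, phantom.envelope)
        d_tot_m = (d_out + d_in) / 1000.0
        phase = (np.outer(d_out / 1000.0, g_trans)
                 + np.outer(d_in / 1000.0, g_in))
        np.clip(d_tot_m, 1e-6, None, out=d_tot_m)
        out[p] = np.exp(-phase) / d_tot_m[:, None]
    return out


def synthesize_scan(phantom: Phantom, array: ProbeArray,
                    freqs: np.ndarray | None = None,
                    noise_level: float = 0.0,
                    artifacts: ArtifactConfig | None = None,
                    seed: int = 0,
                    slices: np.ndarray | None = None) -> ScanData:
    """Synthesize a multistatic scan of a phantom.

    ``S21[i,j,f] = sum_v contrast(v) G_i(v,f) G_j(v,f)`` over lesion voxels
    of each coronal slab (Born sum), plus the configured artifact terms;
    noise is circular complex Gaussian scaled to ``noise_level`` times the
    slice RMS. Reciprocity is exact before noise.

    ``slices`` optionally restricts synthesis to a subset of scan heights.
    """
    if freqs is None:
        freqs = frequency_grid()
    freqs = np.asarray(freqs, float)
    if freqs.size == 0:
        raise ScanConfigError("empty frequency grid")
    artifacts = artifacts or ArtifactConfig()
    z_positions = array.z_positions if slices is None else np.asarray(slices, float)
    n_p, n_f = array.n_probes, len(freqs)
    rng = np.random.default_rng(seed)
    probe_xy = array.probe_xy()
    data = np.zeros((len(z_positions), n_p, n_p, n_f), complex)

    for si, z in enumerate(z_positions):
        vox, con = _slab_voxels(phantom, float(z))
        s = np.zeros((n_p, n_p, n_f), complex)
        if len(vox):
            G = _greens(probe_xy, float(z), vox, freqs, phantom)
            # S[i,j,f] = sum_v con[v] G[i,v,f] G[j,v,f]
            s = np.einsum("v,ivf,jvf->ijf", con, G, G, optimize=True)
        echo_scale = np.abs(s).max() if np.abs(s).max() > 0 else 1e-9
        # noise is referenced to the scattered field, not the (much stronger)
        # injected artifact terms, so noise_level sets the echo SNR directly
        scatter_rms = np.sqrt(np.mean(np.abs(s) ** 2))
        if scatter_rms <= 0:
            scatter_rms = echo_scale

        if artifacts.coupling:
            amp = echo_scale * 10 ** (artifacts.coupling_db / 20.0)
            c = amp * np.exp(-2j * np.pi * freqs * artifacts.coupling_delay_ns * 1e-9)
            s = s + c[None, None, :]

        if artifacts.skin:
            g_t = complex_wavenumber(freqs, phantom.media.transition)
            # entry distance of each probe toward the slice axis
            origin = np.array([[0.0, 0.0, float(z)]])
            d_entry = np.empty(n_p)
            for p in range(n_p):
                src = np.array([probe_xy[p, 0], probe_xy[p, 1], float(z)])
                if phantom.envelope.inside(origin)[0]:
                    u = phantom.envelope.entry_fraction(src, origin)[0]
                    d_entry[p] = u * np.linalg.norm(origin[0] - src)
                else:
                    d_entry[p] = np.linalg.norm(origin[0] - src)
            d_m = (d_entry[:, None] + d_entry[None, :]) / 1000.0
            amp = artifacts.skin_amplitude * echo_scale * 10 ** (artifacts.coupling_db / 40.0)
            s = s + amp * np.exp(-np.einsum("ij,f->ijf", d_m, g_t)) / d_m[..., None]

        if artifacts.fold_amplitude > 0 and phantom.spec.fold_present:
            fold_theta = np.deg2rad(phantom.spec.fold_angle_deg)
            hw = np.deg2rad(artifacts.fold_halfwidth_deg)
            ang = 2 * np.pi * np.arange(n_p) / n_p
            dist = np.abs(np.angle(np.exp(1j * (ang - fold_theta))))
            vis = dist <= hw
            fold_pt = np.array([0.8 * phantom.spec.base_radius * np.cos(fold_theta),
                                0.8 * phantom.spec.base_radius * np.sin(fold_theta),
                                float(z)])
            g_t = complex_wavenumber(freqs, phantom.media.transition)
            d = np.linalg.norm(probe_xy - fold_pt[None, :2], axis=1) / 1000.0
            amp = artifacts.fold_amplitude * echo_scale
            term = amp * np.exp(-(d[:, None, None] + d[None, :, None]) * g_t[None, None, :])
            s = s + term * np.outer(vis, vis)[:, :, None]

        # enforce bitwise reciprocity (summation order can differ across the
        # transpose in the Born einsum) and blank the unmeasured diagonal
        i_lo, j_lo = np.tril_indices(n_p, -1)
        s[i_lo, j_lo, :] = s[j_lo, i_lo, :]
        np.einsum("iif->if", s)[:] = 0.0  # monostatic diagonal not measured
        if noise_level > 0:
            nz = rng.standard_normal(s.shape) + 1j * rng.standard_normal(s.shape)
            s = s + noise_level * scatter_rms * nz / np.sqrt(2.0)
        data[si] = s

    sub_array = ProbeArray(ring_radius=array.ring_radius,
                           z_positions=np.asarray(z_positions, float))
    return ScanData(data=data, freqs=freqs, array=sub_array, seed=seed,
                    meta={"noise_level": noise_level,
                          "phantom_seed": phantom.seed})
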