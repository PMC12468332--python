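"""Scan-data preprocessing: coupling removal and per-IMF filtering.

The chain, applied per bistatic channel of an imaging-sector context:

1. IDFT of the stepped-frequency S21 sweep to a complex analytic time signal.
2. PCA across the sector's channel group to subtract the common strong
   component (antenna coupling / skin reflection).
3. Empirical Mode Decomposition of the real part into Intrinsic Mode
   Functions; the analytic IMFs are recovered by Hilbert transform.
4. Distance-based filtering: drop IMFs whose dominant echo sits implausibly
   close to the probes (residual coupling) or implausibly far (multipath).
5. Propagation-loss compensation per kept IMF, exp(a_trans*d_out +
   a_inbreast*d_in) with the in-breast attenuation a pc_fib-weighted
   adipose/fibroglandular mixture.
6. Amplitude (integrated-PSD) channel veto against a calibration-normalized
   threshold of 5.

Three operating modes: DEFAULT (N_PCA = 12, PSD filter on), CUSTOM1
(amplitude filter disabled, for very small breasts / superficial large
lesions), CUSTOM2 (N_PCA = 10 for a narrower, more severe PCA context: very
large breasts, skin folds, extreme density).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import hilbert

from .geometry import (C0_MM_NS, MediumModel, BreastEnvelope,
                       GeometryError)
from .forward import complex_wavenumber

N_S = 8  # probes per imaging sub-array, always

PSD_TOT_THRESH = 5.0
D_NEAR_MM = 10.0


class Mode(enum.Enum):
    DEFAULT = "default"
    CUSTOM1 = "custom1"
    CUSTOM2 = "custom2"

    @property
    def n_pca(self) -> int:
        return 10 if self is Mode.CUSTOM2 else 12

    @property
    def psd_filter_enabled(self) -> bool:
        return self is not Mode.CUSTOM1


# ---------------------------------------------------------------------------
# Time-domain conversion
# ---------------------------------------------------------------------------

@dataclass
class TimeChannel:
    """Complex analytic time signal of one bistatic channel."""

    signal: np.ndarray
    f0: float
    df: float
    n_freq: int
    pad_factor: int
    provenance: tuple = ()

    @property
    def dt(self) -> float:
        return 1.0 / (self.pad_factor * self.n_freq * self.df)

    @property
    def times(self) -> np.ndarray:
        return self.dt * np.arange(len(self.signal))

    def distances_mm(self, v_mm_ns: float) -> np.ndarray:
        """One-way echo distance annotation of each time sample (radar d = v t / 2)."""
        return 0.5 * v_mm_ns * self.times * 1e9

    def to_spectrum(self) -> np.ndarray:
        """Forward transform back to the original frequency samples."""
        n_pad = len(self.signal)
        t = self.dt * np.arange(n_pad)
        base = self.signal * np.exp(-2j * np.pi * self.f0 * t)
        return np.fft.fft(base)[: self.n_freq] / n_pad


def to_time_domain(spectrum: np.ndarray, freqs: np.ndarray,
                   pad_factor: int = 4, provenance: tuple = ()) -> TimeChannel:
    """Analytic time signal from a one-sided stepped-frequency sweep.

    The measured band is physically one-sided, so the IDFT of the S21 sweep
    is directly the analytic signal; zero-padding (default 4x) refines the
    time sampling.
    """
    spectrum = np.asarray(spectrum)
    freqs = np.asarray(freqs, float)
    if len(freqs) < 4:
        raise GeometryError("need at least 4 frequency points")
    df = freqs[1] - freqs[0]
    if not np.allclose(np.diff(freqs), df):
        raise GeometryError("frequency grid must be uniform")
    n = len(freqs)
    n_pad = pad_factor * n
    padded = np.zeros(n_pad, complex)
    padded[:n] = spectrum
    base = n_pad * np.fft.ifft(padded)
    t = np.arange(n_pad) / (n_pad * df)
    signal = base * np.exp(2j * np.pi * freqs[0] * t)
    return TimeChannel(signal=signal, f0=freqs[0], df=df, n_freq=n,
                       pad_factor=pad_factor, provenance=provenance)


def transition_velocity_mm_ns(media: MediumModel) -> float:
    """Phase velocity in the transition liquid, used for echo-distance annotation."""
    return C0_MM_NS / np.sqrt(float(np.mean(np.asarray(media.transition.eps_r))))


# ---------------------------------------------------------------------------
# PCA coupling removal
# ---------------------------------------------------------------------------

def pca_coupling_removal(channels: np.ndarray, n_components: int = 1) -> np.ndarray:
    """Subtract the leading common component(s) across a channel group.

    ``channels`` is (n_channels, n_samples) complex; the rank-``n_components``
    truncated SVD reconstruction is removed from every channel. Removing the
    first component is exactly idempotent.
    """
    channels = np.asarray(channels)
    if channels.ndim != 2:
        raise GeometryError("channels must be a 2D (channel, sample) array")
    if n_components >= min(channels.shape):
        raise GeometryError("n_components must be smaller than the channel group")
    u, s, vh = np.linalg.svd(channels, full_matrices=False)
    common = (u[:, :n_components] * s[:n_components]) @ vh[:n_components]
    return channels - common


# ---------------------------------------------------------------------------
# Empirical Mode Decomposition
# ---------------------------------------------------------------------------

@dataclass
class IMFSet:
    """Ordered intrinsic mode functions plus residual; sum reconstructs input."""

    imfs: list[np.ndarray]
    residual: np.ndarray
    annotations: list[dict] = field(default_factory=list)

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out = out + imf
        return out


def _extrema(x: np.ndarray):
    d = np.diff(x)
    maxima = np.nonzero((d[:-1] > 0) & (d[1:] <= 0))[0] + 1
    minima = np.nonzero((d[:-1] < 0) & (d[1:] >= 0))[0] + 1
    return maxima, minima


def _envelope_mean(x: np.ndarray):
    """Mean of cubic-spline upper/lower envelopes; None when too few extrema."""
    n = len(x)
    mx, mn = _extrema(x)
    if len(mx) < 2 or len(mn) < 2:
        return None
    idx = np.arange(n)

    def spline(pts, vals):
        # mirror the two outermost extrema about the signal ends
        left = 2 * 0 - pts[:2][::-1]
        right = 2 * (n - 1) - pts[-2:][::-1]
        xs = np.concatenate([left, pts, right])
        ys = np.concatenate([vals[:2][::-1], vals, vals[-2:][::-1]])
        xs, keep = np.unique(xs, return_index=True)
        return CubicSpline(xs, ys[keep])(idx)

    upper = spline(mx, x[mx])
    lower = spline(mn, x[mn])
    return 0.5 * (upper + lower)


def emd_decompose(x: np.ndarray, max_imfs: int = 10, max_sift: int = 10,
                  sd_thresh: float = 0.2) -> IMFSet:
    """Sift a real signal into intrinsic mode functions.

    Stopping: per-IMF sifting ends when the standard-deviation criterion
    falls below ``sd_thresh`` or after ``max_sift`` iterations; decomposition
    ends when the residual has too few extrema to sift (monotone) or after
    ``max_imfs`` IMFs. The decomposition is complete by construction:
    sum(IMFs) + residual == input to rounding.
    """
    x = np.asarray(x, float)
    if len(x) < 16:
        raise GeometryError("signal too short for EMD")
    if not np.all(np.isfinite(x)):
        raise GeometryError("non-finite input")
    imfs: list[np.ndarray] = []
    residual = x.copy()
    for _ in range(max_imfs):
        h = residual.copy()
        m = _envelope_mean(h)
        if m is None:
            break
        for _ in range(max_sift):
            h_new = h - m
            denom = np.sum(h ** 2)
            if denom > 0:
                sd = np.sum((h - h_new) ** 2) / denom
            else:
                sd = 0.0
            h = h_new
            if sd < sd_thresh:
                break
            m = _envelope_mean(h)
            if m is None:
                break
        imfs.append(h)
        residual = residual - h
    return IMFSet(imfs=imfs, residual=residual)


# ---------------------------------------------------------------------------
# Distance-based IMF filtering
# ---------------------------------------------------------------------------

def classify_imfs(imfset: IMFSet, dt: float, v_mm_ns: float,
                  d_near: float = D_NEAR_MM,
                  d_far: float | None = None,
                  ring_diameter: float | None = None,
                  max_chord: float | None = None) -> IMFSet:
    """Annotate each IMF with its dominant echo distance and a keep/drop flag.

    The dominant distance is the argmax of the IMF's analytic envelope mapped
    through the transition-liquid velocity. IMFs peaking nearer than
    ``d_near`` are residual antenna coupling; IMFs peaking beyond ``d_far``
    (default: ring diameter + 2x the maximum breast chord) are multipath.
    """
    if d_far is None:
        rd = ring_diameter if ring_diameter is not None else 240.0
        mc = max_chord if max_chord is not None else 110.0
        d_far = rd + 2.0 * mc
    annotations = []
    for imf in imfset.imfs:
        env = np.abs(hilbert(imf))
        k = int(np.argmax(env))
        d = 0.5 * v_mm_ns * (k * dt) * 1e9
        if d < d_near:
            keep, reason = False, "coupling"
        elif d > d_far:
            keep, reason = False, "multipath"
        else:
            keep, reason = True, "kept"
        annotations.append({"distance_mm": float(d), "keep": keep,
                            "reason": reason})
    return IMFSet(imfs=imfset.imfs, residual=imfset.residual,
                  annotations=annotations)


# ---------------------------------------------------------------------------
# Propagation loss compensation
# ---------------------------------------------------------------------------

def loss_compensate(spectrum: np.ndarray, freqs: np.ndarray,
                    d_out_mm: float, d_in_mm: float, pc_fib: float,
                    media: MediumModel) -> np.ndarray:
    """Multiply each frequency sample by exp(a_trans*d_out + a_in*d_in).

    ``a_in(f) = pc_fib * a_fibroglandular(f) + (1 - pc_fib) * a_adipose(f)``.
    The multiplier is >= 1 and non-decreasing in distance, pc_fib and
    frequency, restoring the amplitude the lossy media removed from deep
    echoes so the time-reversal focusing remains valid.
    """
    if d_out_mm < 0 or d_in_mm < 0:
        raise GeometryError("distances must be non-negative")
    if not 0.0 <= pc_fib <= 1.0:
        raise GeometryError("pc_fib must be in [0,1]")
    freqs = np.asarray(freqs, float)
    a_trans = complex_wavenumber(freqs, media.transition).real
    a_fib = complex_wavenumber(freqs, media.fibroglandular).real
    a_adip = complex_wavenumber(freqs, media.adipose).real
    a_in = pc_fib * a_fib + (1.0 - pc_fib) * a_adip
    mult = np.exp(a_trans * d_out_mm / 1000.0 + a_in * d_in_mm / 1000.0)
    return np.asarray(spectrum) * mult


# ---------------------------------------------------------------------------
# Amplitude (PSD) filtering
# ---------------------------------------------------------------------------

def integrated_psd(signal: np.ndarray, dt: float, calibration_ref: float) -> float:
    """Integrated power of the signal, normalized by a calibration reference."""
    if calibration_ref <= 0:
        raise GeometryError("calibration reference must be positive")
    return float(np.sum(np.abs(signal) ** 2) * dt / calibration_ref)


def psd_filter(psd_tot: float, mode: Mode,
               threshold: float = PSD_TOT_THRESH) -> bool:
    """True when the channel is kept.

    A channel whose calibration-normalized integrated PSD reaches the
    threshold is vetoed as anomalous — unless the amplitude filter is
    disabled (CUSTOM1).
    """
    if not mode.psd_filter_enabled:
        return True
    return psd_tot < threshold


# ---------------------------------------------------------------------------
# Mode selection
# ---------------------------------------------------------------------------

def select_mode(breast_volume_ml: float | None = None,
                superficial_large_lesion: bool = False,
                fold_present: bool = False,
                extreme_density: bool = False,
                v_small_ml: float = 350.0,
                v_large_ml: float = 1300.0) -> tuple[Mode, str]:
    """Rule-based operating-mode attribution; returns (mode, triggering rule).

    CUSTOM1 for very small breasts or large superficial lesions (amplitude
    filter would clip useful echoes); CUSTOM2 for very large breasts, skin
    folds, or extreme density (narrower, more severe PCA); DEFAULT otherwise.
    """
    if breast_volume_ml is not None and breast_volume_ml < v_small_ml:
        return Mode.CUSTOM1, f"breast volume {breast_volume_ml:.0f} mL < {v_small_ml:.0f} mL"
    if superficial_large_lesion:
        return Mode.CUSTOM1, "large superficial lesion"
    if breast_volume_ml is not None and breast_volume_ml > v_large_ml:
        return Mode.CUSTOM2, f"breast volume {breast_volume_ml:.0f} mL > {v_large_ml:.0f} mL"
    if fold_present:
        return Mode.CUSTOM2, "skin fold present"
    if extreme_density:
        return Mode.CUSTOM2, "extreme breast density"
    return Mode.DEFAULT, "no trigger"


# ---------------------------------------------------------------------------
# Sector-context preprocessing (pipeline surface)
# ---------------------------------------------------------------------------

def pca_context_probes(center: int, n_pca: int, n_probes: int = 21) -> np.ndarray:
    """Probe indices of the PCA context: the N_S sub-array extended bilaterally."""
    extra = (n_pca - N_S) // 2
    lo = center - 3 - extra
    return np.mod(np.arange(lo, lo + n_pca), n_probes)


def subarray_probes(center: int, n_probes: int = 21) -> np.ndarray:
    """The 8 contiguous probes of the imaging sub-array centered at ``center``."""
    return np.mod(np.arange(center - 3, center + 5), n_probes)


def calibration_reference(scan_slice: np.ndarray, freqs: np.ndarray,
                          pad_factor: int = 4) -> float:
    """Median integrated channel power of an empty-container calibration scan."""
    n_p = scan_slice.shape[0]
    vals = []
    for i in range(n_p):
        for j in range(i + 1, n_p):
            tc = to_time_domain(scan_slice[i, j], freqs, pad_factor)
            vals.append(np.sum(np.abs(tc.signal) ** 2) * tc.dt)
    med = float(np.median(vals))
    return med if med > 0 else 1.0


@dataclass
class SectorPreprocessResult:
    cleaned: np.ndarray          # (8, 8, n_freq) channel spectra, diag zero
    probes: np.ndarray           # the 8 sub-array probe indices
    log: list[dict]


def preprocess_sector(scan_slice: np.ndarray, freqs: np.ndarray,
                      center: int, mode: Mode,
                      envelope: BreastEnvelope, probe_xy: np.ndarray,
                      z: float, media: MediumModel,
                      pc_fib_ref: float = 0.5,
                      calibration_ref: float | str | None = None,
                      pad_factor: int = 4,
                      emd: bool = True,
                      pca: bool = True,
                      d_far: float | None = None) -> SectorPreprocessResult:
    """Run the full preprocessing chain for one imaging-sector context.

    ``scan_slice`` is the (21, 21, n_freq) multistatic matrix of one vertical
    position. Returns the cleaned 8x8 sub-array channel spectra and a
    structured per-channel decision log.
    """
    ctx = pca_context_probes(center, mode.n_pca)
    sub = subarray_probes(center)
    pairs = [(int(i), int(j)) for a, i in enumerate(ctx) for j in ctx[a + 1:]]
    tcs = [to_time_domain(scan_slice[i, j], freqs, pad_factor, provenance=(i, j))
           for i, j in pairs]
    X = np.array([tc.signal for tc in tcs])
    Xc = pca_coupling_removal(X) if pca else X
    v = transition_velocity_mm_ns(media)
    dt = tcs[0].dt
    ring_r = float(np.max(np.linalg.norm(probe_xy, axis=1)))

    # skin-entry distance per probe toward the slice axis, for d_out/d_in split
    origin = np.array([[0.0, 0.0, z]])
    d_entry = {}
    for p in set(int(q) for q in sub):
        src = np.array([probe_xy[p, 0], probe_xy[p, 1], z])
        if envelope.inside(origin)[0]:
            u = float(envelope.entry_fraction(src, origin)[0])
            d_entry[p] = u * float(np.linalg.norm(origin[0] - src))
        else:
            d_entry[p] = float(np.linalg.norm(origin[0] - src))

    sub_set = {(min(i, j), max(i, j)) for a, i in enumerate(sub.tolist())
               for j in sub.tolist()[a + 1:]}
    n_f = len(freqs)
    cleaned = np.zeros((N_S, N_S, n_f), complex)
    pos = {int(p): k for k, p in enumerate(sub)}
    log: list[dict] = []
    processed: dict[tuple, np.ndarray] = {}

    for (i, j), sig in zip(pairs, Xc):
        key = (min(i, j), max(i, j))
        if key not in sub_set:
            continue
        if emd:
            imfset = emd_decompose(np.real(sig))
            imfset = classify_imfs(imfset, dt, v, d_far=d_far,
                                   ring_diameter=2 * ring_r)
            d_skin = 0.5 * (d_entry[i] + d_entry[j])
            spec_out = np.zeros(n_f, complex)
            for k, (imf, ann) in enumerate(zip(imfset.imfs, imfset.annotations)):
                log.append({"channel": (i, j), "imf": k, **ann})
                if not ann["keep"]:
                    continue
                analytic = hilbert(imf)
                tc = TimeChannel(signal=analytic, f0=freqs[0],
                                 df=freqs[1] - freqs[0], n_freq=n_f,
                                 pad_factor=pad_factor)
                spec_imf = tc.to_spectrum()
                d_echo = 2.0 * ann["distance_mm"]  # two-way path length
                d_out = min(d_echo, 2.0 * d_skin)
                d_in = d_echo - d_out
                spec_out += loss_compensate(spec_imf, freqs, d_out, d_in,
                                            pc_fib_ref, media)
        else:
            tc = TimeChannel(signal=sig, f0=freqs[0], df=freqs[1] - freqs[0],
                             n_freq=n_f, pad_factor=pad_factor)
            spec_out = tc.to_spectrum()
        processed[(i, j)] = spec_out

    # amplitude veto: channel energies normalized either by an explicit
    # calibration reference or by the sector's own median channel energy
    energies = {}
    for key, spec_out in processed.items():
        tc = to_time_domain(spec_out, freqs, pad_factor)
        energies[key] = float(np.sum(np.abs(tc.signal) ** 2) * tc.dt)
    if calibration_ref == "auto":
        med = float(np.median(list(energies.values())))
        ref = med if med > 0 else None
    else:
        ref = calibration_ref
    for (i, j), spec_out in processed.items():
        keep = True
        if ref is not None:
            psd = energies[(i, j)] / ref
            keep = psd_filter(psd, mode)
            if not keep:
                log.append({"channel": (i, j), "imf": None, "keep": False,
                            "reason": "psd", "psd_tot": psd})
        if keep:
            a, b = pos[i], pos[j]
            cleaned[a, b] = spec_out
            cleaned[b, a] = spec_out
    return SectorPreprocessResult(cleaned=cleaned, probes=sub, log=log)
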