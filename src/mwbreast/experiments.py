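"""Canned validation experiments exercising the full chain.

Each function generates its inputs with the package's own simulator, runs
the method under test, and returns measured quantities. They are used by the
test suite and by the acceptance script.
"""

from __future__ import annotations

import warnings

import numpy as np

from .forward import complex_wavenumber, frequency_grid, synthesize_scan
from .geometry import (LesionSpec, MediumModel, PhantomSpec,
                       build_probe_array, make_phantom)
from .imaging import (PCFIB_RANGES, SliceGeometry, pcfib_candidates,
                      reconstruct, select_pcfib, stitch_sectors,
                      trmusic_sector)
from .pipeline import generate_fixtures, run_pipeline
from .preprocess import (Mode, emd_decompose, loss_compensate,
                         pca_coupling_removal, preprocess_sector,
                         to_time_domain)
from .stats import FPReport, anova_f


def fp_rate_from_counts(n_healthy: int = 41, n_unspecified: int = 13,
                        n_confused: int = 4) -> float:
    """False-positive rate (percent) from the FP-workflow counting rule."""
    return FPReport(n_healthy_breasts=n_healthy, n_unspecified=n_unspecified,
                    n_confused=n_confused).fp_rate


def pcfib_sweep_wiring(seed: int = 0, grid_n: int = 64) -> dict:
    """Run the imaging stage with the full 11-range search set.

    Returns the number of parametric volumes emitted and the membership
    counts of the LOW / HIGH composites.
    """
    cfg = generate_fixtures("point-scatterer", seed=seed)
    ph = make_phantom(cfg.cases[0].phantom, seed)
    arr = build_probe_array(cfg.ring_radius, ph.envelope.z_grid[0], -24.0)
    freqs = frequency_grid(n_freq=cfg.n_freq)
    scan = synthesize_scan(ph, arr, freqs, 0.0, seed=seed,
                           slices=np.array([-41.0]))
    rec = reconstruct(scan, ph.envelope, ph.media, Mode.DEFAULT,
                      ranges=PCFIB_RANGES, grid_n=grid_n, emd=False,
                      pca=False)
    return {"n_range_volumes": len(rec.range_volumes),
            "n_low_members": len(rec.composites["LOW"].provenance["members"]),
            "n_high_members": len(rec.composites["HIGH"].provenance["members"]),
            "global_is_mean": bool(np.allclose(
                rec.composites["GLOBAL"].data,
                np.mean([v.data for v in rec.range_volumes.values()], axis=0)))}


def _slice_image(phantom, scan, z, pc_fib, grid_n=64, emd=False, pca=False):
    geom = SliceGeometry.build(phantom.envelope, scan.array, z, grid_n)
    cache: dict = {}
    sectors = []
    for c in range(scan.array.n_probes):
        pre = preprocess_sector(scan.data[0], scan.freqs, c, Mode.DEFAULT,
                                phantom.envelope, scan.array.probe_xy(), z,
                                phantom.media, emd=emd, pca=pca)
        sectors.append(trmusic_sector(pre.cleaned, scan.freqs, geom, c,
                                      pre.probes, pc_fib, phantom.media,
                                      steering_cache=cache))
    return geom, stitch_sectors(sectors, geom.mask)


def localization_experiment(seed: int = 0, n_noisy: int = 20) -> dict:
    """Point-scatterer localization error, noiseless and at 20 dB echo SNR."""
    cfg = generate_fixtures("point-scatterer", seed=seed)
    truth = np.array(cfg.cases[0].phantom.lesions[0].center[:2])
    ph = make_phantom(cfg.cases[0].phantom, seed)
    arr = build_probe_array(cfg.ring_radius, ph.envelope.z_grid[0], -24.0)
    freqs = frequency_grid(n_freq=cfg.n_freq)
    z = float(cfg.cases[0].phantom.lesions[0].center[2])

    def error(noise, s):
        scan = synthesize_scan(ph, arr, freqs, noise, seed=s,
                               slices=np.array([z]))
        geom, img = _slice_image(ph, scan, z, ph.pc_fib_true)
        iy, ix = np.unravel_index(np.argmax(img), img.shape)
        return float(np.hypot(geom.grid_x[ix] - truth[0],
                              geom.grid_y[iy] - truth[1]))

    noiseless = error(0.0, seed)
    rng = np.random.default_rng(seed)
    noisy = [error(0.1, int(rng.integers(2 ** 31))) for _ in range(n_noisy)]
    return {"noiseless_error_mm": noiseless,
            "noisy_median_error_mm": float(np.median(noisy))}


def emd_completeness(seed: int = 0, n_channels: int = 100) -> float:
    """Max relative EMD reconstruction error over scan-derived channels."""
    cfg = generate_fixtures("two-lesion", seed=seed)
    ph = make_phantom(cfg.cases[0].phantom, seed)
    arr = build_probe_array(cfg.ring_radius, ph.envelope.z_grid[0], -24.0)
    freqs = frequency_grid(n_freq=34)
    scan = synthesize_scan(ph, arr, freqs, 0.05, seed=seed,
                           slices=np.array([-41.0]))
    errs = []
    rng = np.random.default_rng(seed)
    count = 0
    while count < n_channels:
        i, j = rng.integers(0, 21, 2)
        if i == j:
            continue
        x = np.real(to_time_domain(scan.data[0, i, j], freqs).signal)
        if np.max(np.abs(x)) == 0:
            continue
        out = emd_decompose(x)
        errs.append(np.max(np.abs(out.reconstruct() - x)) / np.max(np.abs(x)))
        count += 1
    return float(np.max(errs))


def loss_compensation_experiment(pc_fib: float = 0.5) -> dict:
    """Two identical echoes at 20 vs 50 mm in-breast depth, equal total path.

    Measures the pre-compensation peak-amplitude ratio against the
    closed-form two-way loss prediction and the post-compensation ratio.
    """
    media = MediumModel()
    band = frequency_grid(n_freq=34)
    g_t = complex_wavenumber(band, media.transition)
    g_in = complex_wavenumber(band, media.interior(pc_fib))
    # two-way (d_out, d_in): shallow (160, 40), deep (100, 100) mm
    e_shallow = np.exp(-(g_t * 0.160 + g_in * 0.040))
    e_deep = np.exp(-(g_t * 0.100 + g_in * 0.100))

    def peak(s):
        return float(np.abs(to_time_domain(s, band).signal).max())

    pre_ratio = peak(e_deep) / peak(e_shallow)
    r_f = np.exp(-(g_in.real - g_t.real) * 0.060)
    predicted = float(np.sum(np.abs(e_shallow) * r_f) / np.sum(np.abs(e_shallow)))
    c_shallow = loss_compensate(e_shallow, band, 160.0, 40.0, pc_fib, media)
    c_deep = loss_compensate(e_deep, band, 100.0, 100.0, pc_fib, media)
    post_ratio = peak(c_deep) / peak(c_shallow)
    return {"pre_ratio": pre_ratio, "predicted_pre_ratio": predicted,
            "pre_vs_closed_form_rel_err": abs(pre_ratio - predicted) / predicted,
            "post_ratio": post_ratio}


def pca_suppression_experiment(seed: int = 0, coupling_db: float = 30.0) -> dict:
    """Common coupling 30 dB above distinct channel echoes: measure coupling
    suppression and lesion-echo energy retention of the PCA stage."""
    rng = np.random.default_rng(seed)
    n_ch, n_t = 12, 256
    t = np.arange(n_t)
    coupling = np.exp(2j * np.pi * 0.02 * t + 1j * rng.uniform(0, 2 * np.pi))
    echoes = np.zeros((n_ch, n_t), complex)
    for ch in range(n_ch):
        delay = 30 + 18 * ch
        echoes[ch] = np.exp(-0.5 * ((t - delay) / 4.0) ** 2) * np.exp(
            2j * np.pi * (0.11 + 0.004 * ch) * t)
    amp = 10 ** (coupling_db / 20.0) * np.sqrt(np.mean(np.abs(echoes) ** 2))
    X = amp * coupling[None, :] + echoes
    cleaned = pca_coupling_removal(X)
    resid = cleaned - echoes
    e_coup = np.sum(np.abs(amp * coupling) ** 2) * n_ch
    suppression_db = 10 * np.log10(e_coup / np.sum(np.abs(resid) ** 2))
    retention = float(np.abs(np.vdot(echoes.ravel(), cleaned.ravel()))
                      / np.sum(np.abs(echoes) ** 2))
    return {"suppression_db": float(suppression_db),
            "echo_retention": retention}


def anova_experiments(seed: int = 0, n_perm: int = 1000) -> dict:
    """Hand-example F, F = t^2 agreement, and permutation type-I rate."""
    f_example, _ = anova_f(np.array([1.0, 2, 3, 4, 5, 6]),
                           np.array(["a"] * 3 + ["b"] * 3))
    rng = np.random.default_rng(seed)
    from scipy import stats as sps
    x = rng.standard_normal(30)
    labels = np.array(["a"] * 15 + ["b"] * 15)
    f, _ = anova_f(x, labels)
    t = sps.ttest_ind(x[:15], x[15:]).statistic
    f_t2_gap = abs(f - t ** 2)
    hits = 0
    y = rng.standard_normal(24)
    base_labels = np.array(["a"] * 12 + ["b"] * 12)
    for _ in range(n_perm):
        perm = rng.permutation(base_labels)
        _, p = anova_f(y, perm)
        hits += p <= 0.05
    return {"f_hand_example": float(f_example),
            "f_minus_t_squared": float(f_t2_gap),
            "permutation_type1_rate": hits / n_perm}


def cohort_separability(seed: int = 1) -> dict:
    """Full-chain 10+10 cohort: direction and significance of the three
    headline texture features between the heterogeneous-spiculated and
    smooth-homogeneous classes."""
    cfg = generate_fixtures("cohort", seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = run_pipeline(cfg)
    ft = res.feature_table
    les = ft[ft["label"].isin(["malignant", "benign"])]
    out = {"n_roi_rows": int(len(ft)), "n_lesion_rows": int(len(les))}
    for key, name in (("entropy", "First-order Entropy"),
                      ("joint_entropy", "GLCM Joint Entropy"),
                      ("strength", "NGTDM Strength")):
        m = les[les["label"] == "malignant"][name].median()
        b = les[les["label"] == "benign"][name].median()
        F, p = anova_f(les[name].to_numpy(float), les["label"].to_numpy())
        out[f"{key}_malignant_median"] = float(m)
        out[f"{key}_benign_median"] = float(b)
        out[f"{key}_F"] = float(F)
        out[f"{key}_p"] = float(p)
    return out


def pcfib_recovery(seed: int = 0, rng_pair=(20, 50),
                   truth: float = 0.35) -> dict:
    """Fraction of sectors selecting the true interior assumption within one
    5-point grid step (two opposite point scatterers, noiseless)."""
    spec = PhantomSpec(pc_fib=truth, lesions=(
        LesionSpec(center=(23.0, 7.0, -41.0), axes=(1.5,) * 3, contrast=3.0),
        LesionSpec(center=(-23.0, -7.0, -41.0), axes=(1.5,) * 3, contrast=3.0)))
    ph = make_phantom(spec, seed)
    arr = build_probe_array(100.0, ph.envelope.z_grid[0], -24.0)
    freqs = frequency_grid(n_freq=24)
    scan = synthesize_scan(ph, arr, freqs, 0.0, seed=seed,
                           slices=np.array([-41.0]))
    geom = SliceGeometry.build(ph.envelope, scan.array, -41.0, 64)
    cache: dict = {}
    hits = 0
    for c in range(21):
        pre = preprocess_sector(scan.data[0], freqs, c, Mode.DEFAULT,
                                ph.envelope, scan.array.probe_xy(), -41.0,
                                ph.media, emd=False, pca=False)
        cands = [trmusic_sector(pre.cleaned, freqs, geom, c, pre.probes,
                                p / 100.0, ph.media, steering_cache=cache)
                 for p in pcfib_candidates(rng_pair)]
        best = select_pcfib(cands, rng_pair)
        hits += abs(best.pc_fib - truth) <= 0.0501
    return {"sectors_recovered": hits, "fraction": hits / 21.0}
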