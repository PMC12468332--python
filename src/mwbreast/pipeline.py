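"""End-to-end orchestration: simulate -> preprocess -> image -> extract ->
featurize -> analyze, reproducibly from one config and one seed.

The single run seed fans out through ``numpy.random.SeedSequence`` into
independent per-stage, per-phantom substreams, so any stage can be re-run in
isolation with identical results.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geometry, roi, radiomics
from .forward import ArtifactConfig, synthesize_scan, frequency_grid
from .geometry import (PhantomSpec, LesionSpec, make_phantom, build_probe_array,
                       detect_cutout_slice, malignant_like, benign_like)
from .imaging import PCFIB_RANGES, reconstruct
from .preprocess import Mode, select_mode
from .roi import ROILabel, extract_rois, label_volume
from .stats import separability_table, fp_workflow, format_separability


@dataclass
class BreastCase:
    """One breast to scan: phantom spec plus its class annotation."""

    breast_id: str
    phantom: PhantomSpec
    histology: str = "healthy"      # malignant | benign | healthy
    molecular_subtype: str = ""


@dataclass
class RunConfig:
    cases: list[BreastCase] = field(default_factory=list)
    ring_radius: float = 100.0
    band_hz: tuple[float, float] = (0.8e9, 4.1e9)
    n_freq: int = 34
    noise_level: float = 0.02
    coupling: bool = True
    coupling_db: float = 30.0
    skin_term: bool = False
    fold_amplitude: float = 0.0
    mode: str = "auto"              # auto | default | custom1 | custom2
    ranges: tuple = PCFIB_RANGES
    pcfib_step: int = 5
    grid_n: int = 64
    n_slices: int = 3               # slices centered on the lesion zone
    emd: bool = True
    pca: bool = True
    psd_calibration: bool = True
    min_volume_ml: float = roi.MIN_VOLUME_ML
    min_solidity: float = roi.MIN_SOLIDITY
    min_cnr: float = roi.MIN_CNR
    threshold_quantile: float | None = None   # None -> Otsu
    persistence_quorum: int | None = None
    analysis_volume: str = "GLOBAL"
    roi_match_mm: float = 20.0      # ground-truth labeling radius
    seed: int = 0
    outdir: str | None = None

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["ranges"] = [list(r) for r in self.ranges]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["cases"] = [BreastCase(breast_id=c["breast_id"],
                                 phantom=PhantomSpec(
                                     **{**c["phantom"],
                                        "lesions": tuple(
                                            LesionSpec(**{**l, "center": tuple(l["center"]),
                                                          "axes": tuple(l["axes"])})
                                            for l in c["phantom"].get("lesions", []))}),
                                 histology=c.get("histology", "healthy"),
                                 molecular_subtype=c.get("molecular_subtype", ""))
                     for c in d.get("cases", [])]
        d["ranges"] = tuple(tuple(r) for r in d.get("ranges", PCFIB_RANGES))
        d["band_hz"] = tuple(d.get("band_hz", (0.8e9, 4.1e9)))
        return cls(**d)


@dataclass
class CaseResult:
    breast_id: str
    mode: Mode
    mode_rule: str
    composites: dict
    range_volumes: dict
    rois: list
    cutout_index: int | None
    log: list = field(default_factory=list)


@dataclass
class RunResult:
    cases: list[CaseResult]
    feature_table: pd.DataFrame
    separability: pd.DataFrame | None
    fp_report: object | None
    log: list


def lesion_slices(phantom, n_slices: int, array) -> np.ndarray:
    """Scan heights centered on the lesion zone (or mid-breast when none)."""
    if phantom.lesions:
        zc = float(np.mean([l.spec.center[2] for l in phantom.lesions]))
    else:
        zc = float(phantom.envelope.z_grid[0] * 0.45)
    z0 = np.round(zc / 2) * 2
    offs = 2.0 * (np.arange(n_slices) - (n_slices - 1) // 2)
    zs = z0 + offs
    zs = np.clip(zs, array.z_positions.min(), array.z_positions.max())
    return np.unique(zs)[::-1]


FEATURE_CSV_LEAD = ["Breast_ID", "histology", "molecular_subtype", "SNR",
                    "CNR", "max_linear_dimension_mm", "Shape Elongation",
                    "Shape Solidity", "First-order Median",
                    "First-order Entropy", "GLCM Joint Entropy",
                    "NGTDM Contrast", "NGTDM Strength"]


def _assemble_row(case: BreastCase, r: roi.ROIRecord, feats: dict) -> dict:
    row = {"Breast_ID": case.breast_id,
           "patient": case.breast_id,
           "histology": case.histology,
           "molecular_subtype": case.molecular_subtype,
           "label": ("unspecified" if r.label is ROILabel.UNSPECIFIED
                     else case.histology),
           "roi_label": r.label.value,
           "SNR": r.snr, "CNR": r.cnr,
           "max_linear_dimension_mm": r.max_linear_dimension_mm,
           "volume_ml": r.volume_ml,
           "mean_intensity": r.mean_intensity,
           "persistence": r.persistence}
    row.update(feats)
    return row


def phantom_mask_volume(phantom, grid_n: int = 64):
    """Rasterize the envelope and lesion ground truth onto the 2 mm lattice.

    Returns a label volume (0 background, 1 in-breast, 1+k inside lesion k)
    exportable as NIfTI for inspection against the reconstructions.
    """
    from .imaging import VolumeImage
    from .geometry import lattice_centers
    gx = lattice_centers(grid_n)
    z_lo = float(phantom.envelope.z_grid[0])
    z = np.arange(np.ceil(z_lo / 2) * 2 - 1, 0, 2.0)
    xx, yy, zz = np.meshgrid(gx, gx, z, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    lab = phantom.envelope.inside(pts).reshape(xx.shape).astype(np.int16)
    for k, les in enumerate(phantom.lesions, 1):
        for v in les.voxels:
            i = np.argmin(np.abs(gx - v[0]))
            j = np.argmin(np.abs(gx - v[1]))
            m = np.argmin(np.abs(z - v[2]))
            lab[i, j, m] = 1 + k
    return VolumeImage(data=lab, grid_x=gx, grid_y=gx, z_planes=z,
                       mask=lab > 0, provenance={"kind": "phantom_truth"})


def run_case(case: BreastCase, cfg: RunConfig, seed: int,
             calib_ref: float | None) -> CaseResult:
    phantom = make_phantom(case.phantom, seed)
    array = build_probe_array(cfg.ring_radius, phantom.envelope.z_grid[0],
                              -geometry.TOP_OFFSET_MM)
    freqs = frequency_grid(cfg.band_hz, cfg.n_freq)
    if cfg.mode == "auto":
        mode, rule = select_mode(
            breast_volume_ml=phantom.volume_ml,
            fold_present=case.phantom.fold_present)
    else:
        mode, rule = Mode(cfg.mode), "configured"
    artifacts = ArtifactConfig(coupling=cfg.coupling,
                               coupling_db=cfg.coupling_db,
                               skin=cfg.skin_term,
                               fold_amplitude=cfg.fold_amplitude)
    zs = lesion_slices(phantom, cfg.n_slices, array)
    scan = synthesize_scan(phantom, array, freqs, cfg.noise_level,
                           artifacts, seed=seed, slices=zs)
    cut = detect_cutout_slice(phantom.envelope, scan.array,
                              case.phantom.chest_intrusion_mm)
    rec = reconstruct(scan, phantom.envelope, phantom.media, mode,
                      ranges=cfg.ranges, step=cfg.pcfib_step,
                      grid_n=cfg.grid_n, calibration_ref=calib_ref,
                      emd=cfg.emd, pca=cfg.pca, cutout_index=cut)
    analysis = rec.composites[cfg.analysis_volume]
    rois = extract_rois(analysis, rec.range_volumes,
                        min_volume_ml=cfg.min_volume_ml,
                        min_solidity=cfg.min_solidity,
                        min_cnr=cfg.min_cnr,
                        quorum=cfg.persistence_quorum,
                        threshold_quantile=cfg.threshold_quantile)
    # ground-truth labeling: ROIs near a true lesion centroid are clinical
    truth = [np.asarray(l.spec.center, float) for l in phantom.lesions]
    for r in rois:
        if any(np.linalg.norm(r.centroid_mm - t) <= cfg.roi_match_mm
               for t in truth):
            r.label = ROILabel.CLINICAL
        elif case.phantom.fold_present:
            r.label = ROILabel.ARTIFACT_2
        else:
            r.label = ROILabel.UNSPECIFIED
    return CaseResult(breast_id=case.breast_id, mode=mode, mode_rule=rule,
                      composites=rec.composites,
                      range_volumes=rec.range_volumes, rois=rois,
                      cutout_index=cut)


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Run the full chain on every case and assemble the analysis tables."""
    t0 = time.time()
    log: list[dict] = []
    ss = np.random.SeedSequence(cfg.seed)
    case_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
                  ss.spawn(len(cfg.cases) + 1)]

    # amplitude-veto normalization: each sector's channel energies are
    # referenced to the sector's median processed-channel energy
    calib_ref = "auto" if cfg.psd_calibration else None

    case_results = []
    rows = []
    for case, seed in zip(cfg.cases, case_seeds):
        t = time.time()
        res = run_case(case, cfg, seed, calib_ref)
        for r in res.rois:
            vol = res.composites[cfg.analysis_volume]
            feats = radiomics.feature_vector(vol.data, r.mask)
            rows.append(_assemble_row(case, r, feats))
        log.append({"stage": "case", "breast_id": case.breast_id,
                    "mode": res.mode.value, "rule": res.mode_rule,
                    "n_rois": len(res.rois),
                    "cutout_index": res.cutout_index,
                    "seconds": round(time.time() - t, 2)})
        case_results.append(res)

    feature_table = pd.DataFrame(rows)
    sep = None
    fp = None
    if not feature_table.empty:
        has = feature_table["label"].value_counts()
        if has.get("malignant", 0) >= 2 and has.get("benign", 0) >= 2:
            sep = separability_table(feature_table)
            n_healthy = sum(1 for c in cfg.cases if c.histology == "healthy")
            if n_healthy > 0:
                fp = fp_workflow(feature_table, n_healthy)
    log.append({"stage": "done", "seconds": round(time.time() - t0, 2),
                "n_rows": len(feature_table)})

    result = RunResult(cases=case_results, feature_table=feature_table,
                       separability=sep, fp_report=fp, log=log)
    if cfg.outdir:
        write_outputs(result, cfg)
    return result


def write_outputs(result: RunResult, cfg: RunConfig) -> None:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    ft = result.feature_table
    if not ft.empty:
        lead = [c for c in FEATURE_CSV_LEAD if c in ft.columns]
        rest = [c for c in ft.columns if c not in lead]
        ft[lead + rest].to_csv(out / "features.csv", index=False)
    if result.separability is not None:
        format_separability(result.separability).to_csv(
            out / "separability.csv", index=False)
    if result.fp_report is not None:
        fp = result.fp_report
        (out / "fp_report.json").write_text(json.dumps(
            {"n_healthy_breasts": fp.n_healthy_breasts,
             "n_unspecified": fp.n_unspecified,
             "n_confused": fp.n_confused,
             "fp_rate_percent": fp.fp_rate,
             "findings": fp.findings}, indent=2, default=str))
    if not ft.empty:
        scatter_cols = ["Breast_ID", "label", "First-order Entropy",
                        "GLCM Joint Entropy", "NGTDM Strength"]
        ft[[c for c in scatter_cols if c in ft.columns]].to_csv(
            out / "scatter3d.csv", index=False)
    for res in result.cases:
        for kind, vol in res.composites.items():
            vol.save(out / f"{res.breast_id}_{kind}.nii")
            (out / f"{res.breast_id}_{kind}.json").write_text(json.dumps(
                {"provenance": vol.provenance, "mode": res.mode.value,
                 "cutout_index": res.cutout_index}, default=str))
        lab = label_volume(res.rois, res.composites[cfg.analysis_volume])
        lab.save(out / f"{res.breast_id}_roi_labels.nii")
    (out / "run_log.jsonl").write_text(
        "\n".join(json.dumps(e, default=str) for e in result.log))
    cfg.outdir, keep = None, cfg.outdir
    try:
        cfg.to_yaml(out / "config.yaml")
    finally:
        cfg.outdir = keep


# ---------------------------------------------------------------------------
# Canonical fixtures
# ---------------------------------------------------------------------------

def generate_fixtures(kind: str, seed: int = 0, **overrides) -> RunConfig:
    """Canonical small study configurations.

    kinds: ``point-scatterer`` (single near-point lesion), ``two-lesion``,
    ``cohort`` (10 malignant-like + 10 benign-like), ``healthy-batch``
    (20 lesion-free breasts with coupling artifacts on).
    """
    if kind == "point-scatterer":
        cases = [BreastCase(
            "B001",
            PhantomSpec(pc_fib=0.35,
                        lesions=(LesionSpec(center=(15.0, 9.0, -41.0),
                                            axes=(1.5, 1.5, 1.5),
                                            contrast=3.0),)),
            histology="benign")]
        cfg = RunConfig(cases=cases, noise_level=0.0, coupling=False,
                        pca=False, psd_calibration=False, n_slices=1,
                        seed=seed)
    elif kind == "two-lesion":
        cases = [BreastCase(
            "B001",
            PhantomSpec(pc_fib=0.35,
                        lesions=(LesionSpec(center=(19.0, 9.0, -41.0),
                                            axes=(1.5, 1.5, 1.5), contrast=3.0),
                                 LesionSpec(center=(-15.0, -11.0, -41.0),
                                            axes=(1.5, 1.5, 1.5), contrast=3.0))),
            histology="benign")]
        cfg = RunConfig(cases=cases, noise_level=0.0, coupling=False,
                        pca=False, psd_calibration=False, n_slices=1,
                        seed=seed)
    elif kind == "cohort":
        rng = np.random.default_rng(seed)
        cases = []
        for i in range(10):
            c = _random_center(rng)
            cases.append(BreastCase(f"M{i:03d}",
                                    PhantomSpec(pc_fib=0.35,
                                                lesions=(malignant_like(c),)),
                                    histology="malignant",
                                    molecular_subtype="Luminal A"))
        for i in range(10):
            c = _random_center(rng)
            cases.append(BreastCase(f"B{i:03d}",
                                    PhantomSpec(pc_fib=0.35,
                                                lesions=(benign_like(c),)),
                                    histology="benign"))
        cfg = RunConfig(cases=cases, seed=seed, grid_n=48, n_freq=24,
                        n_slices=3, ranges=PCFIB_RANGES,
                        persistence_quorum=6, threshold_quantile=0.95)
    elif kind == "healthy-batch":
        rng = np.random.default_rng(seed)
        cases = [BreastCase(f"H{i:03d}", PhantomSpec(pc_fib=0.35),
                            histology="healthy") for i in range(20)]
        cfg = RunConfig(cases=cases, seed=seed, grid_n=48, n_freq=24,
                        n_slices=2, ranges=((20, 50), (30, 60), (40, 70)),
                        persistence_quorum=2, threshold_quantile=0.95)
    else:
        raise ValueError(f"unknown fixture kind: {kind}")
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def _random_center(rng) -> tuple:
    r = rng.uniform(8, 22)
    th = rng.uniform(0, 2 * np.pi)
    z = -1.0 + 2.0 * np.round(rng.uniform(-44, -36) / 2)
    return (float(r * np.cos(th)), float(r * np.sin(th)), float(z))
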