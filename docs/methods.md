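# Methods

This note documents the models, conventions and numerical choices behind
`mwbreast`, and what the synthetic experiments do and do not demonstrate.

## Coordinate and lattice conventions

Right-handed coordinates, z vertical with z = 0 at the examination-table
plane and negative downward. The probe ring (21 probes, equally spaced)
steps vertically in 2 mm increments; its uppermost usable position is 24 mm
below the table. All reconstruction lattices are 2 mm isotropic with
in-plane voxel centers at odd-millimetre coordinates; volume z-planes sit at
odd millimetres between the even-millimetre scan heights, so the triangular
±2 mm slab weighting in `stack_slices` averages the two adjacent slices.
Distances are center-to-center; one voxel is 0.008 mL.

The ring radius (default 100 mm), container size and transition-liquid
dielectric table are not canonical — they are plausible values exposed in
configuration, chosen so a 55 mm-radius pendulous breast fits with margin.

## Media and propagation

Each medium carries a relative permittivity εr ≥ 1 and loss tangent
tanδ ≥ 0 over the 0.8–4.1 GHz band (defaults: transition liquid 38/0.18,
adipose 9/0.13, fibroglandular 42/0.25, skin 38/0.25 — skin-matched liquid,
fibroglandular tissue dominating adipose at every frequency). The lossy
propagation constant uses the transmission-line forms

    α = (2πf/c₀)·√(εr/2·(√(1+tan²δ) − 1))   [Np/m]
    β = (2πf/c₀)·√(εr/2·(√(1+tan²δ) + 1))   [rad/m]

so tanδ = 0 gives α = 0 and β = k₀√εr. The breast interior is the
pc_fib-weighted convex mixture of adipose and fibroglandular values, with
pc_fib ∈ [0,1] the (unknown) fibroglandular fraction. With these defaults
the transition liquid is slightly *more* attenuating per millimetre than a
50% interior mixture — deliberate, since the liquid is lossy by design to
damp multipath.

## Phantoms and the synthetic-data generator

The pendulous envelope is a radius function ρ(θ,z) on a regular grid
(bilinear interpolation, periodic in θ), semi-ellipsoidal by default:
watertight by construction, O(1) inside tests, star-shaped so a straight ray
from outside enters once. Lesions are ellipsoids (default axes 8 mm)
rasterized at the 2 mm lattice; the "malignant-like" preset adds 8-fold
angular spiculation with 3 mm radial roughness and voxelwise contrast
heterogeneity σ = 0.35; the "benign-like" preset is a smooth homogeneous
ellipsoid of the same contrast (2.5× interior background).

Heterogeneity is a spatially **correlated** Gaussian random field (Gaussian
covariance, correlation length 7 mm by default). White voxel noise at the
2 mm scale would be far below the ~13 mm diffraction-limited resolution of
the 0.8–4.1 GHz aperture and could never appear in a reconstructed image;
a correlation length of several millimetres emulates macroscopic
intratumoral variation (necrosis, lobulation) that imaging can in principle
carry. Phantom realization is bitwise reproducible from (spec, seed).

What the generator does **not** emulate: anatomical parenchyma structure
(ductal/vascular trees, background clutter), skin as a distinct shell,
multiple scattering, antenna patterns, patient positioning variability.
Passing end-to-end tests therefore demonstrates the *computational chain's*
behavior under controlled contrast, not clinical performance.

## Forward model

Born-approximation point-scatterer sum over lesion voxels within a ±2 mm
coronal slab per scan height (matching the slice-wise reconstruction; no
cross-slab propagation). Green factors use the straight-ray two-media split
(`ray_path_split`, bisection to machine precision, conserving total
distance exactly) with 1/d spherical spreading. Artifact terms: antenna
coupling, a frequency-smooth common-mode term with ~0.15 ns delay at a
configurable level (default 30 dB) above the strongest lesion echo; a skin
first-reflection term with per-probe envelope-entry delays; an optional
localized fold echo visible only to probes near the fold azimuth. Noise is
circular complex Gaussian scaled to the *scattered-field* RMS, so
`noise_level = 0.1` is a 20 dB echo SNR regardless of the coupling level.
Reciprocity is enforced bitwise before noise; the monostatic diagonal is
unmeasured and stored as zero.

## Preprocessing

- **IDFT**: the measured band is physically one-sided, so the zero-padded
  (4×) inverse DFT is the analytic signal directly; the forward transform
  inverts it to 1e-10.
- **PCA**: the leading SVD component across the sector-context channel
  group (N_PCA = 12 probes default, 10 in CUSTOM2) is subtracted. With a
  dominant common mode this removes the coupling at ≥ 20 dB while retaining
  ≥ 90% of distinct channel echoes; when channel echoes are mutually
  correlated (adjacent probes viewing one lesion) part of their common
  component is also removed — a real cost of the method, mitigated by the
  EMD distance filter that drops the near-antenna residual.
- **EMD**: classic sifting with cubic-spline envelopes through extrema
  (outermost extrema mirrored at the ends), SD stop criterion 0.2, at most
  10 sifting passes per IMF and 10 IMFs. Completeness (ΣIMF + residual =
  input) holds by construction; the residual (monotone trend, not an echo)
  is not re-included after filtering.
- **Distance filter**: each IMF is annotated with the distance of its
  analytic-envelope peak via the transition-liquid velocity (one-way
  d = v·t/2); IMFs peaking below 10 mm are coupling, beyond
  ring-diameter + 2×max-chord are multipath. These cutoffs are ours.
- **Loss compensation** multiplies each kept IMF spectrum by
  exp(α_trans·d_out + α_in·d_in) with the echo's two-way path split at the
  channel's mean skin-entry distance. A single reference pc_fib (default
  50%) is used rather than recompensating per imaging assumption:
  compensation is a smooth scalar gain and per-candidate recompensation
  would multiply preprocessing cost ~17-fold for a second-order effect.
- **Amplitude veto**: a channel whose integrated PSD reaches 5 in
  calibration-normalized units is dropped (unless CUSTOM1). The default
  normalization reference is the sector's median processed-channel energy,
  making "5" mean "five times the nominal channel level of this scan";
  an explicit reference can be supplied instead.

Mode attribution is rule-based on breast volume (< 350 mL → CUSTOM1,
> 1300 mL → CUSTOM2), fold and density flags, superficial-large-lesion
hints; every decision is logged with its triggering rule.

## Imaging

Sub-arrays of N_S = 8 contiguous probes (indices c−3…c+4, wrapping) slide
over all 21 centers. Per frequency, the SVD of the preprocessed 8×8 matrix
gives the signal subspace; its rank is the largest relative singular-value
gap, capped at 4. The pseudospectrum `P(r) = 1/(1 − Σ_signal |⟨u_k,g(r)⟩|²)`
uses unit-norm steering vectors built from the same two-media straight-ray
propagation (phase and attenuation, 1/d spreading) at the assumed pc_fib;
the wideband sector image is the mean of per-frequency unit-max
pseudospectra, restricted to the sector wedge (the 8-probe arc ±10° of
raised-cosine taper). The zeroed monostatic diagonal perturbs the data
matrix off rank-one; empirically localization remains voxel-exact and the
per-sector pc_fib selection is unaffected for wedge-visible scatterers.

Per search range, candidates step every 5 percentage points inclusive; the
best-focused candidate (peak-to-mean of the normalized sector image, ties
toward the range midpoint) is selected per sector. A sector can only judge
the interior assumption through content in its own ~140° wedge — the
recovery experiment therefore uses two diametrically opposite scatterers so
~17 of the 21 sectors see one; the wedge-blind sectors count as misses.
Stitching renormalizes taper weights to a partition of unity (all-zero
sectors excluded); slabs stack with triangular z-weights; the cut-out rule
(envelope cross-section above 90% of the ring aperture, or chest-wall
intrusion) zeroes and flags untrusted upper planes. Composites are
voxelwise means: GLOBAL over all ranges, LOW/HIGH over the ranges entirely
below/above 50%.

## ROI extraction and radiomics

Candidates: Otsu threshold over in-breast voxels (a fixed-quantile override
exists and is used for the synthetic cohorts, whose hazy pseudospectrum
histograms are unimodal and defeat Otsu), morphological opening and closing
with a 1-voxel ball (in-plane disk for volumes thinner than 3 planes),
26-connected components. Persistence: a candidate must reappear (centroid
within 5 mm) in a quorum of the range volumes (6 of 11 by default, scaled
proportionally for reduced range sets). Structural validation: volume
≥ 0.25 mL, solidity ≥ 0.3, CNR ≥ 2 (all configurable; none canonical).
SNR = mean(ROI)/σ(background), CNR = (mean(ROI) − mean(bg))/σ(bg), with the
background the in-breast voxels outside every ROI dilated by 2 voxels.
Solidity counts lattice centers inside the convex hull (plane-equation
test, 1e-9 tolerance), consistently in the ROI filter and the shape
feature.

The 25 radiomic features follow standard (IBSI-style) definitions with
fixed-bin-number 64 quantization over the ROI min–max (hence invariance to
affine intensity rescaling — which also means generator-level heterogeneity
σ alone cannot move texture features; only heterogeneity *relative to other
image structure* can). GLCM: distance 1, the 13 unique 3D directions,
symmetrized, normalized per direction, features averaged over directions.
NGTDM: in-mask 26-neighbor means, ε = 1e-6 guards on coarseness/strength.
Kurtosis is uncorrected (normal → 3). Sphericity uses the marching-cubes
mesh area. Degenerate cases (single voxel, coplanar masks, no valid pairs)
yield NaN flags rather than fabricated values.

## Separability and false positives

Per-feature one-way ANOVA: F from the explicit sums of squares (so zero
within-class variance with unequal means reports F = ∞, p = 0), p from the
F-distribution upper tail. Two classes only (malignant vs benign); displays
round p to 3 decimals. The false-positive workflow retains unspecified
findings with mean intensity ≥ κ (default 0.9) times the patient's dominant
lesion ROI, standardizes the three top texture features on lesion rows
only, assigns each finding to the nearer class centroid, and reports
100·confused/healthy-breasts. The nearest-centroid rule is our quantitative
stand-in for a visual confusability judgement; it is swappable.

## Problem sizes

Defaults used by the canned experiments and the acceptance script: 64×64
voxels/slice (cohort: 48×48), 34 frequencies (cohort: 24), 1–3 slices per
breast, 21 sectors, the full 11-range pc_fib set (cohort pipelines cache
sector images per unique candidate so overlapping ranges are nearly free),
20 noise seeds for the noisy-localization median, 10+10 breasts in the
separability cohort, 1000 label permutations for the type-I calibration.

## Known limitations

- The Born model omits multiple scattering and mutual probe coupling
  beyond the injected common mode; an inverse-crime flavor is unavoidable
  where steering and forward model share the ray approximation.
- MUSIC pseudospectrum intensity is a focusing measure, not a quantitative
  reflectivity map; intensity-based features on the reconstructions carry
  lesion structure only indirectly (via subspace diversity across
  assumptions and sectors).
- Residual coupling after PCA biases blob centroids a few millimetres
  toward the ring axis at the default 30 dB coupling level; ground-truth
  labeling uses a 20 mm association radius accordingly.
- The per-sector pc_fib selection is uninformative in sectors whose wedge
  contains no scatterer; real breasts (scattering parenchyma everywhere)
  do not have this degeneracy.
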