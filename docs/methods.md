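# Methods

This note records the modeling assumptions, parameter choices and numerical
decisions behind qsmkit, and what validation on the built-in phantom does
and does not demonstrate.

## Signal model and conventions

The multi-echo spoiled-GRE signal at echo time TE is modeled per voxel as
M₀·e^(−TE/T2*)·exp(i(2πf·TE + φ₀)), where f = γ̄·ΔB₀·10⁻⁶·B₀ is the field
shift in Hz and φ₀ the TE-independent phase offset. Phase is kept in
radians in the half-open interval [−π, π); stored integer phase is mapped
affinely with the divisor `range + 1 quantization step` so the top and
bottom integer bins do not both land on ±π. The vendor sign flag makes
paramagnetic tissue (positive χ) accumulate positive phase; γ̄ is fixed at
42.577478 MHz/T, and every formula that needs the angular form uses
2π·γ̄ explicitly, so Hz-based and rad-based expressions cannot mix.

Volumes stay in the file's native axis order with the NIfTI affine as the
single source of spatial truth; the main-field direction is expressed in
image axes (derived from the affine on load), which keeps the dipole
kernel correct for oblique slabs.

## Phantom: what it emulates

The default scene is a brain sphere (χ = 0, radius 0.36 of the field of
view, i.e. 23 mm on the 64³/1 mm default grid) containing a +0.1 ppm and a
−0.1 ppm inclusion (radius 0.22·R, T2* 35/60 ms, distinct M₀), plus an air
sphere outside the brain carrying the ~9 ppm tissue–air susceptibility
difference. The air source is placed so the peak background field in the
brain is ~50 Hz at 3 T with inter-voxel phase steps well below π at 1 mm —
the realistic regime near a sinus; a source placed directly against the
brain surface would produce phase gradients beyond π per voxel, which no
spatial unwrapper can resolve and which real protocols avoid by design.
φ₀ is a fixed low-order polynomial (coefficients up to ~1 rad); noise is
complex Gaussian added to the complex signal (so phase noise is
magnitude-dependent and non-Gaussian, as in MR), with SNR defined at unit
brain magnitude; the default SNR is 50. Acquisition defaults follow a
consensus-style 3 T protocol: 5 echoes at TE 5.25 : 5.83 : 28.57 ms,
TR 33 ms, flip 15°, 1 mm isotropic.

Not emulated: microstructural anisotropy and nonlinear phase-in-TE
evolution, flow, coil sensitivities and combination errors, k-space
undersampling, motion. Passing tests therefore demonstrate correctness of
the *reconstruction chain* under linear phase evolution and ideal coil
combination, not robustness to those real-data effects.

The forward field is computed by dipole multiplication in k-space with
2× zero padding per axis (the dipole is long-range; circular convolution
without padding aliases). The ground-truth container stores the total,
tissue and background fields separately, and their sum is exact by
construction.

## Field estimation

The nonlinear fit initializes f from magnitude-weighted Hermitian products
of consecutive echoes and refines (f, φ₀) by Gauss–Newton on wrapped phase
residuals with weights M², up to 30 iterations or step < 1e−10. For
uniform echo spacing the result is a principal value within ±1/(2ΔTE)
(85.8 Hz at ΔTE = 5.83 ms); the aliased map is rewrapped as 2πf·ΔTE and
spatially unwrapped. The noise map is sqrt of the f-variance from the
normal equations; the quality map is its inverse, min–max normalized over
the FOV.

Weighted echo averaging uses w_e = TE_e·M_e² (inverse phase-variance
weighting under high-SNR complex Gaussian noise, scaled by TE; magnitude-
only and uniform weights are available). φ₀, when not supplied, is the
two-echo linear extrapolation to TE = 0. Template unwrapping spatially
unwraps the first echo only and aligns later echoes to the two-echo linear
prediction by per-voxel 2π rounding; this tolerates |φ₀| up to roughly
π/(TE₂/TE₁ − 1) ≈ 3 rad at the default echo spacing.

The spatial unwrapper is exact region growing: a max-heap on quality,
6-connected, seeded at each component's maximum-quality voxel, ties broken
by voxel index so results are bit-reproducible. Disconnected mask
components are internally consistent with unconstrained mutual offsets
(reported via a warning). Laplacian unwrapping is deliberately absent.

## Masking

Mask 1 (built-in path) is Otsu thresholding of the first-echo (or
RSS-combined) magnitude, largest 6-connected component, closing with a
radius-2 ball; an external brain-extraction command can be substituted.
Mask 2 keeps voxels whose inverse noise is ≥ factor × its FOV mean
(factor 1.0 default, 1.2 as the stricter option). Holes are background
components of Mask1∧Mask2 not connected to the volume border
(6-connectivity, which fills thin-necked cavities consistently); Mask 3 is
the filled intersection. Mask 4 erodes Mask 3 (default 1 voxel, matching
V-SHARP's edge loss; 0 is appropriate after PDF) and optionally
re-excludes the holes for inversion; the display mask is the eroded mask
with holes filled. Two display conventions circulate (eroded mask with
vs without holes); qsmkit defaults to holes filled for display and exposes
both.

## Background-field removal

V-SHARP applies (δ − SMV) high-pass filtering with, per voxel, the largest
sphere radius (default 12→1 mm in 1 mm steps) fitting inside Mask 3, then
inverts (δ − SMV) of the largest radius by thresholded deconvolution
(frequencies with |1 − SMV(k)| < 0.05 zeroed). The SMV kernel is uniform
over the discretized sphere, coefficients summing to 1. The valid mask is
where the smallest radius fits (≈1-voxel erosion). Deconvolving with the
largest radius only (rather than per-radius) was chosen because the
interior — where quantitative values matter — is filtered with that
radius; the choice is recorded in provenance.

PDF fits an effective source distribution supported outside Mask 3 to the
in-mask field by weighted least squares (weights = the echo-combination
quality map, binary fallback), solved by conjugate gradients on the normal
equations (tolerance 1e−6, cap 200 iterations; hitting the cap warns and
returns the best iterate — with the 9 ppm contrast the residual is already
below 1% there). Neither method is followed by polynomial detrending by
default; an optional helper exists.

Known, quantified limitation: SHARP-type filtering removes slowly varying
components of the *tissue* field along with the background. On this
phantom's 23 mm brain the 12 mm maximum radius is large relative to the
object, and the inner-sphere mean χ after the full chain is attenuated by
~9% from this stage alone (measured by running the inversion on the true
tissue field, error 1.4%, vs on the V-SHARP output, error ~9.5%). In vivo,
with a ~70 mm brain, the same radii clip far less. Noise at SNR 50 adds
~2%, so end-to-end inner-sphere recovery lands at 11–12%. This is the
method's genuine behavior at this geometry, not a solver artifact, and it
is reported as-measured by `scripts/acceptance.py`.

## Dipole inversion

The kernel is the continuous-k form D(k) = 1/3 − (k·b̂)²/|k|² on the
discrete Fourier grid with D(0) = 0 — the arbitrary constant is fixed at
zero, consistent with relative susceptibility and explicit referencing.
Fields are converted Hz → ppm before inversion so λ operates on ppm-scale
magnitudes.

TKD replaces D by sign(D)·t where |D| < t (t = 0.2 default, sign(0) → +);
it trades ~20–25% amplitude loss at a point source for stability and
serves as the unregularized baseline.

TV inversion minimizes ‖w(ΔBt − d*χ)‖² + λ·TV(χ) (isotropic TV, circular
forward differences with matching k-space symbols) by ADMM with two
splittings — y = d*χ (quadratic penalty 1.0) and z = ∇χ (penalty
μ = mu_consistency) — so every subproblem is diagonal voxelwise or in
k-space. Defaults λ = 5·10⁻⁴, μ = 0.05, ≤100 outer iterations, stop at
relative update < 1e−3. The objective is monitored: sustained small
(<5%) increases mean the splitting reached its limit cycle and the best
iterate is returned; sustained larger increases raise a divergence error
with diagnostics. The solver is deterministic; repeated runs are
bit-identical. The pipeline's data weight is the quality map restricted to
the inversion mask, clipped at its 99th percentile and normalized to
max 1 (an unnormalized weight would silently rescale λ).

L-curve selection runs the TV solver over a λ grid, records
(log‖residual‖, log TV) and returns the λ of maximum three-point discrete
curvature (interior points only; a 3-point grid returns the middle value
with a warning).

## Referencing, analysis, QC

Maps must be referenced before ROI analysis (enforced); the default
reference is the whole valid mask — stable, and the convention implicit in
SHARP-type pipelines whose output mean is already ~0. Re-referencing
between regions is exact subtraction on the shared scale; differences
between ROI means are invariant to the reference choice. ROI statistics
use only roi ∩ valid voxels and report exclusion counts, so zero-filled
invalid voxels can never bias means. QC flags are heuristics with
configurable thresholds: |ROI mean| > 0.3 ppm (the ±0.2 ppm display
window plus margin) or cohort z > 3 (cohort screening needs ≥5 subjects),
an exact-zero spike inside the valid mask (masking fault), and >1% of
voxels with |χ| > 0.5 ppm (streaking).

## Protocol calculators and reporting

Ernst angle acos(e^(−TR/T1)) with T1 presets 650/850/1220 ms at
1.5/3/7 T; echo-train checks require ≥3 echoes and last TE ≥ target T2*
(putamen presets 55/30/16 ms), warning within 10% below — the warn band
exists because sensible protocols (e.g. last TE 28.57 ms vs 30 ms) sit
just under the target; fat–water shift uses 3.5 ppm × γ̄ × B₀ / bandwidth
(two pixels at 220 Hz/pixel, 3 T). The TR check only verifies
TR > last TE + a configurable rewinder margin, since true minimum TR is
hardware-dependent. The reporting bundle lists every essential hardware,
sequence and pipeline item — parameter values included even at defaults —
flags missing essentials rather than raising, and emits a ready-to-paste
methods paragraph. Susceptibility images should be displayed in linear
grayscale, windowed to [−0.2, +0.2] ppm, through the eroded mask.

## Problem sizes and determinism

The validation grid is 64³ at 1 mm (full pipeline ≈ 6 s on one CPU; unit
tests use 32³). All randomness flows from a single integer seed through
`numpy.random.default_rng`; the pipeline, the phantom and the TV solver
are bit-reproducible given config + seed. Intermediates are written as
NIfTI for visual inspection when an output directory is given, and the
provenance record carries every parameter needed to regenerate the
report.
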