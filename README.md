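# qsmkit

Quantitative susceptibility mapping (QSM) reconstruction for brain
multi-echo gradient-echo (GRE) MRI, with a built-in numerical phantom so the
whole chain can be exercised and validated without any external data.

QSM computes the tissue magnetic susceptibility χ(r), in parts per million,
from the GRE signal phase. The phase encodes the field perturbation ΔB(r),
which is the convolution of χ(r) with the unit magnetic dipole response

    ΔB(r) = d(r) * χ(r),      d(r) = (3 cos²θ − 1) / (4π r³),

or, in the spatial-frequency domain, multiplication with
D(k) = 1/3 − (k·b̂)²/|k|². D vanishes on the magic-angle cone (θ ≈ 54.7°),
so the inversion is ill-posed and must be regularized. Getting from raw
phase to χ requires a chain of steps, each of which this package
implements:

1. **Phase handling** — rescaling stored phase to radians in [−π, π),
   vendor sign conventions, NIfTI I/O with JSON metadata sidecars.
2. **Field estimation** — per-voxel nonlinear complex fitting of
   M(TE)·exp(i(2πf·TE + φ₀)) over ≥3 echoes (with noise and quality maps),
   or weighted echo averaging after template unwrapping and explicit
   φ₀ removal.
3. **Exact spatial unwrapping** — quality-guided region growing; the output
   differs from the input by integer multiples of 2π at every voxel.
4. **Masking** — the four-stage workflow: initial brain mask, reliable-phase
   mask (inverse noise thresholded at its FOV mean), hole-filled mask for
   background removal, eroded mask for inversion and display.
5. **Background-field removal** — V-SHARP (spherical-mean-value filtering
   with radii 12→1 mm and truncated deconvolution) or PDF (projection onto
   dipole fields by noise-weighted least squares).
6. **Dipole inversion** — total-variation-regularized inversion
   argmin‖w(ΔBt − d*χ)‖² + λ·TV(χ) solved by alternating-direction
   splitting (defaults λ = 5·10⁻⁴, gradient-consistency μ = 0.05), a
   thresholded-k-space-division (TKD) baseline, and L-curve selection of λ.
7. **Referencing and analysis** — internal-region referencing (whole brain
   by default), re-referencing arithmetic, ROI statistics restricted to
   valid voxels, and heuristic QC screening.
8. **Protocol calculators and reporting** — Ernst angle acos(e^(−TR/T1)),
   echo-train checks against tissue T2*, fat–water shift per bandwidth, and
   a reporting bundle that lists every essential acquisition/pipeline item.

The phantom module generates a geometric susceptibility scene (brain sphere
with ±0.1 ppm inclusions and an external ~9 ppm air source), computes its
exact forward fields, and simulates the multi-echo acquisition with complex
Gaussian noise — so every intermediate product has a known ground truth.

## Worked example

Run the full default chain on the built-in phantom (no input data needed):

```bash
qsm run --phantom default --seed 1 --out run1
```

which prints the ROI report of the reconstructed, whole-brain-referenced
susceptibility map:

```
     label      mean_ppm  std_ppm  n_voxels  n_excluded
wholebrain -1.543316e-19 0.013264     46040           0
```

and writes every intermediate (field maps, masks, tissue field, χ map,
provenance, reporting bundle) to `run1/`. The whole-brain mean is zero by
construction of the referencing step; the standard deviation reflects the
±0.1 ppm inclusions plus noise. The same chain is available in Python:

```python
import qsmkit as qk
result = qk.run_pipeline(qk.PipelineConfig(seed=1), phantom_preset="default")
print(result.roi_report.to_frame())
print(result.report.methods_text())
```

Library calculators give the protocol numbers directly, e.g.
`qk.ernst_angle(33e-3, field_strength=3.0)` → 15.9°, and
`qk.fatwater_shift_pixels(220.0, 3.0)` → (2.03, 2) pixels.

## Layout

`src/qsmkit/` — `io` (containers, NIfTI, phase scaling), `phantom`,
`fieldmap` (fitting + unwrapping), `masking`, `background`, `inversion`,
`analysis`, `protocol`, `pipeline`, `cli`. See `docs/methods.md` for the
modeling choices, parameter meanings and known limitations.
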